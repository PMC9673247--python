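"""Synthetic multi-species fruit-development datasets with known truth.

The generator emulates the structure of a five-species pericarp study: two
dry-fruited and three fleshy-fruited species sampled at three shared
developmental stages (cell division, cell expansion, and the transition to
maturity/ripening) with ~3 replicates per stage.  Counts are negative
binomial with a mean-dependent dispersion trend ``alpha = a0 + a1/mu`` and
per-sample depth (size) factors; gene classes are planted:

- ``null``             — flat expression;
- ``core``             — one developmental trajectory shared by all species;
- ``divergent``        — trajectories conserved within but differing
  between fruit types (the accessory pattern);
- ``species_specific`` — an independent trajectory per species.

Trajectories are built in the same natural-spline basis used for fitting
(well-specified case) or, optionally, as sinusoids to probe robustness to
basis misspecification.  An orthogroup table with paralogous and
missing-species decoys, and GO annotations with one planted enriched term,
accompany the counts.  All randomness flows through a counter-based Philox
generator keyed by the config seed, so output is bit-reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .orthology import OrthogroupTable
from .splines import natural_spline_basis

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "make_truth",
    "simulate_counts",
    "simulate_orthogroups",
    "simulate_annotations",
    "simulate_dataset",
]

GENE_CLASSES = ("null", "core", "divergent", "species_specific")

DEFAULT_SPECIES = (
    ("tomato", "fleshy"),
    ("wild_tomato", "fleshy"),
    ("melon", "fleshy"),
    ("desert_tobacco", "dry"),
    ("arabidopsis", "dry"),
)
DEFAULT_STAGES = (("2", 2.0), ("3", 3.0), ("Tr", 4.0))


@dataclass
class SimulationConfig:
    """Study design and effect sizes for one simulated dataset."""

    species: tuple = DEFAULT_SPECIES  # (label, fruit_type) pairs
    stages: tuple = DEFAULT_STAGES  # (stage_label, time) pairs
    replicates: int = 3
    n_genes: int = 1000
    proportions: dict = field(
        default_factory=lambda: {
            "null": 0.6,
            "core": 0.2,
            "divergent": 0.2,
            "species_specific": 0.0,
        }
    )
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    amplitude: float = 2.0  # planted trajectory range / divergence, log2 units
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    dispersion_jitter_sd: float = 0.3
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    trajectory_basis: str = "spline"  # or "sine"
    n_paralog_decoys: int = 50
    n_missing_decoys: int = 50
    go_n_terms: int = 50
    go_depth: int = 3
    go_planted_fraction: float = 0.8
    go_background_fraction: float = 0.1
    go_planted_class: str = "core"
    seed: int = 0

    def __post_init__(self):
        total = sum(self.proportions.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.seed is None:
            raise ValueError("seed is required")
        if self.trajectory_basis not in ("spline", "sine"):
            raise ValueError("trajectory_basis must be 'spline' or 'sine'")

    @property
    def stage_times(self) -> np.ndarray:
        return np.array([t for _, t in self.stages], dtype=float)

    @property
    def spline_df(self) -> int:
        return min(len(self.stages) - 1, 3)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(key=self.seed + (stream << 20)))


@dataclass
class GroundTruth:
    """Planted per-orthogene truth.

    ``trajectories[og]`` maps a scope key to a log2 trajectory over the
    config stages: ``'all'`` for core genes, the fruit type for divergent
    genes, the species label for species-specific genes; null genes have an
    empty dict (flat profiles).
    """

    orthogene_ids: list[str]
    labels: pd.Series  # orthogene -> class
    baselines: pd.Series  # orthogene -> baseline log2 mean
    dispersions: pd.Series  # orthogene -> NB alpha
    trajectories: dict[str, dict[str, np.ndarray]]


def _scaled_trajectory(rng, basis_values: np.ndarray, amplitude: float) -> np.ndarray:
    """Random trajectory over stages with range exactly ``amplitude``."""
    n_stage, df = basis_values.shape
    for _ in range(100):
        beta = rng.normal(size=df)
        traj = basis_values @ beta
        rng_span = traj.max() - traj.min()
        if rng_span > 1e-8:
            return traj * (amplitude / rng_span)
    return np.zeros(n_stage)


def _sine_trajectory(rng, times: np.ndarray, amplitude: float) -> np.ndarray:
    span = times.max() - times.min()
    phase = rng.uniform(0, 2 * np.pi)
    period = rng.uniform(1.0, 2.0) * span
    traj = np.sin(2 * np.pi * (times - times.min()) / period + phase)
    rng_span = traj.max() - traj.min()
    if rng_span < 1e-8:
        return np.zeros_like(times)
    return traj * (amplitude / rng_span)


def make_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted gene classes, baselines, dispersions, trajectories.

    Class counts are the rounded proportions (remainder to ``null``);
    everything is deterministic given the config seed.
    """
    rng = config.rng(stream=1)
    n = config.n_genes
    counts = {c: int(round(config.proportions.get(c, 0.0) * n)) for c in GENE_CLASSES}
    counts["null"] += n - sum(counts.values())
    labels = np.concatenate(
        [np.repeat(c, counts[c]) for c in GENE_CLASSES if counts[c] > 0]
    )
    rng.shuffle(labels)
    ids = [f"OG{i:05d}" for i in range(n)]

    times = config.stage_times
    basis = natural_spline_basis(times, config.spline_df)
    B = basis.basis_values

    def draw(amplitude: float) -> np.ndarray:
        if config.trajectory_basis == "sine":
            return _sine_trajectory(rng, times, amplitude)
        return _scaled_trajectory(rng, B, amplitude)

    baselines = rng.uniform(*config.baseline_log2_range, size=n)
    mu_bar = 2.0**baselines
    alpha = (config.dispersion_a0 + config.dispersion_a1 / mu_bar) * np.exp(
        rng.normal(0.0, config.dispersion_jitter_sd, size=n)
    )

    fruit_types = sorted({ft for _, ft in config.species})
    species_labels = [sp for sp, _ in config.species]
    trajectories: dict[str, dict[str, np.ndarray]] = {}
    for og, lab in zip(ids, labels):
        if lab == "null":
            trajectories[og] = {}
        elif lab == "core":
            trajectories[og] = {"all": draw(config.amplitude)}
        elif lab == "divergent":
            base = draw(config.amplitude)
            delta = draw(config.amplitude)
            # divergence between fruit types = amplitude in max-norm
            peak = np.abs(delta).max()
            if peak > 0:
                delta = delta * (config.amplitude / peak)
            trajectories[og] = {
                ft: base + (0.5 if i else -0.5) * delta
                for i, ft in enumerate(fruit_types)
            }
        else:  # species_specific
            trajectories[og] = {sp: draw(config.amplitude) for sp in species_labels}
    return GroundTruth(
        orthogene_ids=ids,
        labels=pd.Series(labels, index=ids, name="class"),
        baselines=pd.Series(baselines, index=ids, name="baseline_log2"),
        dispersions=pd.Series(alpha, index=ids, name="alpha"),
        trajectories=trajectories,
    )


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SimulationConfig
    truth: GroundTruth
    matrices: dict[str, ExpressionMatrix]
    metadata: pd.DataFrame  # all species' samples
    orthogroups: OrthogroupTable
    size_factors: pd.Series  # true per-sample depth factors
    obo_text: str | None = None
    annotation_text: str | None = None
    planted_term: str | None = None


def _species_metadata(config: SimulationConfig, species: str, fruit_type: str) -> pd.DataFrame:
    rows = []
    for stage_label, time in config.stages:
        for rep in range(1, config.replicates + 1):
            rows.append(
                {
                    "sample_id": f"{species}_s{stage_label}_r{rep}",
                    "species": species,
                    "fruit_type": fruit_type,
                    "stage_label": stage_label,
                    "time": float(time),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> SimulatedDataset:
    """NB counts for every species/sample given the planted truth.

    ``mu = size_factor * 2 ** (baseline + trajectory(stage))`` with the
    gene's dispersion; per-sample size factors are log-uniform in the
    configured range.
    """
    rng = config.rng(stream=2)
    stage_index = {lab: i for i, (lab, _) in enumerate(config.stages)}
    matrices: dict[str, ExpressionMatrix] = {}
    metas = []
    sfs = []
    n = config.n_genes
    base_mu = 2.0 ** truth.baselines.to_numpy()
    alpha = truth.dispersions.to_numpy()
    for species, fruit_type in config.species:
        meta = _species_metadata(config, species, fruit_type)
        lo, hi = config.size_factor_range
        sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(meta)))
        # log2 trajectory value per gene x sample
        logfc = np.zeros((n, len(meta)))
        for g, og in enumerate(truth.orthogene_ids):
            traj = truth.trajectories[og]
            if not traj:
                continue
            if "all" in traj:
                t = traj["all"]
            elif fruit_type in traj:
                t = traj[fruit_type]
            elif species in traj:
                t = traj[species]
            else:
                continue
            logfc[g] = t[[stage_index[s] for s in meta["stage_label"]]]
        mu = sf[None, :] * base_mu[:, None] * 2.0**logfc
        if np.all(alpha <= 0):
            counts = rng.poisson(mu)
        else:
            a = np.maximum(alpha, 1e-12)[:, None]
            shape = 1.0 / a
            lam = rng.gamma(shape, a * mu)
            counts = rng.poisson(lam)
        gene_ids = pd.Index([f"{species}_g{i:05d}" for i in range(n)])
        matrices[species] = ExpressionMatrix(gene_ids, meta, counts.astype(np.int64))
        metas.append(meta)
        sfs.append(pd.Series(sf, index=meta["sample_id"].to_numpy()))
    ortho = simulate_orthogroups(config)
    return SimulatedDataset(
        config=config,
        truth=truth,
        matrices=matrices,
        metadata=pd.concat(metas, ignore_index=True),
        orthogroups=ortho,
        size_factors=pd.concat(sfs),
    )


def simulate_orthogroups(config: SimulationConfig) -> OrthogroupTable:
    """Orthogroup table: the universal single-copy groups plus decoys.

    Decoys are paralogous groups (two genes in one species) and
    missing-species groups; ``filter_single_copy`` must remove exactly the
    decoys.  Gene IDs embed the species label and are unique table-wide.
    """
    rng = config.rng(stream=3)
    species = [sp for sp, _ in config.species]
    groups: dict[str, dict[str, list[str]]] = {}
    for i in range(config.n_genes):
        groups[f"OG{i:05d}"] = {sp: [f"{sp}_g{i:05d}"] for sp in species}
    k = config.n_genes
    for j in range(config.n_paralog_decoys):
        og = f"OG{k + j:05d}"
        dup_sp = species[int(rng.integers(len(species)))]
        groups[og] = {
            sp: (
                [f"{sp}_pa{j:04d}", f"{sp}_pb{j:04d}"]
                if sp == dup_sp
                else [f"{sp}_pa{j:04d}"]
            )
            for sp in species
        }
    k += config.n_paralog_decoys
    for j in range(config.n_missing_decoys):
        og = f"OG{k + j:05d}"
        gone = species[int(rng.integers(len(species)))]
        groups[og] = {
            sp: ([] if sp == gone else [f"{sp}_m{j:04d}"]) for sp in species
        }
    return OrthogroupTable(species_list=species, groups=groups)


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[str, str, str]:
    """Mini ontology plus gene annotations with one planted enriched term.

    Returns ``(obo_text, annotation_tsv_text, planted_term_id)``.  The DAG
    has the configured depth with each non-root term attached to one parent
    on the level above; the planted term annotates the configured fraction
    of the planted class and the background fraction of other genes.
    Deterministic given the seed (identical text bytes).
    """
    if config.go_n_terms < 1:
        raise ValueError("go_n_terms must be >= 1")
    rng = config.rng(stream=4)
    n_terms = config.go_n_terms
    depth = max(config.go_depth, 1)
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    levels = [0] + [1 + int(rng.integers(depth)) for _ in range(n_terms - 1)]
    parents: dict[str, str | None] = {term_ids[0]: None}
    for i in range(1, n_terms):
        shallower = [j for j in range(i) if levels[j] == levels[i] - 1]
        if not shallower:
            shallower = [0]
            levels[i] = 1
        parents[term_ids[i]] = term_ids[shallower[int(rng.integers(len(shallower)))]]
    # planted term: a deepest term
    deepest = max(levels[1:], default=0)
    candidates = [term_ids[i] for i in range(n_terms) if levels[i] == deepest and i > 0]
    planted = candidates[0] if candidates else term_ids[0]

    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: synthetic-go\n")
    for i, t in enumerate(term_ids):
        buf.write(f"\n[Term]\nid: {t}\nname: synthetic term {i}\nnamespace: biological_process\n")
        if parents[t] is not None:
            buf.write(f"is_a: {parents[t]} ! synthetic parent\n")
    obo_text = buf.getvalue()

    in_class = (truth.labels == config.go_planted_class).to_numpy()
    annot_lines = ["gene_id\tgo_terms"]
    non_root = term_ids[1:] or term_ids
    for g, og in enumerate(truth.orthogene_ids):
        terms = set()
        p = config.go_planted_fraction if in_class[g] else config.go_background_fraction
        if rng.random() < p:
            terms.add(planted)
        for t in non_root:
            if t != planted and rng.random() < 0.05:
                terms.add(t)
        annot_lines.append(f"{og}\t{','.join(sorted(terms))}")
    annotation_text = "\n".join(annot_lines) + "\n"
    return obo_text, annotation_text, planted


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Truth, counts, orthogroups and GO annotations in one call."""
    truth = make_truth(config)
    ds = simulate_counts(truth, config)
    obo, annot, planted = simulate_annotations(config, truth)
    ds.obo_text, ds.annotation_text, ds.planted_term = obo, annot, planted
    return ds
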
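"""Differential-expression testing surface: BH adjustment and the
core/accessory classification rule.

Three nested models are compared per orthogene:

- **Model 0** (noise): intercept only — expression does not change over
  development;
- **Model 1** (spline): one shared developmental trajectory, blind to
  species and fruit type;
- **Model 2** (spline-by-group): a separate trajectory per group
  (fruit type, or species for within-family comparisons).

A gene is called **divergent** (accessory) when Model 2 beats both the noise
model and Model 1 — i.e. group-specific trajectories are needed *and* the
gene changes between at least two stages.  A gene is **conserved** (core)
when Model 1 beats noise but Model 2 adds nothing.  Everything else is
non-DE.  Calls are made on Benjamini–Hochberg adjusted p-values at
FDR < 0.01 by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignMatrix, build_design
from .dispersion import DispersionSet, estimate_dispersions
from .glm import LRTResult, nested_lrt
from .normalization import size_factors
from .splines import natural_spline_basis

__all__ = [
    "adjust_bh",
    "classify",
    "lrt_table",
    "run_nested_comparison",
    "default_spline_df",
    "CLASS_LABELS",
]

CLASS_LABELS = ("non_de", "conserved_de", "divergent_de")


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the number of tests
    ``m``.  The output is order-preserving (monotone in the input) and
    satisfies ``padj >= p`` elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    padj = np.full(p.shape, np.nan)
    ps = p[finite]
    m = ps.size
    if m == 0:
        return padj
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(monotone, 1.0)
    padj[finite] = out
    return padj


def lrt_table(results: list[LRTResult], adjust: bool = True) -> pd.DataFrame:
    """Assemble LRT results into a table, BH-adjusting the p-values."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "stat": [r.stat for r in results],
            "df": [r.df for r in results],
            "pvalue": [r.p for r in results],
        }
    )
    if adjust:
        df["padj"] = adjust_bh(df["pvalue"].to_numpy())
    return df


def classify(
    lrt_m1_vs_m0: pd.DataFrame,
    lrt_m2_vs_m0: pd.DataFrame,
    lrt_m2_vs_m1: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Label genes non-DE / conserved / divergent from three nested LRTs.

    ``divergent_de`` requires both ``padj(M2 vs M0) < alpha`` (the gene
    changes between at least two stages under the group-aware model) and
    ``padj(M2 vs M1) < alpha`` (group-specific trajectories genuinely beat
    the shared one).  ``conserved_de`` requires ``padj(M1 vs M0) < alpha``
    without the divergence condition.  Labels are mutually exclusive and
    exhaustive over the tested genes.
    """
    tables = {"m1_vs_m0": lrt_m1_vs_m0, "m2_vs_m0": lrt_m2_vs_m0, "m2_vs_m1": lrt_m2_vs_m1}
    genes = lrt_m1_vs_m0["gene_id"].to_numpy()
    for name, tab in tables.items():
        if not np.array_equal(np.sort(tab["gene_id"].to_numpy()), np.sort(genes)):
            raise ValueError(f"gene set of {name} does not match m1_vs_m0")
    idx = {
        name: tab.set_index("gene_id").loc[genes, "padj"].to_numpy()
        for name, tab in tables.items()
    }
    divergent = (idx["m2_vs_m0"] < alpha) & (idx["m2_vs_m1"] < alpha)
    conserved = ~divergent & (idx["m1_vs_m0"] < alpha)
    label = np.where(divergent, "divergent_de", np.where(conserved, "conserved_de", "non_de"))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "label": label,
            "padj_m1_vs_m0": idx["m1_vs_m0"],
            "padj_m2_vs_m0": idx["m2_vs_m0"],
            "padj_m2_vs_m1": idx["m2_vs_m1"],
        }
    )


def default_spline_df(n_stages: int) -> int:
    """Default spline dimension: ``min(n_stages - 1, 3)``."""
    return min(n_stages - 1, 3)


def run_nested_comparison(
    counts: np.ndarray,
    gene_ids,
    samples: pd.DataFrame,
    group_field: str | None = "fruit_type",
    spline_df: int | None = None,
    alpha: float = 0.01,
    min_total_count: int = 10,
    shape_only: bool = False,
    sf: np.ndarray | None = None,
    per_species_sf: bool = False,
    refine_sf: bool = True,
) -> dict:
    """Run the full Model 0 / 1 / 2 comparison on one count matrix.

    Dispersions are estimated once under the fullest design of the
    comparison and shared by every nested fit.  Genes with total count below
    ``min_total_count`` are excluded from testing and reported as untested.
    With ``refine_sf`` (the default), the whole comparison is run twice:
    size factors are re-estimated on the genes the first pass called non-DE
    before the final pass.  Median-of-ratios assumes most genes unchanged,
    so when a sizable fraction of genes shares stage-dependent trajectories
    the reference tilts stage-dependently; restricting it to apparently
    stable genes removes that bias.
    With ``shape_only=True`` the group main effect joins the reduced model
    of the divergence test, so pure magnitude shifts between groups no
    longer count as divergent.

    Returns a dict with the three LRT tables (``m1_vs_m0``, ``m2_vs_m0``,
    ``m2_vs_m1``; the latter two ``None`` when ``group_field is None``), the
    ``classification`` table (or the Model-1 DE table for ungrouped runs),
    ``size_factors``, ``dispersions``, the spline ``basis`` and designs.
    """
    counts = np.asarray(counts)
    gene_ids = np.asarray(list(gene_ids))
    times = np.unique(samples["time"].to_numpy(dtype=float))
    if len(times) < 2:
        raise ValueError("need at least two distinct stages/times")
    if spline_df is None:
        spline_df = default_spline_df(len(times))
    basis = natural_spline_basis(times, spline_df)

    design0 = build_design(samples, None, "noise")
    design1 = build_design(samples, basis, "spline")
    if sf is None:
        if per_species_sf:
            sf = np.empty(counts.shape[1])
            for sp in samples["species"].unique():
                mask = (samples["species"] == sp).to_numpy()
                sf[mask] = size_factors(counts[:, mask])
        else:
            sf = size_factors(counts)
    sf = np.asarray(sf, dtype=float)

    if refine_sf:
        first = run_nested_comparison(
            counts,
            gene_ids,
            samples,
            group_field=group_field,
            spline_df=spline_df,
            alpha=alpha,
            min_total_count=min_total_count,
            shape_only=shape_only,
            sf=sf,
            refine_sf=False,
        )
        cls = first["classification"]
        stable = cls.loc[cls["label"] == "non_de", "gene_id"].to_numpy()
        # refine only when enough apparently stable genes support a reference
        if len(stable) >= max(50, 0.2 * len(gene_ids)):
            idx = pd.Index(gene_ids).get_indexer(stable)
            try:
                sf = size_factors(counts[idx])
            except ValueError:
                return first
        else:
            return first

    tested = counts.sum(axis=1) >= min_total_count
    c_t = counts[tested]
    g_t = gene_ids[tested]

    out: dict = {
        "size_factors": sf,
        "basis": basis,
        "tested": tested,
        "gene_ids": gene_ids,
        "alpha": alpha,
    }

    if group_field is None:
        disp = estimate_dispersions(c_t, design1, sf)
        res10 = nested_lrt(c_t, g_t, design1, design0, sf, disp.final)
        tab10 = lrt_table(res10)
        tab10["label"] = np.where(tab10["padj"] < alpha, "de", "non_de")
        out.update(
            m1_vs_m0=tab10, m2_vs_m0=None, m2_vs_m1=None,
            classification=_with_untested(tab10, gene_ids, tested, de_only=True),
            dispersions=disp, designs={"m0": design0, "m1": design1},
        )
        return out

    design2 = build_design(samples, basis, "spline_by_group", group_field)
    disp = estimate_dispersions(c_t, design2, sf)
    res10 = nested_lrt(c_t, g_t, design1, design0, sf, disp.final)
    res20 = nested_lrt(c_t, g_t, design2, design0, sf, disp.final)
    if shape_only:
        # reduced model keeps the group main effect: magnitude-only shifts
        # between groups do not count as divergence
        cols = [
            i
            for i, name in enumerate(design2.columns)
            if ":" not in name
        ]
        design1g = DesignMatrix(
            "spline",
            tuple(design2.columns[i] for i in cols),
            design2.values[:, cols],
        )
        res21 = nested_lrt(c_t, g_t, design2, design1g, sf, disp.final)
    else:
        res21 = nested_lrt(c_t, g_t, design2, design1, sf, disp.final)
    tab10, tab20, tab21 = lrt_table(res10), lrt_table(res20), lrt_table(res21)
    cls = classify(tab10, tab20, tab21, alpha=alpha)
    out.update(
        m1_vs_m0=tab10,
        m2_vs_m0=tab20,
        m2_vs_m1=tab21,
        classification=_with_untested(cls, gene_ids, tested),
        dispersions=disp,
        designs={"m0": design0, "m1": design1, "m2": design2},
    )
    return out


def _with_untested(
    table: pd.DataFrame, gene_ids: np.ndarray, tested: np.ndarray, de_only: bool = False
) -> pd.DataFrame:
    """Append untested (low-count) genes with label 'untested' and NaN stats."""
    if tested.all():
        return table.reset_index(drop=True)
    untested = pd.DataFrame({"gene_id": gene_ids[~tested]})
    for col in table.columns:
        if col not in ("gene_id", "label"):
            untested[col] = np.nan
    untested["label"] = "untested"
    combined = pd.concat([table, untested], ignore_index=True)
    order = pd.Index(gene_ids, name="gene_id")
    combined = combined.set_index("gene_id").loc[order].reset_index()
    return combined
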
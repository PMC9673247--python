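"""Pipeline orchestration: the study's four analyses as reusable runs.

Each runner takes in-memory inputs (count matrices, metadata, orthogroup
tables, optional GO resources), executes the testing / clustering /
enrichment chain, and returns a :class:`RunReport` whose tables can be
written to a directory as deterministic TSVs with a JSON provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import DianaClustering, pca_summary, profile_matrix
from .data import ExpressionMatrix
from .de import CLASS_LABELS
from .go import GoDag, enrichment_table, propagate_annotations
from .model import CoreAccessoryModel
from .normalization import normalized_counts
from .orthology import OrthogroupTable, filter_single_copy, join_expression

__all__ = [
    "RunReport",
    "run_within_species",
    "run_species_pair",
    "run_cross_species_core_accessory",
    "gene_report",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Tables and provenance from one pipeline run."""

    analysis: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    model: CoreAccessoryModel | None = None


def _provenance(analysis: str, params: dict) -> dict:
    blob = json.dumps({"analysis": analysis, **params}, sort_keys=True, default=str)
    return {
        "analysis": analysis,
        "fruitcore_version": __version__,
        "params": params,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def _cluster_de_genes(
    expr: ExpressionMatrix,
    sf: np.ndarray,
    de_genes: list[str],
    grouping: str,
    min_size: int,
    cut_height: float | None,
    k: int | None,
) -> tuple[pd.DataFrame, object | None]:
    if len(de_genes) < 2:
        return pd.DataFrame(columns=["gene_id", "cluster"]), None
    sub = expr.subset_genes(de_genes)
    prof = profile_matrix(sub.counts, sf, sub.samples, grouping=grouping, gene_ids=sub.gene_ids)
    usable = ~prof.constant
    values = prof.values[usable]
    ids = prof.gene_ids[usable]
    if len(ids) < 2:
        return pd.DataFrame(columns=["gene_id", "cluster"]), None
    if k is None and cut_height is None:
        cut_height = 0.25
    clusterer = DianaClustering(k=k, height=cut_height, min_size=min_size)
    labels = clusterer.fit_predict(values)
    tab = pd.DataFrame({"gene_id": ids, "cluster": labels})
    const = pd.DataFrame({"gene_id": prof.gene_ids[~usable], "cluster": 0})
    return pd.concat([tab, const], ignore_index=True), clusterer


def _go_tables(
    study_sets: dict[str, set[str]],
    universe: set[str],
    dag: GoDag | None,
    annotations: dict[str, set[str]] | None,
    elim_cutoff: float,
    min_annotated: int,
) -> dict[str, pd.DataFrame]:
    if dag is None or annotations is None:
        return {}
    propagated, unresolved = propagate_annotations(annotations, dag)
    if unresolved:
        logger.warning("skipped %d unresolvable GO IDs", len(unresolved))
    out = {}
    for name, study in study_sets.items():
        study = set(study) & universe
        if not study:
            continue
        out[f"go_{name}"] = enrichment_table(
            study, universe, propagated, dag,
            elim_cutoff=elim_cutoff, min_annotated=min_annotated,
        )
    return out


def run_within_species(
    expr: ExpressionMatrix,
    spline_df: int | None = None,
    alpha: float = 0.01,
    min_total_count: int = 10,
    cluster_min_size: int = 15,
    cluster_k: int | None = None,
    cluster_height: float | None = None,
    go_dag: GoDag | None = None,
    go_annotations: dict[str, set[str]] | None = None,
    go_elim_cutoff: float = 0.01,
    go_min_annotated: int = 3,
) -> RunReport:
    """Single-condition time-course DE: spline vs noise, then clustering/GO.

    A gene is differentially expressed when the spline model beats the
    noise-only model at ``padj < alpha``; the DE cohort is profile-clustered
    and (when GO inputs are given) tested for term enrichment.
    """
    if expr.samples["stage_label"].nunique() < 2:
        raise ValueError("within-species analysis needs at least two stages")
    model = CoreAccessoryModel(
        group_field=None, spline_df=spline_df, alpha=alpha, min_total_count=min_total_count
    ).fit(expr)
    cls = model.classification_
    de_genes = cls.loc[cls["label"] == "de", "gene_id"].tolist()
    clusters, _ = _cluster_de_genes(
        expr, model.size_factors_, de_genes, "species", cluster_min_size, cluster_height, cluster_k
    )
    report = RunReport(analysis="within_species", model=model)
    report.tables["de"] = _result_table(cls, model.lrt_m1_vs_m0_)
    report.tables["clusters"] = clusters
    universe = set(map(str, expr.gene_ids))
    study_sets = {"de": set(de_genes)}
    for c in sorted(set(clusters["cluster"]) - {0}):
        study_sets[f"cluster_{c}"] = set(clusters.loc[clusters["cluster"] == c, "gene_id"])
    report.tables.update(
        _go_tables(study_sets, universe, go_dag, go_annotations, go_elim_cutoff, go_min_annotated)
    )
    report.summary = {
        "n_genes": expr.n_genes,
        "n_de": len(de_genes),
        "n_untested": int((cls["label"] == "untested").sum()),
        "n_clusters": int((clusters["cluster"].max() or 0) if len(clusters) else 0),
    }
    report.provenance = _provenance(
        "within_species",
        {"spline_df": spline_df, "alpha": alpha, "min_total_count": min_total_count},
    )
    return report


def _result_table(cls: pd.DataFrame, *lrt_tables: pd.DataFrame) -> pd.DataFrame:
    out = cls.copy()
    for tab in lrt_tables:
        if tab is None:
            continue
        out = out.merge(
            tab[["gene_id", "stat", "df", "pvalue", "padj"]],
            on="gene_id",
            how="left",
            suffixes=("", "_dup"),
        )
        break  # detail columns from the first table only
    return out


def run_species_pair(
    expr: ExpressionMatrix,
    spline_df: int | None = None,
    alpha: float = 0.01,
    min_total_count: int = 10,
    shape_only: bool = False,
    **cluster_go_opts,
) -> RunReport:
    """Two-condition comparison: conserved vs species-divergent genes.

    Model 2 carries the species as the grouping covariate; genes whose
    expression pattern is better explained with species-specific
    trajectories are divergent, genes DE under the species-blind spline
    model without that improvement are conserved.  Classification is
    symmetric under swapping the two species labels.
    """
    n_species = expr.samples["species"].nunique()
    if n_species != 2:
        raise ValueError(f"species-pair analysis needs exactly 2 species, got {n_species}")
    stage_sets = expr.samples.groupby("species")["stage_label"].agg(set)
    if len(set(map(frozenset, stage_sets))) != 1:
        raise ValueError(f"species have mismatched stage sets: {dict(stage_sets)}")
    model = CoreAccessoryModel(
        group_field="species",
        spline_df=spline_df,
        alpha=alpha,
        min_total_count=min_total_count,
        shape_only=shape_only,
    ).fit(expr)
    report = _classification_report("species_pair", model, expr, grouping="species", **cluster_go_opts)
    report.provenance = _provenance(
        "species_pair",
        {"spline_df": spline_df, "alpha": alpha, "shape_only": shape_only},
    )
    return report


def _classification_report(
    analysis: str,
    model: CoreAccessoryModel,
    expr: ExpressionMatrix,
    grouping: str,
    cluster_min_size: int = 15,
    cluster_k: int | None = None,
    cluster_height: float | None = None,
    go_dag: GoDag | None = None,
    go_annotations: dict[str, set[str]] | None = None,
    go_elim_cutoff: float = 0.01,
    go_min_annotated: int = 3,
    run_pca: bool = True,
) -> RunReport:
    cls = model.classification_
    report = RunReport(analysis=analysis, model=model)
    report.tables["classification"] = cls
    for name, tab in (
        ("lrt_m1_vs_m0", model.lrt_m1_vs_m0_),
        ("lrt_m2_vs_m0", model.lrt_m2_vs_m0_),
        ("lrt_m2_vs_m1", model.lrt_m2_vs_m1_),
    ):
        if tab is not None:
            report.tables[name] = tab
    universe = set(map(str, expr.gene_ids))
    study_sets: dict[str, set[str]] = {}
    for label in ("conserved_de", "divergent_de"):
        genes = cls.loc[cls["label"] == label, "gene_id"].tolist()
        study_sets[label] = set(genes)
        clusters, _ = _cluster_de_genes(
            expr, model.size_factors_, genes, grouping,
            cluster_min_size, cluster_height, cluster_k,
        )
        report.tables[f"clusters_{label}"] = clusters
        for c in sorted(set(clusters["cluster"]) - {0}):
            study_sets[f"{label}_cluster_{c}"] = set(
                clusters.loc[clusters["cluster"] == c, "gene_id"]
            )
        if run_pca and len(genes) >= 2:
            sub = expr.subset_genes(genes)
            vals = np.log2(normalized_counts(sub.counts, model.size_factors_) + 1.0)
            pca = pca_summary(vals.T, n_components=5)
            report.tables[f"pca_{label}"] = pd.DataFrame(
                {
                    "sample_id": expr.samples["sample_id"],
                    **{
                        f"PC{i + 1}": pca["scores"][:, i]
                        for i in range(pca["scores"].shape[1])
                    },
                }
            )
            report.summary[f"pca_{label}_percent_variance"] = [
                round(float(v), 3) for v in pca["percent_variance"]
            ]
    report.tables.update(
        _go_tables(study_sets, universe, go_dag, go_annotations, go_elim_cutoff, go_min_annotated)
    )
    tallies = cls["label"].value_counts().to_dict()
    report.summary.update(
        {
            "n_genes": int(len(cls)),
            **{f"n_{lab}": int(tallies.get(lab, 0)) for lab in CLASS_LABELS},
            "n_untested": int(tallies.get("untested", 0)),
        }
    )
    return report


def run_cross_species_core_accessory(
    orthogroups: OrthogroupTable,
    matrices: dict[str, ExpressionMatrix],
    proxy: dict[str, str] | None = None,
    spline_df: int | None = None,
    alpha: float = 0.01,
    min_total_count: int = 10,
    shape_only: bool = False,
    per_species_sf: bool = False,
    **cluster_go_opts,
) -> RunReport:
    """The flagship analysis: core/accessory classification of orthogenes.

    Orthogroups are filtered to universal single-copy orthogenes, the
    per-species counts joined into one orthogene matrix, and the nested
    Model 0/1/2 fruit-type comparison run on it.  Conserved (core) and
    divergent (accessory) cohorts are profile-clustered and GO-tested.
    """
    fruit_types = {sp: m.samples["fruit_type"].iloc[0] for sp, m in matrices.items()}
    for ft in ("dry", "fleshy"):
        if ft not in set(fruit_types.values()):
            raise ValueError(f"no species with fruit_type={ft!r}")
    single = filter_single_copy(orthogroups)
    joint = join_expression(single, matrices, proxy=proxy)
    model = CoreAccessoryModel(
        group_field="fruit_type",
        spline_df=spline_df,
        alpha=alpha,
        min_total_count=min_total_count,
        shape_only=shape_only,
        per_species_sf=per_species_sf,
    ).fit(joint)
    report = _classification_report(
        "cross_species_core_accessory", model, joint, grouping="fruit_type", **cluster_go_opts
    )
    report.summary["n_orthogroups"] = len(orthogroups)
    report.summary["n_single_copy"] = len(single)
    report.tables["orthogene_map"] = (
        single.to_frame().reset_index().rename(columns={"Orthogroup": "orthogroup_id"})
    )
    report.provenance = _provenance(
        "cross_species_core_accessory",
        {
            "spline_df": spline_df,
            "alpha": alpha,
            "shape_only": shape_only,
            "per_species_sf": per_species_sf,
            "species": sorted(matrices),
        },
    )
    return report


def gene_report(
    expr: ExpressionMatrix,
    gene_ids: list[str],
    report: RunReport | None = None,
    sf: np.ndarray | None = None,
    grouping: str = "species",
) -> pd.DataFrame:
    """Per-gene profile table: normalized counts and per-cell means.

    Mirrors the per-gene expression panels of the study (tabular form).
    Unknown IDs raise with the misses listed; genes a previous run left
    untested are flagged in the ``status`` column.
    """
    if not gene_ids:
        return pd.DataFrame(
            columns=["gene_id", "sample_id", "stage_label", grouping, "normalized_count", "cell_mean", "status"]
        )
    missing = [g for g in gene_ids if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"unknown gene IDs: {missing}")
    if sf is None:
        sf = report.model.size_factors_ if report is not None and report.model else np.ones(expr.n_samples)
    status = {}
    if report is not None:
        for name in ("classification", "de"):
            if name in report.tables:
                tab = report.tables[name]
                status = dict(zip(tab["gene_id"], tab["label"]))
                break
    sub = expr.subset_genes(gene_ids)
    norm = normalized_counts(sub.counts, sf)
    meta = sub.samples
    rows = []
    for gi, gene in enumerate(gene_ids):
        cell_means = (
            pd.Series(norm[gi]).groupby([meta[grouping], meta["stage_label"]]).mean()
        )
        for j in range(len(meta)):
            key = (meta[grouping].iloc[j], meta["stage_label"].iloc[j])
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": meta["sample_id"].iloc[j],
                    "stage_label": meta["stage_label"].iloc[j],
                    grouping: meta[grouping].iloc[j],
                    "normalized_count": norm[gi, j],
                    "cell_mean": cell_means[key],
                    "status": status.get(gene, "untested" if status else "unknown"),
                }
            )
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir) -> list[Path]:
    """Write all report tables as TSVs plus a JSON provenance/summary block.

    Missing values are written as ``NA``; column and row order are
    deterministic, so identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(report.tables):
        path = out / f"{name}.tsv"
        report.tables[name].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
        written.append(path)
    meta = {"summary": report.summary, "provenance": report.provenance}
    path = out / "report.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(path)
    return written
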
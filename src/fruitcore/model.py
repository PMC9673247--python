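"""Estimator front-end for the nested spline NB-GLM classification.

``CoreAccessoryModel`` wraps the Model 0 / Model 1 / Model 2 comparison in
a scikit-learn-style estimator: construct with hyperparameters, ``fit`` on
a counts matrix plus sample metadata, read the fitted attributes.  It
composes with sklearn model-selection utilities via ``get_params`` /
``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import ExpressionMatrix
from .de import run_nested_comparison

__all__ = ["CoreAccessoryModel"]


class CoreAccessoryModel(BaseEstimator):
    """Classify genes as conserved (core), divergent (accessory) or non-DE.

    Parameters
    ----------
    group_field : {'fruit_type', 'species', None}
        Grouping for Model 2.  ``None`` runs only the spline-vs-noise test
        (single-condition DE).
    spline_df : int or None
        Natural-spline dimension; default ``min(n_stages - 1, 3)``.
    alpha : float
        FDR threshold on BH-adjusted p-values (default 0.01).
    min_total_count : int
        Genes with a smaller total count are reported untested.
    shape_only : bool
        Put the group main effect in the reduced model of the divergence
        test, so magnitude-only shifts do not count as divergent.
    per_species_sf : bool
        Compute size factors per species instead of on the joint matrix.
    refine_sf : bool
        Re-estimate size factors on first-pass non-DE genes and retest
        (two-pass normalization; guards against stage-correlated reference
        bias when many genes are DE).

    Attributes
    ----------
    classification_ : DataFrame
        gene_id, label, and the three adjusted p-values.
    labels_ : ndarray
        Per-gene label, aligned to the input gene order.
    lrt_m1_vs_m0_, lrt_m2_vs_m0_, lrt_m2_vs_m1_ : DataFrame
        The nested LRT tables.
    size_factors_ : ndarray
    dispersions_ : DispersionSet
    basis_ : SplineBasis
    designs_ : dict of DesignMatrix
    """

    def __init__(
        self,
        group_field: str | None = "fruit_type",
        spline_df: int | None = None,
        alpha: float = 0.01,
        min_total_count: int = 10,
        shape_only: bool = False,
        per_species_sf: bool = False,
        refine_sf: bool = True,
    ):
        self.group_field = group_field
        self.spline_df = spline_df
        self.alpha = alpha
        self.min_total_count = min_total_count
        self.shape_only = shape_only
        self.per_species_sf = per_species_sf
        self.refine_sf = refine_sf

    def fit(self, X, metadata: pd.DataFrame | None = None, gene_ids=None):
        """Fit the nested models.

        ``X`` may be an :class:`ExpressionMatrix` (metadata taken from it)
        or a (genes x samples) count array with ``metadata`` supplied.
        """
        if isinstance(X, ExpressionMatrix):
            counts, metadata = X.counts, X.samples
            gene_ids = X.gene_ids
        else:
            counts = np.asarray(X)
            if metadata is None:
                raise ValueError("metadata is required when X is a bare array")
            if gene_ids is None:
                gene_ids = [f"gene_{i}" for i in range(counts.shape[0])]
        res = run_nested_comparison(
            counts,
            gene_ids,
            metadata,
            group_field=self.group_field,
            spline_df=self.spline_df,
            alpha=self.alpha,
            min_total_count=self.min_total_count,
            shape_only=self.shape_only,
            per_species_sf=self.per_species_sf,
            refine_sf=self.refine_sf,
        )
        self.classification_ = res["classification"]
        self.labels_ = self.classification_["label"].to_numpy()
        self.lrt_m1_vs_m0_ = res["m1_vs_m0"]
        self.lrt_m2_vs_m0_ = res["m2_vs_m0"]
        self.lrt_m2_vs_m1_ = res["m2_vs_m1"]
        self.size_factors_ = res["size_factors"]
        self.dispersions_ = res["dispersions"]
        self.basis_ = res["basis"]
        self.designs_ = res["designs"]
        self.gene_ids_ = np.asarray(list(gene_ids))
        return self

    def fit_predict(self, X, metadata: pd.DataFrame | None = None, gene_ids=None):
        """Fit and return the per-gene labels."""
        return self.fit(X, metadata, gene_ids).labels_

    def summary(self) -> pd.Series:
        """Label tallies of the fitted classification."""
        if not hasattr(self, "classification_"):
            raise AttributeError("model is not fitted")
        return self.classification_["label"].value_counts().sort_index()
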
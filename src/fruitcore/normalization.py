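"""Median-of-ratios size-factor normalization.

Sequencing depth differs between libraries, so raw counts are not comparable
across samples.  The median-of-ratios procedure builds a pseudo-reference
sample from the per-gene geometric mean over samples (genes with any zero
count are excluded, since their geometric mean is zero) and takes each
sample's size factor as the median ratio of its counts to that reference.
Factors are rescaled to geometric mean 1 so normalized counts stay on the
scale of the data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["size_factors", "normalized_counts"]


def size_factors(counts: np.ndarray, pseudo_reference: bool = False) -> np.ndarray:
    """Per-sample size factors by median-of-ratios.

    Parameters
    ----------
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer counts.
    pseudo_reference : bool
        If no gene has all-positive counts, fall back to a reference built
        from ``counts + 1`` instead of raising.

    Returns
    -------
    ndarray of shape (n_samples,)
        Strictly positive factors with geometric mean 1 (to 1e-10).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    all_positive = np.all(c > 0, axis=1)
    if not all_positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; median-of-ratios "
                "is undefined — rerun with pseudo_reference=True to use a "
                "counts+1 pseudo-reference"
            )
        c = c + 1.0
        all_positive = np.ones(c.shape[0], dtype=bool)
    logc = np.log(c[all_positive])
    log_ref = logc.mean(axis=1)  # per-gene log geometric mean
    log_ratios = logc - log_ref[:, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


def normalized_counts(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Counts divided by their sample's size factor."""
    return np.asarray(counts, dtype=float) / np.asarray(sf, dtype=float)[None, :]
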
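"""Population-structure summaries: genotype PCA and cluster-number selection.

The Bayesian clustering MCMC itself is an external tool; this module
consumes its run table of estimated log-probabilities Ln Pr(X | K) and
computes the per-K means and the Evanno ΔK second-difference statistic.
PCA of the dosage matrix (per-locus mean imputation of missing calls)
goes through scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PCAResult:
    """Scores, per-axis variances and percent variance of a genotype PCA."""

    scores: np.ndarray  # (individuals, axes)
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    individual_ids: list[str]


def pca_genotypes(
    G: GenotypeMatrix, n_axes: int = 3, scaling: str = "centered"
) -> PCAResult:
    """PCA of the dosage matrix.

    Missing calls are mean-imputed per locus before centering (and, for
    ``scaling="standardized"``, unit-variance scaling).  Requesting more
    axes than the matrix rank truncates with a warning.  Axis signs are
    arbitrary, as for any eigen-decomposition.
    """
    if scaling not in {"centered", "standardized"}:
        raise ValueError("scaling must be 'centered' or 'standardized'")
    if G.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    x = G.dosage_float()
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    if scaling == "standardized":
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - col_mean) / sd
    max_axes = min(G.n_individuals, G.n_loci)
    if n_axes > max_axes:
        warnings.warn(f"requested {n_axes} axes but rank is at most {max_axes}; truncating")
        n_axes = max_axes
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    eig = pca.explained_variance_
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    k = min(n_axes, scores.shape[1])
    return PCAResult(scores[:, :k], eig[:k], pct[:k], list(G.individual_ids))


def mean_lnp(run_table: pd.DataFrame) -> pd.DataFrame:
    """Per-K mean and sample standard deviation of Ln Pr(X | K).

    K values with a single run get sd NaN (flagged undefined).
    """
    g = run_table.groupby("K")["lnp"]
    out = pd.DataFrame({"mean_lnp": g.mean(), "sd_lnp": g.std(ddof=1)})
    return out.sort_index().reset_index()


def evanno_delta_k(run_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK table: |L(K+1) - 2 L(K) + L(K-1)| / sd(K).

    ΔK is defined only at interior K with both neighbours present and a
    positive across-run sd; boundary or degenerate K get NaN.  The sample
    sd (ddof=1) is used.  Invariant to adding a constant to every lnp.
    """
    stats = mean_lnp(run_table).set_index("K")
    ks = stats.index.to_numpy()
    delta = pd.Series(np.nan, index=stats.index, name="delta_k")
    for k in ks:
        if (k - 1 not in stats.index) or (k + 1 not in stats.index):
            continue
        sd = stats.loc[k, "sd_lnp"]
        if not np.isfinite(sd) or sd <= 0:
            continue
        second = stats.loc[k + 1, "mean_lnp"] - 2 * stats.loc[k, "mean_lnp"] + stats.loc[k - 1, "mean_lnp"]
        delta.loc[k] = abs(second) / sd
    out = stats.copy()
    out["delta_k"] = delta
    return out.reset_index()
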
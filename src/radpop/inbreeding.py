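"""Genomic inbreeding coefficients and identity disequilibrium (g2).

Four per-individual inbreeding measures are computed from biallelic SNP
dosages: standardized multilocus heterozygosity (sMLH) and three
frequency-weighted estimators — based on the variance of additive
genotype values (f1), on excess homozygosity (f2), and on the correlation
of uniting gametes, which up-weights rare-allele homozygotes (f3).  Each
of f1-f3 has expectation f under the inbreeding model.

Identity disequilibrium is quantified by g2, the excess correlation in
heterozygosity across loci within individuals.  Under variable inbreeding
g2 = var(f) / (1 - E[f])², so a significantly positive estimate is
evidence for variance in inbreeding; g2 divided by the variance of an
inbreeding estimate gives the expected squared correlation between that
estimate and realized inbreeding, r²(f̂, f*) = g2 / σ²(f̂).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# per-individual coefficients
# ---------------------------------------------------------------------------

def smlh(G: GenotypeMatrix) -> np.ndarray:
    """Standardized multilocus heterozygosity per individual.

    sMLH_i = (proportion of heterozygous loci among loci typed in i)
    divided by the mean, over those same loci, of the locus's population
    heterozygote frequency.  Loci monomorphic across the sample are
    excluded; the population mean is exactly 1 under complete data.
    Individuals typed at no usable locus get NaN (flagged undefined).
    """
    typed = G.calls != MISSING
    n_typed_all = typed.sum(axis=0)
    alt = np.where(typed, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * np.maximum(n_typed_all, 1))
    poly = (n_typed_all > 0) & (p > 0) & (p < 1)
    het = (G.calls == 1) & typed
    locus_het_freq = np.where(
        n_typed_all > 0, het.sum(axis=0) / np.maximum(n_typed_all, 1), np.nan
    )
    t = typed[:, poly]
    h = het[:, poly]
    hf = locus_het_freq[poly]
    n_i = t.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = h.sum(axis=1) / n_i
        expect = (t * hf).sum(axis=1) / n_i
        out = obs / expect
    out[n_i == 0] = np.nan
    return out


_FHAT_KINDS = {"I", "II", "III", "1", "2", "3"}


def fhat(G: GenotypeMatrix, which: str) -> np.ndarray:
    """Per-individual genomic inbreeding estimate (kind I, II or III).

    Averages a per-locus estimator over the loci typed in each individual,
    with x the alt dosage and p the sample alt-allele frequency:

    * I   — variance of additive genotype values: (x - 2p)²/(2pq) - 1
    * II  — excess homozygosity: 1 - x(2 - x)/(2pq)
    * III — correlation of uniting gametes: [x² - (1+2p)x + 2p²]/(2pq)

    Monomorphic loci are excluded.  Individuals with zero usable loci get
    NaN (flagged undefined).
    """
    which = str(which).upper().replace("1", "I").replace("2", "II").replace("3", "III")
    if which not in {"I", "II", "III"}:
        raise ValueError("which must be one of I, II, III")
    typed = G.calls != MISSING
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * np.maximum(n_typed, 1))
    poly = (n_typed > 0) & (p > 0) & (p < 1)
    x = G.calls[:, poly].astype(float)
    t = typed[:, poly]
    pj = p[poly]
    two_pq = 2.0 * pj * (1.0 - pj)
    if which == "I":
        per_locus = (x - 2.0 * pj) ** 2 / two_pq - 1.0
    elif which == "II":
        per_locus = 1.0 - x * (2.0 - x) / two_pq
    else:
        per_locus = (x**2 - (1.0 + 2.0 * pj) * x + 2.0 * pj**2) / two_pq
    per_locus = np.where(t, per_locus, 0.0)
    n_i = t.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = per_locus.sum(axis=1) / n_i
    out[n_i == 0] = np.nan
    return out


def inbreeding_table(G: GenotypeMatrix) -> pd.DataFrame:
    """All four coefficients per individual (columns smlh, f1, f2, f3, n_loci)."""
    typed = (G.calls != MISSING).sum(axis=1)
    return pd.DataFrame(
        {
            "individual": G.individual_ids,
            "smlh": smlh(G),
            "f1": fhat(G, "I"),
            "f2": fhat(G, "II"),
            "f3": fhat(G, "III"),
            "n_loci": typed,
        }
    )


def coefficient_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among (smlh, f1, f2, f3) on an inbreeding-aligned scale.

    sMLH is entered with its sign flipped (higher sMLH = less inbred) so
    that all pairwise correlations share orientation; the returned frame's
    ``attrs['smlh_orientation']`` records the convention.  Constant
    columns yield NaN entries (flagged undefined).
    """
    cols = table[["smlh", "f1", "f2", "f3"]].copy()
    cols["smlh"] = -cols["smlh"]
    complete = cols.dropna()
    if len(complete) < 3:
        raise ValueError("need >= 3 individuals with all four coefficients defined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = complete.corr()
    corr.attrs["smlh_orientation"] = "sign-flipped (reported as -sMLH)"
    return corr


def expected_r2_f(g2: float, var_fhat: float) -> float:
    """Expected squared correlation between estimated and realized inbreeding."""
    if var_fhat <= 0:
        raise ValueError("var_fhat must be positive")
    return g2 / var_fhat


# ---------------------------------------------------------------------------
# identity disequilibrium
# ---------------------------------------------------------------------------

def _het_matrix(G: GenotypeMatrix) -> np.ndarray:
    """0/1 heterozygosity indicator with missing entries as 0.

    Because every g2 sum is over products of entries, coding missing as 0
    is identical to excluding the combinations that involve them.
    """
    return ((G.calls == 1) & (G.calls != MISSING)).astype(float)


def _g2_from_h(h: np.ndarray) -> float:
    n = h.shape[0]
    if n < 2:
        raise ValueError("g2 needs at least 2 individuals")
    r = h.sum(axis=1)  # per-individual heterozygote counts
    c = h.sum(axis=0)  # per-locus heterozygote counts
    within = float((r**2 - r).sum())  # sum_i sum_{l != m} h_il h_im
    all_pairs = float(c.sum() ** 2 - (c**2).sum())  # sum over i,j and l != m
    cross = all_pairs - within  # sum_{i != j} sum_{l != m} h_il h_jm
    num = within / n
    denom = cross / (n * (n - 1))
    if denom == 0:
        raise ValueError("g2 undefined: no cross-individual heterozygosity products")
    return num / denom - 1.0


def g2_point(G: GenotypeMatrix) -> float:
    """Multilocus identity-disequilibrium estimate (ratio-of-sums ĝ2).

    ĝ2 = [ (1/N) Σ_i Σ_{l≠m} h_il h_im ] /
         [ (1/(N(N-1))) Σ_{i≠j} Σ_{l≠m} h_il h_jm ]  -  1,

    with h the heterozygosity indicator and sums restricted to non-missing
    entries.  Invariant to individual relabeling and locus order.
    """
    return _g2_from_h(_het_matrix(G))


@dataclass(frozen=True)
class G2Estimate:
    """g2 point estimate with bootstrap CI and permutation p-value."""

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    p_perm: float
    n_perm: int
    seed: int
    n_redrawn: int = 0


def g2_bootstrap(
    G: GenotypeMatrix, n_boot: int = 1000, seed: int = 0, return_redrawn: bool = False
):
    """Percentile 95% bootstrap CI for ĝ2, resampling individuals.

    Replicates where ĝ2 is undefined (degenerate resamples) are redrawn;
    the redraw count is available via ``return_redrawn``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    h = _het_matrix(G)
    rng = np.random.default_rng(seed)
    n = h.shape[0]
    values = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            rows = rng.integers(0, n, size=n)
            try:
                values[b] = _g2_from_h(h[rows])
                break
            except ValueError:
                redrawn += 1
                if redrawn > 100 * n_boot:
                    raise
    lo, hi = np.percentile(values, [2.5, 97.5])
    if return_redrawn:
        return float(lo), float(hi), redrawn
    return float(lo), float(hi)


def g2_permutation_p(G: GenotypeMatrix, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for ĝ2 > 0.

    The null permutes each locus column independently across individuals,
    preserving per-locus heterozygosity and missingness while destroying
    within-individual correlation; p = (1 + #{ĝ2_perm >= ĝ2_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    h = _het_matrix(G)
    obs = _g2_from_h(h)
    rng = np.random.default_rng(seed)
    n, L = h.shape
    count = 0
    for _ in range(n_perm):
        # independent column shuffles via per-column random sort keys
        idx = np.argsort(rng.random((n, L)), axis=0)
        hp = np.take_along_axis(h, idx, axis=0)
        try:
            if _g2_from_h(hp) >= obs:
                count += 1
        except ValueError:
            count += 1  # degenerate null counted as extreme (conservative)
    return (1 + count) / (n_perm + 1)


def g2_estimate(
    G: GenotypeMatrix, n_boot: int = 1000, n_perm: int = 1000, seed: int = 0
) -> G2Estimate:
    """Point estimate, bootstrap CI and permutation p-value in one record."""
    point = g2_point(G)
    lo, hi, redrawn = g2_bootstrap(G, n_boot=n_boot, seed=seed, return_redrawn=True)
    p = g2_permutation_p(G, n_perm=n_perm, seed=seed + 1)
    return G2Estimate(point, lo, hi, n_boot, p, n_perm, seed, redrawn)
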
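"""Pairwise linkage disequilibrium and the drift-recombination decay fit.

r² between SNP pairs on the same scaffold (within a physical distance cap)
is estimated either by maximum-likelihood haplotype frequencies from
unphased genotypes (EM over the double-heterozygote phase ambiguity) or as
the squared Pearson correlation of dosage vectors (composite).  Observed
r² against distance is then fitted with the Hill & Weir expectation under
drift-recombination equilibrium,

    E(r²) = [(10+ρ) / ((2+ρ)(11+ρ))] ·
            [1 + ((3+ρ)(12+12ρ+ρ²)) / (n(2+ρ)(11+ρ))],

where ρ = 4·Ne·c grows linearly with distance (ρ = C·d, C fitted per bp)
and n is the number of gametes scored.  The large-ρ asymptote is 1/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import MISSING, GenotypeMatrix

PAIR_COLUMNS = ["scaffold", "i", "j", "pos_i", "pos_j", "distance", "r2", "n_used"]


# ---------------------------------------------------------------------------
# pairwise r²
# ---------------------------------------------------------------------------

def em_r2(g1: np.ndarray, g2: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> float:
    """Haplotypic r² between two dosage vectors via EM haplotype frequencies.

    Resolves the coupling/repulsion ambiguity of double heterozygotes by
    maximum likelihood; missing entries are excluded pairwise.  Returns NaN
    if either locus is monomorphic among complete pairs.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    n = a.size
    if n == 0:
        return np.nan
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.nan
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    n_dh = counts[1, 1]
    # fixed haplotype contributions from unambiguous genotype pairs
    base11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base12 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base21 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base22 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    p11 = pA * pB
    for _ in range(max_iter):
        p12, p21 = pA - p11, pB - p11
        p22 = 1.0 - pA - pB + p11
        denom = p11 * p22 + p12 * p21
        x = 0.5 if denom <= 0 else p11 * p22 / denom
        # each coupling-phase double-het carries exactly one A-B haplotype
        new11 = (base11 + n_dh * x) / (2 * n)
        if abs(new11 - p11) < tol:
            p11 = new11
            break
        p11 = new11
    D = p11 - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def composite_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete pairs."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(float), g2[ok].astype(float)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def pairwise_r2(
    G: GenotypeMatrix, max_distance: int = 500_000, estimator: str = "em"
) -> pd.DataFrame:
    """All same-scaffold SNP pairs within ``max_distance`` bp, with r².

    Pairs where either locus is monomorphic among complete individuals are
    skipped (r² undefined).  Returns a DataFrame with columns
    ``scaffold, i, j, pos_i, pos_j, distance, r2, n_used``.
    """
    if estimator not in {"em", "composite"}:
        raise ValueError("estimator must be 'em' or 'composite'")
    est = em_r2 if estimator == "em" else composite_r2
    rows = []
    scaffolds = G.loci["scaffold"].to_numpy()
    positions = G.loci["position"].to_numpy()
    for scaf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaf)
        pos = positions[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = int(pos[b] - pos[a])
                if dist > max_distance:
                    break
                gi, gj = G.calls[:, idx[a]], G.calls[:, idx[b]]
                r2 = est(gi, gj)
                if np.isnan(r2):
                    continue
                n_used = int(((gi != MISSING) & (gj != MISSING)).sum())
                rows.append((scaf, int(idx[a]), int(idx[b]), int(pos[a]), int(pos[b]),
                             max(dist, 1), r2, n_used))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# Hill-Weir expectation and fit
# ---------------------------------------------------------------------------

def hill_weir_expected_r2(rho, n_gametes: int):
    """Expected r² under drift-recombination equilibrium (see module docstring)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    if n_gametes < 2:
        raise ValueError("n_gametes must be >= 2")
    a = (10.0 + rho) / ((2.0 + rho) * (11.0 + rho))
    b = 1.0 + ((3.0 + rho) * (12.0 + 12.0 * rho + rho**2)) / (
        n_gametes * (2.0 + rho) * (11.0 + rho)
    )
    out = a * b
    return float(out) if out.ndim == 0 else out


class HillWeirDecay(BaseEstimator, RegressorMixin):
    """Least-squares fit of the Hill-Weir decay curve to observed r².

    ρ is modelled as C·distance with a single non-negative rate parameter
    C (per bp).  With a user-supplied per-bp recombination fraction c, the
    composite population parameter 4·Ne·c equals C·d at distance d; Ne
    itself is never estimated here.

    Parameters
    ----------
    n_gametes : int
        Number of gametes scored (2 x individuals for diploids).
    init_C : float, optional
        Starting value for C; by default a coarse log-grid search over
        [1e-7, 1e-2] per bp picks the start, avoiding solver-default
        dependence.

    Attributes
    ----------
    C_ : float
        Fitted decay-rate parameter (per bp), >= 0.
    sse_ : float
        Residual sum of squares at ``C_``.
    n_pairs_ : int
        Number of (distance, r²) pairs fitted.
    converged_ : bool
        Solver convergence flag.
    """

    def __init__(self, n_gametes: int = 66, init_C: Optional[float] = None):
        self.n_gametes = n_gametes
        self.init_C = init_C

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        r2 = np.asarray(y, dtype=float).reshape(-1)
        if d.size != r2.size:
            raise ValueError("X and y must have the same length")
        if d.size < 10:
            raise ValueError("need at least 10 pairs to fit the decay curve")
        if np.any(d <= 0):
            raise ValueError("distances must be positive")

        def resid(c):
            return hill_weir_expected_r2(c[0] * d, self.n_gametes) - r2

        if self.init_C is None:
            grid = np.logspace(-7, -2, 61)
            sses = [float((resid([c]) ** 2).sum()) for c in grid]
            x0 = float(grid[int(np.argmin(sses))])
        else:
            x0 = float(self.init_C)
        sol = optimize.least_squares(
            resid, x0=[x0], bounds=([0.0], [np.inf]), max_nfev=2000
        )
        self.C_ = float(sol.x[0])
        self.sse_ = float((sol.fun**2).sum())
        self.n_pairs_ = int(d.size)
        self.converged_ = bool(sol.status > 0)
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float).reshape(-1)
        return hill_weir_expected_r2(self.C_ * d, self.n_gametes)


@dataclass(frozen=True)
class HillWeirFit:
    """Flat result record of a decay-curve fit."""

    C: float
    n_gametes: int
    residual_sse: float
    n_pairs: int
    converged: bool


def fit_hill_weir(
    pairs: pd.DataFrame, n_gametes: int, init_C: Optional[float] = None
) -> HillWeirFit:
    """Fit the decay curve to a pair table from :func:`pairwise_r2`."""
    est = HillWeirDecay(n_gametes=n_gametes, init_C=init_C).fit(
        pairs["distance"].to_numpy(), pairs["r2"].to_numpy()
    )
    if not est.converged_:
        warnings.warn("decay-curve fit did not converge; returning best C found")
    return HillWeirFit(est.C_, n_gametes, est.sse_, est.n_pairs_, est.converged_)


def decay_distance(fit: HillWeirFit, r2_threshold: float) -> Optional[float]:
    """Smallest distance (bp) at which the fitted curve drops below a threshold.

    The curve is monotone decreasing in distance, so bisection applies.
    Returns None ("not reached") for thresholds outside the curve's range.
    """
    n = fit.n_gametes
    top = hill_weir_expected_r2(0.0, n)
    asymptote = 1.0 / n
    if fit.C <= 0 or not asymptote < r2_threshold < top:
        return None
    lo, hi = 0.0, 1.0
    while hill_weir_expected_r2(fit.C * hi, n) > r2_threshold:
        hi *= 2.0
        if hi > 1e15:
            return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hill_weir_expected_r2(fit.C * mid, n) > r2_threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def background_level(pairs: pd.DataFrame, min_distance: float = 400_000) -> float:
    """Mean r² over pairs at or beyond ``min_distance`` bp."""
    far = pairs.loc[pairs["distance"] >= min_distance, "r2"]
    if far.empty:
        raise ValueError(f"no pairs at distance >= {min_distance}")
    return float(far.mean())
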
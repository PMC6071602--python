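"""SNP and individual filters, and the three analysis-specific cascades.

Each stage takes a :class:`GenotypeMatrix` and returns a filtered copy plus
a :class:`FilterReport`; reports concatenate into a cascade audit trail.
Thresholds follow the "less than" convention throughout: a locus exactly at
a minimum threshold is retained, one strictly below is removed.  Per-locus
statistics are recomputed after every stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Pedigree, ScaffoldIndex, locus_stats


@dataclass(frozen=True)
class FilterReport:
    """Audit record for one cascade stage."""

    stage_name: str
    loci_before: int
    loci_after: int
    individuals_before: int
    individuals_after: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loci_after > self.loci_before or self.individuals_after > self.individuals_before:
            raise ValueError("filter stage cannot increase counts")


def _report(name: str, before: GenotypeMatrix, after: GenotypeMatrix, **params) -> FilterReport:
    return FilterReport(
        name, before.n_loci, after.n_loci, before.n_individuals, after.n_individuals, params
    )


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    """Audit trail as a DataFrame, one row per stage."""
    return pd.DataFrame(
        {
            "stage": [r.stage_name for r in reports],
            "loci_before": [r.loci_before for r in reports],
            "loci_after": [r.loci_after for r in reports],
            "individuals_before": [r.individuals_before for r in reports],
            "individuals_after": [r.individuals_after for r in reports],
            "parameters": [";".join(f"{k}={v}" for k, v in r.parameters.items()) for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# per-genotype and per-individual filters
# ---------------------------------------------------------------------------

def mask_by_depth(
    G: GenotypeMatrix, min_depth: int = 8, max_depth: int = 30
) -> tuple[GenotypeMatrix, FilterReport]:
    """Set calls with read depth outside [min_depth, max_depth] to missing.

    Bounds are inclusive: depth ``min_depth`` and ``max_depth`` are kept.
    The locus set is unchanged; statistics are recomputed.
    """
    if G.depths is None:
        raise ValueError("depth masking requires per-genotype DP; this matrix has none")
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    out = G.copy()
    known = out.depths >= 0
    bad = known & ((out.depths < min_depth) | (out.depths > max_depth))
    out.calls[bad] = MISSING
    locus_stats(out)
    return out, _report("mask_by_depth", G, out, min_depth=min_depth, max_depth=max_depth)


def drop_high_missing_individuals(
    G: GenotypeMatrix, max_missing: float = 0.9
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals with strictly more than ``max_missing`` missing data."""
    frac = G.missing_mask().mean(axis=1) if G.n_loci else np.zeros(G.n_individuals)
    keep = frac <= max_missing
    out = G.select_individuals(keep)
    return out, _report("drop_high_missing_individuals", G, out, max_missing=max_missing)


def keep_individuals(
    G: GenotypeMatrix, ids: Sequence[str], stage_name: str = "keep_individuals"
) -> tuple[GenotypeMatrix, FilterReport]:
    """Restrict to an explicit individual list (sample metadata, not computation)."""
    out = G.select_individuals(ids)
    return out, _report(stage_name, G, out, n_requested=len(list(ids)))


# ---------------------------------------------------------------------------
# per-locus filters
# ---------------------------------------------------------------------------

def filter_maf(G: GenotypeMatrix, min_maf: float) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with minor-allele frequency strictly below ``min_maf``.

    Loci with undefined MAF (no calls) are removed at any positive threshold.
    """
    maf = G.loci["maf"].to_numpy()
    keep = maf >= min_maf  # NaN compares False -> removed
    if min_maf <= 0:
        keep = keep | np.isnan(maf)
    out = G.select_loci(keep)
    return out, _report("filter_maf", G, out, min_maf=min_maf)


def filter_call_rate(G: GenotypeMatrix, min_rate: float) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci called in strictly less than ``min_rate`` of individuals."""
    keep = G.loci["call_rate"].to_numpy() >= min_rate
    out = G.select_loci(keep)
    return out, _report("filter_call_rate", G, out, min_rate=min_rate)


def restrict_scaffolds(
    G: GenotypeMatrix, idx: ScaffoldIndex, top_n: int = 100
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci on the ``top_n`` longest scaffolds (ties broken by label)."""
    unknown = set(G.loci["scaffold"]) - set(idx.lengths)
    if unknown:
        raise KeyError(f"scaffolds absent from length table: {sorted(unknown)}")
    top = idx.top(top_n)
    keep = G.loci["scaffold"].isin(top).to_numpy()
    out = G.select_loci(keep)
    return out, _report("restrict_scaffolds", G, out, top_n=top_n)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value on heterozygote counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (probability-ordering rule; no mid-p).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("HWE test undefined for zero individuals")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # het counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_rare = (n_minor - hets) // 2
    homs_common = n - hets - homs_rare
    logp = (
        math.lgamma(n + 1)
        - _lgamma_arr(homs_rare + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(homs_common + 1)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return min(1.0, float(probs[probs <= obs * (1.0 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def filter_hwe(
    G: GenotypeMatrix,
    alpha: float = 0.001,
    groups: Optional[Mapping[str, str]] = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci out of Hardy-Weinberg equilibrium at fixed ``alpha``.

    With ``groups`` (individual -> population) the exact test runs within
    each population and a locus is removed if p < alpha in *any* group;
    groups with zero typed individuals at a locus are skipped.  No
    multiple-testing correction is applied.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if groups is None:
        member_rows = [np.arange(G.n_individuals)]
    else:
        pops: dict[str, list[int]] = {}
        for i, ind in enumerate(G.individual_ids):
            pops.setdefault(groups.get(ind, "__ungrouped__"), []).append(i)
        member_rows = [np.array(rows) for rows in pops.values()]

    keep = np.ones(G.n_loci, dtype=bool)
    for j in range(G.n_loci):
        col = G.calls[:, j]
        for rows in member_rows:
            sub = col[rows]
            sub = sub[sub != MISSING]
            if sub.size == 0:
                continue
            p = hwe_exact_p(int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum()))
            if p < alpha:
                keep[j] = False
                break
    out = G.select_loci(keep)
    return out, _report(
        "filter_hwe", G, out, alpha=alpha, per_population=groups is not None
    )


# ---------------------------------------------------------------------------
# Mendelian-incompatibility filter
# ---------------------------------------------------------------------------

def _trio_truth_table() -> np.ndarray:
    """Boolean (3,3,3) table, True where (mother, father, child) is impossible."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    table = np.zeros((3, 3, 3), dtype=bool)
    for gm in range(3):
        for gf in range(3):
            possible = {a + b for a in gametes[gm] for b in gametes[gf]}
            for gc in range(3):
                table[gm, gf, gc] = gc not in possible
    return table


_TRIO_ERROR = _trio_truth_table()
# duo: a homozygous parent must transmit its allele
_DUO_ERROR = np.zeros((3, 3), dtype=bool)
_DUO_ERROR[0, 2] = _DUO_ERROR[2, 0] = True


def mendel_errors(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Per-locus count of Mendelian incompatibilities over pedigree entries.

    A (locus, child) pair is checked when the child call and at least one
    parent call are non-missing; with one usable parent the duo rule
    applies.  Children absent from the matrix are skipped (warning).
    """
    index = {ind: i for i, ind in enumerate(G.individual_ids)}
    counts = np.zeros(G.n_loci, dtype=np.int64)
    skipped = 0
    for child, mother, father in ped.entries:
        ci = index.get(child)
        if ci is None:
            skipped += 1
            continue
        mi = index.get(mother) if mother is not None else None
        fi = index.get(father) if father is not None else None
        gc = G.calls[ci]
        gm = G.calls[mi] if mi is not None else np.full(G.n_loci, MISSING, dtype=np.int8)
        gf = G.calls[fi] if fi is not None else np.full(G.n_loci, MISSING, dtype=np.int8)
        c_ok, m_ok, f_ok = gc != MISSING, gm != MISSING, gf != MISSING
        both = c_ok & m_ok & f_ok
        err = np.zeros(G.n_loci, dtype=bool)
        if both.any():
            err[both] = _TRIO_ERROR[gm[both], gf[both], gc[both]]
        only_m = c_ok & m_ok & ~f_ok
        if only_m.any():
            err[only_m] = _DUO_ERROR[gm[only_m], gc[only_m]]
        only_f = c_ok & f_ok & ~m_ok
        if only_f.any():
            err[only_f] = _DUO_ERROR[gf[only_f], gc[only_f]]
        counts += err
    if skipped:
        warnings.warn(f"{skipped} pedigree children absent from genotype matrix; skipped")
    return counts


def filter_mendel(G: GenotypeMatrix, ped: Pedigree) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove every locus with at least one Mendelian incompatibility."""
    if not ped.entries:
        warnings.warn("empty pedigree: Mendelian filter is the identity")
        out = G.copy()
        return out, _report("filter_mendel", G, out, n_trios=0)
    errors = mendel_errors(G, ped)
    out = G.select_loci(errors == 0)
    return out, _report("filter_mendel", G, out, n_trios=len(ped.entries))


# ---------------------------------------------------------------------------
# VIF-based LD pruning
# ---------------------------------------------------------------------------

def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of ``x`` (dosage with NaN missing) against the rest.

    Uses the pairwise-complete correlation matrix; the squared multiple
    correlation of column k on the others is r_k' S_k^{-1} r_k (pseudo-
    inverse, so exact collinearity yields +inf VIF).  Constant columns get
    VIF 1: a monomorphic site cannot be inflated.
    """
    w = x.shape[1]
    if w == 1:
        return np.ones(1)
    corr = pd.DataFrame(x).corr(min_periods=2).to_numpy()
    const = np.isnan(np.diag(corr))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    vifs = np.ones(w)
    for k in range(w):
        if const[k]:
            continue
        others = np.delete(np.arange(w), k)
        r = corr[k, others]
        S = corr[np.ix_(others, others)]
        r2 = float(r @ np.linalg.pinv(S) @ r)
        r2 = min(max(r2, 0.0), 1.0)
        vifs[k] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window variance-inflation-factor pruning of linked SNPs.

    Within each window of ``window`` surviving SNPs (never spanning
    scaffolds) the SNP with the largest VIF is removed, and VIFs
    recomputed, while any VIF exceeds ``vif_threshold``; the window then
    advances by ``step``.  Sweeps repeat until a full sweep removes
    nothing, so no window of the surviving set violates the threshold.
    Ties remove the lower-index SNP.
    """
    x = G.dosage_float()
    keep = np.ones(G.n_loci, dtype=bool)
    scaffolds = G.loci["scaffold"].to_numpy()
    changed = True
    while changed:
        changed = False
        for scaf in pd.unique(scaffolds):
            scaf_idx = np.flatnonzero((scaffolds == scaf) & keep)
            start = 0
            while start < len(scaf_idx):
                win = scaf_idx[start : start + window]
                win = win[keep[win]]  # earlier windows may have pruned
                while len(win) > 1:
                    vifs = _window_vifs(x[:, win])
                    worst = int(np.argmax(vifs))  # argmax -> lowest index on ties
                    if vifs[worst] > vif_threshold:
                        keep[win[worst]] = False
                        changed = True
                        win = np.delete(win, worst)
                    else:
                        break
                start += step
    out = G.select_loci(keep)
    return out, _report(
        "vif_prune", G, out, window=window, step=step, vif_threshold=vif_threshold
    )


# ---------------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------------

def unrelated_pups(ped: Pedigree) -> list[str]:
    """Greedy maximal set of pedigree children sharing no parent.

    Convenience for building cascade B's keep-list when explicit sample
    metadata is not supplied; children are scanned in pedigree order.
    """
    kept: list[str] = []
    used: set[str] = set()
    for child, mother, father in ped.entries:
        parents = {p for p in (mother, father) if p is not None}
        if parents & used:
            continue
        kept.append(child)
        used |= parents
    return kept


def cascade(
    G: GenotypeMatrix,
    which: str,
    ped: Optional[Pedigree] = None,
    idx: Optional[ScaffoldIndex] = None,
    keep_list: Optional[Sequence[str]] = None,
    population_labels: Optional[Mapping[str, str]] = None,
    params: Optional[Mapping[str, object]] = None,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Run one of the three named filter cascades.

    A (LD decay): depth mask [8,30] -> longest-100-scaffold restriction ->
    Mendelian filter -> keep-list (focal-population adults) -> MAF >= 0.1
    and call rate >= 0.5 -> HWE exact p >= 0.001.

    B (population structure): keep-list (unrelated pups + other
    populations; derived from the pedigree when absent) -> MAF >= 0.05 and
    call rate >= 0.99 -> per-population HWE -> VIF pruning (50 / 5 / 2).

    C (inbreeding): drop individuals > 90% missing -> depth mask [8,30] ->
    Mendelian filter -> keep-list -> MAF >= 0.05 and call rate >= 0.7 ->
    HWE -> VIF pruning.

    ``params`` overrides any threshold; defaults are the cascade's
    standard values.  Stages whose required inputs are not supplied
    (pedigree, scaffold index, keep-list) raise, except that an omitted
    keep-list means "keep everyone".
    """
    which = which.upper()
    if which not in {"A", "B", "C"}:
        raise ValueError(f"unknown cascade {which!r}")
    p = {
        "min_depth": 8, "max_depth": 30, "top_scaffolds": 100,
        "hwe_alpha": 0.001, "max_missing": 0.9,
        "vif_window": 50, "vif_step": 5, "vif_threshold": 2.0,
    }
    p["min_maf"] = 0.1 if which == "A" else 0.05
    p["min_call_rate"] = {"A": 0.5, "B": 0.99, "C": 0.7}[which]
    if params:
        p.update(params)

    reports: list[FilterReport] = []

    def run(stage: Callable[..., tuple[GenotypeMatrix, FilterReport]], g, *args, **kw):
        g2, rep = stage(g, *args, **kw)
        reports.append(rep)
        return g2

    g = locus_stats(G.copy())
    if which == "C":
        g = run(drop_high_missing_individuals, g, p["max_missing"])
    if which in {"A", "C"}:
        if G.depths is not None:
            g = run(mask_by_depth, g, p["min_depth"], p["max_depth"])
        elif G.n_loci:
            raise ValueError(f"cascade {which} requires per-genotype depths")
        if which == "A":
            if idx is None and G.n_loci:
                raise ValueError("cascade A requires a scaffold-length index")
            if idx is not None:
                g = run(restrict_scaffolds, g, idx, p["top_scaffolds"])
        if ped is None and G.n_loci:
            raise ValueError(f"cascade {which} requires a pedigree")
        if ped is not None:
            g = run(filter_mendel, g, ped)
    if which == "B" and keep_list is None and ped is not None:
        keep_list = [c for c in unrelated_pups(ped) if c in g.individual_ids]
    if keep_list is not None:
        g = run(keep_individuals, g, [i for i in keep_list if i in g.individual_ids])
    g = run(filter_maf, g, p["min_maf"])
    g = run(filter_call_rate, g, p["min_call_rate"])
    if g.n_loci:
        hwe_groups = population_labels if which == "B" else None
        g = run(filter_hwe, g, p["hwe_alpha"], hwe_groups)
    if which in {"B", "C"} and g.n_loci:
        g = run(vif_prune, g, p["vif_window"], p["vif_step"], p["vif_threshold"])
    return g, reports
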
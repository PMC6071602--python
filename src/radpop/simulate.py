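"""Synthetic genotype data with known truth for every analysis stage.

Each generator is fully determined by its seed and returns the latent
truth alongside the data: per-individual realized inbreeding f*,
population labels, phased haplotype pools, or the loci where Mendelian
errors were injected.  The models are the minimal ones the statistics in
this package assume:

* inbreeding — per locus, with probability f*_i an individual is
  autozygous (a homozygote drawn by allele frequency), otherwise a
  Hardy-Weinberg draw; genotype probabilities are therefore
  P(0) = q² + f pq, P(1) = 2pq(1-f), P(2) = p² + f pq.
* structure — Balding-Nichols: each population's locus frequency is a
  Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the ancestral p.
* LD — a forward Wright-Fisher haplotype pool with per-generation
  recombination between adjacent loci at distance-proportional rates,
  giving distance-dependent r² decay.
* trios — one gamete per parent, with optional injected incompatible
  child genotypes.

Autozygosity is simulated independently per locus (no runs-of-
homozygosity tracts); none of the statistics in this package is
tract-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Pedigree, locus_stats


@dataclass
class SimulationConfig:
    """Bundle of generator settings (one seed determines everything)."""

    n_individuals: int = 56
    n_loci: int = 2000
    seed: int = 0
    maf_min: float = 0.05
    allele_freqs: Optional[Sequence[float]] = None
    f_model: str = "two_point"  # constant | two_point | beta
    f_constant: float = 0.0
    f_two_point: tuple[float, float] = (0.0, 0.25)
    f_beta: tuple[float, float] = (0.5, 9.5)
    n_populations: int = 1
    fst: float = 0.1
    pool_size: int = 100
    generations: int = 100
    recomb_per_bp: float = 1e-6
    positions: Optional[Sequence[int]] = None
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0


def _locus_frame(n_loci: int, positions=None, scaffold: str = "scaf1") -> pd.DataFrame:
    if positions is None:
        positions = 1000 * (np.arange(n_loci) + 1)
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "position": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "G",
        }
    )


def _draw_freqs(rng, n_loci: int, maf_min: float, fixed=None) -> np.ndarray:
    if fixed is not None:
        p = np.asarray(fixed, dtype=float)
        if p.size != n_loci:
            raise ValueError("allele_freqs length must equal n_loci")
        return p
    return rng.uniform(maf_min, 0.5, size=n_loci)


def draw_f(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-individual realized inbreeding f* under the configured model."""
    n = cfg.n_individuals
    if cfg.f_model == "constant":
        return np.full(n, cfg.f_constant)
    if cfg.f_model == "two_point":
        return rng.choice(np.asarray(cfg.f_two_point, dtype=float), size=n)
    if cfg.f_model == "beta":
        a, b = cfg.f_beta
        return rng.beta(a, b, size=n)
    raise ValueError(f"unknown f_model {cfg.f_model!r}")


def simulate_inbred_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes with per-individual inbreeding; returns (matrix, true f*)."""
    rng = np.random.default_rng(cfg.seed)
    p = _draw_freqs(rng, cfg.n_loci, cfg.maf_min, cfg.allele_freqs)
    f = draw_f(cfg, rng)
    n, L = cfg.n_individuals, cfg.n_loci
    auto = rng.random((n, L)) < f[:, None]
    hom_alt = rng.random((n, L)) < p[None, :]
    a1 = rng.random((n, L)) < p[None, :]
    a2 = rng.random((n, L)) < p[None, :]
    hwe = a1.astype(np.int8) + a2.astype(np.int8)
    calls = np.where(auto, 2 * hom_alt.astype(np.int8), hwe).astype(np.int8)
    G = locus_stats(GenotypeMatrix([f"ind{i}" for i in range(n)], _locus_frame(L), calls))
    return G, f


def simulate_structured_populations(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols structured genotypes; returns (matrix, population labels)."""
    if cfg.n_populations < 1:
        raise ValueError("need at least one population")
    if not 0 < cfg.fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    L, n, K = cfg.n_loci, cfg.n_individuals, cfg.n_populations
    p_anc = _draw_freqs(rng, L, cfg.maf_min, cfg.allele_freqs)
    F = cfg.fst
    if K == 1:
        pop_freqs = p_anc[None, :]
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pop_freqs = rng.beta(a[None, :], b[None, :], size=(K, L))
    labels = np.repeat(np.arange(K), int(np.ceil(n / K)))[:n]
    pk = pop_freqs[labels]
    calls = (rng.random((n, L)) < pk).astype(np.int8) + (rng.random((n, L)) < pk).astype(np.int8)
    G = locus_stats(GenotypeMatrix([f"ind{i}" for i in range(n)], _locus_frame(L), calls))
    return G, labels


def simulate_ld_haplotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Wright-Fisher haplotype pool with recombination; returns (matrix, pool).

    The returned pool is the (2 x n_individuals, n_loci) array of phased
    haplotypes actually paired into the genotypes, the oracle for
    haplotypic r².
    """
    if cfg.pool_size < 20:
        raise ValueError("pool_size must be >= 20")
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    positions = (
        np.asarray(cfg.positions, dtype=int)
        if cfg.positions is not None
        else 1000 * (np.arange(L) + 1)
    )
    p0 = _draw_freqs(rng, L, cfg.maf_min, cfg.allele_freqs)
    H = cfg.pool_size
    pool = (rng.random((H, L)) < p0[None, :]).astype(np.int8)
    gaps = np.diff(positions).astype(float)
    rates = np.minimum(cfg.recomb_per_bp * gaps, 0.5)
    for _ in range(cfg.generations):
        pa = pool[rng.integers(0, H, size=H)]
        pb = pool[rng.integers(0, H, size=H)]
        # crossover process: switch source chromosome between adjacent loci
        switch = rng.random((H, L - 1)) < rates[None, :] if L > 1 else np.zeros((H, 0), bool)
        src = np.zeros((H, L), dtype=np.int8)
        src[:, 0] = rng.integers(0, 2, size=H)
        for j in range(1, L):
            src[:, j] = src[:, j - 1] ^ switch[:, j - 1]
        pool = np.where(src == 0, pa, pb).astype(np.int8)
    n = cfg.n_individuals
    picks = rng.integers(0, H, size=(2, n))
    hap1, hap2 = pool[picks[0]], pool[picks[1]]
    calls = (hap1 + hap2).astype(np.int8)
    paired = np.concatenate([hap1, hap2], axis=0)
    G = locus_stats(
        GenotypeMatrix([f"ind{i}" for i in range(n)], _locus_frame(L, positions), calls)
    )
    return G, paired


def haplotype_r2(haps: np.ndarray, i: int, j: int) -> float:
    """Direct haplotypic r² between loci ``i`` and ``j`` of a phased pool."""
    a, b = haps[:, i].astype(float), haps[:, j].astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def simulate_trios(
    G_parents: GenotypeMatrix,
    n_trios: int,
    mendel_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, Pedigree, list[tuple[int, int]]]:
    """Children from random parent pairs, with optional injected errors.

    Returns (matrix of parents + children, pedigree, injected), where
    ``injected`` lists (child_row, locus) positions whose child genotype
    was replaced by one incompatible with its parents.  Loci where both
    parents are heterozygous admit every child genotype, so injection
    skips them.
    """
    if G_parents.n_individuals < 2:
        raise ValueError("need at least 2 parents")
    rng = np.random.default_rng(seed)
    n_par, L = G_parents.shape
    child_calls = np.empty((n_trios, L), dtype=np.int8)
    entries = []
    pairs = []
    for t in range(n_trios):
        mi, fi = rng.choice(n_par, size=2, replace=False)
        pairs.append((mi, fi))
        gm, gf = G_parents.calls[mi], G_parents.calls[fi]
        gam_m = np.where(gm == 1, rng.integers(0, 2, L), (gm == 2).astype(int))
        gam_f = np.where(gf == 1, rng.integers(0, 2, L), (gf == 2).astype(int))
        child = (gam_m + gam_f).astype(np.int8)
        child[(gm == MISSING) | (gf == MISSING)] = MISSING
        child_calls[t] = child
        entries.append(
            (f"child{t}", G_parents.individual_ids[mi], G_parents.individual_ids[fi])
        )
    injected: list[tuple[int, int]] = []
    if mendel_error_rate > 0:
        for t in range(n_trios):
            mi, fi = pairs[t]
            gm, gf = G_parents.calls[mi], G_parents.calls[fi]
            for j in range(L):
                if rng.random() >= mendel_error_rate:
                    continue
                bad = _incompatible_child(int(gm[j]), int(gf[j]))
                if bad is None:
                    continue
                child_calls[t, j] = bad
                injected.append((t, j))
    calls = np.vstack([G_parents.calls, child_calls])
    ids = list(G_parents.individual_ids) + [e[0] for e in entries]
    G = locus_stats(GenotypeMatrix(ids, G_parents.loci.copy(), calls))
    return G, Pedigree(entries), injected


def _incompatible_child(gm: int, gf: int) -> Optional[int]:
    """A child genotype impossible for the given parents, or None if all fit."""
    if MISSING in (gm, gf):
        return None
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {a + b for a in gametes[gm] for b in gametes[gf]}
    impossible = [g for g in (0, 1, 2) if g not in possible]
    return impossible[0] if impossible else None


def apply_depth_and_missingness(G: GenotypeMatrix, cfg: SimulationConfig) -> GenotypeMatrix:
    """Attach negative-binomial read depths and drop calls at ``missing_rate``.

    Depth ~ NB with the configured mean and dispersion (gamma-Poisson
    mixture); larger dispersion is closer to Poisson.
    """
    rng = np.random.default_rng(cfg.seed)
    out = G.copy()
    shape = cfg.depth_dispersion
    lam = rng.gamma(shape, cfg.depth_mean / shape, size=out.shape)
    out.depths = rng.poisson(lam).astype(np.int32)
    if cfg.missing_rate > 0:
        drop = rng.random(out.shape) < cfg.missing_rate
        out.calls[drop] = MISSING
        out.depths[drop] = -1
    locus_stats(out)
    return out


def theoretical_g2(f_values: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Closed-form g2 = var(f) / (1 - E[f])² for a discrete f distribution."""
    f = np.asarray(f_values, dtype=float)
    w = np.full(f.size, 1.0 / f.size) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mean = float((w * f).sum())
    var = float((w * (f - mean) ** 2).sum())
    return var / (1.0 - mean) ** 2
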
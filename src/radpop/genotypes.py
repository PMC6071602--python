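"""Core genotype container and per-locus summary statistics.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a compact
``int8`` matrix with ``MISSING`` (-1) marking no-calls, alongside a locus
table (scaffold, position, alleles and cached per-locus statistics) and an
optional read-depth matrix of the same shape.  Alt-allele dosage is the
stored code; minor-allele orientation is applied per statistic, which keeps
the codes stable under filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage code for a missing genotype call.
MISSING: int = -1

#: Columns every locus table carries.
LOCUS_COLUMNS = ["scaffold", "position", "ref", "alt"]

#: Per-locus statistic columns populated by :func:`locus_stats`.
STAT_COLUMNS = ["alt_freq", "maf", "call_rate", "obs_het"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of biallelic SNP dosages.

    Parameters
    ----------
    individual_ids
        Unique sample labels, one per row of ``calls``.
    loci
        DataFrame with at least ``scaffold``, ``position`` (1-based bp),
        ``ref`` and ``alt`` columns, one row per locus, sorted by
        (scaffold, position) within each scaffold.
    calls
        ``(n_individuals, n_loci)`` int8 array of alt-allele dosages with
        :data:`MISSING` for no-calls.
    depths
        Optional parallel array of non-negative read depths; ``-1`` where
        depth was not recorded.
    """

    individual_ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    depths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n_ind, n_loci = self.calls.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n_ind} call rows"
            )
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("individual_ids must be unique")
        if len(self.loci) != n_loci:
            raise ValueError(f"{len(self.loci)} locus rows for {n_loci} call columns")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depths must match calls shape")
        self.loci = self.loci.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.calls == MISSING

    # -- subsetting ------------------------------------------------------
    def select_loci(self, mask: np.ndarray, recompute: bool = True) -> "GenotypeMatrix":
        """Return a new matrix keeping loci where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        out = GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            loci=self.loci.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
            depths=None if self.depths is None else self.depths[:, mask].copy(),
        )
        return locus_stats(out) if recompute else out

    def select_individuals(
        self, keep: Sequence[str] | np.ndarray, recompute: bool = True
    ) -> "GenotypeMatrix":
        """Return a new matrix keeping the named individuals (or a bool mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            keep_set = set(keep)
            unknown = keep_set - set(self.individual_ids)
            if unknown:
                raise KeyError(f"unknown individuals: {sorted(unknown)}")
            mask = np.array([i in keep_set for i in self.individual_ids])
        out = GenotypeMatrix(
            individual_ids=[i for i, m in zip(self.individual_ids, mask) if m],
            loci=self.loci.copy(),
            calls=self.calls[mask].copy(),
            depths=None if self.depths is None else self.depths[mask].copy(),
        )
        return locus_stats(out) if recompute else out

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            loci=self.loci.copy(),
            calls=self.calls.copy(),
            depths=None if self.depths is None else self.depths.copy(),
        )

    def dosage_float(self) -> np.ndarray:
        """Calls as float with NaN for missing — the substrate for correlations."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_depths = (self.depths is None) == (other.depths is None) and (
            self.depths is None or np.array_equal(self.depths, other.depths)
        )
        return (
            self.individual_ids == other.individual_ids
            and np.array_equal(self.calls, other.calls)
            and self.loci[LOCUS_COLUMNS].equals(other.loci[LOCUS_COLUMNS])
            and same_depths
        )


@dataclass(frozen=True)
class Pedigree:
    """Child / mother / father triples; ``None`` marks an unknown parent."""

    entries: list[tuple[str, Optional[str], Optional[str]]]

    def __post_init__(self) -> None:
        children = [c for c, _, _ in self.entries]
        if len(set(children)) != len(children):
            dupes = sorted({c for c in children if children.count(c) > 1})
            raise ValueError(f"duplicate child ids in pedigree: {dupes}")
        for child, mother, father in self.entries:
            if child in (mother, father):
                raise ValueError(f"child {child!r} listed as its own parent")

    @property
    def children(self) -> list[str]:
        return [c for c, _, _ in self.entries]

    @property
    def parents(self) -> set[str]:
        out: set[str] = set()
        for _, m, f in self.entries:
            out.update(p for p in (m, f) if p is not None)
        return out


@dataclass(frozen=True)
class ScaffoldIndex:
    """Scaffold label -> length (bp), with rank-by-length queries."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.lengths.items() if l <= 0}
        if bad:
            raise ValueError(f"non-positive scaffold lengths: {bad}")

    def top(self, n: int) -> set[str]:
        """Labels of the ``n`` longest scaffolds (ties broken by label order)."""
        ranked = sorted(self.lengths.items(), key=lambda kv: (-kv[1], kv[0]))
        return {label for label, _ in ranked[:n]}


def locus_stats(G: GenotypeMatrix) -> GenotypeMatrix:
    """Populate per-locus alt_freq, maf, call_rate and obs_het in ``G.loci``.

    Frequencies use non-missing calls only.  A locus with zero non-missing
    calls gets ``call_rate`` 0 and NaN (undefined) frequency statistics.
    Mutates and returns ``G`` for chaining.
    """
    calls = G.calls
    typed = calls != MISSING
    n_typed = typed.sum(axis=0)
    alt_counts = np.where(typed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_typed > 0, alt_counts / (2.0 * np.maximum(n_typed, 1)), np.nan)
        obs_het = np.where(
            n_typed > 0, (calls == 1).sum(axis=0) / np.maximum(n_typed, 1), np.nan
        )
    maf = np.minimum(p, 1.0 - p)
    G.loci["alt_freq"] = p
    G.loci["maf"] = maf
    G.loci["call_rate"] = n_typed / max(G.n_individuals, 1)
    G.loci["obs_het"] = obs_het
    return G
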
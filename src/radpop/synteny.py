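"""Pairwise-alignment parsing and per-scaffold synteny profiling.

Alignment blocks between a fragmented query assembly and a chromosome-
level target genome are read from MAF (via Biopython), optionally
filtered by query span, then aggregated per query scaffold: the aligned
length going to each target chromosome, the pooled sequence divergence,
and a classification of each scaffold as mapping *exclusively*, *mainly*
(majority fraction above a threshold) or *split* across targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio import AlignIO


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapped alignment segment, coordinates 0-based half-open, forward strand."""

    query_scaffold: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    aligned_columns: int
    matched_columns: int
    strand: str  # strand of the query relative to the target's forward strand

    def __post_init__(self) -> None:
        if not (0 <= self.matched_columns <= self.aligned_columns):
            raise ValueError("matched_columns must lie in [0, aligned_columns]")
        if self.query_end <= self.query_start or self.target_end <= self.target_start:
            raise ValueError("block ends must exceed starts")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def _forward_coords(start: int, size: int, strand: int, src_size: int) -> tuple[int, int]:
    """MAF strand-relative start/size -> forward-strand half-open interval."""
    if strand >= 0:
        return start, start + size
    return src_size - (start + size), src_size - start


def read_maf(path: str, query_first: bool = False) -> list[AlignmentBlock]:
    """Read pairwise alignment blocks from a MAF file.

    By default the first "s" line of each block is the target (database)
    sequence and the second the query, the convention of LAST output; set
    ``query_first=True`` for the opposite order.  Aligned columns are
    those where both sequences carry a base; matched columns additionally
    agree (case-insensitive).
    """
    blocks: list[AlignmentBlock] = []
    for k, aln in enumerate(AlignIO.parse(path, "maf")):
        if len(aln) != 2:
            raise ValueError(f"alignment block {k} has {len(aln)} sequences, expected 2")
        first, second = aln[0], aln[1]
        query, target = (first, second) if query_first else (second, first)
        qseq, tseq = str(query.seq).upper(), str(target.seq).upper()
        aligned = matched = 0
        for qc, tc in zip(qseq, tseq):
            if qc != "-" and tc != "-":
                aligned += 1
                if qc == tc:
                    matched += 1
        qa, ta = query.annotations, target.annotations
        qs, qe = _forward_coords(qa["start"], qa["size"], qa["strand"], qa["srcSize"])
        ts, te = _forward_coords(ta["start"], ta["size"], ta["strand"], ta["srcSize"])
        strand = "+" if qa["strand"] == ta["strand"] else "-"
        blocks.append(
            AlignmentBlock(query.id, qs, qe, target.id, ts, te, aligned, matched, strand)
        )
    return blocks


def filter_blocks(blocks: Iterable[AlignmentBlock], min_length: int) -> list[AlignmentBlock]:
    """Keep blocks whose query span strictly exceeds ``min_length`` bp."""
    return [b for b in blocks if b.query_span > min_length]


@dataclass(frozen=True)
class SyntenyProfile:
    """Per-scaffold aggregation of aligned length over target chromosomes."""

    query_scaffold: str
    total_aligned: int  # query-side bp summed over blocks
    fractions: dict[str, float]  # target chromosome -> fraction of total
    classification: str  # exclusive | majority | split


def synteny_profile(
    blocks: Iterable[AlignmentBlock], majority_threshold: float = 0.9
) -> dict[str, SyntenyProfile]:
    """Aggregate blocks into per-scaffold synteny profiles.

    Aligned length is the query-side span of each block (overlaps counted
    as-is).  Classification: *exclusive* when a single target chromosome
    receives all alignment, *majority* when the top target's fraction
    strictly exceeds ``majority_threshold``, *split* otherwise.
    """
    sums: dict[str, dict[str, int]] = {}
    for b in blocks:
        sums.setdefault(b.query_scaffold, {})
        sums[b.query_scaffold][b.target_chrom] = (
            sums[b.query_scaffold].get(b.target_chrom, 0) + b.query_span
        )
    profiles: dict[str, SyntenyProfile] = {}
    for scaf, per_target in sums.items():
        total = sum(per_target.values())
        fractions = {t: v / total for t, v in per_target.items()}
        top = max(fractions.values())
        if len(fractions) == 1:
            cls = "exclusive"
        elif top > majority_threshold:
            cls = "majority"
        else:
            cls = "split"
        profiles[scaf] = SyntenyProfile(scaf, total, fractions, cls)
    return profiles


def pairwise_divergence(blocks: Iterable[AlignmentBlock]) -> float:
    """Pooled (length-weighted) substitution divergence over blocks.

    1 - (sum of matched columns / sum of aligned columns); gap columns are
    excluded from both sums.  Invariant to block order.
    """
    aligned = matched = 0
    for b in blocks:
        aligned += b.aligned_columns
        matched += b.matched_columns
    if aligned == 0:
        raise ValueError("no aligned columns: divergence undefined")
    return 1.0 - matched / aligned


def profiles_to_frame(profiles: dict[str, SyntenyProfile]) -> pd.DataFrame:
    """Long-form table of profiles (scaffold, target, fraction, classification)."""
    rows = []
    for scaf in sorted(profiles):
        p = profiles[scaf]
        for target, frac in sorted(p.fractions.items(), key=lambda kv: -kv[1]):
            rows.append((scaf, p.total_aligned, target, frac, p.classification))
    return pd.DataFrame(
        rows, columns=["scaffold", "total_aligned", "target", "fraction", "classification"]
    )
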
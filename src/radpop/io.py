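"""Readers and writers for the package's interchange formats.

VCF v4.2 is the single genotype interchange format (GT, optionally DP);
pedigrees, scaffold lengths and clustering-run tables are plain TSV.
All coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    Pedigree,
    ScaffoldIndex,
    locus_stats,
)

_DP_MISSING = -2147483648  # htslib sentinel for absent integer FORMAT values


def read_vcf(path: str, keep_individuals: Optional[Sequence[str]] = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are dropped.  Genotypes with any
    missing allele (``./.`` and half-calls) become :data:`MISSING`.
    FORMAT/DP populates the depth matrix when present.
    """
    try:
        vcf = VCF(os.fspath(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise ValueError(f"could not parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if keep_individuals is not None:
        missing = [s for s in keep_individuals if s not in samples]
        if missing:
            raise KeyError(f"individuals absent from VCF header: {missing}")
        vcf.close()
        vcf = VCF(os.fspath(path), samples=list(keep_individuals))
        samples = list(vcf.samples)

    rows: list[tuple[str, int, str, str]] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt == "*":
            continue
        rows.append((var.CHROM, var.POS, ref, alt))
        geno = var.genotype.array()  # (n, ploidy+1); last col = phasing
        alleles = geno[:, :-1]
        dosage = alleles.sum(axis=1).astype(np.int8)
        dosage[(alleles < 0).any(axis=1)] = MISSING
        call_cols.append(dosage)
        try:
            dp = var.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is not None:
            any_depth = True
            d = dp[:, 0].astype(np.int64)
            d[d == _DP_MISSING] = -1
            depth_cols.append(d.astype(np.int32))
        else:
            depth_cols.append(np.full(len(samples), -1, dtype=np.int32))
    vcf.close()

    loci = pd.DataFrame(rows, columns=["scaffold", "position", "ref", "alt"])
    calls = (
        np.column_stack(call_cols)
        if call_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depths = (
        np.column_stack(depth_cols).astype(np.int32)
        if (depth_cols and any_depth)
        else None
    )
    G = GenotypeMatrix(samples, loci, calls, depths)
    return locus_stats(G) if G.n_loci else G


def write_genotypes(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF (GT, and DP when depths are present).

    Output is re-readable by :func:`read_vcf`; missing calls are ``./.``.
    """
    has_dp = G.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    contigs = list(dict.fromkeys(G.loci["scaffold"])) if G.n_loci else []
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + list(G.individual_ids)))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(G.n_loci):
        row = G.loci.iloc[j]
        fields = [
            str(row["scaffold"]), str(int(row["position"])), ".",
            str(row["ref"]), str(row["alt"]), ".", ".", ".", fmt,
        ]
        for i in range(G.n_individuals):
            g = gt_str[int(G.calls[i, j])]
            if has_dp:
                d = int(G.depths[i, j])
                g = f"{g}:{d if d >= 0 else '.'}"
            fields.append(g)
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pedigree(path: str) -> Pedigree:
    """Read a 3-column TSV pedigree (child, mother, father; "0"/empty = unknown)."""
    entries: list[tuple[str, Optional[str], Optional[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[0].lower() in {"child", "id", "offspring"}:
                continue
            if len(parts) < 3:
                parts = parts + [""] * (3 - len(parts))
            child, mother, father = (p.strip() for p in parts[:3])
            if not child:
                raise ValueError(f"{path}:{lineno}: empty child id")
            entries.append(
                (
                    child,
                    mother if mother not in {"", "0"} else None,
                    father if father not in {"", "0"} else None,
                )
            )
    return Pedigree(entries)


def read_scaffold_lengths(path: str) -> ScaffoldIndex:
    """Read a 2-column TSV of (scaffold, length_bp)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["scaffold", "length"])
    if df["scaffold"].iloc[0] in {"scaffold", "name"}:
        df = df.iloc[1:]
    return ScaffoldIndex({str(s): int(l) for s, l in zip(df["scaffold"], df["length"])})


def read_run_table(path: str) -> pd.DataFrame:
    """Read a clustering-run table TSV with columns (K, run, lnp)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    need = {"k", "run", "lnp"}
    if not need <= set(cols):
        raise ValueError(f"run table needs columns {sorted(need)}, got {list(df.columns)}")
    out = df.rename(columns={cols["k"]: "K", cols["run"]: "run", cols["lnp"]: "lnp"})
    out["K"] = out["K"].astype(int)
    out["lnp"] = out["lnp"].astype(float)
    return out[["K", "run", "lnp"]]
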
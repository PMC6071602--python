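"""Config-driven orchestration of the cascades and downstream analyses.

A single YAML (or dict) config selects the inputs, the filter cascade and
the analyses to run; all thresholds default to the cascades' standard
values and all randomness derives from one root seed.  The resolved
config is echoed into the output directory so a rerun reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import filtering, inbreeding, io, ld, structure
from .genotypes import GenotypeMatrix

log = logging.getLogger("radpop")

DEFAULT_CONFIG: dict = {
    "vcf": None,
    "pedigree": None,
    "scaffold_lengths": None,
    "populations": None,  # TSV: individual <tab> population
    "keep_individuals": None,  # explicit keep-list file, one id per line
    "cascade": None,  # A | B | C | null (no filtering)
    "filter_params": {},
    "analyses": [],  # subset of: ld, inbreeding, pca, structure_summary
    "run_table": None,
    "ld": {"max_distance": 500_000, "estimator": "em", "n_gametes": None,
           "background_min_distance": 400_000},
    "inbreeding": {"n_boot": 1000, "n_perm": 1000},
    "pca": {"n_axes": 3, "scaling": "centered"},
    "seed": 0,
    "out_dir": "radpop_out",
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _read_two_col(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {str(a): str(b) for a, b in zip(df[0], df[1])}


def run_pipeline(config: Mapping, out_dir: Optional[str] = None) -> str:
    """Run the configured cascade and analyses; returns the output directory.

    Every analysis output is written as TSV/JSON next to the filter audit
    trail (``filter_report.tsv``), a log, and the resolved config.  A
    stage failure leaves partial outputs plus a ``FAILED`` marker file.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = out_dir or cfg["out_dir"]
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "pipeline.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    with open(os.path.join(out, "config.resolved.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    try:
        _run(cfg, out)
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _run(cfg: dict, out: str) -> None:
    if cfg["vcf"] is None:
        raise ValueError("config must name an input VCF")
    G = io.read_vcf(cfg["vcf"])
    log.info("read %d loci x %d individuals", G.n_loci, G.n_individuals)

    ped = io.read_pedigree(cfg["pedigree"]) if cfg["pedigree"] else None
    idx = io.read_scaffold_lengths(cfg["scaffold_lengths"]) if cfg["scaffold_lengths"] else None
    pops = _read_two_col(cfg["populations"]) if cfg["populations"] else None
    keep = None
    if cfg["keep_individuals"]:
        with open(cfg["keep_individuals"]) as fh:
            keep = [l.strip() for l in fh if l.strip()]

    if cfg["cascade"]:
        G, reports = filtering.cascade(
            G, cfg["cascade"], ped=ped, idx=idx, keep_list=keep,
            population_labels=pops, params=cfg["filter_params"],
        )
        filtering.reports_to_frame(reports).to_csv(
            os.path.join(out, "filter_report.tsv"), sep="\t", index=False
        )
        io.write_genotypes(G, os.path.join(out, "filtered.vcf"))
        log.info("cascade %s -> %d loci x %d individuals",
                 cfg["cascade"], G.n_loci, G.n_individuals)

    for analysis in cfg["analyses"]:
        log.info("running analysis: %s", analysis)
        if analysis == "ld":
            _run_ld(cfg, G, out)
        elif analysis == "inbreeding":
            _run_inbreeding(cfg, G, out)
        elif analysis == "pca":
            _run_pca(cfg, G, out)
        elif analysis == "structure_summary":
            _run_structure_summary(cfg, out)
        else:
            raise ValueError(f"unknown analysis {analysis!r}")


def _run_ld(cfg: dict, G: GenotypeMatrix, out: str) -> None:
    opts = cfg["ld"]
    pairs = ld.pairwise_r2(G, opts["max_distance"], opts["estimator"])
    pairs.to_csv(os.path.join(out, "ld_pairs.tsv"), sep="\t", index=False)
    n_gametes = opts["n_gametes"] or 2 * G.n_individuals
    summary: dict = {"n_pairs": int(len(pairs)), "n_gametes": int(n_gametes)}
    if len(pairs) >= 10:
        fit = ld.fit_hill_weir(pairs, n_gametes)
        summary.update(
            C=fit.C, sse=fit.residual_sse, converged=fit.converged,
            decay_bp_r2_0_5=ld.decay_distance(fit, 0.5),
            decay_bp_r2_0_2=ld.decay_distance(fit, 0.2),
        )
        far = pairs["distance"] >= opts["background_min_distance"]
        if far.any():
            summary["background_r2"] = ld.background_level(
                pairs, opts["background_min_distance"]
            )
    with open(os.path.join(out, "ld_fit.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _run_inbreeding(cfg: dict, G: GenotypeMatrix, out: str) -> None:
    opts = cfg["inbreeding"]
    table = inbreeding.inbreeding_table(G)
    table.to_csv(os.path.join(out, "inbreeding.tsv"), sep="\t", index=False)
    est = inbreeding.g2_estimate(
        G, n_boot=opts["n_boot"], n_perm=opts["n_perm"], seed=cfg["seed"]
    )
    payload = dataclasses.asdict(est)
    var_fhat = {f"var_{c}": float(np.nanvar(table[c], ddof=1)) for c in ("smlh", "f1", "f2", "f3")}
    payload["variance_of_estimates"] = var_fhat
    payload["expected_r2_f"] = {
        k: inbreeding.expected_r2_f(est.point, v) for k, v in var_fhat.items() if v > 0
    }
    with open(os.path.join(out, "g2.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _run_pca(cfg: dict, G: GenotypeMatrix, out: str) -> None:
    opts = cfg["pca"]
    res = structure.pca_genotypes(G, opts["n_axes"], opts["scaling"])
    df = pd.DataFrame(
        res.scores, columns=[f"PC{k+1}" for k in range(res.scores.shape[1])]
    )
    df.insert(0, "individual", res.individual_ids)
    df.to_csv(os.path.join(out, "pca_scores.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"eigenvalue": res.eigenvalues, "pct_variance": res.pct_variance}
    ).to_csv(os.path.join(out, "pca_eigenvalues.tsv"), sep="\t", index=False)


def _run_structure_summary(cfg: dict, out: str) -> None:
    if not cfg["run_table"]:
        raise ValueError("structure_summary needs a run_table path")
    table = io.read_run_table(cfg["run_table"])
    structure.evanno_delta_k(table).to_csv(
        os.path.join(out, "delta_k.tsv"), sep="\t", index=False
    )
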
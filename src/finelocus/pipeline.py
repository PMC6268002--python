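"""YAML-configured orchestration of the synthetic study, with output manifest.

Stages run in dependency order: simulate -> ld -> {pics, finemap, paintor}
-> smr -> motif -> aei, as selected.  Every stochastic stage takes an
explicit seed from the config; a fixed config therefore yields
byte-identical outputs.  The manifest lists every file written with its
sha256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from finelocus import aei as aei_mod
from finelocus import motif as motif_mod
from finelocus.finemap import posterior_exhaustive, posterior_sss
from finelocus.ldtools import LDMatrix, read_summary, write_summary
from finelocus.locus import Locus
from finelocus.paintor_em import em_fit
from finelocus.pics import pics_posterior
from finelocus.smr import results_frame, smr_pipeline
from finelocus.synthetic import (
    SimScenario,
    sim_annotations,
    sim_locus,
    sim_pair_scenario,
    sim_qpcr_series,
)

log = logging.getLogger("finelocus")

STAGE_ORDER = ["simulate", "pics", "finemap", "paintor", "smr", "motif", "aei"]

_STAGE_KEYS = {
    "simulate": {"seed", "m_snp", "rho", "lam", "causal_idx", "n_loci", "gamma0", "gamma1"},
    "pics": {"seed", "n_perm", "r2_min"},
    "finemap": {"seed", "mode", "k_max", "prior_sd", "n_iter"},
    "paintor": {"k_max", "tol", "max_iter"},
    "smr": {"seed", "alpha_smr", "alpha_heidi", "scenario", "lambda_gwas", "lambda_eqtl", "n_gwas", "n_eqtl"},
    "motif": {"seed", "p_cutoff", "pwm_file", "range_bp", "window_bp"},
    "aei": {"seed", "slope", "intercept", "noise_sd", "n_het", "true_ratio"},
}
_TOP_KEYS = {"outdir", "stages", "log_level"} | set(_STAGE_KEYS)


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    stages = cfg.get("stages", STAGE_ORDER)
    for st in stages:
        if st not in STAGE_ORDER:
            raise ConfigError(f"unknown stage {st!r}")
    for st, keys in _STAGE_KEYS.items():
        block = cfg.get(st, {})
        if not isinstance(block, dict):
            raise ConfigError(f"stage block {st!r} must be a mapping")
        unknown = set(block) - keys
        if unknown:
            raise ConfigError(
                f"unknown key(s) in stage {st!r}: {', '.join(sorted(unknown))}"
            )
        if st in ("simulate", "pics", "finemap", "smr", "motif", "aei") and st in stages:
            if "seed" not in block:
                raise ConfigError(f"stage {st!r} requires an explicit seed")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config_path, outdir=None) -> dict:
    """Execute the configured stages; returns the output manifest."""
    cfg = load_config(config_path)
    out = Path(outdir or cfg.get("outdir", "finelocus_out"))
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.get("log_level", "INFO")))
    stages = cfg.get("stages", STAGE_ORDER)
    written: list[Path] = []

    locus = None
    truth = None

    if "simulate" in stages:
        b = cfg.get("simulate", {})
        seed = int(b["seed"])
        locus, truth = sim_locus(
            m_snp=int(b.get("m_snp", 12)),
            rho=float(b.get("rho", 0.9)),
            lam=float(b.get("lam", 6.0)),
            causal_idx=b.get("causal_idx"),
            seed=seed,
        )
        annots = sim_annotations(
            truth, float(b.get("gamma0", -2.0)), float(b.get("gamma1", 2.0)), seed=seed + 1
        )
        locus = Locus(stats=locus.stats, ld=locus.ld, annotations=annots)
        write_summary(locus.stats, out / "gwas.ma")
        locus.ld.to_tsv(out / "ld.tsv")
        pd.DataFrame(locus.annotations, columns=["annot1"]).assign(
            SNP=locus.ids
        )[["SNP", "annot1"]].to_csv(out / "annotations.tsv", sep="\t", index=False)
        written += [out / "gwas.ma", out / "ld.tsv", out / "annotations.tsv"]
        log.info("simulate: wrote %d-SNP locus (causal %s)", locus.m, truth.causal_idx)

    def need_locus():
        nonlocal locus
        if locus is None:
            stats = read_summary(out / "gwas.ma")
            ld = LDMatrix.from_tsv(out / "ld.tsv")
            annot_path = out / "annotations.tsv"
            annots = None
            if annot_path.exists():
                annots = pd.read_csv(annot_path, sep="\t").drop(columns="SNP").to_numpy()
            locus = Locus(stats=stats, ld=ld, annotations=annots)
        return locus

    if "pics" in stages:
        b = cfg.get("pics", {})
        res = pics_posterior(
            need_locus(),
            n_perm=int(b.get("n_perm", 10_000)),
            r2_min=float(b.get("r2_min", 0.5)),
            seed=int(b["seed"]),
        )
        res.to_frame().to_csv(out / "pics.tsv", sep="\t", index=False)
        written.append(out / "pics.tsv")
        log.info("pics: top candidate %s", res.to_frame().iloc[0]["id"])

    if "finemap" in stages:
        b = cfg.get("finemap", {})
        mode = b.get("mode", "exhaustive")
        kw = dict(k_max=int(b.get("k_max", 5)), prior_sd=float(b.get("prior_sd", 3.0)))
        if mode == "sss":
            res = posterior_sss(
                need_locus(), n_iter=int(b.get("n_iter", 500)), seed=int(b["seed"]), **kw
            )
        else:
            res = posterior_exhaustive(need_locus(), **kw)
        res.to_frame().to_csv(out / "finemap_pips.tsv", sep="\t", index=False)
        res.configs_frame().to_csv(out / "finemap_configs.tsv", sep="\t", index=False)
        written += [out / "finemap_pips.tsv", out / "finemap_configs.tsv"]
        log.info("finemap (%s): evaluated %d configs", mode, res.n_evaluated)

    if "paintor" in stages:
        b = cfg.get("paintor", {})
        loc = need_locus()
        # single-locus EM is unstable; duplicate the locus for a demo fit only
        model, pips = em_fit(
            [loc, loc],
            k_max=int(b.get("k_max", 2)),
            tol=float(b.get("tol", 1e-4)),
            max_iter=int(b.get("max_iter", 50)),
        )
        pd.DataFrame({"id": loc.ids, "pip": pips[0]}).to_csv(
            out / "paintor_pips.tsv", sep="\t", index=False
        )
        enrich = pd.DataFrame(
            {
                "term": ["intercept"] + [f"annot{i + 1}" for i in range(len(model.gamma) - 1)],
                "gamma": model.gamma,
                "se": model.gamma_se if model.gamma_se is not None else np.nan,
            }
        )
        enrich.to_csv(out / "paintor_enrichment.tsv", sep="\t", index=False)
        written += [out / "paintor_pips.tsv", out / "paintor_enrichment.tsv"]
        log.info("paintor: gamma = %s", np.round(model.gamma, 3))

    if "smr" in stages:
        b = cfg.get("smr", {})
        from finelocus.synthetic import sim_haplotypes
        from finelocus.ldtools import ld_from_haplotypes

        seed = int(b["seed"])
        panel = sim_haplotypes(2000, 30, 0.9, seed=seed)
        kind = b.get("scenario", "pleiotropy")
        ce = 5
        cg = 5 if kind == "pleiotropy" else (12 if kind == "linkage" else 5)
        scen = SimScenario(
            scenario_kind=kind,
            causal_gwas=cg,
            causal_eqtl=ce,
            lambda_gwas=0.0 if kind == "null" else float(b.get("lambda_gwas", 6.0)),
            lambda_eqtl=float(b.get("lambda_eqtl", 8.0)),
            n_gwas=int(b.get("n_gwas", 100_000)),
            n_eqtl=int(b.get("n_eqtl", 500)),
        )
        gwas, eqtl = sim_pair_scenario(panel, scen, seed=seed + 1)
        ld = ld_from_haplotypes(panel)
        res = smr_pipeline(
            gwas,
            {"geneA": eqtl},
            ld,
            alpha_smr=float(b.get("alpha_smr", 0.05)),
            alpha_heidi=float(b.get("alpha_heidi", 0.05)),
        )
        results_frame(res).to_csv(out / "smr.tsv", sep="\t", index=False)
        written.append(out / "smr.tsv")
        log.info("smr: %s", results_frame(res).to_dict("records"))

    if "motif" in stages:
        b = cfg.get("motif", {})
        seed = int(b["seed"])
        if b.get("pwm_file"):
            pwm = motif_mod.parse_jaspar(Path(b["pwm_file"]).read_text())
        else:
            # FOX-family-like AT-rich toy motif
            pwm = motif_mod.PWM(
                counts=np.array(
                    [
                        [20, 1, 1, 25, 25, 1, 25, 1],
                        [2, 1, 1, 1, 1, 25, 1, 1],
                        [2, 25, 1, 1, 1, 1, 1, 1],
                        [4, 1, 25, 1, 1, 1, 1, 25],
                    ]
                ),
                name="toy_forkhead",
            )
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), p=[0.29, 0.21, 0.21, 0.29], size=5000))
        cons = pwm.consensus()
        seq = seq[:2000] + cons + seq[2000 + len(cons):]
        hits = motif_mod.scan_sequences(
            {"synthetic_region": seq}, pwm, p_cutoff=float(b.get("p_cutoff", 1e-4))
        )
        pd.DataFrame(
            [
                {
                    "seq": h.seq_id, "start": h.start, "strand": h.strand,
                    "score": h.score, "rel_score": h.rel_score, "pvalue": h.pvalue,
                }
                for h in hits
            ]
        ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        written.append(out / "motif_hits.tsv")
        log.info("motif: %d hits", len(hits))

    if "aei" in stages:
        b = cfg.get("aei", {})
        seed = int(b["seed"])
        series = sim_qpcr_series(
            slope=float(b.get("slope", 0.9)),
            intercept=float(b.get("intercept", 0.1)),
            noise_sd=float(b.get("noise_sd", 0.05)),
            seed=seed,
        )
        calib = aei_mod.fit_calibration(
            series["true_log2_ratio"], series["measured_log2_ratio"]
        )
        rng = np.random.default_rng(seed + 1)
        n_het = int(b.get("n_het", 12))
        true_ratio = float(b.get("true_ratio", 0.65))
        true_c = np.log2(true_ratio) + rng.normal(0, 0.1, n_het)
        meas_c = calib.intercept + calib.slope * true_c
        meas_g = calib.intercept + calib.slope * np.zeros(n_het)
        ratios = [
            aei_mod.correct_and_normalize(c, g, calib) for c, g in zip(meas_c, meas_g)
        ]
        mean_ratio, p = aei_mod.cohort_imbalance_test(ratios)
        pd.DataFrame(
            {"sample": [f"het{i + 1}" for i in range(n_het)], "normalized_ratio": ratios}
        ).to_csv(out / "aei_samples.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"mean_ratio": mean_ratio, "p": p, "slope": calib.slope, "intercept": calib.intercept, "r2": calib.r_squared}]
        ).to_csv(out / "aei_summary.tsv", sep="\t", index=False)
        written += [out / "aei_samples.tsv", out / "aei_summary.tsv"]
        log.info("aei: mean ratio %.3f (p=%.2g)", mean_ratio, p)

    manifest = {
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
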
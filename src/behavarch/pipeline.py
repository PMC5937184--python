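"""End-to-end pipeline driver: simulate -> meta / grm -> greml -> gwas ->
pleiotropy -> direction, with TSV outputs and a JSON run summary."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from . import io as bio
from . import qtl_meta, heritability, gwas, directionality, simulate

log = logging.getLogger("behavarch")

STAGES = ("simulate", "meta", "greml", "gwas", "pleiotropy", "direction")

_STAGE_DEPS = {
    "meta": ("qtl",),
    "greml": ("panel", "phen"),
    "gwas": ("panel", "phen"),
    "pleiotropy": ("gwas",),
    "direction": ("gwas",),
}


@dataclass
class RunConfig:
    """Flat configuration of a pipeline run (mirrors the YAML config file)."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "behavarch_run"
    seed: int = 0
    # inputs (ignored when the simulate stage provides them)
    qtl_csv: str | None = None
    genotypes: str | None = None
    phenotypes: tuple[str, ...] = ()
    # simulator sizes
    sim_n_lines: int = 300
    sim_n_snps: int = 2000
    sim_n_traits: int = 4
    sim_h2: float = 0.5
    # thresholds
    gwas_p: float = gwas.DEFAULT_P_THRESHOLD
    greml_alpha: float = 0.05
    maf: float = 0.01
    screen_high: float = directionality.SCREEN_HIGH
    screen_low: float = directionality.SCREEN_LOW
    n_perm_meta: int = 10_000
    n_perm_direction: int = 1000
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for name, val in (("gwas_p", self.gwas_p), ("greml_alpha", self.greml_alpha),
                          ("maf", self.maf)):
            if not 0.0 < val < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for k in ("stages", "phenotypes"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Every artifact lands under ``config.out_dir``; a ``run_summary.json``
    records the package version, seed, thresholds and per-stage counts.
    A failing stage aborts its dependents but the summary still reports
    the stages that completed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "gwas_p": config.gwas_p,
            "greml_alpha": config.greml_alpha,
            "maf": config.maf,
            "screen_high": config.screen_high,
            "screen_low": config.screen_low,
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict = {}
    failed: set[str] = set()

    def stage_ready(name: str) -> bool:
        needs = _STAGE_DEPS.get(name, ())
        missing = [k for k in needs if k not in state]
        if missing:
            summary["stages"][name] = {
                "status": "skipped",
                "error": f"missing inputs {missing} for stage {name!r}",
            }
            log.error("stage %s skipped: missing %s", name, missing)
            failed.add(name)
            return False
        return True

    # load externally supplied inputs
    if config.qtl_csv:
        state["qtl"] = bio.read_qtl_csv(config.qtl_csv)
    if config.genotypes:
        state["panel"] = bio.read_genotypes(config.genotypes)
    if config.phenotypes:
        phen = pd.DataFrame({Path(p).stem: bio.read_phen(p) for p in config.phenotypes})
        state["phen"] = phen

    for name in STAGES:
        if name not in config.stages:
            continue
        try:
            if name == "simulate":
                _stage_simulate(config, out, state, summary)
            elif stage_ready(name):
                _STAGE_FNS[name](config, out, state, summary)
        except Exception as exc:  # keep partial artifacts, report failure
            log.exception("stage %s failed", name)
            summary["stages"][name] = {"status": "failed", "error": str(exc)}
            failed.add(name)

    summary["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _stage_simulate(config, out, state, summary):
    qtl = simulate.gen_qtl_table(simulate.QtlSimConfig(seed=config.seed))
    bio.write_qtl_csv(qtl, out / "qtl_table.csv")
    rng = np.random.default_rng(config.seed)
    n_causal = max(5, config.sim_n_snps // 100)
    traits = []
    for t in range(config.sim_n_traits):
        causal = rng.choice(config.sim_n_snps, size=n_causal, replace=False)
        traits.append(
            simulate.TraitArchitecture(f"trait{t:02d}", causal, h2=config.sim_h2)
        )
    pconf = simulate.PanelSimConfig(
        n_lines=config.sim_n_lines,
        n_snps=config.sim_n_snps,
        traits=traits,
        seed=config.seed,
    )
    panel = simulate.gen_genotypes(pconf)
    phen = simulate.gen_phenotypes(panel, pconf)
    bio.write_bed(panel, out / "panel")
    for t in phen.columns:
        bio.write_phen(phen[t], out / f"{t}.phen")
    state.update(qtl=qtl, panel=panel, phen=phen)
    summary["stages"]["simulate"] = {
        "status": "ok",
        "n_qtl": int(len(qtl)),
        "n_lines": panel.n_lines,
        "n_snps": panel.n_snps,
        "n_traits": int(phen.shape[1]),
        "seed": config.seed,
    }


def _stage_meta(config, out, state, summary):
    qtl = state["qtl"]
    overall, per_cat = qtl_meta.summarize_by_category(qtl)
    per_cat.to_csv(out / "meta_category_summary.tsv", sep="\t", float_format="%.6g")
    rows = []
    for cat in per_cat.index:
        stat, p = qtl_meta.category_vs_rest_test(qtl, cat)
        perm = qtl_meta.permutation_category_test(
            qtl, cat, n_perm=config.n_perm_meta, seed=config.seed
        )
        rows.append(
            dict(category=cat, kw_stat=stat, kw_p=p,
                 perm_p=perm.p_value, observed_mean=perm.observed_mean)
        )
    tests = pd.DataFrame(rows)
    tests.to_csv(out / "meta_category_tests.tsv", sep="\t", index=False,
                 float_format="%.6g")
    r, r2, p_div = qtl_meta.divergence_effect_correlation(qtl)
    _, p_cross = qtl_meta.cross_type_test(qtl)
    lmm = qtl_meta.fit_lmm_effects(qtl)
    lmm.fixed_effects.to_csv(out / "meta_lmm_fixed_effects.tsv", sep="\t",
                             float_format="%.6g")
    summary["stages"]["meta"] = {
        "status": "ok",
        "global_mean_pve": overall.mean_pve,
        "fraction_pve_below_20": overall.fraction_pve_below_20,
        "divergence_r2": r2,
        "divergence_p": p_div,
        "cross_type_p": p_cross,
        "lmm_converged": lmm.converged,
    }


def _stage_greml(config, out, state, summary):
    panel = heritability.filter_maf(state["panel"], config.maf)
    grm = heritability.build_grm(panel)
    results = {}
    for t in state["phen"].columns:
        results[t] = heritability.greml_fit(grm, state["phen"][t])
    table = pd.DataFrame(
        {
            t: dict(vg=r.vg, ve=r.ve, h2=r.heritability, se=r.se_heritability,
                    lrt_p=r.p_value, converged=r.converged)
            for t, r in results.items()
        }
    ).T
    table.to_csv(out / "greml_results.tsv", sep="\t", float_format="%.6g")
    retained = heritability.screen_heritable_traits(results, config.greml_alpha)
    state["greml"] = results
    summary["stages"]["greml"] = {
        "status": "ok",
        "n_traits": len(results),
        "n_significant": len(retained),
        "significant_traits": retained,
        "n_snps_grm": grm.n_snps_used,
    }


def _stage_gwas(config, out, state, summary):
    panel = heritability.filter_maf(state["panel"], config.maf)
    scans, hits = {}, {}
    for t in state["phen"].columns:
        scan = gwas.assoc_scan(panel, state["phen"][t], trait=t)
        scans[t] = scan
        hits[t] = gwas.significant_hits(scan, config.gwas_p)
        scan.table.drop(columns="testable").to_csv(
            out / f"gwas_{t}.qassoc.tsv", sep="\t", float_format="%.6g"
        )
    state["gwas"] = (scans, hits)
    em = gwas.build_effect_matrix(scans, hits)
    em.betas.to_csv(out / "effect_matrix.tsv", sep="\t", float_format="%.6g")
    state["effect_matrix"] = em
    if len(scans) >= 2 and em.betas.shape[0] >= 3:
        corr = gwas.trait_correlation_structure(em)
        corr.to_csv(out / "trait_correlations.tsv", sep="\t", float_format="%.6g")
    summary["stages"]["gwas"] = {
        "status": "ok",
        "n_significant_snps": int(em.betas.shape[0]),
        "hits_per_trait": {t: len(h) for t, h in hits.items()},
    }


def _stage_pleiotropy(config, out, state, summary):
    _, hits = state["gwas"]
    pm = gwas.build_pleiotropy_matrix(hits)
    pm.incidence.to_csv(out / "pleiotropy_incidence.tsv", sep="\t")
    summary["stages"]["pleiotropy"] = {
        "status": "ok",
        "n_multitrait_snps": int(pm.incidence.shape[0]),
    }


def _stage_direction(config, out, state, summary):
    em = state["effect_matrix"]
    testable = [t for t in em.traits if len(em.hits.get(t, ())) > directionality.MIN_HITS]
    results = []
    for i, tx in enumerate(testable):
        for ty in testable[i + 1:]:
            results.append(
                directionality.test_trait_pair(
                    em, tx, ty,
                    n_perm=config.n_perm_direction,
                    seed=config.seed,
                    screen_high=config.screen_high,
                    screen_low=config.screen_low,
                )
            )
    if results:
        report = directionality.adjust_and_report(results)
        report.to_csv(out / "directionality.tsv", sep="\t", index=False,
                      float_format="%.6g")
        n_sig = int(report["significant"].sum())
    else:
        n_sig = 0
    summary["stages"]["direction"] = {
        "status": "ok",
        "n_pairs_tested": len(results),
        "n_significant_pairs": n_sig,
    }


_STAGE_FNS = {
    "meta": _stage_meta,
    "greml": _stage_greml,
    "gwas": _stage_gwas,
    "pleiotropy": _stage_pleiotropy,
    "direction": _stage_direction,
}
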
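"""End-to-end run configuration and orchestration.

``run_pipeline`` chains simulate -> transform -> scan (per adjustment) ->
clump -> conditional -> merge -> partition -> score -> associate ->
compare -> bnmf -> mediate, writing every stage artifact as a
schema-commented TSV plus a JSON run log. Reruns with the same config are
bit-identical except for timings.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pprskit import assoc as assoc_mod
from pprskit import bnmf as bnmf_mod
from pprskit import loci as loci_mod
from pprskit import mediation as med_mod
from pprskit import pprs as pprs_mod
from pprskit import simdata
from pprskit.io import write_genotypes, write_phenotypes, write_table

BASE_COVARIATES = ["age", "sex", "age2", "age_sex", "age2_sex"]


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run; YAML/JSON round-trippable."""

    seed: int = 0
    out_dir: str = "pprskit_run"
    n_samples: int = 5000
    n_null_variants: int = 500
    adjustments: tuple = ("none", "BMI", "WFM", "VAT")
    genotype_format: str = "tsv"
    clump_p1: float = 5e-8
    clump_r2: float = 0.01
    clump_kb: int = 1000
    conditional_p: float = 5e-8
    conditional_window_bp: int = 10_000_000
    merge_dist_bp: int = 1_000_000
    merge_r2_min: float = 0.2
    alpha_tg: float = 0.05
    bnmf_k_max: int = 7
    bnmf_restarts: int = 50
    mediation_n_boot: int = 200
    mediation_mediator: str = "VAT"

    def validate(self):
        if not 0 < self.clump_p1 < 1 or not 0 < self.clump_r2 < 1:
            raise ValueError("clump thresholds out of range")
        if not 0 < self.alpha_tg < 1:
            raise ValueError("alpha_tg out of range")
        for adj in self.adjustments:
            if adj not in assoc_mod.ADJUSTMENT_LABELS:
                raise ValueError(f"unknown adjustment {adj!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "adjustments" in data:
            data["adjustments"] = tuple(data["adjustments"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_file(self, path) -> None:
        data = dataclasses.asdict(self)
        data["adjustments"] = list(data["adjustments"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _covariate_matrix(pheno: pd.DataFrame, adjustment: str) -> np.ndarray:
    cols = list(BASE_COVARIATES)
    if adjustment != "none":
        cols.append(adjustment)
    return pheno[cols].to_numpy(dtype=float)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a report dict of stage outputs.

    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    timings: dict = {}
    stage = "setup"

    def _run(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    # --- simulate -----------------------------------------------------------
    sim_cfg = simdata.default_config(seed=config.seed, n_samples=config.n_samples,
                                     n_null_variants=config.n_null_variants)
    gm, pheno = _run("simulate", lambda: simdata.simulate_cohort(sim_cfg))
    truth = simdata.planted_truth(sim_cfg)
    write_genotypes(gm, out / f"genotypes.{config.genotype_format}",
                    format=config.genotype_format)
    write_phenotypes(pheno, out / "phenotypes.tsv")
    write_table(truth.to_frame(), out / "truth.tsv", schema_name="partition")
    report["n_samples"], report["n_variants"] = gm.n_samples, gm.n_variants

    # --- transform + scans --------------------------------------------------
    def _scans():
        pdff = assoc_mod.rank_inverse_normal(pheno["PDFF"])
        tg = assoc_mod.rank_inverse_normal(pheno["TG"])
        ct1 = assoc_mod.rank_inverse_normal(pheno["cT1"])
        scans = {}
        for adj in config.adjustments:
            cov = _covariate_matrix(pheno, adj)
            scans[("PDFF", adj)] = assoc_mod.assoc_scan(gm, pdff, cov, "linear",
                                                        trait="PDFF", adjustment=adj)
        base_cov = _covariate_matrix(pheno, "BMI")
        scans[("TG", "BMI")] = assoc_mod.assoc_scan(gm, tg, base_cov, "linear",
                                                    trait="TG", adjustment="BMI")
        scans[("cT1", "BMI")] = assoc_mod.assoc_scan(gm, ct1, base_cov, "linear",
                                                     trait="cT1", adjustment="BMI")
        return scans

    scans = _run("scan", _scans)
    sumstats = pd.concat([assoc_mod.records_to_frame(r) for r in scans.values()])
    write_table(sumstats, out / "sumstats.tsv", schema_name="sumstats")

    # --- clump + conditional per PDFF scan ---------------------------------
    params = loci_mod.ClumpParams(config.clump_p1, config.clump_r2, config.clump_kb)

    def _leads():
        lead_sets = {}
        for (trait, adj), recs in scans.items():
            if trait != "PDFF":
                continue
            leads = loci_mod.clump(recs, gm, params)
            cov = _covariate_matrix(pheno, adj)
            pdff = assoc_mod.rank_inverse_normal(pheno["PDFF"])
            kept = loci_mod.stepwise_conditional(
                gm, pdff, cov, leads, p_thresh=config.conditional_p,
                window_bp=config.conditional_window_bp)
            by_id = {r.variant_id: r for r in recs}
            lead_sets[(trait, adj)] = [by_id[v] for v in kept]
        return lead_sets

    lead_sets = _run("clump+conditional", _leads)

    # --- merge into pleiotropic loci ---------------------------------------
    loci = _run("merge", lambda: loci_mod.merge_pleiotropic(
        lead_sets, gm, dist_bp=config.merge_dist_bp, r2_min=config.merge_r2_min))
    write_table(loci_mod.loci_to_frame(loci), out / "loci.tsv", schema_name="loci")
    report["n_loci"] = len(loci)

    # --- partition ----------------------------------------------------------
    def _partition():
        pdff_best, tg_best = {}, {}
        tg_by_id = {r.variant_id: r for r in scans[("TG", "BMI")]}
        pdff_scans = {k: {r.variant_id: r for r in v}
                      for k, v in scans.items() if k[0] == "PDFF"}
        for lc in loci:
            lead = lc.lead_by_trait.get("PDFF")
            if lead is None:
                continue
            recs = [s[lead] for s in pdff_scans.values()
                    if lead in s and np.isfinite(s[lead].p)]
            pdff_best[lead] = min(recs, key=lambda r: r.p)
            tg_best[lead] = tg_by_id[lead]
        return pprs_mod.partition_by_concordance(pdff_best, tg_best,
                                                 alpha_tg=config.alpha_tg)

    partition = _run("partition", _partition)
    write_table(partition.to_frame(), out / "partition.tsv", schema_name="partition")
    report["n_discordant"] = len(partition.discordant)
    report["n_concordant"] = len(partition.concordant)

    # --- scores + outcome associations -------------------------------------
    def _scores():
        res = {}
        for name, weights in (("discordant", partition.discordant),
                              ("concordant", partition.concordant)):
            if weights:
                res[name] = pprs_mod.compute_score(gm, weights, partition.orientation)
        return res

    scores = _run("score", _scores)
    score_df = pd.DataFrame({"sample_id": pheno["sample_id"], **scores})
    write_table(score_df, out / "scores.tsv", schema_name="scores")

    outcome_names = list(simdata.DEFAULT_OUTCOMES)
    cov = pheno[BASE_COVARIATES + ["BMI"]].to_numpy(dtype=float)

    def _associate():
        effects = []
        for sname, svec in scores.items():
            for oname in outcome_names:
                effects.append(pprs_mod.outcome_assoc(
                    svec, pheno[oname], cov, model="logistic",
                    score_name=sname, outcome_name=oname))
                effects.append(pprs_mod.outcome_assoc(
                    svec, pheno[f"{oname}_time"], cov, model="cox",
                    score_name=sname, outcome_name=oname,
                    event=pheno[f"{oname}_event"]))
        return effects

    effects = _run("associate", _associate)
    eff_df = pd.DataFrame([{
        "score": e.score_name, "outcome": e.outcome, "model": e.model,
        "estimate": float(np.exp(e.beta)) if np.isfinite(e.beta) else np.nan,
        "ci_low": e.ci95[0], "ci_high": e.ci95[1], "p": e.p,
        "n_cases": e.n_cases, "n_total": e.n_total, "note": e.note,
    } for e in effects])
    write_table(eff_df, out / "effects.tsv", schema_name="effects")

    # --- compare the two scores per outcome --------------------------------
    def _compare():
        rows = []
        by_key = {(e.score_name, e.outcome, e.model): e for e in effects}
        for oname in outcome_names:
            for model in ("logistic", "cox"):
                e1 = by_key.get(("discordant", oname, model))
                e2 = by_key.get(("concordant", oname, model))
                if e1 is None or e2 is None or not np.isfinite(e1.beta) \
                        or not np.isfinite(e2.beta):
                    continue
                wr = pprs_mod.wald_compare(e1, e2)
                rows.append((oname, model, wr.w, wr.p))
        return pd.DataFrame(rows, columns=["outcome", "model", "wald_w", "wald_p"])

    wald_df = _run("compare", _compare)
    write_table(wald_df, out / "wald.tsv", schema_name="wald")

    # --- bNMF on the partitioned leads -------------------------------------
    def _bnmf():
        leads = list(partition.discordant) + list(partition.concordant)
        if len(leads) < 2:
            return None
        sub = {t: {v: recs[v] for v in leads if v in recs}
               for t, recs in {
                   "PDFF": {r.variant_id: r for r in scans[("PDFF",
                                                            config.adjustments[0])]},
                   "TG": {r.variant_id: r for r in scans[("TG", "BMI")]},
                   "cT1": {r.variant_id: r for r in scans[("cT1", "BMI")]},
               }.items()}
        zm = bnmf_mod.build_z_matrix(sub, align_trait="PDFF")
        res = bnmf_mod.bnmf_fit(zm, k_max=config.bnmf_k_max,
                                n_restarts=config.bnmf_restarts, seed=config.seed)
        return bnmf_mod.extract_clusters(res)

    bres = _run("bnmf", _bnmf)
    if bres is not None:
        write_table(bnmf_mod.memberships_to_frame(bres), out / "bnmf_clusters.tsv",
                    schema_name="bnmf_clusters")
        write_table(bres.restart_log, out / "bnmf_restarts.tsv",
                    schema_name="bnmf_restarts")
        report["bnmf_k"] = bres.k_selected

    # --- mediation for the strongest discordant lead ------------------------
    def _mediate():
        if not partition.discordant:
            return None
        vid = max(partition.discordant, key=partition.discordant.get)
        res = med_mod.mediate(
            gm.dosage(vid), pheno[config.mediation_mediator],
            assoc_mod.rank_inverse_normal(pheno["PDFF"]),
            pheno[BASE_COVARIATES].to_numpy(dtype=float),
            n_boot=config.mediation_n_boot, seed=config.seed)
        return {(vid, config.mediation_mediator, "PDFF"): res}

    med = _run("mediate", _mediate)
    if med:
        write_table(med_mod.mediation_to_frame(med), out / "mediation.tsv",
                    schema_name="mediation")

    # --- run log ------------------------------------------------------------
    report["timings"] = timings
    log = {"seed": config.seed, "config": dataclasses.asdict(config),
           "timings": timings,
           "stages": list(timings)}
    log["config"]["adjustments"] = list(config.adjustments)
    (out / "runlog.json").write_text(json.dumps(log, indent=2, default=str))
    summary = {k: v for k, v in report.items() if k != "timings"}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return report
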
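"""End-to-end pipeline: QC -> phenotype derivation -> collapsing ->
burden association -> maternal/fetal decomposition -> follow-up tests.

Each stage reads and writes plain files under ``out_dir``, so stages can
be run separately (see :mod:`bwburden.cli`) or together via
:func:`run_pipeline`; running them separately produces identical files.
All exclusions are accounted in the run log.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .assoc import (
    AnalysisTable,
    BurdenFitError,
    PhenotypeDerivationRules,
    bonferroni_threshold,
    build_analysis_table,
    derive_offspring_bw,
    derive_own_bw,
    fit_burden,
    sex_stratified_fit,
)
from .cohort import MISSING
from .downstream import conditional_fit, sex_heterogeneity, sign_test
from .assoc import AssocResult
from .masks import CarrierVector, annotations_from_frame, collapse_all, dialect_masks
from .partition import MarginalPair, wlm_adjust
from .qc import QCThresholds, apply_genotype_filters, apply_variant_filters


def _thresholds(cfg: bio.PipelineConfig) -> QCThresholds:
    return QCThresholds(
        snv_dp=cfg.snv_dp, snv_gq=cfg.snv_gq, indel_dp=cfg.indel_dp,
        indel_gq=cfg.indel_gq, ab_p=cfg.ab_p, max_missing=cfg.max_missing,
        min_slope=cfg.min_slope, min_aascore=cfg.min_aascore, rule=cfg.qc_rule,
    )


def _rules(cfg: bio.PipelineConfig) -> PhenotypeDerivationRules:
    return PhenotypeDerivationRules(
        max_visit_discordance_kg=cfg.max_visit_discordance_kg,
        min_bw_kg=cfg.min_bw_kg,
        max_bw_kg=cfg.max_bw_kg,
        discordance_inclusive=cfg.discordance_inclusive,
    )


def _out(cfg: bio.PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_qc(cfg: bio.PipelineConfig, log: bio.RunLog | None = None) -> Path:
    """Apply genotype- and variant-level QC; write the filtered VCF."""
    t0 = time.perf_counter()
    gm = bio.read_vcf(cfg.vcf)
    thresholds = _thresholds(cfg)
    aascore = None
    if cfg.use_aascore and cfg.annotations:
        ann = bio.read_annotations(cfg.annotations)
        if "aascore" in ann.columns:
            aascore = {
                k: float(v)
                for k, v in zip(ann["variant_key"], ann["aascore"])
                if pd.notna(v)
            }
    calls_before = int((gm.gt != MISSING).sum())
    gm2, call_counts = apply_genotype_filters(gm, thresholds)
    calls_after = int((gm2.gt != MISSING).sum())
    gm3, var_counts = apply_variant_filters(
        gm2, thresholds, use_ad_dp_slope=cfg.use_ad_dp_slope, aascore=aascore
    )
    out = _out(cfg) / "qc.vcf"
    bio.write_vcf(gm3, out, seed=cfg.seed)
    if log is not None:
        log.add(
            "qc_calls", calls_before, calls_after,
            {k: v for k, v in call_counts.items() if k != "ab_zero_reads"},
            {"rule": thresholds.rule, "ab_zero_reads_skipped": call_counts["ab_zero_reads"]},
            time.perf_counter() - t0,
        )
        log.add(
            "qc_variants", gm2.n_variants, gm3.n_variants,
            {k: v for k, v in var_counts.items() if k != "slope_skipped"},
            {"slope_skipped": var_counts["slope_skipped"]},
        )
    return out


def stage_phenotypes(cfg: bio.PipelineConfig, log: bio.RunLog | None = None) -> dict:
    """Derive both birth-weight phenotypes in kg; write one TSV per arm."""
    t0 = time.perf_counter()
    phen = bio.read_phenotypes(cfg.phenotypes)
    rules = _rules(cfg)
    out = _out(cfg)
    paths = {}
    for arm, kind in (("fetal", "own"), ("maternal", "offspring")):
        if arm not in cfg.arms:
            continue
        sub = phen[phen["kind"] == kind]
        rows, reasons = [], {}
        for pid, grp in sub.groupby("person_id", sort=True):
            mb = bool(grp["multiple_birth"].astype(bool).any())
            if kind == "own":
                derived = derive_own_bw(list(grp["value_kg"]), mb, rules)
            else:
                derived = derive_offspring_bw(
                    list(zip(grp["source"], grp["value_kg"])), mb, rules
                )
            if derived.excluded:
                reasons[derived.reason] = reasons.get(derived.reason, 0) + 1
            else:
                rows.append((pid, derived.value_kg))
        df = pd.DataFrame(rows, columns=["person_id", "value_kg"])
        path = out / f"phenotype_{arm}.tsv"
        bio.write_tsv(df, path)
        paths[arm] = path
        if log is not None:
            log.add(
                f"phenotype_{arm}", sub["person_id"].nunique(), len(df),
                reasons, {"kind": kind}, time.perf_counter() - t0,
            )
    return paths


def _arm_samples(cfg: bio.PipelineConfig, arm: str) -> list[str]:
    df = pd.read_csv(_out(cfg) / f"phenotype_{arm}.tsv", sep="\t",
                     dtype={"person_id": str})
    return list(df["person_id"])


def stage_collapse(cfg: bio.PipelineConfig, arm: str,
                   log: bio.RunLog | None = None) -> Path:
    """Collapse qualifying variants to gene x mask carrier vectors for one
    arm (in-sample MAF and carrier counts are computed on that arm's
    post-exclusion samples)."""
    t0 = time.perf_counter()
    gm = bio.read_vcf(_out(cfg) / "qc.vcf")
    samples = [s for s in gm.samples if s in set(_arm_samples(cfg, arm))]
    gm_arm = gm.subset_samples(samples)
    anns = annotations_from_frame(bio.read_annotations(cfg.annotations))
    masks = dialect_masks(cfg.dialect)
    skipped: list = []
    vectors = collapse_all(
        masks, gm_arm, anns, maf_max=cfg.maf_max,
        min_carriers=cfg.min_carriers, coding=cfg.carrier_coding, log=skipped,
    )
    rows = []
    for cv in vectors:
        carriers = [s for s, st in zip(cv.samples, cv.status) if st > 0]
        missing = [s for s, st in zip(cv.samples, cv.status) if st == MISSING]
        rows.append((
            cv.gene_id, cv.mask_name, cv.n_carriers,
            ";".join(cv.qualifying_variant_keys),
            ";".join(carriers), ";".join(missing),
        ))
    df = pd.DataFrame(rows, columns=[
        "gene_id", "mask", "n_carriers", "qualifying_variant_keys",
        "carrier_samples", "missing_samples",
    ])
    path = _out(cfg) / f"carriers_{arm}.tsv"
    bio.write_tsv(df, path)
    if log is not None:
        reasons: dict[str, int] = {}
        for entry in skipped:
            reasons[entry[0]] = reasons.get(entry[0], 0) + 1
        n_genes = len({a.gene_id for a in anns})
        log.add(
            f"collapse_{arm}", n_genes * len(masks), len(df), reasons,
            {"dialect": cfg.dialect, "maf_max": cfg.maf_max,
             "min_carriers": cfg.min_carriers},
            time.perf_counter() - t0,
        )
    return path


def _carriers_from_tsv(path, samples: list[str]) -> list[CarrierVector]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    sample_pos = {s: j for j, s in enumerate(samples)}
    for _, row in df.iterrows():
        status = np.zeros(len(samples), dtype=np.int32)
        for s in str(row["carrier_samples"]).split(";"):
            if s:
                status[sample_pos[s]] = 1
        for s in str(row["missing_samples"]).split(";"):
            if s:
                status[sample_pos[s]] = MISSING
        keys = tuple(k for k in str(row["qualifying_variant_keys"]).split(";") if k)
        out.append(CarrierVector(row["gene_id"], row["mask"], list(samples), status, keys))
    return out


def _analysis_table(cfg: bio.PipelineConfig, arm: str) -> AnalysisTable:
    persons = bio.read_covariates(cfg.covariates)
    phen = pd.read_csv(_out(cfg) / f"phenotype_{arm}.tsv", sep="\t",
                       dtype={"person_id": str})
    series = phen.set_index("person_id")["value_kg"]
    return build_analysis_table(persons, series, arm)


def stage_assoc(cfg: bio.PipelineConfig, arm: str,
                log: bio.RunLog | None = None) -> Path:
    """Fit the covariate-adjusted burden regression for every collapsed
    gene x mask in one arm; fetal arm additionally gets sex-stratified
    fits. Significance is flagged at 0.05 / (tests in the arm)."""
    t0 = time.perf_counter()
    table = _analysis_table(cfg, arm)
    samples = _arm_samples(cfg, arm)
    carriers = _carriers_from_tsv(_out(cfg) / f"carriers_{arm}.tsv", samples)
    results, skipped = [], 0
    for cv in carriers:
        try:
            results.append(fit_burden(cv, table))
        except BurdenFitError:
            skipped += 1
    threshold = bonferroni_threshold(len(results)) if results else float("nan")
    df = pd.DataFrame(
        [
            (r.gene_id, r.mask_name, r.arm, r.beta_sd, r.se, r.p, r.n,
             r.n_carriers, r.p < threshold)
            for r in results
        ],
        columns=["gene_id", "mask", "arm", "beta_sd", "se", "p", "n",
                 "n_carriers", "significant"],
    )
    path = _out(cfg) / f"assoc_{arm}.tsv"
    bio.write_tsv(df, path)
    if log is not None:
        log.add(f"assoc_{arm}", len(carriers), len(results),
                {"unfittable": skipped},
                {"bonferroni_threshold": threshold}, time.perf_counter() - t0)
    if arm == "fetal":
        persons = bio.read_covariates(cfg.covariates)
        strat_rows = []
        for cv in carriers:
            strata = sex_stratified_fit(cv, table, persons["sex"])
            for label in ("female", "male"):
                r = strata[label]
                if r is None:
                    strat_rows.append((cv.gene_id, cv.mask_name, label,
                                       np.nan, np.nan, np.nan, 0, 0))
                else:
                    strat_rows.append((r.gene_id, r.mask_name, label, r.beta_sd,
                                       r.se, r.p, r.n, r.n_carriers))
        sdf = pd.DataFrame(strat_rows, columns=[
            "gene_id", "mask", "stratum", "beta_sd", "se", "p", "n", "n_carriers",
        ])
        bio.write_tsv(sdf, _out(cfg) / "stratified_fetal.tsv")
    return path


def stage_partition(cfg: bio.PipelineConfig,
                    log: bio.RunLog | None = None) -> Path:
    """Decompose marginal fetal/maternal estimates for every gene x mask
    present in both arms."""
    t0 = time.perf_counter()
    out = _out(cfg)
    path = out / "partition.tsv"
    cols = ["gene_id", "mask", "beta_fetal_adj", "se_fetal_adj", "p_fetal_adj",
            "beta_maternal_adj", "se_maternal_adj", "p_maternal_adj",
            "classification"]
    fet_path, mat_path = out / "assoc_fetal.tsv", out / "assoc_maternal.tsv"
    if not (fet_path.exists() and mat_path.exists()):
        bio.write_tsv(pd.DataFrame(columns=cols), path)
        if log is not None:
            log.add("partition", 0, 0, {}, {"status": "not-run"},
                    time.perf_counter() - t0)
        return path
    fet = pd.read_csv(fet_path, sep="\t")
    mat = pd.read_csv(mat_path, sep="\t")
    merged = fet.merge(mat, on=["gene_id", "mask"], suffixes=("_f", "_m"))
    rows = []
    for _, row in merged.iterrows():
        pair = MarginalPair(
            row["gene_id"], row["mask"],
            AssocResult(row["gene_id"], row["mask"], "fetal", row["beta_sd_f"],
                        row["se_f"], row["p_f"], int(row["n_f"]),
                        int(row["n_carriers_f"])),
            AssocResult(row["gene_id"], row["mask"], "maternal", row["beta_sd_m"],
                        row["se_m"], row["p_m"], int(row["n_m"]),
                        int(row["n_carriers_m"])),
            rho=cfg.rho,
        )
        res = wlm_adjust(pair, alpha=cfg.alpha)
        rows.append((res.gene_id, res.mask_name, res.beta_fetal_adj,
                     res.se_fetal_adj, res.p_fetal_adj, res.beta_maternal_adj,
                     res.se_maternal_adj, res.p_maternal_adj, res.classification))
    df = pd.DataFrame(rows, columns=cols)
    bio.write_tsv(df, path)
    if log is not None:
        skipped = len(fet) + len(mat) - 2 * len(merged)
        log.add("partition", len(fet) + len(mat), 2 * len(merged),
                {"unmatched_arm": skipped}, {"rho": cfg.rho},
                time.perf_counter() - t0)
    return path


def stage_downstream(cfg: bio.PipelineConfig,
                     log: bio.RunLog | None = None) -> dict:
    """Sex-dimorphism tests, optional conditional (sentinel) fits and the
    optional replication sign test."""
    t0 = time.perf_counter()
    out = _out(cfg)
    paths = {}

    strat_path = out / "stratified_fetal.tsv"
    if strat_path.exists():
        strat = pd.read_csv(strat_path, sep="\t")
        wide = strat.pivot(index=["gene_id", "mask"], columns="stratum")
        rows, not_estimable = [], 0
        for (gene, mask), row in wide.iterrows():
            bf, sf = row[("beta_sd", "female")], row[("se", "female")]
            bm, sm_ = row[("beta_sd", "male")], row[("se", "male")]
            if np.isnan(sf) or np.isnan(sm_) or sf <= 0 or sm_ <= 0:
                not_estimable += 1
                continue
            het = sex_heterogeneity(bf, sf, bm, sm_, alpha=cfg.alpha)
            rows.append((gene, mask, bf, sf, bm, sm_, het.z_statistic, het.p,
                         het.dimorphic))
        df = pd.DataFrame(rows, columns=[
            "gene_id", "mask", "beta_female", "se_female", "beta_male",
            "se_male", "z", "p_het", "dimorphic",
        ])
        paths["dimorphism"] = out / "dimorphism.tsv"
        bio.write_tsv(df, paths["dimorphism"])
        if log is not None:
            log.add("dimorphism", len(wide), len(df),
                    {"not_estimable_stratum": not_estimable}, {},
                    time.perf_counter() - t0)

    if cfg.sentinel_dosages and cfg.sentinel_map:
        dos = pd.read_csv(cfg.sentinel_dosages, sep="\t",
                          dtype={"person_id": str}).set_index("person_id")
        smap = pd.read_csv(cfg.sentinel_map, sep="\t")
        rows = []
        for arm in cfg.arms:
            cpath = out / f"carriers_{arm}.tsv"
            if not cpath.exists():
                continue
            table = _analysis_table(cfg, arm)
            carriers = {
                (cv.gene_id, cv.mask_name): cv
                for cv in _carriers_from_tsv(cpath, _arm_samples(cfg, arm))
            }
            for _, m in smap[smap["arm"] == arm].iterrows():
                cv = carriers.get((m["gene_id"], m["mask"]))
                if cv is None or m["snp_id"] not in dos.columns:
                    continue
                res = conditional_fit(cv, dos[m["snp_id"]], table)
                rows.append((m["gene_id"], m["mask"], arm, m["snp_id"],
                             res.beta_unconditional, res.beta_conditional,
                             res.relative_change, res.attenuated, res.defined))
        cdf = pd.DataFrame(rows, columns=[
            "gene_id", "mask", "arm", "snp_id", "beta_unconditional",
            "beta_conditional", "relative_change", "attenuated", "defined",
        ])
        paths["conditional"] = out / "conditional.tsv"
        bio.write_tsv(cdf, paths["conditional"])
        if log is not None:
            log.add("conditional", len(cdf), len(cdf), {}, {})

    if cfg.replication:
        repl = pd.read_csv(cfg.replication, sep="\t")
        rows = []
        for arm in cfg.arms:
            apath = out / f"assoc_{arm}.tsv"
            if not apath.exists():
                continue
            disc = pd.read_csv(apath, sep="\t")
            sub = repl[repl["arm"] == arm] if "arm" in repl.columns else repl
            merged = disc.merge(sub, on=["gene_id", "mask"],
                                suffixes=("_disc", "_repl"))
            if not len(merged):
                continue
            res = sign_test(merged["beta_sd"], merged["beta"])
            rows.append((arm, res.k_concordant, res.n, res.p, res.dropped_zero))
        sdf = pd.DataFrame(rows, columns=["arm", "k_concordant", "n", "p",
                                          "dropped_zero"])
        paths["signtest"] = out / "signtest.tsv"
        bio.write_tsv(sdf, paths["signtest"])
        if log is not None:
            log.add("signtest", len(sdf), len(sdf), {}, {})
    return paths


def run_pipeline(cfg: bio.PipelineConfig) -> bio.RunLog:
    """Run every stage in order and write the run log."""
    log = bio.RunLog()
    stage_qc(cfg, log)
    stage_phenotypes(cfg, log)
    for arm in cfg.arms:
        samples = _arm_samples(cfg, arm)
        if not samples:
            log.add(f"collapse_{arm}", 0, 0, {}, {"status": "not-run"})
            continue
        stage_collapse(cfg, arm, log)
        stage_assoc(cfg, arm, log)
    stage_partition(cfg, log)
    stage_downstream(cfg, log)
    log.to_json(_out(cfg) / "runlog.jsonl")
    return log
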
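"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain text so every stage is inspectable:

* genotypes — VCF 4.2 with FORMAT ``GT:DP:GQ:AD`` (AD as "ref,alt");
  biallelic records only (splitting/normalisation is upstream), 1-based
  positions, ``./.`` parsed as missing;
* annotations — TSV: variant_key (chrom:pos:ref:alt), gene_id,
  consequence, loftee, cadd, optional pathogenic_flag / maf_external /
  aascore;
* phenotypes — TSV: person_id, kind ('own'/'offspring'), source
  ('visit<k>'/'self'/'hospital'), value_kg, multiple_birth;
* covariates — TSV: person_id, sex, mother_id, role, age, pc1..pc10,
  batch;
* results — TSVs with one row per gene x mask (x arm);
* run log — line-delimited JSON, one record per stage, exclusion counts
  summing to records_in - records_out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
import yaml

from .cohort import MISSING, DuoCohort, GenotypeMatrix


# -- VCF ---------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a genotype matrix.

    DP/GQ/AD are optional; absent fields are returned as None arrays so
    QC rules that need them are skipped. Multi-allelic records are a hard
    error (normalisation is an upstream contract).
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample ids in VCF header")
        fmt_keys = set(vf.header.formats.keys())
        has = {k: k in fmt_keys for k in ("DP", "GQ", "AD")}
        rows = []
        gt_rows, dp_rows, gq_rows, adr_rows, ada_rows = [], [], [], [], []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} "
                    f"({rec.ref}->{','.join(alts) or '.'}); split upstream"
                )
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alts[0]}
            )
            gt_r, dp_r, gq_r = [], [], []
            adr_r, ada_r = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    gt_r.append(MISSING)
                else:
                    gt_r.append(int(sum(alleles)))
                dp = call.get("DP")
                gq = call.get("GQ")
                ad = call.get("AD")
                dp_r.append(MISSING if dp is None else int(dp))
                gq_r.append(MISSING if gq is None else int(gq))
                if ad is None or ad[0] is None:
                    adr_r.append(MISSING)
                    ada_r.append(MISSING)
                else:
                    adr_r.append(int(ad[0]))
                    ada_r.append(int(ad[1]) if len(ad) > 1 and ad[1] is not None else MISSING)
            gt_rows.append(gt_r)
            dp_rows.append(dp_r)
            gq_rows.append(gq_r)
            adr_rows.append(adr_r)
            ada_rows.append(ada_r)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = (len(variants), len(samples))
    arr = lambda rows_, key: (
        np.array(rows_, dtype=np.int32).reshape(n) if has[key] else None
    )
    return GenotypeMatrix(
        variants,
        samples,
        np.array(gt_rows, dtype=np.int8).reshape(n),
        arr(dp_rows, "DP"),
        arr(gq_rows, "GQ"),
        arr(adr_rows, "AD"),
        arr(ada_rows, "AD"),
    )


def write_vcf(gm: GenotypeMatrix, path, seed: int | None = None) -> None:
    """Write a genotype matrix as VCF 4.2 with FORMAT GT:DP:GQ:AD (the
    read-level fields are included only when present). The governing seed
    is recorded as a header comment."""
    header = pysam.VariantHeader()
    header.add_line("##source=bwburden")
    if seed is not None:
        header.add_line(f"##bwburden_seed={seed}")
    for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    with_reads = gm.dp is not None
    if with_reads:
        header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
        header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">')
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(gm.n_variants):
            row = gm.variants.iloc[i]
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            rec.id = None
            for j, s in enumerate(gm.samples):
                call = rec.samples[s]
                gt = int(gm.gt[i, j])
                call["GT"] = (None, None) if gt == MISSING else ((0, 0), (0, 1), (1, 1))[gt]
                if with_reads:
                    dp = int(gm.dp[i, j])
                    gq = int(gm.gq[i, j]) if gm.gq is not None else MISSING
                    adr = int(gm.ad_ref[i, j]) if gm.ad_ref is not None else MISSING
                    ada = int(gm.ad_alt[i, j]) if gm.ad_alt is not None else MISSING
                    if dp != MISSING:
                        call["DP"] = dp
                    if gq != MISSING:
                        call["GQ"] = gq
                    if adr != MISSING and ada != MISSING:
                        call["AD"] = (adr, ada)
            out.write(rec)


# -- TSVs --------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"person_id": str, "source": str})


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "mother_id": str},
                     keep_default_na=False, na_values=[])
    df["age"] = df["age"].astype(int)
    for c in df.columns:
        if c.startswith("pc"):
            df[c] = df[c].astype(float)
    return df.set_index("person_id")


def write_cohort(cohort: DuoCohort, outdir) -> dict:
    """Emit a cohort as the four pipeline input files; round-trips
    losslessly through the readers above."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "covariates": outdir / "covariates.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"], seed=cohort.seed)

    config = cohort.truth.get("config")
    if config is not None:
        from .simulate import annotation_frame

        write_tsv(annotation_frame(config), paths["annotations"])

    own = cohort.own_reports.copy()
    own.insert(1, "kind", "own")
    own = own.rename(columns={"visit": "source"})
    own["source"] = ["visit" + str(v) for v in own["source"]]
    off = cohort.offspring_reports.copy()
    off.insert(1, "kind", "offspring")
    off = off.rename(columns={"mother_id": "person_id"})
    phen = pd.concat([own, off], ignore_index=True)
    phen["multiple_birth"] = phen["multiple_birth"].astype(int)
    write_tsv(phen[["person_id", "kind", "source", "value_kg", "multiple_birth"]],
              paths["phenotypes"])

    cov = cohort.persons.reset_index()
    first = cov.columns[0]
    cov = cov.rename(columns={first: "person_id"})
    write_tsv(cov, paths["covariates"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort(indir) -> DuoCohort:
    """Rebuild a cohort from emitted files (ground truth is not
    persisted, so ``truth`` is empty apart from the recorded seed)."""
    indir = Path(indir)
    gm = read_vcf(indir / "cohort.vcf")
    persons = read_covariates(indir / "covariates.tsv")
    phen = read_phenotypes(indir / "phenotypes.tsv")
    own = phen[phen["kind"] == "own"].copy()
    own["visit"] = own["source"].str.removeprefix("visit").astype(int)
    own = own[["person_id", "visit", "value_kg", "multiple_birth"]]
    own["multiple_birth"] = own["multiple_birth"].astype(bool)
    off = phen[phen["kind"] == "offspring"].copy()
    off = off.rename(columns={"person_id": "mother_id"})
    off = off[["mother_id", "source", "value_kg", "multiple_birth"]]
    off["multiple_birth"] = off["multiple_birth"].astype(bool)
    seed = _seed_from_vcf_header(indir / "cohort.vcf")
    return DuoCohort(persons, gm, own.reset_index(drop=True),
                     off.reset_index(drop=True), {}, seed=seed)


def _seed_from_vcf_header(path) -> int | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##bwburden_seed="):
                return int(line.strip().split("=", 1)[1])
            if not line.startswith("##"):
                break
    return None


# -- pipeline configuration --------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the end-to-end pipeline. Paths are
    resolved relative to the config file when loaded from YAML."""

    vcf: str = ""
    annotations: str = ""
    phenotypes: str = ""
    covariates: str = ""
    out_dir: str = "results"
    dialect: str = "discovery"
    arms: tuple[str, ...] = ("fetal", "maternal")
    alpha: float = 0.05
    maf_max: float = 0.001
    min_carriers: int = 10
    carrier_coding: str = "indicator"
    rho: float = 0.0
    use_ad_dp_slope: bool = False
    use_aascore: bool = False
    seed: int = 0
    # QC thresholds
    snv_dp: int = 7
    snv_gq: int = 20
    indel_dp: int = 10
    indel_gq: int = 20
    ab_p: float = 1e-3
    max_missing: float = 0.5
    min_slope: float = 0.5
    min_aascore: float = 0.8
    qc_rule: str = "or"
    # phenotype derivation
    max_visit_discordance_kg: float = 1.0
    discordance_inclusive: bool = False
    min_bw_kg: float = 1.0
    max_bw_kg: float = 7.0
    # optional follow-up inputs
    sentinel_dosages: str = ""
    sentinel_map: str = ""
    replication: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        self.arms = tuple(self.arms)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("vcf", "annotations", "phenotypes", "covariates", "out_dir",
                    "sentinel_dosages", "sentinel_map", "replication"):
            val = getattr(cfg, key)
            if val and not Path(val).is_absolute():
                setattr(cfg, key, str((path.parent / val)))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["arms"] = list(self.arms)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# -- run log -----------------------------------------------------------------


@dataclass
class StageRecord:
    stage: str
    records_in: int
    records_out: int
    exclusions: dict
    params: dict = field(default_factory=dict)
    wall_s: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.exclusions.values())
        if self.records_in - self.records_out != total:
            raise ValueError(
                f"stage {self.stage}: in ({self.records_in}) - out "
                f"({self.records_out}) != sum of exclusions ({total})"
            )


class RunLog:
    """Structured account of every exclusion; each stage conserves
    records_in = records_out + sum(exclusions)."""

    def __init__(self) -> None:
        self.stages: list[StageRecord] = []

    def add(self, stage: str, records_in: int, records_out: int,
            exclusions: dict | None = None, params: dict | None = None,
            wall_s: float | None = None) -> None:
        self.stages.append(StageRecord(
            stage, records_in, records_out, exclusions or {}, params or {}, wall_s
        ))

    def to_json(self, path, include_timing: bool = False) -> None:
        """Write line-delimited JSON. Timing is excluded by default so a
        rerun under the same seed is byte-identical."""
        with open(path, "w") as fh:
            for rec in self.stages:
                d = asdict(rec)
                if not include_timing:
                    d.pop("wall_s")
                fh.write(json.dumps(d, sort_keys=True) + "\n")
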
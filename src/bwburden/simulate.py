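"""Synthetic mother-child duo cohorts with rare-variant burden
architecture, sequencing artifacts, and messy phenotype reporting.

The generator realises the genetic structure the analysis relies on:

* mothers are drawn under Hardy-Weinberg equilibrium (genotype ~
  Binomial(2, af)); each child receives one allele transmitted at random
  from its mother and one drawn from the population frequency (fathers
  are not modelled explicitly — the untransmitted allele draw is
  sufficient to induce the r = 0.5 mother-child dosage correlation and
  supports every analysis in scope);
* per-gene effects are planted on the SD scale as
  latent = sum_genes(beta_F * child_carrier + beta_M * mother_carrier)
  + covariate effects + Normal(0, noise_sd), where a carrier holds >= 1
  alt allele at >= 1 of the gene's variants. Optional sex-specific fetal
  betas replace beta_F for children of that sex. The latent scale maps to
  kg as bw_mean_kg + bw_sd_kg * latent so the kg-domain exclusion rules
  are exercisable;
* sequencing artifacts (low depth, low genotype quality, allele-imbalanced
  heterozygotes, missing calls) and raw phenotype reporting (repeat
  visits, discordant and extreme reports, multiple births, hospital
  vs. self-report duplicates) are injected at configurable rates.

All randomness is governed by a single integer seed; a fixed config and
seed yield byte-identical emitted files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, DuoCohort, GenotypeMatrix, variant_class

_INDEL_CONSEQUENCES = {"frameshift", "inframe_indel"}


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: population alt-allele frequency plus the
    annotation columns the mask builder consumes."""

    af: float
    consequence: str = "stop_gained"
    loftee: str = "HC"
    cadd: float | None = None
    allele_biased: bool = False
    pathogenic: bool = False
    aascore: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.af < 1.0):
            raise ValueError(f"allele frequency must lie in (0, 1), got {self.af}")


@dataclass(frozen=True)
class GeneSpec:
    """A gene's variants and its true conditional fetal/maternal effects
    (SD units per carrier allele-set). ``beta_fetal_female`` /
    ``beta_fetal_male``, when set, replace ``beta_fetal`` for children of
    that sex (the planted sexual dimorphism)."""

    gene_id: str
    variants: tuple[VariantSpec, ...]
    beta_fetal: float = 0.0
    beta_maternal: float = 0.0
    beta_fetal_female: float | None = None
    beta_fetal_male: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        for b in (
            self.beta_fetal, self.beta_maternal,
            self.beta_fetal_female, self.beta_fetal_male,
        ):
            if b is not None and not math.isfinite(b):
                raise ValueError("effect sizes must be finite")

    def fetal_beta(self, sex: str) -> float:
        if sex == "F" and self.beta_fetal_female is not None:
            return self.beta_fetal_female
        if sex == "M" and self.beta_fetal_male is not None:
            return self.beta_fetal_male
        return self.beta_fetal


@dataclass(frozen=True)
class ArtifactRates:
    low_dp_rate: float = 0.01
    low_gq_rate: float = 0.01
    allele_bias_rate: float = 0.0  # per-variant flagging probability
    missing_rate: float = 0.005

    def __post_init__(self) -> None:
        for name in ("low_dp_rate", "low_gq_rate", "allele_bias_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ReportingConfig:
    n_visits: int = 2
    report_noise_kg: float = 0.05
    discordant_rate: float = 0.01
    multiple_birth_rate: float = 0.02
    extreme_rate: float = 0.005
    hospital_record_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        for name in (
            "discordant_rate", "multiple_birth_rate",
            "extreme_rate", "hospital_record_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


#: default covariate effects, in SD units per (z-scored) covariate
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.03,
    "age2": 0.01,
    "sex": 0.08,
    "pc": 0.02,    # applied to each of the 10 PCs
    "batch": 0.02,  # per batch-index step
}


@dataclass(frozen=True)
class SimulationConfig:
    n_duos: int
    gene_specs: tuple[GeneSpec, ...] = ()
    noise_sd: float = 1.0
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    artifact_rates: ArtifactRates = ArtifactRates()
    reporting: ReportingConfig = ReportingConfig()
    bw_mean_kg: float = 3.5
    bw_sd_kg: float = 0.5
    dp_mean: float = 30.0
    bias_p: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_specs", tuple(self.gene_specs))
        if self.n_duos < 1:
            raise ValueError("n_duos must be >= 1")
        if not (self.noise_sd >= 0 and math.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be finite and non-negative")
        if self.bw_sd_kg <= 0:
            raise ValueError("bw_sd_kg must be positive")
        if not (0 < self.bias_p < 0.5):
            raise ValueError("bias_p must lie in (0, 0.5)")
        keys = [g.gene_id for g in self.gene_specs]
        if len(set(keys)) != len(keys):
            raise ValueError("gene ids must be unique")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic genomic layout for the configured variants: one gene
    per 100 kb block on chromosome 1; indel consequences get indel
    alleles so both depth/quality rules are exercised."""
    rows = []
    for g, gene in enumerate(config.gene_specs):
        for v, vs in enumerate(gene.variants):
            pos = 100_000 * (g + 1) + 100 * (v + 1)
            if vs.consequence in _INDEL_CONSEQUENCES:
                ref, alt = "AT", "A"
            else:
                ref, alt = "A", "G"
            rows.append(
                {
                    "chrom": "1", "pos": pos, "ref": ref, "alt": alt,
                    "gene_id": gene.gene_id, "af": vs.af,
                    "consequence": vs.consequence, "loftee": vs.loftee,
                    "cadd": vs.cadd, "allele_biased": vs.allele_biased,
                    "pathogenic": vs.pathogenic, "aascore": vs.aascore,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "af", "consequence",
            "loftee", "cadd", "allele_biased", "pathogenic", "aascore",
        ],
    )
    if len(df):
        df["key"] = [
            f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)
        ]
        if df["key"].duplicated().any():
            raise ValueError("variant keys not unique")
        df["vclass"] = [variant_class(r, a) for r, a in zip(df.ref, df.alt)]
    else:
        df["key"] = []
        df["vclass"] = []
    return df


def annotation_frame(config: SimulationConfig) -> pd.DataFrame:
    """The annotation TSV contents implied by the gene specs."""
    vt = variant_table(config)
    out = vt[["key", "gene_id", "consequence", "loftee", "cadd"]].rename(
        columns={"key": "variant_key"}
    ).copy()
    out["pathogenic_flag"] = vt["pathogenic"].astype(bool) if len(vt) else []
    out["aascore"] = vt["aascore"]
    return out


def simulate_duos(config: SimulationConfig) -> DuoCohort:
    """Generate true genotypes, covariates, latent phenotypes and raw
    phenotype reports (read-level fields are filled by
    :func:`simulate_reads`)."""
    n = config.n_duos
    vt = variant_table(config)
    n_var = len(vt)
    af = vt["af"].to_numpy(dtype=float) if n_var else np.zeros(0)

    rng_geno = _rng(config.seed, 0)
    rng_cov = _rng(config.seed, 1)
    rng_noise = _rng(config.seed, 2)
    rng_rep = _rng(config.seed, 3)

    mother_gt = rng_geno.binomial(2, af[:, None], size=(n_var, n)).astype(np.int8)
    transmitted = np.where(
        mother_gt == 2, 1,
        np.where(mother_gt == 1, rng_geno.integers(0, 2, size=(n_var, n)), 0),
    ).astype(np.int8)
    paternal = rng_geno.binomial(1, af[:, None], size=(n_var, n)).astype(np.int8)
    child_gt = transmitted + paternal

    child_ids = [f"C{i:06d}" for i in range(1, n + 1)]
    mother_ids = [f"M{i:06d}" for i in range(1, n + 1)]
    sexes = np.where(rng_cov.integers(0, 2, size=n) == 0, "F", "M")

    persons = pd.DataFrame(index=pd.Index(child_ids + mother_ids, name="person_id"))
    persons["sex"] = np.concatenate([sexes, np.full(n, "F")])
    persons["mother_id"] = mother_ids + [""] * n
    persons["role"] = ["child"] * n + ["mother"] * n
    persons["age"] = np.concatenate(
        [rng_cov.integers(40, 70, size=n), rng_cov.integers(20, 41, size=n)]
    )
    # 6-dp rounding keeps the emitted covariate TSV lossless
    pcs = np.round(rng_cov.normal(size=(2 * n, 10)), 6)
    for j in range(10):
        persons[f"pc{j + 1}"] = pcs[:, j]
    persons["batch"] = rng_cov.choice(["b1", "b2", "b3"], size=2 * n)

    # covariate contribution to the child's latent phenotype
    eff = config.covariate_effects
    child = persons.iloc[:n]
    age = child["age"].to_numpy(dtype=float)
    z = lambda x: (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
    latent = eff.get("age", 0.0) * z(age) + eff.get("age2", 0.0) * z(age**2)
    latent = latent + eff.get("sex", 0.0) * (sexes == "M")
    latent = latent + eff.get("pc", 0.0) * pcs[:n].sum(axis=1)
    batch_idx = child["batch"].map({"b1": 0, "b2": 1, "b3": 2}).to_numpy(dtype=float)
    latent = latent + eff.get("batch", 0.0) * batch_idx

    carriers: dict[str, pd.DataFrame] = {}
    for gene in config.gene_specs:
        vidx = np.flatnonzero((vt["gene_id"] == gene.gene_id).to_numpy())
        c_carrier = (child_gt[vidx] > 0).any(axis=0).astype(int)
        m_carrier = (mother_gt[vidx] > 0).any(axis=0).astype(int)
        beta_f = np.array([gene.fetal_beta(s) for s in sexes])
        latent = latent + beta_f * c_carrier + gene.beta_maternal * m_carrier
        carriers[gene.gene_id] = pd.DataFrame(
            {"child_carrier": c_carrier, "mother_carrier": m_carrier},
            index=pd.Index(child_ids, name="child"),
        )

    latent = latent + rng_noise.normal(0.0, config.noise_sd, size=n)
    true_bw = config.bw_mean_kg + config.bw_sd_kg * latent

    multiple_birth = rng_rep.random(n) < config.reporting.multiple_birth_rate
    own, offspring = _reports(
        config, rng_rep, child_ids, mother_ids, true_bw, multiple_birth
    )

    gt = np.concatenate([child_gt, mother_gt], axis=1)
    gm = GenotypeMatrix(
        vt[["chrom", "pos", "ref", "alt", "key", "vclass"]].copy(),
        child_ids + mother_ids,
        gt,
    )
    truth = {
        "config": config,
        "latent": pd.Series(latent, index=child_ids),
        "true_bw_kg": pd.Series(true_bw, index=child_ids),
        "paternal": paternal,
        "carriers": carriers,
        "multiple_birth": pd.Series(multiple_birth, index=child_ids),
    }
    return DuoCohort(persons, gm, own, offspring, truth, seed=config.seed)


def _reports(config, rng, child_ids, mother_ids, true_bw, multiple_birth):
    rep = config.reporting
    n = len(child_ids)
    extreme = rng.random(n) < rep.extreme_rate
    extreme_vals = np.where(
        rng.random(n) < 0.5,
        0.5 + rng.random(n) * 0.4,      # implausibly small, < 1 kg
        7.0 + rng.random(n) * 1.0,      # implausibly large, >= 7 kg
    )
    discordant = rng.random(n) < rep.discordant_rate

    own_rows = []
    for visit in range(1, rep.n_visits + 1):
        vals = true_bw + rng.normal(0.0, rep.report_noise_kg, size=n)
        if visit == rep.n_visits and rep.n_visits >= 2:
            offset = 1.5 + np.abs(rng.normal(0.0, 0.5, size=n))
            vals = np.where(discordant, vals + offset, vals)
        vals = np.where(extreme, extreme_vals, vals)
        for i, cid in enumerate(child_ids):
            own_rows.append((cid, visit, round(float(vals[i]), 3), bool(multiple_birth[i])))
    own = pd.DataFrame(
        own_rows, columns=["person_id", "visit", "value_kg", "multiple_birth"]
    )

    # mothers' records of the same births: repeated self-reports, plus a
    # more accurate hospital record for a configurable fraction
    off_rows = []
    for visit in range(1, rep.n_visits + 1):
        vals = true_bw + rng.normal(0.0, rep.report_noise_kg, size=n)
        if visit == rep.n_visits and rep.n_visits >= 2:
            offset = 1.5 + np.abs(rng.normal(0.0, 0.5, size=n))
            vals = np.where(discordant, vals + offset, vals)
        vals = np.where(extreme, extreme_vals, vals)
        for i, mid in enumerate(mother_ids):
            off_rows.append((mid, "self", round(float(vals[i]), 3), bool(multiple_birth[i])))
    hospital = rng.random(n) < rep.hospital_record_rate
    hvals = true_bw + rng.normal(0.0, 0.02, size=n)
    hvals = np.where(extreme, extreme_vals, hvals)
    for i, mid in enumerate(mother_ids):
        if hospital[i]:
            off_rows.append((mid, "hospital", round(float(hvals[i]), 3), bool(multiple_birth[i])))
    offspring = pd.DataFrame(
        off_rows, columns=["mother_id", "source", "value_kg", "multiple_birth"]
    )
    return own, offspring


def simulate_reads(
    cohort: DuoCohort,
    artifact_rates: ArtifactRates | None = None,
    seed: int | None = None,
) -> DuoCohort:
    """Fill DP/GQ/AD and inject artifacts; returns a new cohort, leaving
    the clean input untouched.

    Depth is Poisson (configurable mean, floor 1); heterozygotes draw
    AD_alt ~ Binomial(DP, 0.5), or Binomial(DP, bias_p) at variants
    flagged allele-biased (explicitly or at ``allele_bias_rate``); GQ is
    high by default and degraded below 20 at ``low_gq_rate``; whole calls
    go missing at ``missing_rate``. AD_ref + AD_alt always equals DP here;
    the QC layer must not rely on that in general.
    """
    config: SimulationConfig = cohort.truth["config"]
    rates = artifact_rates if artifact_rates is not None else config.artifact_rates
    rng = _rng(config.seed if seed is None else seed, 10)
    gm = cohort.genotypes.copy()
    n_var, n_samp = gm.gt.shape
    shape = (n_var, n_samp)

    dp = np.maximum(1, rng.poisson(config.dp_mean, size=shape)).astype(np.int32)
    low_dp = rng.random(shape) < rates.low_dp_rate
    dp = np.where(low_dp, 1 + rng.poisson(3.0, size=shape), dp).astype(np.int32)

    gq = rng.integers(60, 100, size=shape).astype(np.int32)
    low_gq = rng.random(shape) < rates.low_gq_rate
    gq = np.where(low_gq, rng.integers(0, 20, size=shape), gq).astype(np.int32)

    vt = variant_table(config)
    explicit = vt["allele_biased"].to_numpy(dtype=bool) if len(vt) else np.zeros(n_var, bool)
    flagged = explicit | (rng.random(n_var) < rates.allele_bias_rate)
    p_alt = np.where(flagged, config.bias_p, 0.5)[:, None]

    ad_alt = np.zeros(shape, dtype=np.int32)
    het = gm.gt == 1
    ad_alt[het] = rng.binomial(np.broadcast_to(dp, shape)[het],
                               np.broadcast_to(p_alt, shape)[het])
    ad_alt[gm.gt == 2] = dp[gm.gt == 2]
    ad_ref = dp - ad_alt

    missing = rng.random(shape) < rates.missing_rate
    gt = gm.gt.copy()
    gt[missing] = MISSING
    for arr in (dp, gq, ad_ref, ad_alt):
        arr[missing] = MISSING

    gm2 = GenotypeMatrix(gm.variants, gm.samples, gt, dp, gq, ad_ref, ad_alt)
    truth = dict(cohort.truth)
    truth["biased_variants"] = tuple(vt["key"][flagged]) if len(vt) else ()
    return DuoCohort(
        cohort.persons, gm2, cohort.own_reports, cohort.offspring_reports,
        truth, seed=cohort.seed,
    )


def simulate_cohort(config: SimulationConfig) -> DuoCohort:
    """Genotypes, phenotypes and read-level fields in one call."""
    return simulate_reads(simulate_duos(config))


def emit_cohort(cohort: DuoCohort, outdir) -> dict:
    """Write the four pipeline input files (VCF + three TSVs); see
    :mod:`bwburden.io` for the formats. Returns the paths."""
    from . import io as bio

    return bio.write_cohort(cohort, outdir)


# -- reference scenarios -----------------------------------------------------


def default_gene_specs() -> tuple[GeneSpec, ...]:
    """Five-gene reference architecture: a glucokinase-like gene with
    opposing fetal/maternal effects, a large positive fetal-effect gene
    whose signal is concentrated in one splice variant, a sex-dimorphic
    strongly negative gene, a fetal-only moderate gene, and a null gene.
    Each gene also carries non-qualifying decoy variants (synonymous,
    low-CADD missense)."""

    def decoys():
        return (
            VariantSpec(af=8e-4, consequence="synonymous", loftee="none", cadd=2.0),
            VariantSpec(af=8e-4, consequence="missense", loftee="none", cadd=10.0),
        )

    def ptvs(*cadds):
        kinds = ("stop_gained", "frameshift", "splice_donor", "splice_acceptor")
        return tuple(
            VariantSpec(af=5e-4, consequence=kinds[i % 4], loftee="HC", cadd=c)
            for i, c in enumerate(cadds)
        )

    def damaging_missense(*cadds, af=5e-4):
        return tuple(
            VariantSpec(af=af, consequence="missense", loftee="none", cadd=c)
            for c in cadds
        )

    gck = GeneSpec(
        "GENE_A",
        variants=ptvs(40.0, 35.0, 36.0, 38.0)
        + damaging_missense(28.0, 30.0, 27.0)
        + decoys(),
        beta_fetal=-0.311,
        beta_maternal=0.430,
    )
    splice_gene = GeneSpec(
        "GENE_B",
        variants=(
            VariantSpec(af=5e-4, consequence="splice_acceptor", loftee="HC", cadd=33.0),
            VariantSpec(af=4e-4, consequence="stop_gained", loftee="HC", cadd=38.0),
            VariantSpec(af=4e-4, consequence="frameshift", loftee="HC", cadd=36.0),
            VariantSpec(af=4e-4, consequence="splice_donor", loftee="HC", cadd=34.0),
        )
        + damaging_missense(27.0, 26.0, 29.0, af=2e-4)
        + decoys(),
        beta_fetal=0.218,
    )
    dimorphic = GeneSpec(
        "GENE_C",
        variants=ptvs(42.0, 34.0, 36.0, 39.0) + decoys(),
        beta_fetal=-1.416,
        beta_fetal_female=-1.710,
        beta_fetal_male=-0.177,
    )
    fetal_only = GeneSpec(
        "GENE_D",
        variants=ptvs(39.0, 37.0, 41.0, 35.0)
        + damaging_missense(27.0, 31.0, 26.0)
        + decoys(),
        beta_fetal=0.330,
    )
    null = GeneSpec(
        "GENE_E",
        variants=ptvs(37.0, 33.0, 38.0, 36.0)
        + damaging_missense(28.0, 29.0)
        + decoys(),
    )
    return (gck, splice_gene, dimorphic, fetal_only, null)


def default_config(n_duos: int = 5000, seed: int = 0, **overrides) -> SimulationConfig:
    """The reference study conditions used by the end-to-end tests and the
    worked example."""
    return SimulationConfig(
        n_duos=n_duos, gene_specs=default_gene_specs(), seed=seed, **overrides
    )
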
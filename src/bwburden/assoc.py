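"""Birth-weight phenotype derivation and covariate-adjusted burden tests.

Two phenotypes are derived in kg and analysed in SD units:

* own birth weight (fetal arm) — the mean of a participant's repeated
  visit reports, excluding multiple births, discordant repeats (range of
  reports > 1 kg) and extreme values (< 1 kg or >= 7 kg, the upper bound
  inclusive);
* offspring birth weight (maternal arm) — a mother's record of her first
  child's weight, preferring hospital records over self-reports, under the
  same exclusion rules.

After exclusions each phenotype is z-standardised within its arm (sexes
combined), and per-gene carrier status is regressed on the standardised
phenotype by OLS with covariates: age, age^2, the first ten principal
components, sequencing-batch indicators, and sex in the (sex-combined)
fetal arm. Effects are therefore reported in phenotype SD units per
carrier. With unrelated samples OLS estimates the same quantity as the
mixed-model machinery used at biobank scale; no relatedness adjustment
is implemented (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort import MISSING
from .masks import CarrierVector


@dataclass(frozen=True)
class PhenotypeDerivationRules:
    max_visit_discordance_kg: float = 1.0
    min_bw_kg: float = 1.0
    max_bw_kg: float = 7.0
    exclude_multiple_births: bool = True
    prefer_hospital: bool = True
    #: strict '>' (discovery dialect) vs '>=' (confirmatory dialect) on the
    #: visit-discordance rule
    discordance_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.min_bw_kg >= self.max_bw_kg:
            raise ValueError("min_bw_kg must be below max_bw_kg")
        if self.max_visit_discordance_kg <= 0:
            raise ValueError("discordance threshold must be positive")


@dataclass(frozen=True)
class DerivedPhenotype:
    value_kg: float | None
    excluded: bool
    reason: str | None = None  # multiple_birth | discordant | extreme | invalid


def _derive(values: Sequence[float], multiple_birth: bool,
            rules: PhenotypeDerivationRules) -> DerivedPhenotype:
    vals = [float(v) for v in values if v is not None and math.isfinite(float(v))]
    if not vals:
        return DerivedPhenotype(None, True, "invalid")
    if multiple_birth and rules.exclude_multiple_births:
        return DerivedPhenotype(None, True, "multiple_birth")
    spread = max(vals) - min(vals)
    discordant = (
        spread >= rules.max_visit_discordance_kg
        if rules.discordance_inclusive
        else spread > rules.max_visit_discordance_kg
    )
    if discordant:
        return DerivedPhenotype(None, True, "discordant")
    mean = sum(vals) / len(vals)
    if mean < rules.min_bw_kg or mean >= rules.max_bw_kg:
        return DerivedPhenotype(None, True, "extreme")
    return DerivedPhenotype(mean, False, None)


def derive_own_bw(
    reports: Sequence[float],
    multiple_birth: bool = False,
    rules: PhenotypeDerivationRules = PhenotypeDerivationRules(),
) -> DerivedPhenotype:
    """Combine a participant's repeated own-birth-weight visit reports."""
    if len(reports) == 0:
        raise ValueError("at least one report required")
    return _derive(reports, multiple_birth, rules)


def derive_offspring_bw(
    records: Sequence[tuple[str, float]],
    multiple_birth: bool = False,
    rules: PhenotypeDerivationRules = PhenotypeDerivationRules(),
) -> DerivedPhenotype:
    """Combine a mother's offspring-birth-weight records.

    ``records`` are (source, value_kg) pairs with source 'hospital' or
    'self'; hospital records are preferentially retained when present.
    """
    if len(records) == 0:
        raise ValueError("at least one record required")
    hospital = [v for s, v in records if s == "hospital"]
    selfrep = [v for s, v in records if s != "hospital"]
    use = hospital if (hospital and rules.prefer_hospital) else (selfrep or hospital)
    return _derive(use, multiple_birth, rules)


def standardize(values: Iterable[float]) -> np.ndarray:
    """z-scores (sample SD, ddof=1). Applied once per analysis arm, after
    all exclusions, sexes combined."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (arr - arr.mean()) / sd


@dataclass
class AnalysisTable:
    """Per-arm regression-ready table: standardised phenotype plus
    complete-case covariates, indexed by sample id."""

    data: pd.DataFrame  # column 'phenotype' + covariate columns
    arm: str  # 'fetal' | 'maternal'
    covariates: list[str]

    def __post_init__(self) -> None:
        if self.arm not in ("fetal", "maternal"):
            raise ValueError("arm must be 'fetal' or 'maternal'")
        missing = [c for c in ["phenotype", *self.covariates] if c not in self.data]
        if missing:
            raise ValueError(f"missing columns {missing}")


def build_analysis_table(
    persons: pd.DataFrame,
    phenotype_kg: pd.Series,
    arm: str,
    n_pcs: int = 10,
) -> AnalysisTable:
    """Assemble a covariate table for one arm and standardise the phenotype.

    persons must carry age, pc1..pc{n_pcs}, batch and (fetal arm) sex.
    Continuous covariates are z-scored for conditioning; this leaves the
    carrier coefficient untouched. Batch enters as indicator columns
    (first level dropped). Complete-case on phenotype and covariates.
    """
    ids = [i for i in phenotype_kg.index if i in persons.index]
    df = persons.loc[ids].copy()
    df["phenotype_kg"] = phenotype_kg.loc[ids]
    pc_cols = [f"pc{i}" for i in range(1, n_pcs + 1)]
    needed = ["age", "batch", "phenotype_kg", *pc_cols]
    if arm == "fetal":
        needed.append("sex")
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    out = pd.DataFrame(index=df.index)
    out["phenotype"] = standardize(df["phenotype_kg"])
    age = df["age"].astype(float)
    out["age"] = standardize(age)
    out["age2"] = standardize(age**2)
    for c in pc_cols:
        out[c] = df[c].astype(float)
    covs = ["age", "age2", *pc_cols]
    if arm == "fetal":
        out["sex"] = (df["sex"] == "M").astype(float)
        covs.append("sex")
    batches = sorted(df["batch"].astype(str).unique())
    for b in batches[1:]:
        col = f"batch_{b}"
        out[col] = (df["batch"].astype(str) == b).astype(float)
        covs.append(col)
    return AnalysisTable(out, arm, covs)


@dataclass(frozen=True)
class AssocResult:
    gene_id: str
    mask_name: str
    arm: str
    beta_sd: float
    se: float
    p: float
    n: int
    n_carriers: int


class BurdenFitError(ValueError):
    """Raised when a burden regression cannot be fit (zero-variance
    carrier status after alignment, or too few samples)."""


def _aligned_frame(carrier: CarrierVector, table: AnalysisTable) -> pd.DataFrame:
    status = pd.Series(carrier.status, index=carrier.samples)
    ids = [s for s in table.data.index if s in status.index and status[s] != MISSING]
    df = table.data.loc[ids].copy()
    df["carrier"] = status.loc[ids].astype(float)
    return df


def fit_burden(
    carrier: CarrierVector,
    table: AnalysisTable,
    drop_covariates: Iterable[str] = (),
) -> AssocResult:
    """OLS of the standardised phenotype on carrier status plus covariates.

    Samples with missing carrier status are excluded (complete-case). The
    two-sided p-value uses the t distribution with residual df. Collinear
    covariates are handled by the pinv-based solver (rank-adjusted df).
    """
    df = _aligned_frame(carrier, table)
    covs = [c for c in table.covariates if c not in set(drop_covariates)]
    n = len(df)
    if n < len(covs) + 3:
        raise BurdenFitError(f"too few samples (n={n}) for the design")
    if df["carrier"].nunique() < 2:
        raise BurdenFitError("carrier status has no variance in the analysis set")
    X = sm.add_constant(df[["carrier", *covs]], has_constant="add")
    fit = sm.OLS(df["phenotype"], X).fit()
    return AssocResult(
        gene_id=carrier.gene_id,
        mask_name=carrier.mask_name,
        arm=table.arm,
        beta_sd=float(fit.params["carrier"]),
        se=float(fit.bse["carrier"]),
        p=float(fit.pvalues["carrier"]),
        n=n,
        n_carriers=int((df["carrier"] > 0).sum()),
    )


def sex_stratified_fit(
    carrier: CarrierVector,
    table: AnalysisTable,
    sex: pd.Series,
) -> dict[str, AssocResult | None]:
    """Fit the burden regression within each sex stratum, dropping the sex
    covariate. A stratum with no carriers (or no variance) is reported as
    None rather than erroring: the gene list is inherited from the
    sex-combined analysis and no per-stratum carrier minimum applies."""
    out: dict[str, AssocResult | None] = {}
    for label, code in (("female", "F"), ("male", "M")):
        ids = [s for s in table.data.index if sex.get(s) == code]
        sub = AnalysisTable(
            table.data.loc[ids],
            table.arm,
            [c for c in table.covariates if c != "sex"],
        )
        try:
            out[label] = fit_burden(carrier, sub)
        except BurdenFitError:
            out[label] = None
    return out


def bonferroni_threshold(n_tests: int) -> float:
    """Exome-wide significance level 0.05 / (number of gene x mask tests,
    summed across masks within an arm)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


def bh_adjust(p_values: Iterable[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the reject flags at
    ``alpha``."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(arr, alpha=alpha, method="fdr_bh")
    return adjusted, reject
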
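"""Secondary inference on identified genes: sex dimorphism, conditional
attenuation on GWAS sentinel variants, and sign-test replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import AnalysisTable, BurdenFitError, _aligned_frame
from .masks import CarrierVector


@dataclass(frozen=True)
class HetTestResult:
    z_statistic: float
    p: float
    dimorphic: bool


def sex_heterogeneity(
    beta_f: float, se_f: float, beta_m: float, se_m: float, alpha: float = 0.05
) -> HetTestResult:
    """Two-sample comparison of sex-stratified effect estimates.

    z = (beta_female - beta_male) / sqrt(se_f^2 + se_m^2), two-sided p from
    the standard normal (the large-df limit of the two-sample t-test,
    which is the relevant regime for summary estimates from large strata).
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_f - beta_m) / (se_f**2 + se_m**2) ** 0.5
    p = float(2.0 * stats.norm.sf(abs(z)))
    return HetTestResult(z_statistic=float(z), p=p, dimorphic=p < alpha)


@dataclass(frozen=True)
class ConditionalResult:
    beta_unconditional: float
    beta_conditional: float
    relative_change: float
    attenuated: bool
    defined: bool = True  # False when |beta_uncond| is below numerical floor


def conditional_fit(
    carrier: CarrierVector,
    snp_dosage: pd.Series,
    table: AnalysisTable,
    attenuation_threshold: float = 0.10,
    floor: float = 1e-12,
) -> ConditionalResult:
    """Test whether a common GWAS sentinel explains the burden signal.

    The phenotype is first residualised on the covariates; the residuals
    are then regressed on carrier status alone (unconditional) and on
    carrier status plus the sentinel dosage jointly (conditional). An
    absolute relative change of the carrier estimate above 10% flags
    attenuation; sign flips larger than the threshold also count.
    """
    if ((snp_dosage < 0) | (snp_dosage > 2)).any():
        raise ValueError("sentinel dosages must lie in [0, 2]")
    df = _aligned_frame(carrier, table)
    df = df.loc[[s for s in df.index if s in snp_dosage.index]]
    if len(df) < 4:
        raise BurdenFitError("too few samples for the conditional fit")
    covs = sm.add_constant(df[table.covariates], has_constant="add")
    resid = sm.OLS(df["phenotype"], covs).fit().resid
    x_un = sm.add_constant(df[["carrier"]], has_constant="add")
    beta_un = float(sm.OLS(resid, x_un).fit().params["carrier"])
    xj = df[["carrier"]].copy()
    xj["dosage"] = snp_dosage.loc[df.index].astype(float)
    x_co = sm.add_constant(xj, has_constant="add")
    beta_co = float(sm.OLS(resid, x_co).fit().params["carrier"])
    if abs(beta_un) < floor:
        return ConditionalResult(beta_un, beta_co, float("nan"), False, defined=False)
    change = abs(beta_co - beta_un) / abs(beta_un)
    return ConditionalResult(beta_un, beta_co, change, change > attenuation_threshold)


@dataclass(frozen=True)
class SignTestResult:
    k_concordant: int
    n: int
    p: float
    dropped_zero: int = 0


def sign_test_p(k: int, n: int) -> float:
    """Exact two-sided binomial p for k successes in n under p0 = 0.5
    (symmetric doubled tail, capped at 1)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        raise ValueError("n must be >= 1")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sign_test(
    discovery_betas: Sequence[float], replication_betas: Sequence[float]
) -> SignTestResult:
    """Directional concordance of paired discovery/replication estimates.

    Pairs where either beta is exactly zero carry no direction and are
    dropped (counted in ``dropped_zero``).
    """
    a = np.asarray(discovery_betas, dtype=float)
    b = np.asarray(replication_betas, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired beta vectors must have equal length")
    nonzero = (a != 0) & (b != 0)
    dropped = int((~nonzero).sum())
    a, b = a[nonzero], b[nonzero]
    n = len(a)
    if n == 0:
        raise ValueError("no non-zero pairs to test")
    k = int((np.sign(a) == np.sign(b)).sum())
    return SignTestResult(k, n, sign_test_p(k, n), dropped)
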
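"""Decomposition of marginal fetal/maternal burden effects into
conditional effects.

Because a child inherits one of each maternal allele pair, maternal and
fetal genotypes are correlated with r = 0.5, so marginal burden estimates
mix the two effects:

    E[b_F] = beta_F + 0.5 * beta_M        (fetal-arm marginal)
    E[b_M] = beta_M + 0.5 * beta_F        (maternal-arm marginal)

The weighted linear model inverts this map:

    beta_F_adj = (4 b_F - 2 b_M) / 3
    beta_M_adj = (4 b_M - 2 b_F) / 3

with variances by linear error propagation, including an optional
covariance term rho between the two marginal estimates (the arms overlap
in women reporting both their own and their first child's birth weight;
by default rho = 0). The inversion assumes all qualifying variants in the
mask share a common effect; heterogeneous per-variant effects bias it.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .assoc import AssocResult


@dataclass(frozen=True)
class MarginalPair:
    gene_id: str
    mask_name: str
    fetal: AssocResult
    maternal: AssocResult
    #: correlation between the two marginal estimates from sample overlap
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.fetal.se <= 0 or self.maternal.se <= 0:
            raise ValueError("standard errors must be positive")


@dataclass(frozen=True)
class PartitionResult:
    gene_id: str
    mask_name: str
    beta_fetal_adj: float
    se_fetal_adj: float
    p_fetal_adj: float
    beta_maternal_adj: float
    se_maternal_adj: float
    p_maternal_adj: float
    classification: str  # fetal_only | maternal_only | both | neither


def classify(p_fetal: float, p_maternal: float, alpha: float = 0.05) -> str:
    fetal = p_fetal < alpha
    maternal = p_maternal < alpha
    if fetal and maternal:
        return "both"
    if fetal:
        return "fetal_only"
    if maternal:
        return "maternal_only"
    return "neither"


def wlm_adjust(pair: MarginalPair, alpha: float = 0.05) -> PartitionResult:
    """Invert the marginal-expectation map and propagate uncertainty.

    p-values are two-sided normal: the adjusted estimates are linear
    combinations of asymptotically normal marginals.
    """
    bf, bm = pair.fetal.beta_sd, pair.maternal.beta_sd
    sf, sm_ = pair.fetal.se, pair.maternal.se
    beta_f = (4.0 * bf - 2.0 * bm) / 3.0
    beta_m = (4.0 * bm - 2.0 * bf) / 3.0
    var_f = (16.0 / 9.0) * sf**2 + (4.0 / 9.0) * sm_**2 \
        - (16.0 / 9.0) * pair.rho * sf * sm_
    var_m = (16.0 / 9.0) * sm_**2 + (4.0 / 9.0) * sf**2 \
        - (16.0 / 9.0) * pair.rho * sf * sm_
    if var_f <= 0 or var_m <= 0:
        raise ValueError("non-positive adjusted variance; check rho and SEs")
    se_f, se_m = var_f**0.5, var_m**0.5
    p_f = float(2.0 * stats.norm.sf(abs(beta_f) / se_f))
    p_m = float(2.0 * stats.norm.sf(abs(beta_m) / se_m))
    return PartitionResult(
        gene_id=pair.gene_id,
        mask_name=pair.mask_name,
        beta_fetal_adj=beta_f,
        se_fetal_adj=se_f,
        p_fetal_adj=p_f,
        beta_maternal_adj=beta_m,
        se_maternal_adj=se_m,
        p_maternal_adj=p_m,
        classification=classify(p_f, p_m, alpha),
    )


def classify_gene(result: PartitionResult, alpha: float = 0.05) -> str:
    """Re-derive the fetal-only / maternal-only / both / neither label at a
    chosen alpha from an existing partition result."""
    return classify(result.p_fetal_adj, result.p_maternal_adj, alpha)
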
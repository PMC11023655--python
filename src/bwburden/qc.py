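"""Sequencing quality control applied before any association analysis.

Three genotype/variant-level filters mirror standard exome-QC practice for
short-read calls:

* per-call depth/quality: SNV calls need DP >= 7 and GQ >= 20, indel calls
  DP >= 10 and GQ >= 20 (strict ``<`` fails); the default combines the two
  criteria disjunctively (failing either sets the call missing), with the
  conjunctive reading available via ``QCThresholds.rule``;
* heterozygous SNV allele balance: an exact two-sided binomial test of
  AD_alt against an expected 50/50 read split; p <= 1e-3 sets the call
  missing;
* per-variant missingness: variants with > 50% missing calls are dropped.

Two further variant-level screens target spurious calls in whole-genome
replication data: a no-intercept regression of alt-allele counts on
genotype-weighted depth (slope < 0.5 drops the variant) and a pass-through
AAscore threshold (score <= 0.8 drops, when the annotation is present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import (
    GT_HET,
    GT_HOM_ALT,
    INDEL,
    MISSING,
    SNV,
    GenotypeCall,
    GenotypeMatrix,
    VariantRecord,
)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow the discovery-analysis settings."""

    snv_dp: int = 7
    snv_gq: int = 20
    indel_dp: int = 10
    indel_gq: int = 20
    ab_p: float = 1e-3
    max_missing: float = 0.5
    min_slope: float = 0.5
    min_aascore: float = 0.8
    #: 'or' = a call failing either the DP or the GQ criterion is removed;
    #: 'and' = only calls failing both are removed.
    rule: str = "or"
    #: minimum non-missing carrier calls for the AD~DP slope fit
    slope_min_carriers: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.max_missing <= 1):
            raise ValueError("max_missing must be in (0, 1]")
        for name in ("snv_dp", "snv_gq", "indel_dp", "indel_gq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ab_p <= 0 or self.min_slope <= 0 or self.min_aascore <= 0:
            raise ValueError("thresholds must be positive")
        if self.rule not in ("or", "and"):
            raise ValueError("rule must be 'or' or 'and'")


def filter_genotype(
    call: GenotypeCall, vclass: str, thresholds: QCThresholds = QCThresholds()
) -> GenotypeCall:
    """Set a call to missing when it fails the depth/quality rule.

    A DP or GQ recorded as MISSING (field absent) passes its criterion: the
    rule cannot be evaluated, so the call is left unchanged.
    """
    if vclass == SNV:
        dp_min, gq_min = thresholds.snv_dp, thresholds.snv_gq
    elif vclass == INDEL:
        dp_min, gq_min = thresholds.indel_dp, thresholds.indel_gq
    else:
        raise ValueError(f"unknown variant class {vclass!r}")
    if call.is_missing:
        return call
    low_dp = call.dp != MISSING and call.dp < dp_min
    low_gq = call.gq != MISSING and call.gq < gq_min
    fails = (low_dp or low_gq) if thresholds.rule == "or" else (low_dp and low_gq)
    return call.as_missing() if fails else call


def allele_balance_test(ad_alt: int, total: int) -> float:
    """Exact two-sided binomial p-value for AD_alt out of ``total`` reads
    under a 50% expected alternate-allele balance.

    Two-sided means the symmetric doubled tail, capped at 1 — at p0 = 0.5
    the common two-sided definitions coincide.
    """
    if total < 1:
        raise ValueError("total read count must be >= 1")
    if not (0 <= ad_alt <= total):
        raise ValueError("ad_alt must be within [0, total]")
    lower = stats.binom.cdf(ad_alt, total, 0.5)
    upper = stats.binom.sf(ad_alt - 1, total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _allele_balance_pvalues(ad_alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    lower = stats.binom.cdf(ad_alt, total, 0.5)
    upper = stats.binom.sf(ad_alt - 1, total, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def missingness_filter(
    variant: VariantRecord | np.ndarray, thresholds: QCThresholds = QCThresholds()
) -> tuple[bool, float]:
    """Return (keep, missing_fraction); drop when the fraction is strictly
    greater than ``max_missing``. Accepts a VariantRecord or a gt row."""
    if isinstance(variant, VariantRecord):
        gts = np.array([c.gt for c in variant.calls])
    else:
        gts = np.asarray(variant)
    if gts.size == 0:
        raise ValueError("variant has zero samples")
    frac = float(np.mean(gts == MISSING))
    return frac <= thresholds.max_missing, frac


def ad_dp_slope(
    variant: VariantRecord | GenotypeMatrix,
    index: int | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[float, str]:
    """No-intercept least-squares slope of AD_alt on genotype-weighted depth.

    Each non-missing call contributes (w(GT)*DP, AD_alt) with w = 0, 0.5, 1
    for hom-ref, het, hom-alt; a clean variant lies on the identity line so
    b ~= 1, while b < ``min_slope`` marks the variant spurious ('drop').
    Returns (slope, status) with status in {'keep', 'drop', 'skipped'}; the
    fit is skipped when fewer than ``slope_min_carriers`` carrier calls are
    available or all weighted depths are zero.
    """
    if isinstance(variant, GenotypeMatrix):
        if index is None:
            raise ValueError("index required with a GenotypeMatrix")
        gt = variant.gt[index].astype(float)
        dp = variant.dp[index].astype(float) if variant.dp is not None else None
        ad = variant.ad_alt[index].astype(float) if variant.ad_alt is not None else None
    else:
        gt = np.array([c.gt for c in variant.calls], dtype=float)
        dp = np.array([c.dp for c in variant.calls], dtype=float)
        ad = np.array([c.ad_alt for c in variant.calls], dtype=float)
    if dp is None or ad is None:
        return np.nan, "skipped"
    ok = (gt != MISSING) & (dp != MISSING) & (ad != MISSING)
    carriers = ok & (gt > 0)
    if carriers.sum() < thresholds.slope_min_carriers:
        return np.nan, "skipped"
    w = np.where(gt == GT_HET, 0.5, np.where(gt == GT_HOM_ALT, 1.0, 0.0))
    x = (w * dp)[ok]
    y = ad[ok]
    denom = float(np.sum(x * x))
    if denom == 0.0:
        return np.nan, "skipped"
    slope = float(np.sum(y * x) / denom)
    return slope, ("keep" if slope >= thresholds.min_slope else "drop")


def apply_genotype_filters(
    gm: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, dict]:
    """Vectorised per-call filters: depth/quality rule, then heterozygous
    SNV allele balance. Returns a new matrix plus counts of calls removed
    by each filter."""
    out = gm.copy()
    counts = {"low_dp_gq": 0, "allele_balance": 0, "ab_zero_reads": 0}
    present = out.gt != MISSING
    is_snv = (out.variants["vclass"] == SNV).to_numpy()[:, None]

    if out.dp is not None or out.gq is not None:
        dp_min = np.where(is_snv, thresholds.snv_dp, thresholds.indel_dp)
        gq_min = np.where(is_snv, thresholds.snv_gq, thresholds.indel_gq)
        low_dp = (
            np.zeros_like(present)
            if out.dp is None
            else (out.dp != MISSING) & (out.dp < dp_min)
        )
        low_gq = (
            np.zeros_like(present)
            if out.gq is None
            else (out.gq != MISSING) & (out.gq < gq_min)
        )
        fails = (low_dp | low_gq) if thresholds.rule == "or" else (low_dp & low_gq)
        fails &= present
        counts["low_dp_gq"] = int(fails.sum())
        out.gt[fails] = MISSING
        present = out.gt != MISSING

    if out.ad_ref is not None and out.ad_alt is not None:
        het_snv = present & (out.gt == GT_HET) & is_snv
        het_snv &= (out.ad_ref != MISSING) & (out.ad_alt != MISSING)
        total = out.ad_ref + out.ad_alt
        zero = het_snv & (total == 0)
        counts["ab_zero_reads"] = int(zero.sum())  # test skipped, call kept
        testable = het_snv & (total > 0)
        if testable.any():
            p = _allele_balance_pvalues(out.ad_alt[testable], total[testable])
            fail = p <= thresholds.ab_p
            counts["allele_balance"] = int(fail.sum())
            idx = np.flatnonzero(testable.ravel())[fail]
            out.gt.ravel()[idx] = MISSING
    return out, counts


def apply_variant_filters(
    gm: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    use_ad_dp_slope: bool = False,
    aascore: dict[str, float] | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Variant-level filters after the per-call stage: missingness, and
    optionally the AD~DP slope screen and the AAscore pass-through.
    Returns the reduced matrix and per-reason drop counts."""
    keep = np.ones(gm.n_variants, dtype=bool)
    counts = {"missingness": 0, "ad_dp_slope": 0, "aascore": 0, "slope_skipped": 0}
    for i in range(gm.n_variants):
        ok, _frac = missingness_filter(gm.gt[i], thresholds)
        if not ok:
            keep[i] = False
            counts["missingness"] += 1
            continue
        if use_ad_dp_slope:
            _slope, status = ad_dp_slope(gm, i, thresholds)
            if status == "drop":
                keep[i] = False
                counts["ad_dp_slope"] += 1
                continue
            if status == "skipped":
                counts["slope_skipped"] += 1
        if aascore is not None:
            score = aascore.get(gm.variants.key.iloc[i])
            if score is not None and score <= thresholds.min_aascore:
                keep[i] = False
                counts["aascore"] += 1
    return gm.subset_variants(keep), counts


def apply_qc(
    gm: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    use_ad_dp_slope: bool = False,
    aascore: dict[str, float] | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Full QC sequence: per-call filters, then variant-level filters."""
    out, call_counts = apply_genotype_filters(gm, thresholds)
    out, var_counts = apply_variant_filters(out, thresholds, use_ad_dp_slope, aascore)
    return out, {"calls": call_counts, "variants": var_counts}
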
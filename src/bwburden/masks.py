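"""Variant collapsing masks and per-gene carrier vectors.

A collapsing mask is a rule set deciding which annotated variants qualify
for a gene's burden. Masks are expressed as a disjunction of clauses so
that, e.g., the "Missense + PTV" mask can require LOFTEE high confidence
for truncating consequences while requiring CADD >= 25 (but no LOFTEE
flag) for missense variants. Three dialects are built in:

* ``discovery``  — PTV = {stop_gained, splice_donor, splice_acceptor,
  frameshift} with LOFTEE HC; Missense+PTV adds missense with CADD >= 25.
* ``regenie``    — as discovery, but the damaging-missense clause also
  admits inframe insertions/deletions with CADD >= 25.
* ``decode``     — LOF additionally includes start_lost and stop_lost;
  LOF+MIS adds the moderate-impact classes (missense, inframe_indel,
  splice_region) with CADD >= 25.

Qualifying variants must also be rare: the in-sample minor allele
frequency (post-QC, per analysis arm) must be strictly below 0.1%.
Collapsed gene x mask carrier vectors with fewer than 10 carriers are
excluded from association testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import MISSING, GenotypeMatrix

CONSEQUENCES = (
    "stop_gained",
    "splice_donor",
    "splice_acceptor",
    "frameshift",
    "start_lost",
    "stop_lost",
    "missense",
    "inframe_indel",
    "splice_region",
    "synonymous",
    "other",
)

PTV_CONSEQUENCES = frozenset(
    {"stop_gained", "splice_donor", "splice_acceptor", "frameshift"}
)
DECODE_LOF_CONSEQUENCES = PTV_CONSEQUENCES | {"start_lost", "stop_lost"}
MODERATE_CONSEQUENCES = frozenset({"missense", "inframe_indel", "splice_region"})

MAF_MAX = 0.001
MIN_CARRIERS = 10


@dataclass(frozen=True)
class VariantAnnotation:
    """Prioritised (single-transcript, most-damaging) annotation of one
    variant: consequence class, LOFTEE confidence, CADD score, plus
    optional pathogenicity / external-frequency columns."""

    variant_key: str
    gene_id: str
    consequence: str
    loftee: str = "none"  # 'HC', 'LC' or 'none'
    cadd: float | None = None
    pathogenic_flag: bool = False
    maf_external: float | None = None
    aascore: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.loftee not in ("HC", "LC", "none"):
            raise ValueError(f"unknown LOFTEE confidence {self.loftee!r}")


@dataclass(frozen=True)
class MaskClause:
    consequences: frozenset[str]
    require_loftee_hc: bool = False
    cadd_min: float | None = None

    def __post_init__(self) -> None:
        if self.cadd_min is not None and self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")

    def matches(self, ann: VariantAnnotation) -> bool:
        if ann.consequence not in self.consequences:
            return False
        if self.require_loftee_hc and ann.loftee != "HC":
            return False
        if self.cadd_min is not None:
            if ann.cadd is None:
                return False  # cannot evaluate the CADD requirement
            if ann.cadd < self.cadd_min:
                return False
        return True


@dataclass(frozen=True)
class MaskDefinition:
    """A named mask: a variant qualifies if any clause matches, or — for
    the custom dialect — if its key is in the explicit variant list."""

    name: str
    dialect: str = "discovery"  # discovery | regenie | decode | custom
    clauses: tuple[MaskClause, ...] = ()
    explicit_variant_list: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.dialect == "custom" and not self.explicit_variant_list:
            raise ValueError("custom dialect requires an explicit variant list")


def ptv_mask(dialect: str = "discovery") -> MaskDefinition:
    """High-confidence protein-truncating mask for the given dialect."""
    if dialect in ("discovery", "regenie"):
        cons = PTV_CONSEQUENCES
    elif dialect == "decode":
        cons = DECODE_LOF_CONSEQUENCES
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    name = "LOF" if dialect == "decode" else "PTV"
    return MaskDefinition(name, dialect, (MaskClause(cons, require_loftee_hc=True),))


def missense_ptv_mask(dialect: str = "discovery", cadd_min: float = 25.0) -> MaskDefinition:
    """Truncating variants plus damaging missense (CADD-thresholded)."""
    base = ptv_mask(dialect)
    if dialect == "discovery":
        extra = frozenset({"missense"})
    elif dialect == "regenie":
        extra = frozenset({"missense", "inframe_indel"})
    elif dialect == "decode":
        extra = MODERATE_CONSEQUENCES
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    name = "LOF+MIS" if dialect == "decode" else "MissensePTV"
    return MaskDefinition(
        name, dialect, base.clauses + (MaskClause(extra, cadd_min=cadd_min),)
    )


def dialect_masks(dialect: str = "discovery") -> list[MaskDefinition]:
    return [ptv_mask(dialect), missense_ptv_mask(dialect)]


def build_custom_mask(variant_list: Iterable[str], name: str = "custom") -> MaskDefinition:
    """Mask matching exactly the listed variant keys (pathogenic panels,
    score-defined subsets, ...). Duplicates collapse."""
    keys = frozenset(variant_list)
    if not keys:
        raise ValueError("custom mask requires a non-empty variant list")
    return MaskDefinition(name, "custom", (), keys)


def qualifies(annotation: VariantAnnotation, mask: MaskDefinition) -> bool:
    """Deterministic mask membership for one annotated variant."""
    if mask.explicit_variant_list is not None:
        return annotation.variant_key in mask.explicit_variant_list
    return any(clause.matches(annotation) for clause in mask.clauses)


def compute_maf(gt_row: np.ndarray) -> float:
    """Minor allele frequency over non-missing calls (alt frequency folded
    to the minor allele). Raises on an all-missing row."""
    gts = np.asarray(gt_row)
    ok = gts != MISSING
    if not ok.any():
        raise ValueError("all calls missing; MAF undefined")
    af = float(gts[ok].sum()) / (2.0 * int(ok.sum()))
    return min(af, 1.0 - af)


@dataclass(frozen=True)
class GeneBurdenSet:
    """The qualifying variants of one gene under one mask."""

    gene_id: str
    mask_name: str
    variant_keys: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_keys", tuple(sorted(set(self.variant_keys))))


def leave_one_out(burden_set: GeneBurdenSet, variant_key: str) -> GeneBurdenSet:
    """Remove one variant from a burden set; removing an absent key is the
    identity (a fresh, equal object)."""
    keys = tuple(k for k in burden_set.variant_keys if k != variant_key)
    return GeneBurdenSet(burden_set.gene_id, burden_set.mask_name, keys)


@dataclass
class CarrierVector:
    """Collapsed per-sample carrier status for one gene x mask.

    status: 1 = carries >= 1 alt allele at >= 1 qualifying variant,
    0 = non-carrier, MISSING = all qualifying calls missing for the sample
    (such samples are excluded complete-case from the regression). With
    ``coding='count'`` status holds the summed alt-allele count instead of
    the indicator; carriers are still counted as status > 0.
    """

    gene_id: str
    mask_name: str
    samples: list[str]
    status: np.ndarray
    qualifying_variant_keys: tuple[str, ...]

    @property
    def n_carriers(self) -> int:
        return int((self.status > 0).sum())

    @property
    def n_missing(self) -> int:
        return int((self.status == MISSING).sum())


def build_burden_set(
    gene_id: str,
    mask: MaskDefinition,
    annotations: Sequence[VariantAnnotation],
    gm: GenotypeMatrix,
    maf_max: float = MAF_MAX,
    log: list | None = None,
) -> GeneBurdenSet:
    """Select the gene's qualifying variants present in the genotype matrix
    and strictly rarer than ``maf_max`` (in-sample, post-QC, folded)."""
    keys: list[str] = []
    for ann in annotations:
        if ann.gene_id != gene_id or not qualifies(ann, mask):
            continue
        try:
            i = gm.index_of(ann.variant_key)
        except KeyError:
            continue
        try:
            maf = compute_maf(gm.gt[i])
        except ValueError:
            if log is not None:
                log.append(("all_missing", ann.variant_key))
            continue
        if maf < maf_max:
            keys.append(ann.variant_key)
        elif log is not None:
            log.append(("maf", ann.variant_key))
    return GeneBurdenSet(gene_id, mask.name, tuple(keys))


def collapse_set(
    burden_set: GeneBurdenSet, gm: GenotypeMatrix, coding: str = "indicator"
) -> CarrierVector:
    """Collapse a burden set to a carrier vector over ``gm``'s samples."""
    if coding not in ("indicator", "count"):
        raise ValueError("coding must be 'indicator' or 'count'")
    idx = [gm.index_of(k) for k in burden_set.variant_keys]
    if idx:
        gt = gm.gt[idx].astype(np.int32)
        present = gt != MISSING
        alt = np.where(present, gt, 0)
        total = alt.sum(axis=0)
        any_present = present.any(axis=0)
        if coding == "indicator":
            status = np.where(total > 0, 1, 0)
        else:
            status = total
        status = np.where(any_present, status, MISSING).astype(np.int32)
    else:
        status = np.full(gm.n_samples, MISSING, dtype=np.int32)
    return CarrierVector(
        burden_set.gene_id,
        burden_set.mask_name,
        list(gm.samples),
        status,
        burden_set.variant_keys,
    )


def collapse(
    gene_id: str,
    mask: MaskDefinition,
    gm: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    maf_max: float = MAF_MAX,
    coding: str = "indicator",
) -> CarrierVector:
    """Convenience: qualify + MAF-filter + collapse in one call."""
    bset = build_burden_set(gene_id, mask, annotations, gm, maf_max)
    return collapse_set(bset, gm, coding)


def collapse_all(
    masks: Sequence[MaskDefinition],
    gm: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    maf_max: float = MAF_MAX,
    min_carriers: int = MIN_CARRIERS,
    coding: str = "indicator",
    log: list | None = None,
) -> list[CarrierVector]:
    """Collapse every annotated gene under every mask, keeping only
    gene x mask combinations with >= ``min_carriers`` carriers (genes with
    no qualifying variants or too few carriers are logged and skipped)."""
    genes = sorted({a.gene_id for a in annotations})
    out: list[CarrierVector] = []
    for gene in genes:
        ganns = [a for a in annotations if a.gene_id == gene]
        for mask in masks:
            bset = build_burden_set(gene, mask, ganns, gm, maf_max)
            if not bset.variant_keys:
                if log is not None:
                    log.append(("no_qualifying_variants", gene, mask.name))
                continue
            cv = collapse_set(bset, gm, coding)
            if cv.n_carriers < min_carriers:
                if log is not None:
                    log.append(("lt_min_carriers", gene, mask.name, cv.n_carriers))
                continue
            out.append(cv)
    return out


def annotations_from_frame(df: pd.DataFrame) -> list[VariantAnnotation]:
    """Build annotation records from a TSV-derived DataFrame with columns
    variant_key, gene_id, consequence, loftee, cadd and optional
    pathogenic_flag / maf_external / aascore."""
    def _opt(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(
            VariantAnnotation(
                variant_key=row["variant_key"],
                gene_id=row["gene_id"],
                consequence=row["consequence"],
                loftee=row.get("loftee", "none") if pd.notna(row.get("loftee")) else "none",
                cadd=_opt(row, "cadd"),
                pathogenic_flag=bool(row.get("pathogenic_flag", False))
                if pd.notna(row.get("pathogenic_flag", False))
                else False,
                maf_external=_opt(row, "maf_external"),
                aascore=_opt(row, "aascore"),
            )
        )
    return out
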
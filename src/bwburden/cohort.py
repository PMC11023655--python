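"""In-memory containers shared across the pipeline.

The unit of analysis is the mother-child duo: children carry their own
birth weight ("fetal" arm), mothers carry the birth weight of their first
child ("maternal" arm). Genotypes are held as dense per-variant integer
arrays with the sentinel ``MISSING`` (-1) standing in for both missing
calls and absent FORMAT fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: sentinel for a missing genotype / absent FORMAT value
MISSING = -1

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

SNV = "SNV"
INDEL = "indel"


def variant_class(ref: str, alt: str) -> str:
    """Classify a biallelic ref/alt pair as SNV or indel."""
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """A single sample's call at one variant.

    ``gt`` is the alt-allele count (0/1/2) or MISSING. Depth, quality and
    allele depths default to MISSING, meaning the field was absent in the
    source; ``ad_ref + ad_alt <= dp`` is deliberately not enforced because
    real callers violate it.
    """

    gt: int
    dp: int = MISSING
    gq: int = MISSING
    ad_ref: int = MISSING
    ad_alt: int = MISSING

    def __post_init__(self) -> None:
        if self.gt not in (MISSING, GT_HOM_REF, GT_HET, GT_HOM_ALT):
            raise ValueError(f"invalid genotype code {self.gt!r}")
        for name in ("dp", "gq", "ad_ref", "ad_alt"):
            v = getattr(self, name)
            if v != MISSING and v < 0:
                raise ValueError(f"{name} must be >= 0 (or MISSING), got {v}")

    @property
    def is_missing(self) -> bool:
        return self.gt == MISSING

    def as_missing(self) -> "GenotypeCall":
        return GenotypeCall(MISSING, self.dp, self.gq, self.ad_ref, self.ad_alt)


@dataclass
class VariantRecord:
    """One biallelic variant with its per-sample calls."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    calls: list[GenotypeCall] = field(default_factory=list)

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


def _as_array(values, dtype, shape) -> np.ndarray | None:
    if values is None:
        return None
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != shape:
        raise ValueError(f"array shape {arr.shape} != expected {shape}")
    return arr


class GenotypeMatrix:
    """Dense genotype store: variants x samples.

    ``variants`` is a DataFrame with columns chrom, pos, ref, alt (key and
    vclass are derived if absent). ``gt`` holds alt-allele counts with -1
    for missing; ``dp``/``gq``/``ad_ref``/``ad_alt`` are optional arrays of
    the same shape (None when the FORMAT field is absent altogether).
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: Iterable[str],
        gt: np.ndarray,
        dp: np.ndarray | None = None,
        gq: np.ndarray | None = None,
        ad_ref: np.ndarray | None = None,
        ad_alt: np.ndarray | None = None,
    ) -> None:
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        variants = variants.reset_index(drop=True).copy()
        if "key" not in variants.columns:
            variants["key"] = [
                variant_key(c, int(p), r, a)
                for c, p, r, a in zip(
                    variants.chrom, variants.pos, variants.ref, variants.alt
                )
            ]
        if "vclass" not in variants.columns:
            variants["vclass"] = [
                variant_class(r, a) for r, a in zip(variants.ref, variants.alt)
            ]
        self.variants = variants
        shape = (len(variants), len(self.samples))
        self.gt = _as_array(gt, np.int8, shape)
        self.dp = _as_array(dp, np.int32, shape)
        self.gq = _as_array(gq, np.int32, shape)
        self.ad_ref = _as_array(ad_ref, np.int32, shape)
        self.ad_alt = _as_array(ad_alt, np.int32, shape)
        self._key_index = {k: i for i, k in enumerate(self.variants.key)}
        if len(self._key_index) != len(variants):
            raise ValueError("duplicated variant keys")

    # -- basic introspection -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def index_of(self, key: str) -> int:
        return self._key_index[key]

    def _field(self, arr: np.ndarray | None, i: int, j: int) -> int:
        return MISSING if arr is None else int(arr[i, j])

    def call(self, i: int, j: int) -> GenotypeCall:
        return GenotypeCall(
            gt=int(self.gt[i, j]),
            dp=self._field(self.dp, i, j),
            gq=self._field(self.gq, i, j),
            ad_ref=self._field(self.ad_ref, i, j),
            ad_alt=self._field(self.ad_alt, i, j),
        )

    def variant_record(self, i: int) -> VariantRecord:
        row = self.variants.iloc[i]
        calls = [self.call(i, j) for j in range(self.n_samples)]
        return VariantRecord(str(row.chrom), int(row.pos), row.ref, row.alt, calls)

    def dosage(self, key: str) -> np.ndarray:
        """Alt-allele dosage for one variant; NaN where missing."""
        row = self.gt[self.index_of(key)].astype(float)
        row[row == MISSING] = np.nan
        return row

    # -- transformation ------------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.copy(),
            list(self.samples),
            self.gt.copy(),
            None if self.dp is None else self.dp.copy(),
            None if self.gq is None else self.gq.copy(),
            None if self.ad_ref is None else self.ad_ref.copy(),
            None if self.ad_alt is None else self.ad_alt.copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.samples)}
        cols = [pos[s] for s in ids]
        take = lambda a: None if a is None else a[:, cols]
        return GenotypeMatrix(
            self.variants.copy(), ids, self.gt[:, cols],
            take(self.dp), take(self.gq), take(self.ad_ref), take(self.ad_alt),
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        take = lambda a: None if a is None else a[idx]
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples), self.gt[idx],
            take(self.dp), take(self.gq), take(self.ad_ref), take(self.ad_alt),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples:
            return False
        if not self.variants[["chrom", "pos", "ref", "alt"]].astype(
            {"pos": int}
        ).equals(other.variants[["chrom", "pos", "ref", "alt"]].astype({"pos": int})):
            return False
        for a, b in (
            (self.gt, other.gt), (self.dp, other.dp), (self.gq, other.gq),
            (self.ad_ref, other.ad_ref), (self.ad_alt, other.ad_alt),
        ):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


PERSON_COLUMNS = ["sex", "mother_id", "role"]


@dataclass
class DuoCohort:
    """A simulated or loaded mother-child duo cohort.

    persons: indexed by person id; columns sex ('F'/'M'), mother_id ('' for
        founders), role ('child'/'mother'), age, pc1..pc10, batch.
    genotypes: all persons as samples.
    own_reports: person_id, visit, value_kg, multiple_birth — repeated
        self-reports of one's own birth weight (fetal arm).
    offspring_reports: mother_id, source ('self'/'hospital'), value_kg,
        multiple_birth — a mother's records of her first child's weight.
    truth: simulator-only ground truth (latent phenotype, paternal draws,
        per-gene carrier matrices); empty for cohorts read from disk.
    """

    persons: pd.DataFrame
    genotypes: GenotypeMatrix
    own_reports: pd.DataFrame
    offspring_reports: pd.DataFrame
    truth: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        roles = self.persons["role"]
        children = self.persons[roles == "child"]
        mothers = self.persons[roles == "mother"]
        missing_mothers = set(children["mother_id"]) - set(mothers.index)
        if missing_mothers:
            raise ValueError(f"children with absent mothers: {sorted(missing_mothers)[:5]}")
        if not (mothers["sex"] == "F").all():
            raise ValueError("mothers must be female")
        if set(self.genotypes.samples) != set(self.persons.index):
            raise ValueError("genotype samples inconsistent with persons table")

    @property
    def children(self) -> list[str]:
        return list(self.persons.index[self.persons["role"] == "child"])

    @property
    def mothers(self) -> list[str]:
        return list(self.persons.index[self.persons["role"] == "mother"])

    def mother_of(self) -> Mapping[str, str]:
        sub = self.persons[self.persons["role"] == "child"]
        return dict(zip(sub.index, sub["mother_id"]))

    def true_carriers(self, gene_variant_keys: Iterable[str]) -> pd.DataFrame:
        """Per-duo carrier status (child, mother) from the current genotype
        matrix, treating any non-missing alt allele at any listed variant
        as carriage. Intended for validation against planted effects."""
        keys = list(gene_variant_keys)
        idx = [self.genotypes.index_of(k) for k in keys]
        gt = self.genotypes.gt[idx]
        carrier = (gt > 0).any(axis=0).astype(int)
        by_sample = dict(zip(self.genotypes.samples, carrier))
        mother = self.mother_of()
        rows = [
            (c, by_sample[c], by_sample[mother[c]]) for c in self.children
        ]
        return pd.DataFrame(
            rows, columns=["child", "child_carrier", "mother_carrier"]
        ).set_index("child")
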
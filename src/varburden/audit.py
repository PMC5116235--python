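"""Frequency-based reassessment of previously reported pathogenic variants.

Literature-curated disease-mutation lists accumulate false positives; a
variant reported as disease-causing but present in a large reference
population at a frequency above what a penetrant dominant allele could
sustain is incompatible with causation.  Each reported variant is placed in
one of four statuses by its reference MAF, and per-disease summaries give
the proportions observed, the proportion too common to be causal, and the
cumulative fraction of reference individuals carrying any reported variant.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from varburden.frequency import FrequencyConfig
from varburden.variant_io import ReferenceSite

logger = logging.getLogger(__name__)


class ReportedTag(enum.Enum):
    """Curated database pathogenicity tags admitted to the audit."""

    DM = "DM"
    DM_UNCERTAIN = "DM?"


class AuditStatus(enum.Enum):
    ABSENT = "absent"
    PRESENT_RARE = "present_rare"
    EXCEEDS_RARE_THRESHOLD = "exceeds_rare_threshold"
    POLYMORPHISM_EXCLUDED = "polymorphism_excluded"


@dataclass(frozen=True)
class ReportedVariant:
    """A variant previously reported as disease-causing."""

    disease: str
    gene: str
    variant_id: str
    reported_tag: ReportedTag = ReportedTag.DM
    reference_maf: float | None = None

    def __post_init__(self) -> None:
        if self.reference_maf is not None and not 0 <= self.reference_maf <= 1:
            raise ValueError(
                f"reference_maf must be in [0,1], got {self.reference_maf}"
            )


@dataclass(frozen=True)
class AuditSummary:
    """Per-disease audit of a reported-pathogenic variant list."""

    disease: str
    n_variants: int
    n_observed: int
    n_exceeding_rare: int
    n_polymorphism_excluded: int
    observed_proportion: float
    exceeding_proportion: float
    cumulative_carrier_frequency: float


def classify_reported(
    variant: ReportedVariant, config: FrequencyConfig | None = None
) -> AuditStatus:
    """Place a reported variant in a frequency-compatibility status.

    ABSENT: never seen in the reference.  PRESENT_RARE: seen but below the
    rare threshold, so frequency alone cannot exclude it.
    EXCEEDS_RARE_THRESHOLD: too common to be a penetrant dominant allele.
    POLYMORPHISM_EXCLUDED: an outright polymorphism, removed from analyses.
    """
    config = config or FrequencyConfig()
    maf = variant.reference_maf
    if maf is None or maf == 0:
        return AuditStatus.ABSENT
    if maf > config.polymorphism_threshold:
        return AuditStatus.POLYMORPHISM_EXCLUDED
    if maf > config.rare_maf_threshold:
        return AuditStatus.EXCEEDS_RARE_THRESHOLD
    return AuditStatus.PRESENT_RARE


def attach_reference_maf(
    variants: Iterable[ReportedVariant], reference_sites: Sequence[ReferenceSite]
) -> list[ReportedVariant]:
    """Fill reference_maf by matching variant ids against reference sites."""
    maf = {s.variant_id: s.maf for s in reference_sites}
    return [
        ReportedVariant(
            disease=v.disease,
            gene=v.gene,
            variant_id=v.variant_id,
            reported_tag=v.reported_tag,
            reference_maf=maf.get(v.variant_id, v.reference_maf),
        )
        for v in variants
    ]


def audit_summary(
    variants: Sequence[ReportedVariant],
    reference_sites: Sequence[ReferenceSite],
    n_ref_effective: float,
    config: FrequencyConfig | None = None,
    dm_only: bool = False,
) -> dict[str, AuditSummary]:
    """Summarise a reported-variant list per disease.

    Counts (after polymorphism exclusion) how many reported variants are
    observed in the reference at any frequency and how many exceed the rare
    threshold.  The cumulative carrier frequency sums reference allele
    counts over retained reported variants and divides by the effective
    reference cohort size, capped at 1 — an independence approximation,
    since summary data cannot de-duplicate individuals carrying several
    reported variants.
    """
    config = config or FrequencyConfig()
    if dm_only:
        variants = [v for v in variants if v.reported_tag is ReportedTag.DM]
    variants = attach_reference_maf(variants, reference_sites)
    ac_by_id: Mapping[str, int] = {s.variant_id: s.ac for s in reference_sites}

    out: dict[str, AuditSummary] = {}
    for disease in sorted({v.disease for v in variants}):
        dvs = [v for v in variants if v.disease == disease]
        statuses = [classify_reported(v, config) for v in dvs]
        retained = [
            (v, s)
            for v, s in zip(dvs, statuses)
            if s is not AuditStatus.POLYMORPHISM_EXCLUDED
        ]
        n_poly = len(dvs) - len(retained)
        n_total = len(retained)
        n_observed = sum(1 for _, s in retained if s is not AuditStatus.ABSENT)
        n_exceed = sum(
            1 for _, s in retained if s is AuditStatus.EXCEEDS_RARE_THRESHOLD
        )
        sum_ac = sum(ac_by_id.get(v.variant_id, 0) for v, _ in retained)
        cum = min(1.0, sum_ac / n_ref_effective) if n_ref_effective > 0 else 0.0
        out[disease] = AuditSummary(
            disease=disease,
            n_variants=n_total,
            n_observed=n_observed,
            n_exceeding_rare=n_exceed,
            n_polymorphism_excluded=n_poly,
            observed_proportion=n_observed / n_total if n_total else 0.0,
            exceeding_proportion=n_exceed / n_total if n_total else 0.0,
            cumulative_carrier_frequency=cum,
        )
    return out


def read_reported_table(path) -> list[ReportedVariant]:
    """Read a reported-variant TSV (disease, gene, variant_id, reported_tag)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["disease", "gene", "variant_id", "reported_tag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"reported-variant table {path} missing column(s): " + ", ".join(missing)
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            tag = ReportedTag(row.reported_tag)
        except ValueError as exc:
            raise ValueError(
                f"{path}, data row {i}: invalid reported_tag {row.reported_tag!r}"
            ) from exc
        maf = getattr(row, "reference_maf", None)
        if maf is not None and not (isinstance(maf, float) and pd.isna(maf)) and maf != "":
            maf = float(maf)
        else:
            maf = None
        out.append(
            ReportedVariant(
                disease=row.disease,
                gene=row.gene,
                variant_id=row.variant_id,
                reported_tag=tag,
                reference_maf=maf,
            )
        )
    return out
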
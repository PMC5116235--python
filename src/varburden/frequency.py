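"""Allele frequencies, the rare-variant filter, and coverage-adjusted denominators.

The filter keeps variants whose reference-population minor allele frequency
is below a threshold (default 1e-4) chosen so that no variant more common
than the most frequent known-pathogenic allele survives; variants absent
from the reference are assigned frequency zero and always pass.  Reference
carrier denominators are coverage-adjusted per gene and class: the
effective number of reference individuals is half the mean per-site allele
number over the retained sites, so incompletely genotyped sites shrink the
denominator rather than biasing the frequency.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from varburden.variant_io import CaseVariant, ReferenceSite, VariantClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyConfig:
    """Thresholds governing rarity and polymorphism exclusion.

    rare_maf_threshold
        Variants at or above this reference MAF are considered too common
        to be highly penetrant pathogenic alleles (default 1e-4).
    polymorphism_threshold
        Variants above this MAF are polymorphisms, removed outright from
        audits of reported-pathogenic lists (default 1e-2).
    assume_het
        Treat every reference allele as one heterozygous carrier when
        converting allele counts to carrier counts.  At the frequencies
        retained by the filter the homozygote correction is negligible.
    """

    rare_maf_threshold: float = 1e-4
    polymorphism_threshold: float = 1e-2
    assume_het: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rare_maf_threshold < self.polymorphism_threshold < 1:
            raise ValueError(
                "require 0 < rare_maf_threshold < polymorphism_threshold < 1, got "
                f"{self.rare_maf_threshold}, {self.polymorphism_threshold}"
            )


@dataclass(frozen=True)
class GeneReferenceSummary:
    """Coverage-adjusted reference carrier summary for one gene and class."""

    gene: str
    variant_class: VariantClass
    sum_ac: int
    mean_an: float
    used_fallback_an: bool = False

    def __post_init__(self) -> None:
        if self.sum_ac < 0:
            raise ValueError("sum_ac must be >= 0")
        if self.mean_an <= 0:
            raise ValueError("mean_an must be > 0")

    @property
    def n_ref_effective(self) -> float:
        """Effective reference sample size: mean AN over two alleles each."""
        return self.mean_an / 2.0

    def carrier_frequency(self, config: FrequencyConfig | None = None) -> float:
        """Proportion of effective reference individuals carrying a variant."""
        carriers = min(float(self.sum_ac), self.n_ref_effective)
        if carriers < self.sum_ac:
            logger.warning(
                "reference carriers capped at n_ref_effective for %s/%s",
                self.gene,
                self.variant_class.value,
            )
        return carriers / self.n_ref_effective


def compute_maf(ac: int, an: int) -> float:
    """Allele frequency ac/an.

    Raises ValueError when an == 0 (frequency undefined) or the counts are
    inconsistent.
    """
    if an == 0:
        raise ValueError("allele frequency undefined: an = 0")
    if not 0 <= ac <= an:
        raise ValueError(f"require 0 <= ac <= an, got ac={ac}, an={an}")
    return ac / an


def filter_rare(
    case_variants: Iterable[CaseVariant],
    reference_sites: Iterable[ReferenceSite],
    config: FrequencyConfig | None = None,
) -> tuple[list[CaseVariant], list[ReferenceSite]]:
    """Apply the rarity filter symmetrically to cases and reference.

    A variant is retained iff its reference MAF is strictly below
    ``config.rare_maf_threshold`` and its consequence classifies into a
    burden class (truncating or nontruncating).  Case variants absent from
    the reference have frequency 0 and always pass.  Applying the same
    reference-frequency criterion to both sides keeps the shared benign
    background symmetric between cohorts.
    """
    config = config or FrequencyConfig()
    reference_sites = list(reference_sites)
    ref_maf = {s.variant_id: s.maf for s in reference_sites}

    def rare(variant_id: str) -> bool:
        return ref_maf.get(variant_id, 0.0) < config.rare_maf_threshold

    kept_cases = [
        v
        for v in case_variants
        if v.variant_class is not VariantClass.EXCLUDED and rare(v.variant_id)
    ]
    kept_sites = [
        s
        for s in reference_sites
        if s.variant_class is not VariantClass.EXCLUDED and rare(s.variant_id)
    ]
    return kept_cases, kept_sites


def summarize_reference_gene(
    sites: Sequence[ReferenceSite],
    gene: str | None = None,
    variant_class: VariantClass | None = None,
    fallback_an: float | None = None,
) -> GeneReferenceSummary:
    """Aggregate retained reference sites of one gene and class.

    sum_ac is the total allele count over sites; mean_an the mean per-site
    allele number, which halved gives the effective number of reference
    individuals.  With zero retained sites the carrier numerator is 0 and
    the denominator falls back to ``fallback_an`` (callers typically pass
    the median AN over all sites of the gene, or 2x the nominal cohort
    size); without a fallback this is an error.
    """
    sites = list(sites)
    if gene is None:
        if not sites:
            raise ValueError("gene must be given when no sites are provided")
        gene = sites[0].gene
    if variant_class is None and sites:
        variant_class = sites[0].variant_class
    if any(s.gene != gene for s in sites):
        raise ValueError(f"sites from multiple genes passed for {gene}")
    if not sites:
        if fallback_an is None:
            raise ValueError(
                f"no retained reference sites for {gene} and no gene-level AN "
                "fallback available; supply fallback_an"
            )
        logger.warning("using fallback AN %.1f for %s (no retained sites)", fallback_an, gene)
        return GeneReferenceSummary(
            gene=gene,
            variant_class=variant_class or VariantClass.NONTRUNCATING,
            sum_ac=0,
            mean_an=float(fallback_an),
            used_fallback_an=True,
        )
    sum_ac = sum(s.ac for s in sites)
    mean_an = statistics.fmean(s.an for s in sites)
    return GeneReferenceSummary(
        gene=gene,
        variant_class=variant_class or VariantClass.NONTRUNCATING,
        sum_ac=sum_ac,
        mean_an=mean_an,
    )


def gene_fallback_an(all_gene_sites: Sequence[ReferenceSite]) -> float | None:
    """Median AN over every site of a gene, used when a class has no sites."""
    if not all_gene_sites:
        return None
    return float(statistics.median(s.an for s in all_gene_sites))
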
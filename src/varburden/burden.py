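"""Per-gene case-versus-reference burden statistics.

For each gene and variant class a 2x2 table of carriers and non-carriers in
cases versus the reference population yields: case excess (the difference in
carrier proportions, an estimate of how many case carriers are explained by
the gene), a two-sided Fisher's exact test with Bonferroni control across the
disease panel, the odds ratio with a Woolf log-normal confidence interval
(Haldane-Anscombe corrected at zero cells), and the etiological fraction
EF = (OR - 1)/OR, the estimated probability that a qualifying variant found
in an affected carrier is causal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from varburden.frequency import (
    FrequencyConfig,
    GeneReferenceSummary,
    gene_fallback_an,
    summarize_reference_gene,
)
from varburden.variant_io import CaseVariant, PanelEntry, ReferenceSite, VariantClass

logger = logging.getLogger(__name__)

#: Pseudo-class covering the union of truncating and nontruncating variants.
ALL_CLASSES = "all"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carriers-by-cohort table.

    a: case carriers, b: case non-carriers, c: reference carriers,
    d: reference non-carriers.  c and d may be non-integer after coverage
    adjustment of the reference denominator.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in contingency table {self}")

    def rounded(self) -> tuple[int, int, int, int]:
        return (
            int(round(self.a)),
            int(round(self.b)),
            int(round(self.c)),
            int(round(self.d)),
        )


@dataclass(frozen=True)
class MultipleTestingPlan:
    """Family-wise error control across the genes of one disease panel."""

    alpha: float = 0.05
    m: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


@dataclass(frozen=True)
class GeneBurdenResult:
    """All per-gene, per-class burden statistics."""

    disease: str
    gene: str
    variant_class: str
    n_cases: int
    n_ref_effective: float
    case_carriers: float
    ref_carriers: float
    case_freq: float
    ref_freq: float
    case_excess: float
    fisher_p: float
    significant: bool
    or_point: float
    or_lo: float
    or_hi: float
    ef_point: float
    ef_lo: float
    ef_hi: float
    predicted_pathogenic: float
    used_fallback_an: bool = False


def case_frequency(
    case_variants: Iterable[CaseVariant], n_cases: int
) -> float:
    """Proportion of cases carrying a qualifying variant.

    Sums per-variant carrier counts; the sum is capped at n_cases with a
    warning, since summary tables cannot resolve cases carrying two
    qualifying variants.
    """
    if n_cases <= 0:
        raise ValueError(f"n_cases must be > 0, got {n_cases}")
    total = sum(v.carrier_count for v in case_variants)
    if total > n_cases:
        logger.warning(
            "carrier total %d exceeds n_cases %d; capping (multi-variant "
            "carriers unresolvable from summary input)",
            total,
            n_cases,
        )
        total = n_cases
    return total / n_cases


def case_excess(case_freq: float, ref_freq: float) -> float:
    """Difference in carrier proportions, cases minus reference (may be < 0)."""
    for name, p in (("case_freq", case_freq), ("ref_freq", ref_freq)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    return case_freq - ref_freq


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Cells are rounded to the nearest integer (the exact test requires
    counts).  The p-value is the sum of hypergeometric probabilities, over
    all tables with the same margins, that do not exceed the observed
    table's probability — the standard two-sided definition.  A table with
    an empty cohort margin carries no information and returns p = 1.
    """
    a, b, c, d = table.rounded()
    return _fisher_two_sided(a, b, c, d)


# relative tolerance when comparing hypergeometric point probabilities;
# guards against float noise excluding ties (same device as R/fisher.test)
_REL_TIE = 1.0 + 1e-7


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    n1 = a + c  # first-column margin (carriers)
    total = r1 + r2
    if r1 == 0 or r2 == 0 or n1 == 0 or n1 == total:
        if r1 == 0 or r2 == 0:
            logger.warning("degenerate margin in Fisher table; returning p = 1")
        return 1.0
    k = np.arange(max(0, n1 - r2), min(r1, n1) + 1)
    logpmf = _log_hypergeom_pmf(k, total, r1, n1)
    logp_obs = float(_log_hypergeom_pmf(np.array([a]), total, r1, n1)[0])
    pmf = np.exp(logpmf)
    p = float(pmf[logpmf <= logp_obs + math.log(_REL_TIE)].sum())
    return min(p, 1.0)


def _log_hypergeom_pmf(k: np.ndarray, total: int, r1: int, n1: int) -> np.ndarray:
    """log P(K = k) for K ~ Hypergeom(total, r1, n1) over the support."""
    from scipy.special import gammaln

    def logchoose(n, x):
        return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)

    return logchoose(r1, k) + logchoose(total - r1, n1 - k) - logchoose(total, n1)


def odds_ratio_ci(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Odds ratio with Woolf log-normal CI.

    OR = (a*d)/(b*c).  If any cell is zero, the Haldane-Anscombe correction
    (0.5 added to all four cells) is used for both the point estimate and
    the interval.  A table with an all-zero cohort row has no defined OR.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0):
        raise ValueError("odds ratio undefined: one cohort row is all zero")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return (
        or_point,
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
    )


def etiological_fraction(
    or_point: float, or_lo: float | None = None, or_hi: float | None = None
) -> tuple[float, float | None, float | None]:
    """Etiological fraction (OR - 1)/OR, floored at 0, for point and CI bounds.

    EF estimates the probability that the exposure (a qualifying rare
    variant) caused disease in an affected carrier.  The transform is
    monotone in OR, so CI bounds map directly; bounds below OR = 1 floor
    at 0.
    """

    def ef(or_value: float | None) -> float | None:
        if or_value is None:
            return None
        if or_value <= 0:
            raise ValueError(f"OR must be > 0, got {or_value}")
        return max(0.0, (or_value - 1.0) / or_value)

    return ef(or_point), ef(or_lo), ef(or_hi)


def bonferroni_threshold(plan: MultipleTestingPlan) -> float:
    """Per-test p-value threshold alpha/m for family-wise control."""
    return plan.alpha / plan.m


def binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion x/n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    lo, hi = proportion_confint(x, n, alpha=1 - level, method="wilson")
    # Wilson bounds are exactly 0 at x=0 and 1 at x=n; clear float residue
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return lo, hi


def predicted_pathogenic(case_excess: float, n_cases: int) -> float:
    """Expected number of cohort carriers whose variant is causal.

    max(0, case excess) times cohort size; the reporting layer rounds.
    """
    if n_cases <= 0:
        raise ValueError(f"n_cases must be > 0, got {n_cases}")
    return max(0.0, case_excess) * n_cases


def _class_of(name: str) -> tuple[VariantClass, ...]:
    if name == ALL_CLASSES:
        return (VariantClass.TRUNCATING, VariantClass.NONTRUNCATING)
    return (VariantClass(name),)


def burden_result(
    disease: str,
    gene: str,
    class_name: str,
    case_variants: Sequence[CaseVariant],
    summary: GeneReferenceSummary,
    n_cases: int,
    plan: MultipleTestingPlan,
) -> GeneBurdenResult:
    """Assemble the full statistics record for one gene and variant class.

    The Fisher test uses the table rounded to counts; OR and EF use the
    unrounded coverage-adjusted cells so effect estimates keep full
    precision.
    """
    n_ref = summary.n_ref_effective
    cf = case_frequency(case_variants, n_cases)
    a = cf * n_cases
    rf = summary.carrier_frequency()
    c = rf * n_ref
    table = ContingencyTable(a=a, b=n_cases - a, c=c, d=n_ref - c)
    p = fisher_exact(table)
    try:
        or_point, or_lo, or_hi = odds_ratio_ci(table)
        ef_point, ef_lo, ef_hi = etiological_fraction(or_point, or_lo, or_hi)
    except ValueError:
        or_point = or_lo = or_hi = math.nan
        ef_point = ef_lo = ef_hi = math.nan
    excess = case_excess(cf, rf)
    return GeneBurdenResult(
        disease=disease,
        gene=gene,
        variant_class=class_name,
        n_cases=n_cases,
        n_ref_effective=n_ref,
        case_carriers=a,
        ref_carriers=c,
        case_freq=cf,
        ref_freq=rf,
        case_excess=excess,
        fisher_p=p,
        significant=p <= bonferroni_threshold(plan),
        or_point=or_point,
        or_lo=or_lo,
        or_hi=or_hi,
        ef_point=ef_point,
        ef_lo=ef_lo,
        ef_hi=ef_hi,
        predicted_pathogenic=predicted_pathogenic(excess, n_cases),
        used_fallback_an=summary.used_fallback_an,
    )


def run_burden(
    disease: str,
    case_variants: Sequence[CaseVariant],
    reference_sites: Sequence[ReferenceSite],
    panel: Sequence[PanelEntry],
    config: FrequencyConfig | None = None,
    plan: MultipleTestingPlan | None = None,
    all_reference_sites: Sequence[ReferenceSite] | None = None,
    default_an: float | None = None,
) -> list[GeneBurdenResult]:
    """Run the burden comparison for every gene of a disease panel.

    ``case_variants`` and ``reference_sites`` are the rarity-filtered
    inputs (see :func:`varburden.frequency.filter_rare`).  One result is
    produced per gene and per class in {all, truncating, nontruncating}.
    When a gene/class has no retained reference site, the reference
    denominator falls back to the gene's median AN over
    ``all_reference_sites`` (the unfiltered site list), then to
    ``default_an``.  A case gene absent from the panel is a hard error:
    without its cohort size no frequency can be formed.

    The Bonferroni family size defaults to the number of genes on the
    panel for this disease.
    """
    config = config or FrequencyConfig()
    panel_entries = {e.gene: e for e in panel if e.disease == disease}
    if not panel_entries:
        raise ValueError(f"panel defines no genes for disease {disease!r}")
    if plan is None:
        plan = MultipleTestingPlan(alpha=0.05, m=len(panel_entries))

    cases = [v for v in case_variants if v.disease == disease]
    missing = sorted({v.gene for v in cases} - set(panel_entries))
    if missing:
        raise ValueError(
            f"case table contains gene(s) absent from the {disease} panel: "
            + ", ".join(missing)
        )

    by_gene_sites: dict[str, list[ReferenceSite]] = {g: [] for g in panel_entries}
    for s in reference_sites:
        if s.gene in by_gene_sites:
            by_gene_sites[s.gene].append(s)
    all_by_gene: dict[str, list[ReferenceSite]] = {g: [] for g in panel_entries}
    for s in all_reference_sites or reference_sites:
        if s.gene in all_by_gene:
            all_by_gene[s.gene].append(s)

    results: list[GeneBurdenResult] = []
    for gene, entry in sorted(panel_entries.items()):
        gene_cases = [v for v in cases if v.gene == gene]
        gene_sites = by_gene_sites[gene]
        fallback = gene_fallback_an(all_by_gene[gene])
        if fallback is None:
            fallback = default_an
        for class_name in (
            ALL_CLASSES,
            VariantClass.TRUNCATING.value,
            VariantClass.NONTRUNCATING.value,
        ):
            wanted = _class_of(class_name)
            cls_cases = [v for v in gene_cases if v.variant_class in wanted]
            cls_sites = [s for s in gene_sites if s.variant_class in wanted]
            summary = summarize_reference_gene(
                cls_sites,
                gene=gene,
                variant_class=wanted[0] if len(wanted) == 1 else None,
                fallback_an=fallback,
            )
            results.append(
                burden_result(
                    disease,
                    gene,
                    class_name,
                    cls_cases,
                    summary,
                    entry.n_cases,
                    plan,
                )
            )
    return results


def results_to_frame(results: Sequence[GeneBurdenResult]):
    """Tabulate results with fraction and x100 percentage columns."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in results])
    if not df.empty:
        df["case_excess_pct"] = df["case_excess"] * 100
        df["ef_pct"] = df["ef_point"] * 100
    return df
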
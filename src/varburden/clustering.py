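"""Nonrandom mutation clustering over protein residue positions.

Distinct rare missense variants are mapped to residue indices along the
canonical protein.  Under the null of uniform placement, the normalized
positions behave as uniform order statistics, and the gap between the i-th
and j-th order statistics follows Beta(j - i, n - (j - i) + 1).  A gap much
smaller than expected therefore flags a cluster.  The scan tests every pair,
controls the false discovery rate across pairs with Benjamini-Hochberg, and
merges the residue intervals of significant pairs into maximal clusters.
Cluster-restricted burden statistics then sharpen the etiological fraction
within a mutation-enriched region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from varburden.burden import (
    GeneBurdenResult,
    MultipleTestingPlan,
    burden_result,
)
from varburden.frequency import FrequencyConfig, summarize_reference_gene
from varburden.variant_io import CaseVariant, ReferenceSite, VariantClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionSet:
    """Residue positions of distinct missense variants in one cohort."""

    gene: str
    cohort: str
    positions: tuple[int, ...]
    protein_length: int

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        for p in self.positions:
            if not 1 <= p <= self.protein_length:
                raise ValueError(
                    f"residue {p} outside [1, {self.protein_length}] for {self.gene}"
                )


@dataclass(frozen=True)
class ClusterResult:
    """A maximal significant cluster interval on the protein."""

    start_residue: int
    end_residue: int
    n_in_cluster: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("start_residue must be <= end_residue")


def normalize_positions(
    positions: Sequence[int], protein_length: int
) -> np.ndarray:
    """Scale residue indices to (0, 1], sorted ascending, duplicates collapsed.

    Distinct substitutions at the same residue are collapsed to a single
    position: the continuous order-statistic model degenerates at zero gaps.
    """
    unique = sorted(set(positions))
    if not unique:
        return np.array([], dtype=float)
    if unique[0] < 1:
        raise ValueError(f"positions must be >= 1 (1-based), got {unique[0]}")
    if unique[-1] > protein_length:
        raise ValueError(
            f"position {unique[-1]} exceeds protein length {protein_length}"
        )
    return np.asarray(unique, dtype=float) / protein_length


def nmc_pair_pvalue(i: int, j: int, n: int, gap: float) -> float:
    """P(X_(j) - X_(i) <= gap) for n uniform order statistics.

    The spacing X_(j) - X_(i) of n iid Uniform(0,1) order statistics is
    Beta(j - i, n - (j - i) + 1); the CDF at the observed gap is the
    probability of clustering at least this tight under uniformity.
    Indices are 1-based with 1 <= i < j <= n.
    """
    if not (1 <= i < j <= n):
        raise ValueError(f"require 1 <= i < j <= n, got i={i}, j={j}, n={n}")
    if not 0 <= gap <= 1:
        raise ValueError(f"gap must be in [0,1], got {gap}")
    k = j - i
    return float(stats.beta.cdf(gap, k, n - k + 1))


def nmc_scan(
    position_set: PositionSet, fdr_threshold: float = 0.05
) -> list[ClusterResult]:
    """Scan all position pairs for tighter-than-uniform clustering.

    Computes the Beta spacing p-value for every pair of distinct positions,
    adjusts across all n(n-1)/2 pairs with Benjamini-Hochberg, maps pairs
    with q <= fdr_threshold back to residue intervals, and merges
    overlapping intervals into maximal clusters.  Each cluster reports its
    minimum pair p-value and that pair's q-value.  Deterministic and
    invariant to input ordering.
    """
    x = normalize_positions(position_set.positions, position_set.protein_length)
    n = len(x)
    if n < 2:
        logger.warning(
            "NMC scan needs >= 2 distinct positions for %s/%s; got %d",
            position_set.gene,
            position_set.cohort,
            n,
        )
        return []
    residues = np.rint(x * position_set.protein_length).astype(int)

    ii, jj = np.triu_indices(n, k=1)  # 0-based order indices, i < j
    k = jj - ii
    gaps = x[jj] - x[ii]
    pvals = stats.beta.cdf(gaps, k, n - k + 1)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    sig = qvals <= fdr_threshold
    if not sig.any():
        return []
    intervals = sorted(
        zip(residues[ii[sig]], residues[jj[sig]], pvals[sig], qvals[sig]),
        key=lambda t: (t[0], t[1]),
    )
    clusters: list[ClusterResult] = []
    cur_start, cur_end, cur_p, cur_q = intervals[0]
    for start, end, p, q in intervals[1:]:
        if start <= cur_end:  # overlap: extend the maximal cluster
            cur_end = max(cur_end, end)
            if p < cur_p:
                cur_p, cur_q = p, q
        else:
            clusters.append(_make_cluster(cur_start, cur_end, cur_p, cur_q, residues))
            cur_start, cur_end, cur_p, cur_q = start, end, p, q
    clusters.append(_make_cluster(cur_start, cur_end, cur_p, cur_q, residues))
    return clusters


def _make_cluster(start, end, p, q, residues) -> ClusterResult:
    inside = int(((residues >= start) & (residues <= end)).sum())
    return ClusterResult(
        start_residue=int(start),
        end_residue=int(end),
        n_in_cluster=inside,
        p_value=float(p),
        q_value=float(q),
    )


def cluster_ef(
    case_variants: Sequence[CaseVariant],
    reference_sites: Sequence[ReferenceSite],
    cluster: ClusterResult,
    disease: str,
    gene: str,
    n_cases: int,
    plan: MultipleTestingPlan | None = None,
    n_ref_effective: float | None = None,
    config: FrequencyConfig | None = None,
) -> GeneBurdenResult:
    """Burden statistics restricted to nontruncating variants in a cluster.

    Keeps only variants with a protein position inside
    [start_residue, end_residue]; denominators (n_cases and the gene-level
    coverage-adjusted reference size) are unchanged, so the cluster result
    is directly comparable to the gene-level one.  ``n_ref_effective``
    should be the gene-level effective reference size; it anchors the
    denominator when few sites fall inside the interval.
    """
    plan = plan or MultipleTestingPlan()

    def inside(pos: int | None) -> bool:
        return pos is not None and cluster.start_residue <= pos <= cluster.end_residue

    cls_cases = [
        v
        for v in case_variants
        if v.gene == gene
        and v.variant_class is VariantClass.NONTRUNCATING
        and inside(v.protein_pos)
    ]
    if not cls_cases:
        raise ValueError(
            f"no case variants inside cluster "
            f"[{cluster.start_residue}, {cluster.end_residue}] for {gene}; "
            "cluster EF undefined"
        )
    cls_sites = [
        s
        for s in reference_sites
        if s.gene == gene
        and s.variant_class is VariantClass.NONTRUNCATING
        and inside(s.protein_pos)
    ]
    sum_ac = sum(s.ac for s in cls_sites)
    if n_ref_effective is not None:
        mean_an = 2.0 * n_ref_effective
        from varburden.frequency import GeneReferenceSummary

        summary = GeneReferenceSummary(
            gene=gene,
            variant_class=VariantClass.NONTRUNCATING,
            sum_ac=sum_ac,
            mean_an=mean_an,
        )
    else:
        gene_sites = [
            s
            for s in reference_sites
            if s.gene == gene and s.variant_class is VariantClass.NONTRUNCATING
        ]
        from varburden.frequency import gene_fallback_an

        summary = summarize_reference_gene(
            cls_sites,
            gene=gene,
            variant_class=VariantClass.NONTRUNCATING,
            fallback_an=gene_fallback_an(gene_sites),
        )
    return burden_result(
        disease,
        gene,
        f"nontruncating[{cluster.start_residue}-{cluster.end_residue}]",
        cls_cases,
        summary,
        n_cases,
        plan,
    )


def positions_from_variants(
    variants: Sequence[CaseVariant] | Sequence[ReferenceSite],
    gene: str,
    cohort: str,
    protein_length: int,
) -> PositionSet:
    """Collect distinct missense residue positions for an NMC scan."""
    positions = tuple(
        sorted(
            {
                v.protein_pos
                for v in variants
                if v.gene == gene
                and v.protein_pos is not None
                and v.variant_class is VariantClass.NONTRUNCATING
            }
        )
    )
    return PositionSet(
        gene=gene, cohort=cohort, positions=positions, protein_length=protein_length
    )
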
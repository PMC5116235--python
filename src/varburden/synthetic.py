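"""Synthetic case cohorts and reference panels with known ground truth.

The generator embodies the model assumptions behind the burden comparison:
rare benign variation occurs at the same per-individual rate in cases and in
the reference population; pathogenic variants occur only in cases, in a
gene-specific fraction of them; pathogenic missense variants cluster within
a residue interval; and per-site reference allele numbers vary with
sequencing coverage.  Every draw flows from one seeded generator, so a seed
fully determines the emitted tables, and the realized ground truth (carrier
counts, implied odds ratio and etiological fraction, cluster interval) is
returned alongside them for parameter-recovery testing.

Benign alleles are drawn from a long-tailed ("Zipf-like") allelic spectrum:
carrier draws land on a catalog of alleles with probability proportional to
rank^-s, producing a few recurrent alleles and many singletons, the
rare-but-collectively-common regime of reference populations.  The catalog
is sized so that even the most recurrent benign allele stays below the rare
MAF threshold; otherwise recurrent alleles would self-filter (symmetrically
on both sides) and shift the realized etiological fraction away from its
nominal value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from varburden.variant_io import (
    CaseVariant,
    PanelEntry,
    ReferenceSite,
)

logger = logging.getLogger(__name__)

CoverageModel = Callable[[np.random.Generator, int, int], np.ndarray]

_NONTRUNC_TERMS = ("missense_variant", "inframe_deletion", "inframe_insertion")
_TRUNC_TERMS = ("frameshift_variant", "stop_gained", "splice_donor_variant")


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Generative parameters for one gene.

    background_rate
        Probability that any one individual (case or reference alike)
        carries a rare benign variant in this gene.
    pathogenic_fraction
        Probability that a case carries a causal variant in this gene
        (zero in the reference by assumption).
    pathogenic_class_mix / benign_class_mix
        Proportions over {truncating, nontruncating} for each variant
        origin.  Defaults reflect a dominant-negative missense gene with
        mostly-missense benign background.
    cluster_interval
        Optional [start, end] residue interval confining pathogenic
        missense positions; benign positions stay uniform over the protein.
    spectrum_exponent / spectrum_size
        Shape and size of the benign allelic spectrum; size defaults to a
        multiple of the expected carrier count so top alleles stay rare.
    """

    gene: str
    protein_length: int
    background_rate: float
    pathogenic_fraction: float = 0.0
    pathogenic_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"nontruncating": 0.8, "truncating": 0.2}
    )
    benign_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"nontruncating": 0.92, "truncating": 0.08}
    )
    cluster_interval: tuple[int, int] | None = None
    spectrum_exponent: float = 0.5
    spectrum_size: int | None = None

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        if not 0 <= self.pathogenic_fraction <= 1:
            raise ValueError("pathogenic_fraction must be in [0, 1]")
        for mix in (self.pathogenic_class_mix, self.benign_class_mix):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"class mix must sum to 1, got {mix}")
        if self.cluster_interval is not None:
            a, b = self.cluster_interval
            if not 1 <= a <= b <= self.protein_length:
                raise ValueError(
                    f"cluster_interval {self.cluster_interval} outside "
                    f"[1, {self.protein_length}]"
                )


@dataclass(frozen=True)
class GeneTruth:
    """Realized and implied ground truth for one generated gene."""

    gene: str
    background_rate: float
    pathogenic_fraction: float
    true_or: float
    true_ef: float
    cluster_interval: tuple[int, int] | None
    n_pathogenic_cases: int
    n_benign_case_carriers: int
    n_benign_ref_carriers: int
    case_carrier_counts: Mapping[str, int]  # class -> sum of carrier counts


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated dataset, keyed by gene."""

    seed: int
    n_cases: int
    n_ref: int
    genes: Mapping[str, GeneTruth]


def implied_or_ef(
    pathogenic_fraction: float, background_rate: float
) -> tuple[float, float]:
    """Odds ratio and etiological fraction implied by the generative rates.

    Uses the summary-level counting convention of the pipeline: expected
    case carrier events per case are pathogenic_fraction + background_rate
    (a case can contribute one of each), and the expected reference carrier
    rate is background_rate.
    """
    p_case = pathogenic_fraction + background_rate
    p_ref = background_rate
    if p_ref <= 0 or p_case >= 1:
        raise ValueError("rates must give 0 < p_ref and p_case < 1")
    or_true = (p_case / (1 - p_case)) / (p_ref / (1 - p_ref))
    return or_true, (or_true - 1.0) / or_true


def pathogenic_fraction_for_ef(ef: float, background_rate: float) -> float:
    """Solve for the pathogenic fraction producing a target etiological fraction."""
    if not 0 <= ef < 1:
        raise ValueError("ef must be in [0, 1)")
    if ef == 0:
        return 0.0

    def f(pf: float) -> float:
        return implied_or_ef(pf, background_rate)[1] - ef

    hi = 1.0 - background_rate - 1e-9
    return float(brentq(f, 1e-12, hi))


def coverage_model_uniform(
    depth_fraction: float = 1.0, jitter: float = 0.0
) -> CoverageModel:
    """Per-site allele-number generator around a mean genotyping fraction.

    Each site's fraction of successfully genotyped alleles is drawn
    uniformly in [depth_fraction - jitter, depth_fraction + jitter]
    (truncated to (0, 1]); the allele number is 2 * n_ref * fraction,
    rounded to the nearest even integer.  With jitter 0 and fraction 1
    every site is genotyped in every sample.
    """
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must be in (0, 1]")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")

    def model(rng: np.random.Generator, n_sites: int, n_ref: int) -> np.ndarray:
        if jitter == 0:
            f = np.full(n_sites, depth_fraction)
        else:
            f = rng.uniform(
                max(1e-6, depth_fraction - jitter),
                min(1.0, depth_fraction + jitter),
                n_sites,
            )
        an = 2 * np.rint(n_ref * f).astype(int)
        return np.maximum(an, 2)

    return model


def _spectrum(spec: SyntheticGeneSpec, expected_carriers: float) -> np.ndarray:
    """Rank-frequency probabilities for the benign allele catalog."""
    if spec.spectrum_size is not None:
        size = spec.spectrum_size
    else:
        size = max(2000, int(40 * expected_carriers))
    ranks = np.arange(1, size + 1, dtype=float)
    probs = ranks ** (-spec.spectrum_exponent)
    return probs / probs.sum()


def generate(
    specs: Sequence[SyntheticGeneSpec],
    n_cases: int,
    n_ref: int,
    coverage_model: CoverageModel | None = None,
    seed: int = 0,
    disease: str = "synthetic_disease",
    rare_maf_threshold: float = 1e-4,
) -> tuple[list[CaseVariant], list[ReferenceSite], list[PanelEntry], SyntheticTruth]:
    """Generate matched case, reference, and panel tables with ground truth.

    Each case and reference individual independently carries a benign rare
    variant in each gene with probability ``background_rate``; each case
    additionally carries a private pathogenic variant with probability
    ``pathogenic_fraction``.  Benign carriers draw their allele from the
    gene's shared long-tailed catalog, so the same alleles appear on both
    sides at matched frequencies.  Reference allele numbers come from the
    coverage model.  Identical seeds give identical outputs.
    """
    if n_cases < 1 or n_ref < 1:
        raise ValueError("n_cases and n_ref must be >= 1")
    coverage_model = coverage_model or coverage_model_uniform(1.0)
    rng = np.random.default_rng(seed)

    case_rows: list[CaseVariant] = []
    ref_rows: list[ReferenceSite] = []
    panel: list[PanelEntry] = []
    truths: dict[str, GeneTruth] = {}

    for spec in specs:
        expected = (n_cases + n_ref) * spec.background_rate
        probs = _spectrum(spec, expected)
        top_maf = probs[0] * n_ref * spec.background_rate / (2 * n_ref)
        if top_maf >= rare_maf_threshold:
            logger.warning(
                "gene %s: most recurrent benign allele has expected MAF %.2e "
                ">= rare threshold %.1e; such alleles will self-filter",
                spec.gene,
                top_maf,
                rare_maf_threshold,
            )

        gene_case_rows, gene_ref_rows, truth = _generate_gene(
            spec, n_cases, n_ref, probs, coverage_model, rng, disease
        )
        case_rows.extend(gene_case_rows)
        ref_rows.extend(gene_ref_rows)
        truths[spec.gene] = truth
        panel.append(
            PanelEntry(
                disease=disease,
                gene=spec.gene,
                n_cases=n_cases,
                protein_length=spec.protein_length,
            )
        )

    truth = SyntheticTruth(seed=seed, n_cases=n_cases, n_ref=n_ref, genes=truths)
    return case_rows, ref_rows, panel, truth


def _split_classes(
    rng: np.random.Generator, n: int, mix: Mapping[str, float]
) -> dict[str, int]:
    names = sorted(mix)
    if not names or n == 0:
        return {}
    counts = rng.multinomial(n, [mix[k] for k in names])
    return dict(zip(names, (int(c) for c in counts)))


def _generate_gene(
    spec: SyntheticGeneSpec,
    n_cases: int,
    n_ref: int,
    probs: np.ndarray,
    coverage_model: CoverageModel,
    rng: np.random.Generator,
    disease: str,
):
    L = spec.protein_length
    n_benign_case = int(rng.binomial(n_cases, spec.background_rate))
    n_benign_ref = int(rng.binomial(n_ref, spec.background_rate))
    n_path = int(rng.binomial(n_cases, spec.pathogenic_fraction))

    case_by_class = _split_classes(rng, n_benign_case, spec.benign_class_mix)
    ref_by_class = _split_classes(rng, n_benign_ref, spec.benign_class_mix)
    path_by_class = _split_classes(rng, n_path, spec.pathogenic_class_mix)

    case_rows: list[CaseVariant] = []
    ref_rows: list[ReferenceSite] = []
    class_counts = {"truncating": 0, "nontruncating": 0}

    # Shared benign catalogs, one per class: allele attributes (position,
    # consequence term) are fixed per allele and identical on both sides.
    for class_name in ("nontruncating", "truncating"):
        k_case = case_by_class.get(class_name, 0)
        k_ref = ref_by_class.get(class_name, 0)
        case_counts = (
            rng.multinomial(k_case, probs) if k_case else np.zeros(len(probs), int)
        )
        ref_counts = (
            rng.multinomial(k_ref, probs) if k_ref else np.zeros(len(probs), int)
        )
        seen = np.nonzero((case_counts > 0) | (ref_counts > 0))[0]
        if len(seen) == 0:
            continue
        positions = rng.integers(1, L + 1, size=len(seen))
        terms = _NONTRUNC_TERMS if class_name == "nontruncating" else _TRUNC_TERMS
        term_idx = rng.integers(0, len(terms), size=len(seen))
        an = coverage_model(rng, len(seen), n_ref)
        for row, (allele, pos, ti) in enumerate(zip(seen, positions, term_idx)):
            vid = f"{spec.gene}:benign:{class_name}:{allele + 1}"
            term = terms[ti]
            cc = int(case_counts[allele])
            rc = int(ref_counts[allele])
            if cc:
                case_rows.append(
                    CaseVariant(
                        disease=disease,
                        gene=spec.gene,
                        variant_id=vid,
                        consequence=term,
                        carrier_count=cc,
                        protein_pos=int(pos),
                    )
                )
                class_counts[class_name] += cc
            if rc:
                ref_rows.append(
                    ReferenceSite(
                        gene=spec.gene,
                        variant_id=vid,
                        consequence=term,
                        ac=min(rc, int(an[row])),
                        an=int(an[row]),
                        protein_pos=int(pos),
                    )
                )

    # Pathogenic variants: one private causal variant per pathogenic case,
    # never present in the reference.
    path_id = 0
    for class_name, k in sorted(path_by_class.items()):
        terms = _NONTRUNC_TERMS if class_name == "nontruncating" else _TRUNC_TERMS
        for _ in range(k):
            path_id += 1
            if class_name == "nontruncating":
                term = "missense_variant"
                if spec.cluster_interval is not None:
                    a, b = spec.cluster_interval
                    pos = int(rng.integers(a, b + 1))
                else:
                    pos = int(rng.integers(1, L + 1))
            else:
                term = terms[int(rng.integers(0, len(terms)))]
                pos = int(rng.integers(1, L + 1))
            case_rows.append(
                CaseVariant(
                    disease=disease,
                    gene=spec.gene,
                    variant_id=f"{spec.gene}:pathogenic:{path_id}",
                    consequence=term,
                    carrier_count=1,
                    protein_pos=pos,
                    )
            )
            class_counts[class_name] += 1

    if spec.background_rate > 0:
        true_or, true_ef = implied_or_ef(
            spec.pathogenic_fraction, spec.background_rate
        )
    else:
        true_or, true_ef = float("inf"), 1.0
    truth = GeneTruth(
        gene=spec.gene,
        background_rate=spec.background_rate,
        pathogenic_fraction=spec.pathogenic_fraction,
        true_or=true_or,
        true_ef=true_ef,
        cluster_interval=spec.cluster_interval,
        n_pathogenic_cases=n_path,
        n_benign_case_carriers=n_benign_case,
        n_benign_ref_carriers=n_benign_ref,
        case_carrier_counts=dict(class_counts),
    )
    return case_rows, ref_rows, truth
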
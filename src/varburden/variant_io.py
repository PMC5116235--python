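"""Domain types, table readers/writers, and variant-consequence classification.

Case cohorts are summary-level: one row per distinct variant with the number
of cases carrying it.  Reference populations are site-level: one row per
variant with its allele count (AC) and the total number of alleles
successfully genotyped at that site (AN).  Consequence terms are classified
into truncating (frameshift, nonsense, essential splice site) and
nontruncating (missense, in-frame indel) classes; everything else is
excluded from burden comparisons.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class VariantClass(enum.Enum):
    """Protein-level impact class used for burden stratification."""

    TRUNCATING = "truncating"
    NONTRUNCATING = "nontruncating"
    EXCLUDED = "excluded"


class ReportedClass(enum.Enum):
    """Diagnostic-laboratory classification labels, consumed as annotations."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    UNCLASSIFIED = "unclassified"


#: Sequence Ontology terms (and common legacy spellings) that prevent
#: production of the full-length protein.
_TRUNCATING_TERMS = {
    "frameshift_variant",
    "frameshift",
    "stop_gained",
    "stop gained",
    "nonsense",
    "splice_donor_variant",
    "splice_donor",
    "splice donor",
    "splice_acceptor_variant",
    "splice_acceptor",
    "splice acceptor",
}

#: Terms that alter but do not truncate the protein.
_NONTRUNCATING_TERMS = {
    "missense_variant",
    "missense",
    "inframe_insertion",
    "in-frame insertion",
    "inframe_deletion",
    "in-frame deletion",
    "inframe_indel",
}

#: Terms recognised as valid but excluded from burden classes.
_KNOWN_EXCLUDED_TERMS = {
    "synonymous_variant",
    "synonymous",
    "intron_variant",
    "intronic",
    "splice_region_variant",
    "splice region",
    "5_prime_utr_variant",
    "3_prime_utr_variant",
    "utr",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "stop_retained_variant",
    "start_lost",
    "stop_lost",
    "non_coding_transcript_exon_variant",
}

CONSEQUENCE_VOCABULARY = frozenset(
    _TRUNCATING_TERMS | _NONTRUNCATING_TERMS | _KNOWN_EXCLUDED_TERMS
)


def classify_consequence(term: str) -> VariantClass:
    """Map a consequence term to its burden class.

    Frameshift, nonsense (stop gained) and essential splice-site terms
    (donor/acceptor, i.e. the first and last two bases of each intron) are
    TRUNCATING; missense and in-frame insertions/deletions are
    NONTRUNCATING.  Any other term — including unknown or empty strings —
    is EXCLUDED; unknown terms additionally emit a warning so they can
    never silently enter a burden class.

    An intronic term with an explicit offset such as ``intron_variant+2``
    or ``c.IVS-1`` style ``intronic-1`` is treated as essential splice if
    the offset magnitude is 1 or 2, otherwise excluded.
    """
    if not term or not term.strip():
        logger.warning("empty consequence term classified as EXCLUDED")
        return VariantClass.EXCLUDED
    key = term.strip().lower()
    if key in _TRUNCATING_TERMS:
        return VariantClass.TRUNCATING
    if key in _NONTRUNCATING_TERMS:
        return VariantClass.NONTRUNCATING
    offset = _intronic_offset(key)
    if offset is not None:
        return (
            VariantClass.TRUNCATING if abs(offset) <= 2 else VariantClass.EXCLUDED
        )
    if key not in _KNOWN_EXCLUDED_TERMS:
        logger.warning("unknown consequence term %r classified as EXCLUDED", term)
    return VariantClass.EXCLUDED


def _intronic_offset(key: str) -> int | None:
    """Extract the intron offset from terms like ``intron_variant-2``."""
    for stem in ("intron_variant", "intronic", "splice_region_variant"):
        if key.startswith(stem) and len(key) > len(stem):
            tail = key[len(stem):]
            if tail[0] in "+-":
                try:
                    return int(tail)
                except ValueError:
                    return None
    return None


@dataclass(frozen=True)
class CaseVariant:
    """A distinct variant observed in a disease cohort, with carrier count."""

    disease: str
    gene: str
    variant_id: str
    consequence: str
    carrier_count: int
    protein_pos: int | None = None
    reported_class: ReportedClass = ReportedClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.carrier_count < 1:
            raise ValueError(
                f"carrier_count must be >= 1, got {self.carrier_count} "
                f"for {self.variant_id}"
            )
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError(
                f"protein_pos must be >= 1 (1-based), got {self.protein_pos}"
            )

    @property
    def variant_class(self) -> VariantClass:
        return classify_consequence(self.consequence)


@dataclass(frozen=True)
class ReferenceSite:
    """A reference-population site summary: allele count over total alleles."""

    gene: str
    variant_id: str
    consequence: str
    ac: int
    an: int
    protein_pos: int | None = None

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError(f"an must be > 0, got {self.an} at {self.variant_id}")
        if not 0 <= self.ac <= self.an:
            raise ValueError(
                f"require 0 <= ac <= an, got ac={self.ac}, an={self.an} "
                f"at {self.variant_id}"
            )
        if self.an % 2 != 0:
            logger.warning(
                "odd AN %d at %s (expected even for diploid samples)",
                self.an,
                self.variant_id,
            )

    @property
    def maf(self) -> float:
        return self.ac / self.an

    @property
    def variant_class(self) -> VariantClass:
        return classify_consequence(self.consequence)


@dataclass(frozen=True)
class PanelEntry:
    """A disease-gene pairing: cases sequenced and canonical protein length."""

    disease: str
    gene: str
    n_cases: int
    protein_length: int
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError(f"n_cases must be > 0 for {self.gene}")
        if self.protein_length <= 0:
            raise ValueError(f"protein_length must be > 0 for {self.gene}")


_CASE_REQUIRED = ["disease", "gene", "variant_id", "consequence", "carrier_count"]
_REF_REQUIRED = ["gene", "variant_id", "consequence", "ac", "an"]
_PANEL_REQUIRED = ["disease", "gene", "n_cases", "protein_length"]


def _read_tsv(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{label} table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    return df


def _to_int(value: str, column: str, path: str | Path, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"{path}, data row {line}: column {column!r} must be an integer, "
            f"got {value!r}"
        ) from exc


def _opt_pos(value, path, line) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return _to_int(value, "protein_pos", path, line)


def read_case_table(path: str | Path) -> list[CaseVariant]:
    """Read a case-cohort variant summary TSV.

    Required columns: disease, gene, variant_id, consequence, carrier_count.
    Optional: protein_pos, reported_class.  ``#``-prefixed comment lines are
    skipped.  Malformed rows raise with their data-row number.
    """
    df = _read_tsv(path, _CASE_REQUIRED, "case")
    records: list[CaseVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rc = getattr(row, "reported_class", None)
        if rc is None or (isinstance(rc, float) and pd.isna(rc)) or rc == "":
            reported = ReportedClass.UNCLASSIFIED
        else:
            try:
                reported = ReportedClass(rc)
            except ValueError as exc:
                raise ValueError(
                    f"{path}, data row {i}: invalid reported_class {rc!r}"
                ) from exc
        try:
            records.append(
                CaseVariant(
                    disease=row.disease,
                    gene=row.gene,
                    variant_id=row.variant_id,
                    consequence=row.consequence,
                    carrier_count=_to_int(row.carrier_count, "carrier_count", path, i),
                    protein_pos=_opt_pos(getattr(row, "protein_pos", None), path, i),
                    reported_class=reported,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, data row {i}: {exc}") from exc
    return records


def write_case_table(variants: Iterable[CaseVariant], path: str | Path) -> None:
    """Write case variants back out in the dialect :func:`read_case_table` reads."""
    rows = [
        {
            "disease": v.disease,
            "gene": v.gene,
            "variant_id": v.variant_id,
            "consequence": v.consequence,
            "carrier_count": v.carrier_count,
            "protein_pos": "" if v.protein_pos is None else v.protein_pos,
            "reported_class": v.reported_class.value,
        }
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=[
            "disease",
            "gene",
            "variant_id",
            "consequence",
            "carrier_count",
            "protein_pos",
            "reported_class",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_reference_table(
    path: str | Path, format: str = "tsv"
) -> list[ReferenceSite]:
    """Read reference-population site summaries.

    ``format="tsv"`` expects columns gene, variant_id, consequence, ac, an
    (optional protein_pos).  ``format="vcf_sites"`` expects a sites-only VCF
    with per-alt INFO ``AC`` and site-level ``AN``; gene, consequence and
    protein position are taken from INFO fields ``GENE``, ``CSQ`` and
    ``AAPOS`` when present.  Multiallelic records are decomposed into one
    site per alternate allele; only PASS-filter records are retained.
    """
    if format == "tsv":
        df = _read_tsv(path, _REF_REQUIRED, "reference")
        sites = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                sites.append(
                    ReferenceSite(
                        gene=row.gene,
                        variant_id=row.variant_id,
                        consequence=row.consequence,
                        ac=_to_int(row.ac, "ac", path, i),
                        an=_to_int(row.an, "an", path, i),
                        protein_pos=_opt_pos(getattr(row, "protein_pos", None), path, i),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}, data row {i}: {exc}") from exc
        return sites
    if format == "vcf_sites":
        return _read_sites_vcf(path)
    raise ValueError(f"unknown reference format {format!r}")


def write_reference_table(sites: Iterable[ReferenceSite], path: str | Path) -> None:
    rows = [
        {
            "gene": s.gene,
            "variant_id": s.variant_id,
            "consequence": s.consequence,
            "ac": s.ac,
            "an": s.an,
            "protein_pos": "" if s.protein_pos is None else s.protein_pos,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows, columns=["gene", "variant_id", "consequence", "ac", "an", "protein_pos"]
    ).to_csv(path, sep="\t", index=False)


def _read_sites_vcf(path: str | Path) -> list[ReferenceSite]:
    from cyvcf2 import VCF

    sites: list[ReferenceSite] = []
    for record in VCF(str(path)):
        if record.FILTER is not None:  # cyvcf2: None means PASS/'.'
            logger.info(
                "dropping non-PASS site %s:%d (%s)",
                record.CHROM,
                record.POS,
                record.FILTER,
            )
            continue
        an = record.INFO.get("AN")
        if an is None:
            raise ValueError(
                f"VCF record {record.CHROM}:{record.POS} lacks required INFO AN"
            )
        ac = record.INFO.get("AC")
        if ac is None:
            raise ValueError(
                f"VCF record {record.CHROM}:{record.POS} lacks required INFO AC"
            )
        acs = ac if isinstance(ac, tuple) else (ac,)
        gene = record.INFO.get("GENE") or ""
        csq = record.INFO.get("CSQ") or ""
        aapos = record.INFO.get("AAPOS")
        genes = _per_alt(gene, len(record.ALT))
        csqs = _per_alt(csq, len(record.ALT))
        for alt, ac_i, gene_i, csq_i in zip(record.ALT, acs, genes, csqs):
            sites.append(
                ReferenceSite(
                    gene=gene_i,
                    variant_id=f"{record.CHROM}:{record.POS}:{record.REF}:{alt}",
                    consequence=csq_i,
                    ac=int(ac_i),
                    an=int(an),
                    protein_pos=int(aapos) if aapos is not None else None,
                )
            )
    return sites


def _per_alt(value: str, n_alt: int) -> list[str]:
    """Expand a comma-delimited per-alt INFO string; broadcast a scalar."""
    parts = str(value).split(",")
    if len(parts) == n_alt:
        return parts
    return [str(value)] * n_alt


def read_panel_table(path: str | Path) -> list[PanelEntry]:
    """Read a panel definition TSV (disease, gene, n_cases, protein_length)."""
    df = _read_tsv(path, _PANEL_REQUIRED, "panel")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        tid = getattr(row, "transcript_id", None)
        if tid is not None and isinstance(tid, float) and pd.isna(tid):
            tid = None
        try:
            entries.append(
                PanelEntry(
                    disease=row.disease,
                    gene=row.gene,
                    n_cases=_to_int(row.n_cases, "n_cases", path, i),
                    protein_length=_to_int(
                        row.protein_length, "protein_length", path, i
                    ),
                    transcript_id=tid,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, data row {i}: {exc}") from exc
    return entries


def write_panel_table(entries: Iterable[PanelEntry], path: str | Path) -> None:
    rows = [
        {
            "disease": e.disease,
            "gene": e.gene,
            "n_cases": e.n_cases,
            "protein_length": e.protein_length,
            "transcript_id": e.transcript_id or "",
        }
        for e in entries
    ]
    pd.DataFrame(
        rows,
        columns=["disease", "gene", "n_cases", "protein_length", "transcript_id"],
    ).to_csv(path, sep="\t", index=False)
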
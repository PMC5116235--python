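"""End-to-end orchestration: read inputs, filter, test, and write reports.

A run reads the case, reference, and panel tables, applies the rarity
filter, computes per-gene burden statistics per disease, and optionally the
missense cluster scan and the reported-variant audit.  Outputs are a burden
TSV with a JSON mirror keyed by disease/gene/class (the "atlas" export),
cluster and audit TSVs when requested, and a manifest recording the
configuration, input checksums and package version so a run can be replayed
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from varburden import __version__
from varburden.audit import audit_summary, read_reported_table
from varburden.burden import (
    GeneBurdenResult,
    MultipleTestingPlan,
    results_to_frame,
    run_burden,
)
from varburden.clustering import cluster_ef, nmc_scan, positions_from_variants
from varburden.frequency import FrequencyConfig, filter_rare, summarize_reference_gene
from varburden.variant_io import (
    read_case_table,
    read_panel_table,
    read_reference_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    case_path: str
    reference_path: str
    panel_path: str
    out_dir: str
    reference_format: str = "tsv"
    frequency: FrequencyConfig = dataclasses.field(default_factory=FrequencyConfig)
    alpha: float = 0.05
    reported_path: str | None = None
    cluster_genes: tuple[str, ...] = ()
    fdr_threshold: float = 0.05
    seed: int | None = None

    def input_paths(self) -> list[str]:
        paths = [self.case_path, self.reference_path, self.panel_path]
        if self.reported_path:
            paths.append(self.reported_path)
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_BURDEN_COLUMNS = [
    "disease",
    "gene",
    "variant_class",
    "n_cases",
    "n_ref_effective",
    "case_carriers",
    "ref_carriers",
    "case_freq",
    "ref_freq",
    "case_excess",
    "case_excess_pct",
    "fisher_p",
    "significant",
    "or_point",
    "or_lo",
    "or_hi",
    "ef_point",
    "ef_pct",
    "ef_lo",
    "ef_hi",
    "predicted_pathogenic",
    "used_fallback_an",
]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis and write its outputs.

    Returns a mapping from output kind to written path.  Any stage failure
    raises with a stage-named message, and partially written outputs are
    removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    try:
        return _run(config, out_dir, written)
    except Exception:
        for path in written.values():
            Path(path).unlink(missing_ok=True)
        raise


def _stage(name: str):
    def wrap(exc: Exception) -> Exception:
        return RuntimeError(f"pipeline stage {name!r} failed: {exc}")

    return wrap


def _run(config: RunConfig, out_dir: Path, written: dict[str, str]) -> dict[str, str]:
    try:
        cases = read_case_table(config.case_path)
        reference = read_reference_table(
            config.reference_path, format=config.reference_format
        )
        panel = read_panel_table(config.panel_path)
    except Exception as exc:
        raise _stage("variant_io")(exc) from exc

    try:
        kept_cases, kept_sites = filter_rare(cases, reference, config.frequency)
    except Exception as exc:
        raise _stage("frequency")(exc) from exc

    diseases = sorted({e.disease for e in panel})
    results: list[GeneBurdenResult] = []
    try:
        for disease in diseases:
            m = sum(1 for e in panel if e.disease == disease)
            plan = MultipleTestingPlan(alpha=config.alpha, m=m)
            results.extend(
                run_burden(
                    disease,
                    kept_cases,
                    kept_sites,
                    panel,
                    config.frequency,
                    plan,
                    all_reference_sites=reference,
                )
            )
    except Exception as exc:
        raise _stage("burden")(exc) from exc

    df = results_to_frame(results)[_BURDEN_COLUMNS]
    burden_tsv = out_dir / "burden.tsv"
    df.to_csv(burden_tsv, sep="\t", index=False, float_format="%.10g")
    written["burden_tsv"] = str(burden_tsv)

    atlas = {}
    for r in results:
        atlas.setdefault(r.disease, {}).setdefault(r.gene, {})[r.variant_class] = {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in r.__dict__.items()
        }
    burden_json = out_dir / "burden.json"
    burden_json.write_text(json.dumps(atlas, indent=2, sort_keys=True))
    written["burden_json"] = str(burden_json)

    if config.cluster_genes:
        try:
            cluster_rows = _run_clusters(config, kept_cases, kept_sites, panel)
        except Exception as exc:
            raise _stage("clustering")(exc) from exc
        cluster_tsv = out_dir / "clusters.tsv"
        pd.DataFrame(
            cluster_rows,
            columns=[
                "disease",
                "gene",
                "cohort",
                "start_residue",
                "end_residue",
                "n_in_cluster",
                "p_value",
                "q_value",
                "cluster_ef",
            ],
        ).to_csv(cluster_tsv, sep="\t", index=False, float_format="%.6g")
        written["cluster_tsv"] = str(cluster_tsv)

    if config.reported_path:
        try:
            reported = read_reported_table(config.reported_path)
            n_ref_eff = _dataset_n_ref_effective(reference)
            summaries = audit_summary(
                reported, reference, n_ref_eff, config.frequency
            )
        except Exception as exc:
            raise _stage("audit")(exc) from exc
        audit_tsv = out_dir / "audit.tsv"
        pd.DataFrame([s.__dict__ for s in summaries.values()]).to_csv(
            audit_tsv, sep="\t", index=False, float_format="%.6g"
        )
        written["audit_tsv"] = str(audit_tsv)

    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "inputs": {p: _sha256(p) for p in config.input_paths()},
        "outputs": {k: _sha256(v) for k, v in written.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = str(manifest_path)
    return written


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cluster_genes"] = list(config.cluster_genes)
    return d


def _dataset_n_ref_effective(reference) -> float:
    if not reference:
        return 0.0
    return sum(s.an for s in reference) / len(reference) / 2.0


def _run_clusters(config: RunConfig, kept_cases, kept_sites, panel) -> list[dict]:
    rows: list[dict] = []
    lengths = {(e.disease, e.gene): e for e in panel}
    for (disease, gene), entry in sorted(lengths.items()):
        if gene not in config.cluster_genes:
            continue
        pos = positions_from_variants(
            [v for v in kept_cases if v.disease == disease],
            gene,
            disease,
            entry.protein_length,
        )
        gene_sites = [s for s in kept_sites if s.gene == gene]
        gene_summary = None
        nontrunc_sites = [
            s for s in gene_sites if s.variant_class.value == "nontruncating"
        ]
        if nontrunc_sites:
            gene_summary = summarize_reference_gene(nontrunc_sites, gene=gene)
        for cluster in nmc_scan(pos, config.fdr_threshold):
            try:
                ef = cluster_ef(
                    kept_cases,
                    kept_sites,
                    cluster,
                    disease,
                    gene,
                    entry.n_cases,
                    n_ref_effective=(
                        gene_summary.n_ref_effective if gene_summary else None
                    ),
                ).ef_point
            except ValueError:
                ef = float("nan")
            rows.append(
                {
                    "disease": disease,
                    "gene": gene,
                    "cohort": disease,
                    "start_residue": cluster.start_residue,
                    "end_residue": cluster.end_residue,
                    "n_in_cluster": cluster.n_in_cluster,
                    "p_value": cluster.p_value,
                    "q_value": cluster.q_value,
                    "cluster_ef": ef,
                }
            )
    return rows
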
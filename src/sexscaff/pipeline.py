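"""Pipeline driver: configuration, run manifest and stage orchestration.

The discovery strategy runs in two steps: first classify scaffolds from
male/female coverage ratios, then scan the Y candidates for windows of
sequence unique within the assembly, from which male-specific PCR targets
are selected.  The qPCR validation arm is independent and runs whenever
qPCR inputs are configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import yaml

from . import __version__
from .coverage import (
    DEFAULT_PSEUDOCOUNT,
    compute_raw_coverage,
    log2_fold_table,
    normalize_profile,
)
from .io import (
    read_coverage_table,
    read_fasta,
    read_qpcr_table,
    write_bed,
    write_calls_tsv,
    write_qpcr_report,
    write_ratio_tsv,
    write_summary_tsv,
)
from .qpcr import group_compare, relative_quantity
from .sexlink import (
    Call,
    ClassifierParams,
    classify_scaffolds,
    summarize_candidates,
)
from .uniqueness import (
    MatchEngineParams,
    enumerate_windows,
    flag_unique_windows,
    merge_unique_regions,
    select_assay_regions,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("sexscaff")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from one YAML file."""

    coverage_table: str | None = None
    sample_metadata: str | None = None
    coverage_dialect: str = "counts"
    fasta: str | None = None
    qpcr_table: str | None = None
    out_dir: str = "sexscaff_out"
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    match_engine: MatchEngineParams = field(default_factory=MatchEngineParams)
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    normalize_to_min_length: bool = False  # restrict the mean to >=10kb scaffolds
    min_assay_region_bp: int = 1_000
    max_regions_per_scaffold: int = 3
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        classifier = ClassifierParams(**raw.pop("classifier", {}))
        engine = MatchEngineParams(**raw.pop("match_engine", {}))
        return cls(classifier=classifier, match_engine=engine, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    timestamp: str

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages and write all outputs + a manifest.

    Order: coverage -> ratios -> classification -> uniqueness scan on Y
    candidates -> assay regions; the qPCR arm runs independently at the
    end.  Missing-but-required inputs are reported before any work starts.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    if config.coverage_table is None:
        raise ValueError("config.coverage_table is required")
    if config.sample_metadata is None and config.coverage_dialect == "counts":
        raise ValueError("sample_metadata required for the counts dialect")
    inputs = {
        k: p
        for k, p in (
            ("coverage_table", config.coverage_table),
            ("sample_metadata", config.sample_metadata),
            ("fasta", config.fasta),
            ("qpcr_table", config.qpcr_table),
        )
        if p is not None
    }
    missing = {k: p for k, p in inputs.items() if not os.path.exists(p)}
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")

    os.makedirs(config.out_dir, exist_ok=True)
    counts: dict[str, int] = {}

    # --- coverage ---
    try:
        table = read_coverage_table(
            config.coverage_table,
            config.sample_metadata or {},
            dialect=config.coverage_dialect,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("coverage", exc) from exc
    counts["scaffolds"] = len(table.scaffold_ids)
    counts["samples"] = len(table.sample_ids)
    logger.info("coverage: %d scaffolds, %d samples",
                counts["scaffolds"], counts["samples"])

    males = table.samples_by_sex("M")
    females = table.samples_by_sex("F")
    if not males or not females:
        raise StageError(
            "ratios", ValueError("need at least one male and one female sample")
        )
    norm_set = None
    if config.normalize_to_min_length:
        keep = table.lengths[
            table.lengths >= config.classifier.min_length_bp
        ].index.tolist()
        norm_set = keep
    profiles = {
        s: normalize_profile(compute_raw_coverage(table, s), scaffold_set=norm_set)
        for s in table.sample_ids
    }

    # --- ratios ---
    try:
        male = males[0]
        mf_tables = [
            log2_fold_table(profiles[male], profiles[f], config.pseudocount)
            for f in females
        ]
        ratio_tables = list(mf_tables)
        if len(females) >= 2:  # female/female negative control, never classified on
            ratio_tables.append(
                log2_fold_table(
                    profiles[females[0]], profiles[females[1]], config.pseudocount
                )
            )
        write_ratio_tsv(
            ratio_tables, table.lengths, os.path.join(config.out_dir, "ratios.tsv")
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("ratios", exc) from exc
    counts["ratio_pairs"] = len(ratio_tables)

    # --- classification (male vs first female) ---
    try:
        calls = classify_scaffolds(
            mf_tables[0],
            table.lengths,
            config.classifier,
            male_normcov=profiles[male].normalized,
        )
        summary = summarize_candidates(calls)
        write_calls_tsv(calls, os.path.join(config.out_dir, "calls.tsv"))
        write_summary_tsv(summary, os.path.join(config.out_dir, "summary.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc
    counts["x_candidates"] = summary.n_x
    counts["y_candidates"] = summary.n_y
    logger.info(
        "classify: %d X-candidate scaffolds totalling %.0f kb; "
        "%d Y-candidate scaffolds totalling %.0f kb",
        summary.n_x, summary.total_x_bp / 1000,
        summary.n_y, summary.total_y_bp / 1000,
    )

    # --- uniqueness scan on Y candidates ---
    if config.fasta is not None:
        try:
            genome = read_fasta(config.fasta)
            y_ids = [c.scaffold_id for c in calls if c.call is Call.Y_CANDIDATE]
            lengths = {sid: len(genome[sid]) for sid in y_ids if sid in genome}
            windows = enumerate_windows(
                lengths,
                config.match_engine.window_size_bp,
                config.match_engine.offset_bp,
            )
            flag_unique_windows(windows, genome, config.match_engine)
            regions = merge_unique_regions(windows)
            write_bed(regions, os.path.join(config.out_dir, "unique_regions.bed"))
            assay = select_assay_regions(
                regions,
                config.min_assay_region_bp,
                config.max_regions_per_scaffold,
            )
            write_bed(assay, os.path.join(config.out_dir, "assay_regions.bed"))
        except Exception as exc:  # noqa: BLE001
            raise StageError("uniqueness", exc) from exc
        counts["windows_scanned"] = len(windows)
        counts["unique_regions"] = len(regions)
        counts["assay_regions"] = len(assay)
        counts["y_scaffolds_with_unique_region"] = len(
            {r.scaffold_id for r in regions}
        )
        logger.info(
            "uniqueness: %d of %d Y candidates contain unique regions",
            counts["y_scaffolds_with_unique_region"], len(y_ids),
        )

    # --- qPCR arm (independent) ---
    if config.qpcr_table is not None:
        try:
            assays = read_qpcr_table(config.qpcr_table)
            results = {}
            by_target: dict[str, list] = {}
            for a in assays:
                by_target.setdefault(a.target_scaffold_id, []).append(a)
            for target, group in by_target.items():
                quantities = {a.sample_id: relative_quantity(a) for a in group}
                sexes = {a.sample_id: a.sex for a in group}
                results[target] = group_compare(quantities, sexes)
            write_qpcr_report(
                results, os.path.join(config.out_dir, "qpcr_report.tsv")
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("qpcr", exc) from exc
        counts["qpcr_assays"] = len(assays)
        counts["qpcr_targets"] = len(results)

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        input_checksums={k: _checksum(p) for k, p in inputs.items()},
        stage_counts=counts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(os.path.join(config.out_dir, "manifest.json"))
    return manifest
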
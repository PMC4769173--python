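"""Text formats: coverage/ratio/call TSVs, FASTA, BED, qPCR tables.

Everything is plain TSV/CSV/FASTA/BED with documented headers so that runs
are reproducible and diffable.  Coordinates in BED files are 0-based
half-open, as the format requires.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTable, RatioTable, SampleInfo
from .qpcr import CalibrationSeries, QpcrAssay
from .sexlink import CandidateSummary, LinkageCall
from .uniqueness import UniqueRegion

__all__ = [
    "read_coverage_table",
    "read_sample_metadata",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_ratio_tsv",
    "write_calls_tsv",
    "write_summary_tsv",
    "read_qpcr_table",
    "read_calibration_tsv",
    "read_curves_csv",
    "write_qpcr_report",
    "write_qpcr_table",
    "write_coverage_table",
]


def read_sample_metadata(path: str) -> dict[str, SampleInfo]:
    """Sample metadata TSV: sample_id, sex (M/F/U), read_length_bp."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    samples = {}
    for _, row in df.iterrows():
        read_len = None
        if "read_length_bp" in df.columns and pd.notna(row["read_length_bp"]):
            read_len = int(row["read_length_bp"])
        samples[row["sample_id"]] = SampleInfo(
            sample_id=row["sample_id"], sex=row["sex"], read_length_bp=read_len
        )
    return samples


def read_coverage_table(
    path: str,
    samples: dict[str, SampleInfo] | str,
    dialect: str = "counts",
) -> CoverageTable:
    """Read the per-scaffold coverage TSV.

    Header: ``scaffold_id``, ``length_bp``, then one column per sample.
    ``dialect`` is "counts" (mapped read counts; read lengths taken from the
    sample metadata) or "coverage" (precomputed fold-coverage values).
    ``samples`` is the metadata dict or a path to the metadata TSV.
    """
    if dialect not in ("counts", "coverage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(samples, str):
        samples = read_sample_metadata(samples)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"scaffold_id", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    if df["scaffold_id"].duplicated().any():
        dups = df.loc[df["scaffold_id"].duplicated(), "scaffold_id"].tolist()
        raise ValueError(f"{path}: duplicate scaffold ids: {dups}")
    for col in ["length_bp", *sample_cols]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = (df.index[bad | df[col].isna()] + 2).tolist()  # 1-based + header
            raise ValueError(f"{path}: non-numeric cells in {col!r}, rows {rows}")
    df = df.set_index("scaffold_id")
    return CoverageTable(
        lengths=df["length_bp"].astype(float),
        values=df[sample_cols].astype(float),
        samples=samples,
        precomputed=(dialect == "coverage"),
    )


def read_fasta(path: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped or not) as an id -> sequence dict."""
    records = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(regions: list[UniqueRegion], path: str) -> None:
    """BED6: scaffold, start, end, region id, score = region length, '.'."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"region_{i:04d}"
            fh.write(
                f"{r.scaffold_id}\t{r.start}\t{r.end}\t{name}\t{r.length}\t.\n"
            )


def read_bed(path: str) -> list[UniqueRegion]:
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED columns")
            regions.append(
                UniqueRegion(
                    scaffold_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    n_windows_merged=0,
                )
            )
    return regions


def write_ratio_tsv(
    ratios: list[RatioTable], lengths: pd.Series, path: str
) -> None:
    """One column per sample pair, log2 values at 4 decimals, inf as 'inf'."""
    out = pd.DataFrame({"scaffold_id": lengths.index, "length_bp": lengths.values})
    out["length_bp"] = out["length_bp"].astype(int)
    out = out.set_index("scaffold_id")
    for rt in ratios:
        col = f"log2_{rt.numerator_sample}_over_{rt.denominator_sample}"
        out[col] = rt.log2_fold.reindex(out.index).map(
            lambda v: "inf" if np.isposinf(v) else ("-inf" if np.isneginf(v) else f"{v:.4f}")
        )
    out.to_csv(path, sep="\t")


def write_calls_tsv(calls: list[LinkageCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tlength_bp\tlog2_mf\tfold_mf\tcall\n")
        for c in calls:
            fold = 2.0**c.log2_mf
            fh.write(
                f"{c.scaffold_id}\t{c.length_bp}\t{c.log2_mf:.4f}"
                f"\t{fold:.4f}\t{c.call.value}\n"
            )


def write_summary_tsv(summary: CandidateSummary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("class\tn_scaffolds\ttotal_bp\ttotal_kb\n")
        fh.write(f"X_CANDIDATE\t{summary.n_x}\t{summary.total_x_bp}"
                 f"\t{summary.total_x_bp / 1000:.0f}\n")
        fh.write(f"Y_CANDIDATE\t{summary.n_y}\t{summary.total_y_bp}"
                 f"\t{summary.total_y_bp / 1000:.0f}\n")


def read_qpcr_table(path: str) -> list[QpcrAssay]:
    """qPCR TSV: sample_id, sex, target, reference, ct_t1..3, ct_r1..3,
    optional efficiency_target, efficiency_reference, single_product."""
    df = pd.read_csv(path, sep="\t")
    required = {
        "sample_id", "sex", "target", "reference",
        "ct_t1", "ct_t2", "ct_t3", "ct_r1", "ct_r2", "ct_r3",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    assays = []
    for _, row in df.iterrows():
        assays.append(
            QpcrAssay(
                sample_id=str(row["sample_id"]),
                sex=str(row["sex"]),
                target_scaffold_id=str(row["target"]),
                reference_scaffold_id=str(row["reference"]),
                ct_replicates_target=(
                    float(row["ct_t1"]), float(row["ct_t2"]), float(row["ct_t3"])
                ),
                ct_replicates_reference=(
                    float(row["ct_r1"]), float(row["ct_r2"]), float(row["ct_r3"])
                ),
                efficiency_target=float(row.get("efficiency_target", 2.0) or 2.0),
                efficiency_reference=float(
                    row.get("efficiency_reference", 2.0) or 2.0
                ),
                single_product=bool(row.get("single_product", True)),
            )
        )
    return assays


def write_qpcr_table(assays: list[QpcrAssay], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tsex\ttarget\treference\t"
            "ct_t1\tct_t2\tct_t3\tct_r1\tct_r2\tct_r3\t"
            "efficiency_target\tefficiency_reference\n"
        )
        for a in assays:
            t = "\t".join(f"{v:.4f}" for v in a.ct_replicates_target[:3])
            r = "\t".join(f"{v:.4f}" for v in a.ct_replicates_reference[:3])
            fh.write(
                f"{a.sample_id}\t{a.sex}\t{a.target_scaffold_id}\t"
                f"{a.reference_scaffold_id}\t{t}\t{r}\t"
                f"{a.efficiency_target:.4f}\t{a.efficiency_reference:.4f}\n"
            )


def read_calibration_tsv(path: str) -> dict[str, CalibrationSeries]:
    """Calibration TSV: primer_pair, input_ng, ct -> series per primer pair."""
    df = pd.read_csv(path, sep="\t")
    missing = {"primer_pair", "input_ng", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    series = {}
    for pair, grp in df.groupby("primer_pair", sort=False):
        grp = grp.sort_values("input_ng", ascending=False)
        series[pair] = CalibrationSeries(
            input_amount=grp["input_ng"].to_numpy(float),
            ct=grp["ct"].to_numpy(float),
        )
    return series


def read_curves_csv(path: str):
    """Curves CSV: sample_id, well, cycle, fluorescence -> grouped frames."""
    df = pd.read_csv(path)
    missing = {"sample_id", "well", "cycle", "fluorescence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    return {
        key: grp.sort_values("cycle")
        for key, grp in df.groupby(["sample_id", "well"], sort=False)
    }


def write_qpcr_report(results: dict[str, "object"], path: str) -> None:
    """Per-target group comparison report with significance stars."""
    with open(path, "w") as fh:
        fh.write(
            "target\tn_m\tn_f\tmean_m\tmean_f\tsem_m\tsem_f\t"
            "fm_ratio\tt\tp\tsignificance\n"
        )
        for target, res in results.items():
            fh.write(
                f"{target}\t{res.n_m}\t{res.n_f}\t{res.mean_m:.6g}\t"
                f"{res.mean_f:.6g}\t{res.sem_m:.3g}\t{res.sem_f:.3g}\t"
                f"{res.fm_ratio:.4f}\t{res.t_statistic:.3f}\t"
                f"{res.p_value:.3g}\t{res.stars}\n"
            )


def write_coverage_table(table: CoverageTable, dir_path: str,
                         prefix: str = "coverage", seed: int | None = None) -> tuple[str, str]:
    """Write a coverage TSV + sample metadata TSV pair; returns their paths."""
    os.makedirs(dir_path, exist_ok=True)
    cov_path = os.path.join(dir_path, f"{prefix}.tsv")
    meta_path = os.path.join(dir_path, f"{prefix}_samples.tsv")
    with open(cov_path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("scaffold_id\tlength_bp\t" + "\t".join(table.sample_ids) + "\n")
        for sid in table.scaffold_ids:
            vals = "\t".join(
                f"{table.values.at[sid, s]:.0f}" for s in table.sample_ids
            )
            fh.write(f"{sid}\t{int(table.lengths.at[sid])}\t{vals}\n")
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tsex\tread_length_bp\n")
        for s in table.sample_ids:
            info = table.samples[s]
            fh.write(f"{s}\t{info.sex}\t{info.read_length_bp or ''}\n")
    return cov_path, meta_path
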
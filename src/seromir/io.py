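"""Plain-text readers and writers for scans, metadata, and matrices.

Array scans use a four-column TSV dialect (``probe_id``, ``probe_class``,
``signal``, ``flagged`` with flagged in {0,1}), one file per array.
Metadata is a TSV with columns sample_id, group, age, sex, cohort.  The
normalized cohort matrix is a TSV with probes as rows (first column
``probe_id``) and samples as columns, values written with 6 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ArrayScan, CohortMatrix, SampleMeta, PreprocessError
from .synthetic import GeneratedStudy

__all__ = [
    "write_scan_tsv",
    "read_scan_tsv",
    "write_metadata_tsv",
    "read_metadata_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_study",
]

SCAN_HEADER = ["probe_id", "probe_class", "signal", "flagged"]
META_HEADER = ["sample_id", "group", "age", "sex", "cohort"]


def write_scan_tsv(scan: ArrayScan, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SCAN_HEADER) + "\n")
        for pid, cls_, sig, flg in zip(
            scan.probe_ids, scan.probe_classes, scan.signals, scan.flagged
        ):
            fh.write(f"{pid}\t{cls_}\t{float(sig)!r}\t{int(flg)}\n")


def read_scan_tsv(path, sample_id: str | None = None) -> ArrayScan:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probe_class": str},
                     float_precision="round_trip")
    missing = set(SCAN_HEADER) - set(df.columns)
    if missing:
        raise PreprocessError(f"{path}: missing columns {sorted(missing)}")
    return ArrayScan(
        sample_id=sample_id if sample_id is not None else path.stem,
        probe_ids=list(df["probe_id"]),
        probe_classes=df["probe_class"].to_numpy(dtype=object),
        signals=df["signal"].to_numpy(dtype=float),
        flagged=df["flagged"].to_numpy(dtype=int).astype(bool),
    )


def write_metadata_tsv(metadata: list[SampleMeta], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(META_HEADER) + "\n")
        for m in metadata:
            fh.write(f"{m.sample_id}\t{m.group}\t{m.age!r}\t{m.sex}\t{m.cohort}\n")


def read_metadata_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    missing = set(META_HEADER) - set(df.columns)
    if missing:
        raise PreprocessError(f"{path}: missing columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id), group=str(r.group), age=float(r.age),
            sex=str(r.sex), cohort=str(r.cohort),
        )
        for r in df.itertuples()
    ]


def write_matrix_tsv(cm: CohortMatrix, path) -> None:
    out = cm.matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_matrix_tsv(path, metadata: list[SampleMeta]) -> CohortMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    by_id = {m.sample_id: m for m in metadata}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise PreprocessError(f"{path}: samples missing from metadata: {missing}")
    samples = [by_id[c] for c in df.columns]
    return CohortMatrix(matrix=df, samples=samples)


def write_study(study: GeneratedStudy, out_dir) -> None:
    """Write a generated study: one scan TSV per array, metadata TSV, truth JSON."""
    out = Path(out_dir)
    scans_dir = out / "scans"
    scans_dir.mkdir(parents=True, exist_ok=True)
    for scan in study.scans:
        write_scan_tsv(scan, scans_dir / f"{scan.sample_id}.tsv")
    write_metadata_tsv(study.metadata, out / "metadata.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=2)
        fh.write("\n")
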
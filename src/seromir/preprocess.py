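"""Per-array signal processing for serum miRNA expression arrays.

A scanned array yields linear fluorescence intensities for three probe
classes: *target* probes (one per miRNA), *negative-control* probes (no
target; they measure non-specific background), and three *internal-control*
miRNAs used to put every array on a common scale.

The processing chain applied to each array is

1. quality control — coefficient of variation of the negative controls and
   the number of scanner-flagged probes must both be below thresholds;
2. presence call — a probe is detected when its signal exceeds the trimmed
   mean + 2 SD of the negative controls;
3. background subtraction — the trimmed negative-control mean is subtracted
   from detected probes and the result moved to log2 scale; undetected
   probes are floored at (lowest detected log2 value on the array) − 0.1;
4. normalization — every log2 value is shifted so that the linear mean of
   the three internal-control miRNAs equals a preset level.

Passing arrays are then assembled into a probe × sample matrix joined to
sample metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROBE_CLASSES",
    "GROUPS",
    "COHORTS",
    "DEFAULT_INTERNAL_CONTROLS",
    "DEFAULT_PRESET",
    "ProbeRecord",
    "ArrayScan",
    "SampleMeta",
    "QCThresholds",
    "QCReport",
    "NormalizedScan",
    "CohortMatrix",
    "PreprocessError",
    "qc_array",
    "detection_threshold",
    "trimmed_nc_stats",
    "background_correct",
    "normalize_scan",
    "assemble_matrix",
    "preprocess_cohort",
]

PROBE_CLASSES = ("target", "negative_control", "internal_control")
GROUPS = ("healthy", "benign", "intermediate", "malignant", "other_cancer")
COHORTS = ("discovery", "training", "training2", "validation", "exploratory")

#: The three serum miRNAs used to rescale each array.
DEFAULT_INTERNAL_CONTROLS = ("miR-149-3p", "miR-2861", "miR-4463")

#: Linear level the internal-control mean is standardized to (2**8).
DEFAULT_PRESET = 256.0

FLOOR_OFFSET = 0.1  # log2 units below the lowest detected probe


class PreprocessError(ValueError):
    """Raised on structurally invalid scans or undefined statistics."""


@dataclass(frozen=True)
class ProbeRecord:
    """A single probe on one array."""

    probe_id: str
    probe_class: str
    signal: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise PreprocessError(
                f"probe_class must be one of {PROBE_CLASSES}, got {self.probe_class!r}"
            )
        if not (self.signal >= 0):
            raise PreprocessError(
                f"signal must be nonnegative, got {self.signal!r} for {self.probe_id}"
            )


@dataclass
class ArrayScan:
    """One array read-out, stored as parallel per-probe arrays.

    Parameters
    ----------
    sample_id
        Identifier of the serum sample hybridized to this array.
    probe_ids
        Probe names, unique within the scan.
    probe_classes
        One of ``target``, ``negative_control``, ``internal_control`` per probe.
    signals
        Linear fluorescence intensities (nonnegative).
    flagged
        Scanner flags marking uneven hybridization.
    """

    sample_id: str
    probe_ids: list[str]
    probe_classes: np.ndarray
    signals: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.probe_classes = np.asarray(self.probe_classes, dtype=object)
        self.signals = np.asarray(self.signals, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        n = len(self.probe_ids)
        if not (len(self.probe_classes) == len(self.signals) == len(self.flagged) == n):
            raise PreprocessError(f"scan {self.sample_id}: per-probe arrays differ in length")
        if len(set(self.probe_ids)) != n:
            raise PreprocessError(f"scan {self.sample_id}: duplicate probe ids")
        bad = set(self.probe_classes) - set(PROBE_CLASSES)
        if bad:
            raise PreprocessError(f"scan {self.sample_id}: unknown probe classes {sorted(bad)}")
        if np.any(self.signals < 0) or not np.all(np.isfinite(self.signals)):
            raise PreprocessError(f"scan {self.sample_id}: signals must be finite and >= 0")

    @classmethod
    def from_records(cls, sample_id: str, records: list[ProbeRecord]) -> "ArrayScan":
        return cls(
            sample_id=sample_id,
            probe_ids=[r.probe_id for r in records],
            probe_classes=np.array([r.probe_class for r in records], dtype=object),
            signals=np.array([r.signal for r in records], dtype=float),
            flagged=np.array([r.flagged for r in records], dtype=bool),
        )

    @property
    def records(self) -> list[ProbeRecord]:
        return [
            ProbeRecord(pid, cls_, float(sig), bool(flg))
            for pid, cls_, sig, flg in zip(
                self.probe_ids, self.probe_classes, self.signals, self.flagged
            )
        ]

    def class_mask(self, probe_class: str) -> np.ndarray:
        return self.probe_classes == probe_class

    def negative_control_signals(self) -> np.ndarray:
        return self.signals[self.class_mask("negative_control")]


@dataclass(frozen=True)
class SampleMeta:
    """Clinical metadata attached to one serum sample."""

    sample_id: str
    group: str
    age: float
    sex: str
    cohort: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PreprocessError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise PreprocessError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.cohort not in COHORTS:
            raise PreprocessError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")


@dataclass(frozen=True)
class QCThresholds:
    """Array-level quality-control limits (both strict inequalities)."""

    max_nc_cv: float = 0.15
    max_flagged: int = 10

    def __post_init__(self) -> None:
        if not self.max_nc_cv > 0:
            raise PreprocessError("max_nc_cv must be > 0")
        if self.max_flagged < 0:
            raise PreprocessError("max_flagged must be >= 0")


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    nc_cv: float
    n_flagged: int
    passed: bool


@dataclass
class NormalizedScan:
    """Background-corrected (and possibly normalized) log2 values for one array.

    ``values`` holds every target and internal-control probe; probes that
    failed the presence call carry the array floor value and ``presence``
    False.
    """

    sample_id: str
    values: pd.Series
    presence: pd.Series


@dataclass
class CohortMatrix:
    """Normalized log2 miRNA × sample matrix joined to sample metadata."""

    matrix: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.matrix.columns) != ids:
            raise PreprocessError("matrix column order must match sample metadata order")
        if self.matrix.isna().any().any():
            raise PreprocessError("matrix contains missing cells")

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples], dtype=object)

    @property
    def cohorts(self) -> np.ndarray:
        return np.array([s.cohort for s in self.samples], dtype=object)

    def subset_samples(self, mask: np.ndarray) -> "CohortMatrix":
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return CohortMatrix(self.matrix.loc[:, mask], samples)


def qc_array(scan: ArrayScan, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Quality-control one array.

    The coefficient of variation is computed on the raw linear
    negative-control signals (sample SD over mean); flagged probes of any
    class are counted.  The array passes only if the CV is strictly below
    ``max_nc_cv`` and the flag count strictly below ``max_flagged``.
    """
    nc = scan.negative_control_signals()
    if len(nc) < 2:
        raise PreprocessError(f"scan {scan.sample_id}: need >= 2 negative-control probes for CV")
    mean = float(np.mean(nc))
    if mean <= 0:
        raise PreprocessError(f"scan {scan.sample_id}: negative-control mean <= 0, CV undefined")
    cv = float(np.std(nc, ddof=1)) / mean
    n_flagged = int(np.count_nonzero(scan.flagged))
    passed = (cv < thresholds.max_nc_cv) and (n_flagged < thresholds.max_flagged)
    return QCReport(scan.sample_id, cv, n_flagged, passed)


def _trim(signals: np.ndarray) -> np.ndarray:
    """Drop floor(5% n) signals from each end after sorting by intensity."""
    s = np.sort(np.asarray(signals, dtype=float))
    k = math.floor(0.05 * len(s))
    trimmed = s[k : len(s) - k] if k > 0 else s
    if len(trimmed) == 0:
        raise PreprocessError("no negative-control signals remain after 5% trimming")
    return trimmed


def trimmed_nc_stats(nc_signals: np.ndarray) -> tuple[float, float]:
    """Return (trimmed mean, trimmed sample SD) of negative-control signals."""
    t = _trim(nc_signals)
    mean = float(np.mean(t))
    sd = float(np.std(t, ddof=1)) if len(t) > 1 else 0.0
    return mean, sd


def detection_threshold(nc_signals: np.ndarray) -> float:
    """Linear presence-call threshold: trimmed NC mean + 2 × trimmed NC SD."""
    mean, sd = trimmed_nc_stats(nc_signals)
    return mean + 2.0 * sd


def background_correct(scan: ArrayScan) -> NormalizedScan:
    """Presence call, background subtraction, and floor replacement.

    Target and internal-control probes are called present when their raw
    linear signal strictly exceeds :func:`detection_threshold`.  Present
    probes get ``log2(signal − trimmed NC mean)``; absent probes (and any
    probe nonpositive after subtraction) get the array floor, 0.1 log2
    units below the lowest present value.
    """
    nc = scan.negative_control_signals()
    if len(nc) == 0:
        raise PreprocessError(f"scan {scan.sample_id}: no negative-control probes")
    nc_mean, nc_sd = trimmed_nc_stats(nc)
    threshold = nc_mean + 2.0 * nc_sd

    keep = ~scan.class_mask("negative_control")
    ids = [pid for pid, k in zip(scan.probe_ids, keep) if k]
    sig = scan.signals[keep]

    present = sig > threshold
    diff = sig - nc_mean
    quantified = present & (diff > 0)
    if not np.any(quantified):
        raise PreprocessError(
            f"scan {scan.sample_id}: no probe above the detection threshold; floor undefined"
        )
    values = np.empty(len(sig), dtype=float)
    values[quantified] = np.log2(diff[quantified])
    floor = float(values[quantified].min()) - FLOOR_OFFSET
    values[~quantified] = floor
    return NormalizedScan(
        sample_id=scan.sample_id,
        values=pd.Series(values, index=ids),
        presence=pd.Series(quantified, index=ids),
    )


def normalize_scan(
    corrected: NormalizedScan,
    control_names: tuple[str, str, str] = DEFAULT_INTERNAL_CONTROLS,
    preset: float = DEFAULT_PRESET,
) -> NormalizedScan:
    """Rescale one array so the internal-control linear mean equals ``preset``.

    The factor is ``preset / mean(2**v)`` over the three control probes'
    corrected values; every log2 value is shifted by ``log2(factor)``.
    Raises if any control probe is missing, undetected, or floored.
    """
    for name in control_names:
        if name not in corrected.values.index:
            raise PreprocessError(
                f"scan {corrected.sample_id}: internal control {name!r} missing"
            )
        if not corrected.presence[name]:
            raise PreprocessError(
                f"scan {corrected.sample_id}: internal control {name!r} undetected or floored;"
                " normalization failed"
            )
    control_linear = np.exp2(corrected.values[list(control_names)].to_numpy())
    factor = preset / float(np.mean(control_linear))
    shift = math.log2(factor)
    return NormalizedScan(
        sample_id=corrected.sample_id,
        values=corrected.values + shift,
        presence=corrected.presence.copy(),
    )


def assemble_matrix(scans: list[NormalizedScan], metadata: list[SampleMeta]) -> CohortMatrix:
    """Join normalized scans into a probe × sample matrix.

    Row order follows the first scan's probe order; column order follows
    ``metadata``.  Scan/metadata sample ids must match one-to-one and every
    scan must carry the identical probe set.
    """
    if len(scans) == 0:
        raise PreprocessError("no scans to assemble (all arrays may have failed QC)")
    scan_ids = {s.sample_id for s in scans}
    meta_ids = {m.sample_id for m in metadata}
    if scan_ids != meta_ids:
        missing = sorted(meta_ids - scan_ids)
        extra = sorted(scan_ids - meta_ids)
        raise PreprocessError(
            f"sample id mismatch between scans and metadata: missing scans {missing},"
            f" unmatched scans {extra}"
        )
    ref = list(scans[0].values.index)
    ref_set = set(ref)
    by_id = {}
    for scan in scans:
        probes = set(scan.values.index)
        if probes != ref_set:
            offenders = sorted(probes.symmetric_difference(ref_set))
            raise PreprocessError(
                f"scan {scan.sample_id}: probe set differs from reference: {offenders}"
            )
        by_id[scan.sample_id] = scan.values.reindex(ref)
    matrix = pd.DataFrame({m.sample_id: by_id[m.sample_id] for m in metadata}, index=ref)
    return CohortMatrix(matrix=matrix, samples=list(metadata))


def preprocess_cohort(
    scans: list[ArrayScan],
    metadata: list[SampleMeta],
    thresholds: QCThresholds = QCThresholds(),
    control_names: tuple[str, str, str] = DEFAULT_INTERNAL_CONTROLS,
    preset: float = DEFAULT_PRESET,
) -> tuple[CohortMatrix, list[QCReport]]:
    """QC, background-correct, normalize, and assemble a whole cohort.

    Arrays failing QC are dropped (their reports are still returned) and
    their metadata excluded from the resulting matrix.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    reports: list[QCReport] = []
    normalized: list[NormalizedScan] = []
    kept_meta: list[SampleMeta] = []
    for scan in scans:
        report = qc_array(scan, thresholds)
        reports.append(report)
        if not report.passed:
            continue
        corrected = background_correct(scan)
        normalized.append(normalize_scan(corrected, control_names, preset))
        kept_meta.append(meta_by_id[scan.sample_id])
    return assemble_matrix(normalized, kept_meta), reports
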
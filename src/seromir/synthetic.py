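"""Synthetic serum-miRNA study generator.

Emulates the statistical structure the downstream pipeline assumes: log2
miRNA signals that are approximately normal within a clinical group, a
per-array multiplicative scale factor (the reason internal-control
normalization exists), low-signal negative-control probes, three
internal-control miRNAs with a stable baseline, and planted marker probes
whose levels rise step-wise across healthy < benign < malignant with
configurable effect sizes.  The study-design premise is a minimum
detectable log2 difference of 0.5 at a representative within-group SD of
about 1.

The generator is deterministic: the same :class:`CohortSpec` (including its
seed) always yields the identical study.  Each array draws from its own RNG
substream keyed by the spec seed and the sample index, so generation order
never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_INTERNAL_CONTROLS,
    ArrayScan,
    SampleMeta,
)

__all__ = [
    "PlantedMarker",
    "CohortSpec",
    "GeneratedStudy",
    "SpecError",
    "generate_cohort",
    "generate_array_scan",
    "generate_qpcr_matrix",
]


class SpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass(frozen=True)
class PlantedMarker:
    """A target probe with a step-wise group effect on log2 scale.

    Benign and intermediate samples receive ``benign_shift``; malignant
    samples receive ``malignant_shift``.  ``intermediate_shift`` overrides
    the intermediate group's shift where a bimodal intermediate behaviour
    is wanted.
    """

    probe: str
    benign_shift: float
    malignant_shift: float
    intermediate_shift: float | None = None

    def __post_init__(self) -> None:
        if not (self.malignant_shift >= self.benign_shift >= 0):
            raise SpecError(
                f"planted_markers: require malignant_shift >= benign_shift >= 0 for "
                f"{self.probe!r} (got {self.benign_shift}, {self.malignant_shift})"
            )

    def shift_for(self, group: str) -> float:
        if group == "malignant":
            return self.malignant_shift
        if group == "benign":
            return self.benign_shift
        if group == "intermediate":
            return (
                self.intermediate_shift
                if self.intermediate_shift is not None
                else self.benign_shift
            )
        return 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic study.

    Counts are totals per clinical group; the pipeline later partitions
    samples into discovery/training/validation cohorts in round-robin
    order.  All signal parameters are on log2 scale unless noted.
    """

    n_healthy: int = 100
    n_benign: int = 100
    n_malignant: int = 100
    n_intermediate: int = 0
    n_mirna: int = 300
    n_negative_controls: int = 20
    internal_control_names: tuple[str, str, str] = DEFAULT_INTERNAL_CONTROLS
    planted_markers: tuple[PlantedMarker, ...] = ()
    within_group_sd: float = 1.0
    array_scale_sd: float = 0.2
    flag_rate: float = 0.01
    seed: int = 0
    # background / baseline model
    baseline_log2_range: tuple[float, float] = (6.0, 12.0)
    planted_baseline_log2_range: tuple[float, float] = (8.0, 11.0)
    nc_log2_mean: float = 4.0
    nc_log2_sd: float = 0.1
    control_log2_baseline: float = 8.0
    control_log2_sd: float = 0.1
    cohort_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_benign", "n_malignant", "n_intermediate",
                     "n_mirna", "n_negative_controls"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not self.within_group_sd > 0:
            raise SpecError("within_group_sd must be > 0")
        if self.array_scale_sd < 0:
            raise SpecError("array_scale_sd must be >= 0")
        if not 0 <= self.flag_rate <= 1:
            raise SpecError("flag_rate must be in [0, 1]")
        if len(self.internal_control_names) != 3:
            raise SpecError("internal_control_names must name exactly 3 probes")
        if len(set(self.internal_control_names)) != 3:
            raise SpecError("internal_control_names must be distinct")
        planted_names = [m.probe for m in self.planted_markers]
        if len(set(planted_names)) != len(planted_names):
            raise SpecError("planted_markers contains duplicate probe names")
        if set(planted_names) & set(self.internal_control_names):
            raise SpecError("planted_markers must be disjoint from internal_control_names")
        if len(planted_names) > self.n_mirna:
            raise SpecError("planted_markers: more planted markers than n_mirna target probes")
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-9:
            raise SpecError("cohort_fractions must sum to 1")

    @property
    def target_names(self) -> list[str]:
        """Planted marker names first, then synthetic filler probes."""
        planted = [m.probe for m in self.planted_markers]
        n_fill = self.n_mirna - len(planted)
        return planted + [f"miR-synth-{i:04d}" for i in range(n_fill)]

    @property
    def group_counts(self) -> dict[str, int]:
        return {
            "healthy": self.n_healthy,
            "benign": self.n_benign,
            "intermediate": self.n_intermediate,
            "malignant": self.n_malignant,
        }


@dataclass
class GeneratedStudy:
    """One synthetic study: per-sample scans, metadata, and the ground truth."""

    scans: list[ArrayScan]
    metadata: list[SampleMeta]
    truth: dict

    def __post_init__(self) -> None:
        if len(self.scans) != len(self.metadata):
            raise SpecError("one scan per metadata record required")


def _baselines(spec: CohortSpec) -> pd.Series:
    """Per-probe baseline log2 means, drawn once from the spec's probe stream.

    Filler probes span the abundance cut (some pass, some fail); planted
    markers are drawn from a higher range so they are always quantifiable.
    """
    rng = np.random.default_rng([spec.seed, 0, 0])
    names = spec.target_names
    lo, hi = spec.baseline_log2_range
    values = rng.uniform(lo, hi, size=len(names))
    plo, phi = spec.planted_baseline_log2_range
    n_planted = len(spec.planted_markers)
    if n_planted:
        values[:n_planted] = rng.uniform(plo, phi, size=n_planted)
    return pd.Series(values, index=names)


def _cohort_assignment(spec: CohortSpec, n: int) -> list[str]:
    """Deterministic proportional split of one group across cohorts."""
    cohorts = ("discovery", "training", "validation")
    counts = [int(np.floor(f * n)) for f in spec.cohort_fractions]
    i = 0
    while sum(counts) < n:
        counts[i % 3] += 1
        i += 1
    out: list[str] = []
    for cohort, c in zip(cohorts, counts):
        out.extend([cohort] * c)
    return out


def generate_array_scan(
    sample_id: str,
    group: str,
    baselines: pd.Series,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[ArrayScan, float]:
    """Generate one array for one sample from its own RNG substream.

    Returns the scan and the array's log2 scale factor (part of the study
    truth).  Probe order is targets, internal controls, negative controls.
    """
    shift = pd.Series(0.0, index=baselines.index)
    for marker in spec.planted_markers:
        shift[marker.probe] = marker.shift_for(group)

    target_log2 = (
        baselines.to_numpy()
        + shift.to_numpy()
        + rng.normal(0.0, spec.within_group_sd, size=len(baselines))
    )
    control_log2 = rng.normal(spec.control_log2_baseline, spec.control_log2_sd, size=3)
    nc_log2 = rng.normal(spec.nc_log2_mean, spec.nc_log2_sd, size=spec.n_negative_controls)
    scale_log2 = float(rng.normal(0.0, spec.array_scale_sd)) if spec.array_scale_sd > 0 else 0.0

    log2_all = np.concatenate([target_log2, control_log2, nc_log2]) + scale_log2
    signals = np.exp2(log2_all)
    n_total = len(signals)
    flagged = rng.random(n_total) < spec.flag_rate

    probe_ids = list(baselines.index) + list(spec.internal_control_names) + [
        f"NC-{i:04d}" for i in range(spec.n_negative_controls)
    ]
    classes = np.array(
        ["target"] * len(baselines)
        + ["internal_control"] * 3
        + ["negative_control"] * spec.n_negative_controls,
        dtype=object,
    )
    scan = ArrayScan(
        sample_id=sample_id,
        probe_ids=probe_ids,
        probe_classes=classes,
        signals=signals,
        flagged=flagged,
    )
    return scan, scale_log2


def generate_cohort(spec: CohortSpec) -> GeneratedStudy:
    """Generate a full synthetic study from a :class:`CohortSpec`.

    Sample order is healthy, benign, intermediate, malignant; within each
    group, samples cycle through discovery/training/validation cohorts per
    ``spec.cohort_fractions``.  Ages are truncated-normal(48, 20) on
    [1, 95]; sex is Bernoulli(0.55 male).
    """
    baselines = _baselines(spec)
    meta_rng = np.random.default_rng([spec.seed, 2, 0])

    scans: list[ArrayScan] = []
    metadata: list[SampleMeta] = []
    scale_log2: dict[str, float] = {}
    index = 0
    for group in ("healthy", "benign", "intermediate", "malignant"):
        n = spec.group_counts[group]
        cohorts = _cohort_assignment(spec, n)
        for j in range(n):
            sample_id = f"S{index:05d}-{group[:3]}"
            rng = np.random.default_rng([spec.seed, 1, index])
            scan, s_log2 = generate_array_scan(sample_id, group, baselines, spec, rng)
            age = _truncated_normal(meta_rng, 48.0, 20.0, 1.0, 95.0)
            sex = "M" if meta_rng.random() < 0.55 else "F"
            metadata.append(
                SampleMeta(sample_id=sample_id, group=group, age=age, sex=sex,
                           cohort=cohorts[j])
            )
            scans.append(scan)
            scale_log2[sample_id] = s_log2
            index += 1

    truth = {
        "planted_markers": [
            {
                "probe": m.probe,
                "benign_shift": m.benign_shift,
                "malignant_shift": m.malignant_shift,
                "intermediate_shift": m.intermediate_shift,
            }
            for m in spec.planted_markers
        ],
        "scale_log2": scale_log2,
    }
    return GeneratedStudy(scans=scans, metadata=metadata, truth=truth)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled truncated normal (acceptance rate ~0.98 here)."""
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def generate_qpcr_matrix(
    spec: CohortSpec,
    metadata: list[SampleMeta],
    probes: list[str],
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Relative expression (2^−ΔCt analog) for selected probes and samples.

    Emulates an independent re-measurement of the same planted truth with
    fresh noise: expression is ``2 ** (group shift + N(0, noise_sd))``, a
    positive quantity normalized against the internal-control reference,
    with no array scale factor (the reference normalization removes it).
    """
    if noise_sd is None:
        noise_sd = spec.within_group_sd
    rng = np.random.default_rng([spec.seed, 3, 0])
    shifts = {m.probe: m for m in spec.planted_markers}
    rows = {}
    for probe in probes:
        marker = shifts.get(probe)
        delta = np.array(
            [marker.shift_for(m.group) if marker is not None else 0.0 for m in metadata]
        )
        rows[probe] = np.exp2(delta + rng.normal(0.0, noise_sd, size=len(metadata)))
    return pd.DataFrame(rows, index=[m.sample_id for m in metadata]).T
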
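"""End-to-end orchestration: simulate → preprocess → select → search → evaluate.

Cohort roles follow the original study design: the discovery cohort feeds
the abundance filter and the univariate LOOCV screen; the training cohort
feeds the step-wise cluster screen, the differential screen, and the
combinatorial index search; the validation cohort is reserved for the
final performance evaluation and influences nothing upstream.  The whole
run is deterministic given the cohort spec's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import published_index
from .discriminant import (
    IndexModel,
    SearchResult,
    combinatorial_search,
    fit_fisher_lda,
    index_scores,
)
from .performance import PerformanceReport, evaluate
from .preprocess import (
    CohortMatrix,
    QCReport,
    QCThresholds,
    preprocess_cohort,
    DEFAULT_PRESET,
)
from .selection import SelectionConfig, SelectionResult, run_selection
from .synthetic import CohortSpec, generate_cohort, generate_qpcr_matrix

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full synthetic-study run."""

    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    sizes: tuple[int, ...] = tuple(range(2, 10))
    index: str = "search"  # "search" or a published roman numeral
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    preset: float = DEFAULT_PRESET
    qpcr_from_truth: bool = True
    # When True, the differential screen runs on a fresh relative-expression
    # re-measurement drawn from the study truth; when False, on 2**values of
    # the training matrix itself.


@dataclass
class PipelineResult:
    matrix: CohortMatrix
    qc_reports: list[QCReport]
    selection: SelectionResult
    search: SearchResult | None
    model: IndexModel
    report: PerformanceReport
    provenance: dict


def _cohort_view(matrix: CohortMatrix, cohort: str, groups: tuple[str, ...]) -> CohortMatrix:
    mask = (matrix.cohorts == cohort) & np.isin(matrix.groups, groups)
    return matrix.subset_samples(mask)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full pipeline on a freshly generated synthetic study.

    Returns the normalized matrix, per-stage selection output, the fitted
    (or published) index, the validation performance report, and a
    provenance log recording which samples fed each stage.  With
    ``out_dir`` set, stage artifacts and a run manifest are written there.
    """
    spec = config.cohort_spec
    study = generate_cohort(spec)
    matrix, qc_reports = preprocess_cohort(
        study.scans, study.metadata, config.thresholds,
        spec.internal_control_names, config.preset,
    )

    discovery = _cohort_view(matrix, "discovery", ("healthy", "benign", "malignant"))
    training = _cohort_view(matrix, "training", ("healthy", "benign", "malignant"))
    validation = _cohort_view(
        matrix, "validation", ("healthy", "benign", "malignant")
    )
    for name, view in (("discovery", discovery), ("training", training),
                       ("validation", validation)):
        if len(view.samples) == 0:
            raise PipelineError(f"{name} cohort is empty after QC")

    # training-cohort relative expression for the differential screen
    tr_mb_mask = np.isin(training.groups, ("benign", "malignant"))
    tr_mb = training.subset_samples(tr_mb_mask)
    tr_labels = (tr_mb.groups == "malignant").astype(int)
    if config.qpcr_from_truth:
        expr = generate_qpcr_matrix(spec, tr_mb.samples, list(matrix.matrix.index))
    else:
        expr = np.exp2(tr_mb.matrix)

    selection = run_selection(discovery, training, expr, tr_labels, config.selection,
                              exclude=spec.internal_control_names)
    candidates = selection.differential_pass
    if not candidates:
        raise PipelineError("selection funnel returned no candidate markers")

    search: SearchResult | None = None
    if config.index == "search":
        Xtr = tr_mb.matrix.loc[candidates].to_numpy().T
        if len(candidates) >= 2:
            sizes = [k for k in config.sizes if k <= len(candidates)]
            if not sizes:
                sizes = [len(candidates)]
            search = combinatorial_search(Xtr, tr_labels, candidates, sizes)
            model = search.overall_best
        else:
            model = fit_fisher_lda(Xtr, tr_labels, markers=tuple(candidates),
                                   name="best-1")
    else:
        model = published_index(config.index)

    val_scores = index_scores(model, validation.matrix)
    val_labels = (validation.groups == "malignant").astype(int)
    report = evaluate(val_scores.to_numpy(), val_labels)

    provenance = {
        "version": __version__,
        "seed": spec.seed,
        "index": config.index,
        "stages": {
            "selection": {
                "discovery_samples": [s.sample_id for s in discovery.samples],
                "training_samples": [s.sample_id for s in tr_mb.samples],
            },
            "search": {"training_samples": [s.sample_id for s in tr_mb.samples]},
            "evaluate": {"validation_samples": [s.sample_id for s in validation.samples]},
        },
        "qc_failed": [r.sample_id for r in qc_reports if not r.passed],
        "funnel": {
            "abundant": len(selection.abundant),
            "loocv_pass": len(selection.loocv_pass),
            "stepwise_pass": len(selection.stepwise_pass),
            "differential_pass": len(selection.differential_pass),
        },
        "model": model.to_dict(),
    }
    sel_ids = set(provenance["stages"]["selection"]["discovery_samples"]) | set(
        provenance["stages"]["selection"]["training_samples"]
    )
    val_ids = set(provenance["stages"]["evaluate"]["validation_samples"])
    if sel_ids & val_ids:
        raise PipelineError("cohort hygiene violation: validation samples used upstream")

    result = PipelineResult(
        matrix=matrix, qc_reports=qc_reports, selection=selection,
        search=search, model=model, report=report, provenance=provenance,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    from .io import write_matrix_tsv, write_metadata_tsv

    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(result.matrix, out / "matrix.tsv")
    write_metadata_tsv(result.matrix.samples, out / "metadata.tsv")
    with open(out / "selection.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "abundant": result.selection.abundant,
                "loocv_scores": result.selection.loocv_scores,
                "loocv_pass": result.selection.loocv_pass,
                "stepwise_pass": result.selection.stepwise_pass,
                "stepwise_decreasing": result.selection.stepwise_decreasing,
                "differential_pass": result.selection.differential_pass,
            },
            fh, indent=2,
        )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report.to_dict(), fh, indent=2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.provenance, fh, indent=2)
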
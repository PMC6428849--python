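"""Multi-stage candidate-miRNA selection funnel.

Candidates for the diagnostic index are narrowed in four stages:

1. abundance — keep probes whose log2 signal exceeds a cut (default 6, i.e.
   linear 2^6) in strictly more than half of the malignant or of the benign
   samples;
2. discrimination — keep probes whose univariate leave-one-out
   cross-validation hit score (malignant vs benign, midpoint-of-means rule)
   strictly exceeds 0.6;
3. step-wise cluster screen — average-linkage clustering of probe profiles
   (Euclidean distance); keep clusters whose centroid group means rise
   strictly healthy < benign < malignant (strictly decreasing clusters are
   reported separately);
4. differential screen — on a positive relative-expression matrix
   (2^−ΔCt scale), keep probes with a two-sided pooled-variance Student
   t-test p < 0.05 and a higher malignant than benign mean.

Each stage's output is a subset of its input (funnel monotonicity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats

from .preprocess import CohortMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "StepwiseResult",
    "SelectionError",
    "abundant_filter",
    "loocv_marker_score",
    "select_by_loocv",
    "stepwise_cluster_screen",
    "differential_screen",
    "run_selection",
]

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the selection funnel (defaults follow the study design)."""

    abundance_log2_cut: float = 6.0
    abundance_fraction: float = 0.5
    loocv_cut: float = 0.6
    alpha_diff: float = 0.05
    n_clusters: int = 10
    welch: bool = False  # pooled Student t by default

    def __post_init__(self) -> None:
        if not 0 < self.abundance_fraction < 1:
            raise SelectionError("abundance_fraction must be in (0, 1)")
        if not 0 < self.loocv_cut < 1:
            raise SelectionError("loocv_cut must be in (0, 1)")
        if not 0 < self.alpha_diff < 1:
            raise SelectionError("alpha_diff must be in (0, 1)")
        if self.n_clusters < 1:
            raise SelectionError("n_clusters must be >= 1")


@dataclass
class SelectionResult:
    """Probe lists surviving each funnel stage, plus the LOOCV score map."""

    abundant: list[str]
    loocv_scores: dict[str, float]
    loocv_pass: list[str]
    stepwise_pass: list[str]
    stepwise_decreasing: list[str]
    differential_pass: list[str]

    def __post_init__(self) -> None:
        if not set(self.loocv_pass) <= set(self.abundant):
            raise SelectionError("loocv_pass must be a subset of abundant")
        if not set(self.stepwise_pass) <= set(self.loocv_pass):
            raise SelectionError("stepwise_pass must be a subset of loocv_pass")
        if not set(self.differential_pass) <= set(self.stepwise_pass):
            raise SelectionError("differential_pass must be a subset of stepwise_pass")


@dataclass
class StepwiseResult:
    increasing: list[str]
    decreasing: list[str]
    cluster_ids: dict[str, int]


def _group_columns(matrix: CohortMatrix, group: str) -> np.ndarray:
    return matrix.groups == group


def abundant_filter(matrix: CohortMatrix, config: SelectionConfig = SelectionConfig()) -> list[str]:
    """Probes abundant in serum: log2 value strictly above the cut in
    strictly more than ``abundance_fraction`` of malignant OR benign samples."""
    mal = _group_columns(matrix, "malignant")
    ben = _group_columns(matrix, "benign")
    if not mal.any():
        raise SelectionError("no malignant samples in matrix")
    if not ben.any():
        raise SelectionError("no benign samples in matrix")
    values = matrix.matrix.to_numpy()
    above = values > config.abundance_log2_cut
    frac_mal = above[:, mal].mean(axis=1)
    frac_ben = above[:, ben].mean(axis=1)
    keep = (frac_mal > config.abundance_fraction) | (frac_ben > config.abundance_fraction)
    return [p for p, k in zip(matrix.matrix.index, keep) if k]


def loocv_marker_score(values, labels) -> float:
    """Univariate LOOCV hit score under the midpoint-of-means rule.

    For each sample, the two class means are recomputed without it; the
    held-out value is called malignant when it falls on the malignant side
    of the midpoint (the Fisher discriminant decision in one dimension; on
    the boundary the score is 0, which calls sarcoma).  Returns hits / n.
    Invariant under increasing affine transforms of ``values``.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise SelectionError("need >= 2 samples per class for LOOCV")
    sum0, sum1 = x[y == 0].sum(), x[y == 1].sum()
    # leave-one-out class means, vectorized over samples
    mu0 = np.where(y == 0, (sum0 - x) / (n0 - 1), sum0 / n0)
    mu1 = np.where(y == 1, (sum1 - x) / (n1 - 1), sum1 / n1)
    score = (mu1 - mu0) * (x - (mu0 + mu1) / 2.0)
    predicted = (score >= 0).astype(int)
    return float(np.mean(predicted == y))


def select_by_loocv(
    matrix: CohortMatrix,
    probes: list[str] | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], dict[str, float]]:
    """Probes with LOOCV score strictly above ``loocv_cut`` (malignant vs
    benign), together with the full score map."""
    mal = _group_columns(matrix, "malignant")
    ben = _group_columns(matrix, "benign")
    use = mal | ben
    y = mal[use].astype(int)
    if probes is None:
        probes = list(matrix.matrix.index)
    scores: dict[str, float] = {}
    selected: list[str] = []
    sub = matrix.matrix.loc[probes, use]
    for probe in probes:
        s = loocv_marker_score(sub.loc[probe].to_numpy(), y)
        scores[probe] = s
        if s > config.loocv_cut:
            selected.append(probe)
    return selected, scores


def stepwise_cluster_screen(
    matrix: CohortMatrix,
    probes: list[str] | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> StepwiseResult:
    """Average-linkage cluster screen for step-wise group trends.

    Probe profiles (rows) are agglomerated with average linkage on
    Euclidean distance and the dendrogram cut into ``n_clusters`` flat
    clusters.  A cluster is step-wise increasing when its centroid's group
    means satisfy healthy < benign < malignant strictly; decreasing
    clusters (the strict reverse ordering) are reported separately.
    """
    if probes is None:
        probes = list(matrix.matrix.index)
    for group in ("healthy", "benign", "malignant"):
        if not (matrix.groups == group).any():
            raise SelectionError(f"group {group!r} absent from matrix")
    if len(probes) < 2:
        raise SelectionError("need >= 2 probes to cluster")
    if config.n_clusters > len(probes):
        raise SelectionError(
            f"n_clusters={config.n_clusters} exceeds number of probes ({len(probes)})"
        )
    profiles = matrix.matrix.loc[probes].to_numpy()
    Z = linkage(profiles, method="average", metric="euclidean")
    flat = fcluster(Z, t=config.n_clusters, criterion="maxclust")

    h = _group_columns(matrix, "healthy")
    b = _group_columns(matrix, "benign")
    m = _group_columns(matrix, "malignant")
    increasing: list[str] = []
    decreasing: list[str] = []
    for cid in np.unique(flat):
        members = [p for p, c in zip(probes, flat) if c == cid]
        centroid = profiles[flat == cid].mean(axis=0)
        mh, mb, mm = centroid[h].mean(), centroid[b].mean(), centroid[m].mean()
        if mh < mb < mm:
            increasing.extend(members)
        elif mh > mb > mm:
            decreasing.extend(members)
    cluster_ids = {p: int(c) for p, c in zip(probes, flat)}
    # preserve input probe order
    inc = [p for p in probes if p in set(increasing)]
    dec = [p for p in probes if p in set(decreasing)]
    return StepwiseResult(increasing=inc, decreasing=dec, cluster_ids=cluster_ids)


def differential_screen(
    expr: pd.DataFrame,
    labels,
    config: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Directional t-test screen on a positive expression matrix.

    ``expr`` is probe × sample on a positive relative-expression scale
    (e.g. 2^−ΔCt); ``labels`` codes benign 0 / malignant 1 per column.
    Retains probes with two-sided Student (pooled-variance) t-test
    p < ``alpha_diff`` and malignant mean > benign mean.  With zero pooled
    variance, equal means give p = 1 and unequal means p = 0 (logged).
    """
    y = np.asarray(labels, dtype=int)
    if expr.shape[1] != len(y):
        raise SelectionError("labels must match expression columns")
    if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
        raise SelectionError("need >= 2 samples per group")
    values = expr.to_numpy()
    if np.any(values <= 0):
        raise SelectionError("expression values must be > 0")
    mal, ben = values[:, y == 1], values[:, y == 0]
    selected: list[str] = []
    for i, probe in enumerate(expr.index):
        a, b = mal[i], ben[i]
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                p = 1.0
            else:
                p = 0.0
                logger.warning("probe %s: zero pooled variance with unequal means; p=0", probe)
        else:
            _, p = stats.ttest_ind(a, b, equal_var=not config.welch)
        if p < config.alpha_diff and np.mean(a) > np.mean(b):
            selected.append(str(probe))
    return selected


def run_selection(
    discovery: CohortMatrix,
    training: CohortMatrix,
    expr: pd.DataFrame,
    expr_labels,
    config: SelectionConfig = SelectionConfig(),
    exclude: tuple[str, ...] = (),
) -> SelectionResult:
    """Run the whole funnel across its cohorts.

    Abundance and LOOCV stages use the discovery cohort; the cluster screen
    uses the training cohort; the differential screen uses the supplied
    relative-expression matrix (restricted to surviving probes).  Probes in
    ``exclude`` (typically the internal-control miRNAs, which are abundant
    by construction) never enter the funnel.
    """
    abundant = [p for p in abundant_filter(discovery, config) if p not in set(exclude)]
    loocv_pass, scores = select_by_loocv(discovery, abundant, config)
    if len(loocv_pass) < 2:
        stepwise = StepwiseResult(increasing=list(loocv_pass), decreasing=[], cluster_ids={})
        if loocv_pass:
            logger.warning("only %d probe(s) passed LOOCV; cluster screen skipped", len(loocv_pass))
    else:
        cfg = config
        if config.n_clusters > len(loocv_pass):
            cfg = SelectionConfig(
                abundance_log2_cut=config.abundance_log2_cut,
                abundance_fraction=config.abundance_fraction,
                loocv_cut=config.loocv_cut,
                alpha_diff=config.alpha_diff,
                n_clusters=len(loocv_pass),
                welch=config.welch,
            )
        stepwise = stepwise_cluster_screen(training, loocv_pass, cfg)
    surviving = [p for p in stepwise.increasing if p in expr.index]
    if surviving:
        differential = differential_screen(expr.loc[surviving], expr_labels, config)
    else:
        differential = []
    return SelectionResult(
        abundant=abundant,
        loocv_scores=scores,
        loocv_pass=loocv_pass,
        stepwise_pass=stepwise.increasing,
        stepwise_decreasing=stepwise.decreasing,
        differential_pass=differential,
    )
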
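"""Fisher linear discriminant indices and exhaustive marker-subset search.

A diagnostic index is a linear score over log2 marker levels,

    score(x) = w.x + b,   w = S_pooled^-1 (mu_mal - mu_ben),
    b = -w.(mu_ben + mu_mal)/2,

with the equal-prior midpoint intercept, so the decision boundary sits
halfway between the class means in the discriminant direction.  A score
>= 0 calls sarcoma (the boundary is inclusive).

Model quality is measured by leave-one-out cross-validation: refit on each
n−1 subset and classify the held-out sample.  The best marker panel is
found by exhaustively scoring every subset of sizes 2–9 of a candidate
list, with deterministic tie-breaking.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SARCOMA",
    "NON_SARCOMA",
    "IndexModel",
    "SearchResult",
    "DiscriminantError",
    "MissingMarkerError",
    "fit_fisher_lda",
    "index_score",
    "index_scores",
    "classify",
    "loocv_model_accuracy",
    "loocv_scores",
    "combinatorial_search",
    "write_index_model",
    "read_index_model",
]

SARCOMA = "sarcoma"
NON_SARCOMA = "non_sarcoma"

SEARCH_GUARD = 1_000_000  # max total subsets the exhaustive search will enumerate


class DiscriminantError(ValueError):
    pass


class MissingMarkerError(KeyError):
    """A sample lacks a marker the index requires."""


@dataclass(frozen=True)
class IndexModel:
    """A named linear diagnostic index over log2 marker levels."""

    name: str
    markers: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.markers):
            raise DiscriminantError("one coefficient per marker required")
        if self.threshold != 0.0:
            raise DiscriminantError("decision threshold is fixed at 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "markers": list(self.markers),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "threshold": 0.0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexModel":
        return cls(
            name=d["name"],
            markers=tuple(d["markers"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            intercept=float(d["intercept"]),
            threshold=float(d.get("threshold", 0.0)),
        )


@dataclass
class SearchResult:
    """Outcome of the exhaustive subset search."""

    best_per_size: dict[int, tuple[IndexModel, float]]
    overall_best: IndexModel
    overall_best_accuracy: float
    n_evaluated: int


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _pooled_stats(X: np.ndarray, y: np.ndarray):
    """Class means and pooled (n−2 denominator) within-class covariance."""
    X0, X1 = X[y == 0], X[y == 1]
    n0, n1 = len(X0), len(X1)
    if n0 < 2 or n1 < 2:
        raise DiscriminantError("need >= 2 samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S0 = (X0 - mu0).T @ (X0 - mu0)
    S1 = (X1 - mu1).T @ (X1 - mu1)
    S = (S0 + S1) / (n0 + n1 - 2)
    return mu0, mu1, S


def _solve_direction(S: np.ndarray, delta: np.ndarray, ridge: bool) -> np.ndarray:
    try:
        np.linalg.cholesky(S)  # positive-definiteness check
        w = np.linalg.solve(S, delta)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite solution")
        return w
    except np.linalg.LinAlgError:
        if not ridge:
            raise DiscriminantError("pooled within-class covariance is singular")
        p = S.shape[0]
        lam = 1e-6 * (np.trace(S) / p if np.trace(S) > 0 else 1.0)
        return np.linalg.solve(S + lam * np.eye(p), delta)


def fit_fisher_lda(
    X, y, markers: tuple[str, ...] | None = None, name: str = "fisher-lda",
    ridge: bool = True,
) -> IndexModel:
    """Fit the two-class Fisher discriminant with midpoint intercept.

    ``y`` codes benign/non-sarcoma as 0 and malignant/sarcoma as 1.  When
    the pooled covariance is singular a small ridge (1e-6 · trace(S)/p) is
    added unless ``ridge=False``, in which case an error is raised.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=int)
    mu0, mu1, S = _pooled_stats(X, y)
    w = _solve_direction(S, mu1 - mu0, ridge)
    intercept = float(-w @ (mu0 + mu1) / 2.0)
    if markers is None:
        markers = tuple(f"m{i}" for i in range(X.shape[1]))
    return IndexModel(name=name, markers=tuple(markers),
                      coefficients=tuple(float(v) for v in w), intercept=intercept)


def index_score(model: IndexModel, sample) -> float:
    """Apply an index to one sample (mapping probe → log2 value)."""
    total = model.intercept
    for marker, coef in zip(model.markers, model.coefficients):
        try:
            value = sample[marker]
        except KeyError:
            raise MissingMarkerError(f"sample is missing marker {marker!r}") from None
        if isinstance(value, float) and math.isnan(value):
            raise MissingMarkerError(f"sample is missing marker {marker!r}")
        total += coef * float(value)
    return float(total)


def index_scores(model: IndexModel, matrix: pd.DataFrame) -> pd.Series:
    """Apply an index to every column (sample) of a probe × sample matrix."""
    missing = [m for m in model.markers if m not in matrix.index]
    if missing:
        raise MissingMarkerError(f"matrix is missing markers {missing}")
    X = matrix.loc[list(model.markers)].to_numpy().T
    return pd.Series(X @ np.asarray(model.coefficients) + model.intercept,
                     index=matrix.columns)


def classify(score: float) -> str:
    """Score >= 0 calls sarcoma; the zero boundary is inclusive."""
    return SARCOMA if score >= 0 else NON_SARCOMA


def loocv_scores(X, y, ridge: bool = True) -> np.ndarray:
    """Held-out index score for every sample under leave-one-out refitting.

    Uses rank-one downdates of the class sums and scatter matrices, so each
    fold costs one small linear solve; equivalent to refitting from scratch.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    out = np.empty(n, dtype=float)
    X0, X1 = X[y == 0], X[y == 1]
    n0, n1 = len(X0), len(X1)
    if n0 < 3 or n1 < 3:
        # folds would leave < 2 samples in a class only if nc-1 < 2
        if n0 < 2 or n1 < 2:
            raise DiscriminantError("need >= 2 samples per class")
    sum0, sum1 = X0.sum(axis=0), X1.sum(axis=0)
    mu0, mu1 = sum0 / n0, sum1 / n1
    S0 = (X0 - mu0).T @ (X0 - mu0)
    S1 = (X1 - mu1).T @ (X1 - mu1)
    for i in range(n):
        xi = X[i]
        if y[i] == 0:
            if n0 - 1 < 2:
                raise DiscriminantError(f"fold {i}: a training class would be empty or singleton")
            m0 = (sum0 - xi) / (n0 - 1)
            d = xi - mu0
            Sc0 = S0 - (n0 / (n0 - 1)) * np.outer(d, d)
            m1, Sc1, k0, k1 = mu1, S1, n0 - 1, n1
        else:
            if n1 - 1 < 2:
                raise DiscriminantError(f"fold {i}: a training class would be empty or singleton")
            m1 = (sum1 - xi) / (n1 - 1)
            d = xi - mu1
            Sc1 = S1 - (n1 / (n1 - 1)) * np.outer(d, d)
            m0, Sc0, k0, k1 = mu0, S0, n0, n1 - 1
        S = (Sc0 + Sc1) / (k0 + k1 - 2)
        w = _solve_direction(S, m1 - m0, ridge)
        out[i] = w @ xi - w @ (m0 + m1) / 2.0
    return out


def loocv_model_accuracy(X, y, subset: tuple[str, ...] | None = None,
                         matrix: pd.DataFrame | None = None) -> float:
    """LOOCV hit rate of the refit index at the score >= 0 rule.

    Either pass ``X`` (samples × markers) directly, or a probe × sample
    ``matrix`` plus a ``subset`` of its row names.
    """
    if matrix is not None:
        if subset is None:
            raise DiscriminantError("subset of matrix rows required")
        X = matrix.loc[list(subset)].to_numpy().T
    y = np.asarray(y, dtype=int)
    scores = loocv_scores(X, y)
    predicted = (scores >= 0).astype(int)
    return float(np.mean(predicted == y))


def _mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = scores[y == 1]
    n1, n0 = len(pos), len(scores) - len(pos)
    ranks = rankdata(scores)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def combinatorial_search(
    X, y, candidates: list[str], sizes: range | tuple[int, ...] = range(2, 10),
) -> SearchResult:
    """Exhaustive LOOCV evaluation of every candidate subset of each size.

    ``X`` is samples × candidates (columns ordered as ``candidates``).  The
    best subset per size maximizes LOOCV accuracy; ties break by higher
    LOOCV AUC of the held-out scores, then lexicographic marker order.  The
    overall best maximizes accuracy across sizes, ties to the smaller panel.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=int)
    if X.shape[1] != len(candidates):
        raise DiscriminantError("X must have one column per candidate")
    sizes = [k for k in sizes]
    if not sizes:
        raise DiscriminantError("empty size range")
    if len(candidates) < max(sizes):
        raise DiscriminantError(
            f"need >= {max(sizes)} candidates for the requested sizes, got {len(candidates)}"
        )
    total = sum(math.comb(len(candidates), k) for k in sizes)
    if total > SEARCH_GUARD:
        raise DiscriminantError(
            f"{total} subsets exceed the exhaustive-search guard ({SEARCH_GUARD});"
            " restrict the size range or candidate list"
        )

    col = {name: i for i, name in enumerate(candidates)}
    best_per_size: dict[int, tuple[IndexModel, float]] = {}
    n_evaluated = 0
    for k in sizes:
        best_key = None
        best_subset = None
        for subset in itertools.combinations(sorted(candidates), k):
            idx = [col[m] for m in subset]
            scores = loocv_scores(X[:, idx], y)
            acc = float(np.mean((scores >= 0).astype(int) == y))
            auc = _mann_whitney_auc(scores, y)
            key = (-acc, -auc, subset)
            n_evaluated += 1
            if best_key is None or key < best_key:
                best_key, best_subset = key, subset
        acc = -best_key[0]
        model = fit_fisher_lda(X[:, [col[m] for m in best_subset]], y,
                               markers=best_subset, name=f"best-{k}")
        best_per_size[k] = (model, acc)

    overall_size = min(
        best_per_size, key=lambda k: (-best_per_size[k][1], k)
    )
    model, acc = best_per_size[overall_size]
    return SearchResult(
        best_per_size=best_per_size,
        overall_best=model,
        overall_best_accuracy=acc,
        n_evaluated=n_evaluated,
    )


def write_index_model(model: IndexModel, path) -> None:
    """Write an index as JSON (12 significant digits)."""
    d = model.to_dict()
    d["coefficients"] = [float(f"{c:.12g}") for c in d["coefficients"]]
    d["intercept"] = float(f"{d['intercept']:.12g}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def read_index_model(path) -> IndexModel:
    with open(path, encoding="utf-8") as fh:
        return IndexModel.from_dict(json.load(fh))
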
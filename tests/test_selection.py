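"""Selection funnel: abundance, LOOCV screen, cluster screen, t-test screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage

from seromir.preprocess import CohortMatrix, SampleMeta
from seromir.selection import (
    SelectionConfig,
    SelectionError,
    abundant_filter,
    differential_screen,
    loocv_marker_score,
    run_selection,
    select_by_loocv,
    stepwise_cluster_screen,
)
from seromir.synthetic import generate_cohort, generate_qpcr_matrix
from seromir.preprocess import preprocess_cohort


def make_matrix(values: dict, groups: list, cohort="discovery"):
    samples = [
        SampleMeta(sample_id=f"S{i}", group=g, age=50.0, sex="F", cohort=cohort)
        for i, g in enumerate(groups)
    ]
    df = pd.DataFrame(values, index=[s.sample_id for s in samples]).T
    return CohortMatrix(matrix=df, samples=samples)


class TestAbundantFilter:
    def test_half_is_not_more_than_half(self):
        cm = make_matrix(
            {"p": [7, 7, 5, 5, 5, 5, 5, 5]},
            ["malignant"] * 4 + ["benign"] * 4,
        )
        assert abundant_filter(cm) == []

    def test_three_quarters_passes(self):
        cm = make_matrix(
            {"p": [7, 7, 7, 5, 5, 5, 5, 5]},
            ["malignant"] * 4 + ["benign"] * 4,
        )
        assert abundant_filter(cm) == ["p"]

    def test_either_group_suffices(self):
        cm = make_matrix(
            {"p": [5, 5, 5, 5, 7, 7, 7, 5]},
            ["malignant"] * 4 + ["benign"] * 4,
        )
        assert abundant_filter(cm) == ["p"]

    def test_exact_cut_value_excluded(self):
        cm = make_matrix({"p": [6.0] * 8}, ["malignant"] * 4 + ["benign"] * 4)
        assert abundant_filter(cm) == []

    def test_missing_group_is_an_error(self):
        cm = make_matrix({"p": [7, 7]}, ["malignant", "malignant"])
        with pytest.raises(SelectionError, match="benign"):
            abundant_filter(cm)


class TestLoocvMarkerScore:
    def test_perfect_separation(self):
        assert loocv_marker_score([0, 1, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_outlier_dragged_midpoint(self):
        # six LOOCV rounds by hand under the midpoint rule: held-out 3 and 4
        # fall below the outlier-dragged midpoint and are missed
        score = loocv_marker_score([0, 1, 2, 3, 4, 50], [0, 0, 0, 1, 1, 1])
        assert score == pytest.approx(4 / 6)

    def test_needs_two_per_class(self):
        with pytest.raises(SelectionError):
            loocv_marker_score([0, 1, 2], [0, 0, 1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=24),
        st.floats(0.01, 100.0),
        st.floats(-1000, 1000),
    )
    def test_affine_invariance(self, values, a, b):
        y = [i % 2 for i in range(len(values))]
        x = np.asarray(values)
        assert loocv_marker_score(x, y) == pytest.approx(
            loocv_marker_score(a * x + b, y)
        )

    def test_permutation_null_centers_at_half(self, rng):
        x = rng.normal(size=200)
        y = np.array([0] * 100 + [1] * 100)
        scores = [loocv_marker_score(x, rng.permutation(y)) for _ in range(100)]
        assert np.mean(scores) == pytest.approx(0.5, abs=0.05)


class TestSelectByLoocv:
    def test_cut_is_strict(self, rng):
        # a moderately separated marker: score strictly between 0.6 and 1
        values = {"mid": np.concatenate([rng.normal(7, 1, 20), rng.normal(8.5, 1, 20)])}
        cm = make_matrix(values, ["benign"] * 20 + ["malignant"] * 20)
        _, scores = select_by_loocv(cm)
        cut = scores["mid"]
        assert 0.6 < cut < 1.0
        # with the cut set at the exact achieved score, the probe is excluded
        selected, _ = select_by_loocv(cm, config=SelectionConfig(loocv_cut=cut))
        assert "mid" not in selected
        selected, _ = select_by_loocv(cm)
        assert "mid" in selected

    def test_strong_marker_passes(self, rng):
        values = {
            "null": rng.normal(8, 1, 40),
            "strong": np.concatenate([rng.normal(7, 1, 20), rng.normal(10, 1, 20)]),
        }
        cm = make_matrix(values, ["benign"] * 20 + ["malignant"] * 20)
        selected, scores = select_by_loocv(cm)
        assert "strong" in selected
        assert scores["strong"] > 0.6


def brute_force_average_linkage(points):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = lambda i, j: float(np.linalg.norm(points[i] - points[j]))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = np.mean([d(i, j) for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestStepwiseScreen:
    def three_group_matrix(self, rows):
        groups = ["healthy"] * 3 + ["benign"] * 3 + ["malignant"] * 3
        return make_matrix(rows, groups, cohort="training")

    def test_monotone_cluster_returned(self):
        rows = {
            "up1": [0, 0, 0, 1, 1, 1, 2, 2, 2],
            "up2": [0.1, 0, 0, 1.1, 1, 1, 2.1, 2, 2],
        }
        cm = self.three_group_matrix(rows)
        res = stepwise_cluster_screen(cm, config=SelectionConfig(n_clusters=1))
        assert res.increasing == ["up1", "up2"]
        assert res.decreasing == []

    def test_non_monotone_cluster_excluded(self):
        rows = {"vee": [2, 2, 2, 1, 1, 1, 2, 2, 2]}
        cm = self.three_group_matrix({**rows, "flat": [1] * 9})
        res = stepwise_cluster_screen(cm, config=SelectionConfig(n_clusters=2))
        assert "vee" not in res.increasing

    def test_decreasing_reported_separately(self):
        rows = {
            "down": [2, 2, 2, 1, 1, 1, 0, 0, 0],
            "up": [0, 0, 0, 1, 1, 1, 2, 2, 2],
        }
        cm = self.three_group_matrix(rows)
        res = stepwise_cluster_screen(cm, config=SelectionConfig(n_clusters=2))
        assert res.increasing == ["up"]
        assert res.decreasing == ["down"]

    def test_too_many_clusters_is_an_error(self):
        cm = self.three_group_matrix({"a": [0] * 9, "b": [1] * 9})
        with pytest.raises(SelectionError, match="n_clusters"):
            stepwise_cluster_screen(cm, config=SelectionConfig(n_clusters=5))

    def test_hand_dendrogram_one_dimensional(self):
        # profiles at coordinates 0, 1, 5: merge {0,1} at height 1, then with
        # {5} at height mean(5, 4) = 4.5
        Z = linkage(np.array([[0.0], [1.0], [5.0]]), method="average", metric="euclidean")
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.5)

    def test_average_linkage_matches_brute_force(self, rng):
        for _ in range(5):
            points = rng.normal(size=(rng.integers(4, 12), 6))
            Z = linkage(points, method="average", metric="euclidean")
            assert np.allclose(sorted(Z[:, 2]), brute_force_average_linkage(points))


class TestDifferentialScreen:
    def test_hand_t_example_retained(self):
        expr = pd.DataFrame({"p": [1, 2, 3, 4, 5, 6]}).T
        expr.columns = [f"S{i}" for i in range(6)]
        y = [0, 0, 0, 1, 1, 1]
        # pooled SD 1, t = -3.674 on 4 df, p ~ 0.0213, malignant higher
        assert differential_screen(expr, y) == ["p"]

    def test_identical_groups_excluded(self):
        expr = pd.DataFrame({"p": [2.0, 3.0, 4.0, 2.0, 3.0, 4.0]}).T
        assert differential_screen(expr, [0, 0, 0, 1, 1, 1]) == []

    def test_direction_gate(self):
        expr = pd.DataFrame({"p": [4, 5, 6, 1, 2, 3]}).T
        assert differential_screen(expr, [0, 0, 0, 1, 1, 1]) == []

    def test_zero_variance_conventions(self):
        equal = pd.DataFrame({"p": [2.0] * 6}).T
        assert differential_screen(equal, [0, 0, 0, 1, 1, 1]) == []
        jump = pd.DataFrame({"p": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]}).T
        assert differential_screen(jump, [0, 0, 0, 1, 1, 1]) == ["p"]

    def test_nonpositive_values_rejected(self):
        expr = pd.DataFrame({"p": [0.0, 1, 2, 3, 4, 5]}).T
        with pytest.raises(SelectionError, match="> 0"):
            differential_screen(expr, [0, 0, 0, 1, 1, 1])

    def test_null_retention_near_alpha_over_two(self, rng):
        # approximately normal positive expression keeps the t-test calibrated
        expr = pd.DataFrame(
            rng.normal(20, 2, size=(1000, 120)),
            index=[f"p{i}" for i in range(1000)],
        )
        y = np.array([0] * 60 + [1] * 60)
        kept = differential_screen(expr, y)
        assert 0.010 <= len(kept) / 1000 <= 0.040


@pytest.mark.parametrize("malignant_shift, floor", [(2.0, 0.75), (3.0, 0.85)])
def test_planted_marker_loocv_score_tracks_effect_size(malignant_shift, floor):
    """A marker shifted by d log2 units at SD 1 separates malignant from
    benign with LOOCV accuracy concentrating near Phi(d/2): about 0.84 at
    d = 2 and 0.93 at d = 3."""
    from seromir.synthetic import CohortSpec, PlantedMarker

    spec = CohortSpec(
        n_healthy=0, n_benign=100, n_malignant=100, n_mirna=20, seed=1,
        planted_markers=(PlantedMarker("miR-X", 0.0, malignant_shift),),
    )
    study = generate_cohort(spec)
    cm, _ = preprocess_cohort(study.scans, study.metadata)
    y = (cm.groups == "malignant").astype(int)
    score = loocv_marker_score(cm.matrix.loc["miR-X"].to_numpy(), y)
    assert score > floor


def test_funnel_is_monotone_on_synthetic_study(small_planted_spec):
    study = generate_cohort(small_planted_spec)
    cm, _ = preprocess_cohort(study.scans, study.metadata)
    discovery = cm.subset_samples(cm.cohorts == "discovery")
    training = cm.subset_samples(
        (cm.cohorts == "training") & np.isin(cm.groups, ("healthy", "benign", "malignant"))
    )
    tr_mb = training.subset_samples(np.isin(training.groups, ("benign", "malignant")))
    expr = generate_qpcr_matrix(small_planted_spec, tr_mb.samples, list(cm.matrix.index))
    result = run_selection(discovery, training, expr, (tr_mb.groups == "malignant").astype(int))
    assert set(result.loocv_pass) <= set(result.abundant)
    assert set(result.stepwise_pass) <= set(result.loocv_pass)
    assert set(result.differential_pass) <= set(result.stepwise_pass)
    assert {"miR-A", "miR-B", "miR-C"} <= set(result.differential_pass)
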
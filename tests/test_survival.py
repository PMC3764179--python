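"""Two-miRNA clustering, Kaplan-Meier estimation, and the log-rank test.

Oracles: exhaustive 2-partition search for 1-D k-means, hand computation of
the product-limit estimator, and a from-scratch O/E/V tabulation for the
log-rank statistic.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsubnet.survival import (
    cluster_two_mirnas,
    compare_groups,
    exhaustive_two_means_1d,
    km_curve,
    logrank,
)


def patients_frame(expr_a, expr_b, time=None, event=None):
    n = len(expr_a)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "expr_a": expr_a,
            "expr_b": expr_b,
            "time": time if time is not None else np.ones(n),
            "event": event if event is not None else np.ones(n, dtype=int),
        }
    )


def logrank_by_hand(times, events, groups):
    """Observed-minus-expected chi-square with hypergeometric variance,
    tabulated at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    observed = expected = variance = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        deaths = (times == t) & (events == 1)
        n_total, d_total = at_risk.sum(), deaths.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = (deaths & (groups == labels[0])).sum()
        observed += d1
        expected += d_total * n1 / n_total
        if n_total > 1:
            variance += (
                d_total
                * (n1 / n_total)
                * (1 - n1 / n_total)
                * (n_total - d_total)
                / (n_total - 1)
            )
    return (observed - expected) ** 2 / variance


class TestClusterTwoMirnas:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = np.concatenate([rng.normal(5, 0.3, 20), rng.normal(-5, 0.3, 20)])
        b = np.concatenate([rng.normal(-5, 0.3, 20), rng.normal(5, 0.3, 20)])
        labels = cluster_two_mirnas(patients_frame(a, b), seed=0)
        assert list(labels) == [1] * 20 + [2] * 20

    def test_matches_exhaustive_partition_in_1d(self):
        values = np.array([0.1, 0.3, 0.2, 5.0, 5.3, 4.8])
        frame = patients_frame(values, np.zeros_like(values))
        labels = cluster_two_mirnas(frame, seed=1, standardize=False)
        oracle = exhaustive_two_means_1d(values)
        assert list(labels) == list(oracle)

    def test_duplicated_patients_get_identical_labels(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(size=15)
        frame = patients_frame(np.tile(a, 2), np.tile(b, 2))
        labels = cluster_two_mirnas(frame, seed=3)
        assert list(labels[:15]) == list(labels[15:])

    def test_group_one_has_higher_mean_expr_a(self):
        rng = np.random.default_rng(4)
        a = np.concatenate([rng.normal(-3, 0.5, 10), rng.normal(3, 0.5, 10)])
        b = rng.normal(size=20)
        labels = cluster_two_mirnas(patients_frame(a, b), seed=0)
        assert a[labels == 1].mean() > a[labels == 2].mean()

    def test_identical_points_rejected(self):
        frame = patients_frame(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="identical"):
            cluster_two_mirnas(frame, seed=0)


class TestKMCurve:
    def test_no_events_flat_at_one(self):
        curve = km_curve([3.0, 5.0, 7.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_three_uncensored_events(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        steps = dict(zip(curve.times, curve.survival))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_single_event_steps_to_zero(self):
        curve = km_curve([5.0], [1])
        assert curve.survival[0] == 1.0  # S(0)
        assert curve.survival[-1] == 0.0

    def test_censoring_between_events(self):
        # hand computation: deaths at 1 (5 at risk) and 4 (3 at risk)
        curve = km_curve([1.0, 2.0, 4.0, 4.5, 6.0], [1, 0, 1, 0, 0])
        steps = dict(zip(curve.times, curve.survival))
        assert steps[1.0] == pytest.approx(4 / 5)
        assert steps[4.0] == pytest.approx(4 / 5 * 2 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [1, 1])

    @given(
        times=st.lists(
            st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=30
        ),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_curve_invariants(self, times, data):
        events = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=1),
                min_size=len(times),
                max_size=len(times),
            )
        )
        curve = km_curve(times, events)
        assert curve.survival[0] <= 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((0.0 <= curve.survival) & (curve.survival <= 1.0))


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0] * 2
        events = [1, 1, 0] * 2
        groups = [1, 1, 1, 2, 2, 2]
        result = logrank(times, events, groups)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.pvalue == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        times = [2.0, 3.0, 5.0, 7.0, 8.0, 11.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = [1, 2, 1, 2, 1, 2]
        result = logrank(times, events, groups)
        assert result.statistic == pytest.approx(
            logrank_by_hand(times, events, groups), rel=1e-9
        )
        assert result.df == 1

    def test_tied_event_times_match_hand_tabulation(self):
        times = [4.0, 4.0, 4.0, 6.0, 6.0, 9.0, 9.0, 12.0]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [1, 2, 1, 1, 2, 2, 1, 2]
        result = logrank(times, events, groups)
        assert result.statistic == pytest.approx(
            logrank_by_hand(times, events, groups), rel=1e-9
        )

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        groups = rng.integers(1, 3, 40)
        if len(np.unique(groups)) < 2:  # pragma: no cover
            groups[0], groups[1] = 1, 2
        a = logrank(times, events, groups)
        b = logrank(times, events, 3 - groups)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2.0], [1, 1], [1, 1])
        with pytest.raises(ValueError):
            logrank([1.0, 2.0, 3.0], [1, 1, 1], [1, 2, 3])


class TestCompareGroups:
    def test_end_to_end_on_synthetic_patients(self, planted_bundle):
        patients = planted_bundle.patients
        labels = cluster_two_mirnas(patients, seed=0)
        result = compare_groups(patients, labels)
        assert set(result["group_sizes"]) == {1, 2}
        assert sum(result["group_sizes"].values()) == len(patients)
        assert 0.0 < result["logrank"].pvalue <= 1.0
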
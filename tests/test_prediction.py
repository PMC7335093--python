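"""Score aggregation, correlation and permutation inference."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import fiberfilter as ff
from fiberfilter.connectivity import IncidenceMatrix
from fiberfilter.formats import CohortTable, StimulationRecord
from fiberfilter.prediction import AggregateScores
from fiberfilter.volumes import make_grid, sphere_mask


def _cohort(amplitudes, improvements):
    grid = make_grid((8, 8, 8), 1.0)
    mask = sphere_mask(np.zeros(3), 1.5, grid)
    recs = [
        StimulationRecord(f"s{i}", f"p{i}", "c", [mask], float(a), float(y))
        for i, (a, y) in enumerate(zip(amplitudes, improvements))
    ]
    return CohortTable(recs)


def _model(ts, valid=None):
    ts = np.asarray(ts, dtype=float)
    valid = np.ones(len(ts), bool) if valid is None else np.asarray(valid)
    ts = np.where(valid, ts, 0.0)
    return ff.FiberScoreModel(np.arange(len(ts)), ts, (valid * 4).astype(int), valid, 2, 10)


def _inc(entries):
    entries = np.asarray(entries, dtype=bool)
    return IncidenceMatrix(
        entries, np.arange(entries.shape[0]), [f"s{j}" for j in range(entries.shape[1])]
    )


# -- aggregation -------------------------------------------------------------


def test_aggregate_arithmetic_and_amplitude_normalization():
    inc = _inc([[1], [1], [0]])
    model = _model([2.0, -1.0, 5.0])
    cohort = _cohort([2.0], [10.0])
    agg = ff.aggregate_scores(inc, model, cohort)
    assert agg.raw_sum[0] == pytest.approx(1.0)
    assert agg.score[0] == pytest.approx(0.5)

    double = _cohort([4.0], [10.0])
    assert ff.aggregate_scores(inc, model, double).score[0] == pytest.approx(0.25)


def test_stimulation_with_no_valid_fiber_scores_zero():
    inc = _inc([[1], [1]])
    model = _model([3.0, -2.0], valid=[False, False])
    agg = ff.aggregate_scores(inc, model, _cohort([2.0], [10.0]))
    assert agg.score[0] == 0.0


def test_invalid_fibers_never_contribute():
    inc = _inc([[1], [1]])
    model = _model([3.0, 100.0], valid=[True, False])
    agg = ff.aggregate_scores(inc, model, _cohort([1.0], [10.0]))
    assert agg.raw_sum[0] == pytest.approx(3.0)


def test_score_additivity_in_model_weights():
    rng = np.random.default_rng(0)
    entries = rng.random((50, 6)) < 0.4
    inc = _inc(entries)
    cohort = _cohort(rng.uniform(1, 4, 6), rng.normal(30, 10, 6))
    t1, t2 = rng.normal(size=50), rng.normal(size=50)
    a1 = ff.aggregate_scores(inc, _model(t1), cohort)
    a2 = ff.aggregate_scores(inc, _model(t2), cohort)
    a12 = ff.aggregate_scores(inc, _model(t1 + t2), cohort)
    assert np.allclose(a12.raw_sum, a1.raw_sum + a2.raw_sum)


def test_unconnected_extra_fibers_change_no_score():
    rng = np.random.default_rng(1)
    entries = rng.random((40, 6)) < 0.4
    cohort = _cohort(rng.uniform(1, 4, 6), rng.normal(30, 10, 6))
    t = rng.normal(size=40)
    base = ff.aggregate_scores(_inc(entries), _model(t), cohort)
    padded_entries = np.vstack([entries, np.zeros((10, 6), bool)])
    padded_t = np.concatenate([t, rng.normal(size=10)])
    padded = ff.aggregate_scores(_inc(padded_entries), _model(padded_t), cohort)
    assert np.allclose(base.score, padded.score)


# -- correlation -------------------------------------------------------------


def test_correlate_identity_and_negation():
    y = np.array([1.0, 4.0, 2.0, 8.0])
    assert ff.correlate(y, y) == pytest.approx(1.0)
    assert ff.correlate(-y, y) == pytest.approx(-1.0)


def test_correlate_hand_value():
    # {(1,2),(2,1),(3,3)}: centered cross product 1, sds sqrt(2) each -> 0.5
    assert ff.correlate(np.array([1.0, 2, 3]), np.array([2.0, 1, 3])) == pytest.approx(0.5)


def test_correlate_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="zero variance"):
        ff.correlate(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
    with pytest.raises(ValueError, match="at least 3"):
        ff.correlate(np.array([1.0, 2]), np.array([1.0, 2]))


def test_pearson_invariant_to_positive_affine_rescaling():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=12), rng.normal(size=12)
    r = ff.correlate(x, y)
    assert ff.correlate(3.2 * x + 7, y) == pytest.approx(r, abs=1e-12)
    assert ff.correlate(x, 0.5 * y - 40) == pytest.approx(r, abs=1e-12)


# -- permutation test --------------------------------------------------------


def test_perfect_association_reaches_resolution_floor():
    rng = np.random.default_rng(3)
    y = rng.normal(30, 10, 12)  # 12 distinct values
    res = ff.permutation_p(y.copy(), y, n_perm=1000, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_perm == pytest.approx(1.0 / 1001.0)


def test_permutation_p_is_deterministic_per_seed():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=15), rng.normal(size=15)
    r1 = ff.permutation_p(x, y, n_perm=500, seed=42)
    r2 = ff.permutation_p(x, y, n_perm=500, seed=42)
    r3 = ff.permutation_p(x, y, n_perm=500, seed=43)
    assert r1.p_perm == r2.p_perm
    assert r1.seed == 42 and r1.n_perm == 500
    assert r1.p_perm != r3.p_perm or r1.r == r3.r  # same r, p may coincide rarely


def test_null_rejection_rate_calibrated():
    """Independent scores/outcomes, 500 repetitions: rejection at 0.05
    stays within the binomial 99% interval [0.030, 0.072]."""
    rng = np.random.default_rng(5)
    rej = 0
    reps = 500
    for k in range(reps):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = ff.permutation_p(x, y, n_perm=500, seed=k)
        rej += res.p_perm < 0.05
    assert 0.030 <= rej / reps <= 0.072


def test_one_sided_alternatives_bracket_two_sided():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=15), rng.normal(size=15)
    p_two = ff.permutation_p(x, y, n_perm=1000, seed=1).p_perm
    p_gr = ff.permutation_p(x, y, n_perm=1000, seed=1, alternative="greater").p_perm
    p_le = ff.permutation_p(x, y, n_perm=1000, seed=1, alternative="less").p_perm
    assert min(p_gr, p_le) <= p_two


def test_spearman_matches_scipy_observed_statistic():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=15), rng.normal(size=15)
    res = ff.permutation_p(x, y, n_perm=200, seed=0, method="spearman")
    assert res.r == pytest.approx(stats.spearmanr(x, y).statistic)


# -- cross-prediction --------------------------------------------------------


def test_cross_predict_on_identical_cohorts_equals_in_sample(small_experiment):
    inc, cohort = small_experiment["inc_a"], small_experiment["cohort_a"]
    res = ff.cross_predict((inc, cohort), (inc, cohort), n_perm=200, seed=0)
    model = ff.fit_fiber_scores(inc, cohort.improvements)
    agg = ff.aggregate_scores(inc, model, cohort)
    assert res.r == pytest.approx(ff.correlate(agg, cohort.improvements))


def test_cross_predict_rejects_fiber_order_mismatch(small_experiment):
    inc_a = small_experiment["inc_a"]
    flipped = IncidenceMatrix(inc_a.entries[::-1], inc_a.fiber_ids[::-1], inc_a.stim_ids)
    with pytest.raises(ValueError, match="fiber order"):
        ff.cross_predict((inc_a, small_experiment["cohort_a"]),
                         (flipped, small_experiment["cohort_a"]), n_perm=200)


def test_train_test_firewall_mutating_test_outcomes(small_experiment):
    """The fitted weights depend on the training cohort only."""
    inc_a, cohort_a = small_experiment["inc_a"], small_experiment["cohort_a"]
    inc_b, cohort_b = small_experiment["inc_b"], small_experiment["cohort_b"]
    model_before = ff.fit_fiber_scores(inc_a, cohort_a.improvements)
    mutated = CohortTable(
        [
            StimulationRecord(r.stim_id, r.patient_id, r.cohort, r.masks, r.amplitude,
                              r.improvement_pct + 1000.0)
            for r in cohort_b
        ],
        name=cohort_b.name,
    )
    ff.cross_predict((inc_a, cohort_a), (inc_b, mutated), n_perm=200, seed=0)
    model_after = ff.fit_fiber_scores(inc_a, cohort_a.improvements)
    assert np.array_equal(model_before.t_values, model_after.t_values)


# -- subgroup comparison -----------------------------------------------------


def _result(scores, improvements):
    agg = AggregateScores([f"s{i}" for i in range(len(scores))],
                          np.asarray(scores, float), np.asarray(scores, float))
    return ff.PredictionResult(0.0, 1.0, 100, "pearson", 0, agg,
                               np.asarray(improvements, float))


def test_low_high_comparison_hand_value():
    # low improvements {10,20} vs high {30,40}: pooled t = -2.8284 (low minus high)
    res = _result([1.0, 2.0, 10.0, 11.0], [10.0, 20.0, 30.0, 40.0])
    t, p, sizes = ff.low_high_comparison(res, cutoff=5.0)
    assert t == pytest.approx(-2.0 * np.sqrt(2.0), abs=1e-12)
    assert sizes == (2, 2)
    assert 0 < p < 1


def test_low_high_comparison_zero_when_groups_identical():
    res = _result([1.0, 2.0, 10.0, 11.0], [25.0, 30.0, 25.0, 30.0])
    t, _, _ = ff.low_high_comparison(res, cutoff=5.0)
    assert t == pytest.approx(0.0, abs=1e-12)


def test_low_high_comparison_bad_cutoff_reports_range():
    res = _result([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
    with pytest.raises(ValueError, match="cutoff"):
        ff.low_high_comparison(res, cutoff=0.5)
    with pytest.raises(ValueError, match="cutoff"):
        ff.low_high_comparison(res, cutoff=99.0)


def test_prediction_result_serializes_to_json(tmp_path, small_experiment):
    inc, cohort = small_experiment["inc_a"], small_experiment["cohort_a"]
    model = ff.fit_fiber_scores(inc, cohort.improvements)
    agg = ff.aggregate_scores(inc, model, cohort)
    res = ff.permutation_p(agg, cohort.improvements, n_perm=200, seed=0)
    res.to_json(tmp_path / "pred.json")
    import json

    payload = json.loads((tmp_path / "pred.json").read_text())
    assert payload["r"] == res.r
    assert payload["stim_ids"] == cohort.stim_ids
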
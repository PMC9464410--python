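"""Design analysis: binomial worked example, BFDA mechanics, calibration."""

import numpy as np
import pytest
from scipy import stats

import survbma as sb
from survbma.design import (
    DesignAnalysisResult,
    DesignSpec,
    _rep_plan,
    binomial_misleading_rate,
    binomial_point_bf,
    calibrate_fixed,
    calibrate_sequential,
    fixed_n_bfda,
    misleading_rates,
    sequential_bfda,
    simulate_trial,
)
from survbma.models import testing_ensemble as make_testing_ensemble


# ----------------------------------------------------------- binomial example


@pytest.mark.parametrize(
    "theta_alt, expected",
    [(0.6, 2.75), (0.7, 5.31)],
)
def test_binomial_bf_for_eight_of_ten(theta_alt, expected):
    assert binomial_point_bf(8, 10, theta_alt, 0.5) == pytest.approx(expected, abs=0.005)


def test_binomial_bf_identity_cases():
    assert binomial_point_bf(4, 10, 0.5, 0.5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        binomial_point_bf(11, 10, 0.6, 0.5)


def test_binomial_misleading_rate_enumeration():
    # brute-force over all 11 outcomes: BF >= 5 at k in {8, 9, 10} for theta=0.7
    assert binomial_misleading_rate(0.7, 0.5, 10, 5.0) == pytest.approx(56 / 1024)
    # for theta=0.6 only k=10 reaches BF >= 5
    assert binomial_misleading_rate(0.6, 0.5, 10, 5.0) == pytest.approx(1 / 1024)
    assert binomial_misleading_rate(0.7, 0.5, 10, 1e9) == 0.0


# ------------------------------------------------------------ trial simulation


def test_simulate_trial_deterministic(prior_table):
    spec = DesignSpec(reps=10, seed=1, n_total=200)
    gen = make_testing_ensemble(prior_table)[7]
    a = simulate_trial(gen, spec, rep_seed=5)
    b = simulate_trial(gen, spec, rep_seed=5)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.events, b.events)


def test_simulate_trial_tiny_horizon_censors_everything(prior_table):
    spec = DesignSpec(reps=10, seed=1, n_total=100, horizon=1e-6, interval=1e-6)
    gen = make_testing_ensemble(prior_table)[0]
    ds = simulate_trial(gen, spec, rep_seed=2)
    assert ds.n_events == 0
    assert np.all(ds.times == 1e-6)


def test_null_generating_models_are_arm_symmetric(prior_table):
    """Under H0 both arms have the same event rate up to binomial noise."""
    spec = DesignSpec(reps=10, seed=3, n_total=400)
    gens = [m for m in make_testing_ensemble(prior_table) if m.is_null]
    diffs = []
    for rep in range(50):
        ds = simulate_trial(gens[rep % 5], spec, rep_seed=900 + rep)
        p0 = ds.events[ds.arms == 0].mean()
        p1 = ds.events[ds.arms == 1].mean()
        diffs.append(p1 - p0)
    # mean difference across reps should be ~0 within MC error
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se


def test_rep_plan_equal_split_and_validation():
    spec = DesignSpec(reps=10, seed=0)
    plan = _rep_plan(spec, "h0")
    names = [g.name for g, _ in plan]
    assert len(plan) == 10
    assert all(n.endswith("[null]") for n in names)
    assert len(set(names)) == 5
    with pytest.raises(ValueError):
        _rep_plan(DesignSpec(reps=7, seed=0), "h0")


# ---------------------------------------------------------------- fixed-n BFDA


@pytest.fixture(scope="module")
def tiny_fixed_run():
    """A deliberately small fixed-n BFDA used for mechanical checks."""
    return fixed_n_bfda(DesignSpec(reps=10, seed=17, n_total=300, horizon=1825.0))


def test_fixed_bfda_single_rep_is_finite():
    res = fixed_n_bfda(DesignSpec(reps=5, seed=2, n_total=100))
    assert res.h0_bfs.shape == (5,)
    assert np.all(np.isfinite(res.h0_bfs)) and np.all(res.h0_bfs > 0)


def test_misleading_rates_complement_identity(tiny_fixed_run):
    """At bound 1 the error rates are the complements of the correct-call rates."""
    rates = misleading_rates(tiny_fixed_run, 1.0, 1.0)
    assert rates["false_positive"] == pytest.approx(
        1.0 - np.mean(tiny_fixed_run.h0_bfs < 1.0)
    )
    assert rates["false_negative"] == pytest.approx(
        1.0 - np.mean(tiny_fixed_run.h1_bfs > 1.0)
    )


def test_misleading_rates_trivial_cases():
    res = DesignAnalysisResult(
        design=DesignSpec(reps=5, seed=0),
        kind="fixed",
        h0_bfs=np.ones(5),
        h1_bfs=np.ones(5),
    )
    rates = misleading_rates(res, 10.0, 10.0)
    assert rates["false_positive"] == 0.0
    assert rates["false_negative"] == 0.0
    with pytest.raises(ValueError):
        misleading_rates(res, 0.5, 10.0)


def test_rate_monotonicity_in_bounds(tiny_fixed_run):
    """Widening the decision bounds can only reduce misleading-evidence rates."""
    prev_fp, prev_fn = 1.0, 1.0
    for bound in (1.0, 2.0, 5.0, 10.0, 50.0):
        rates = misleading_rates(tiny_fixed_run, bound, bound)
        assert rates["false_positive"] <= prev_fp + 1e-12
        assert rates["false_negative"] <= prev_fn + 1e-12
        prev_fp, prev_fn = rates["false_positive"], rates["false_negative"]


def test_calibrate_fixed_quantile_oracle():
    h0 = np.array([0.1, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
    h1 = np.array([0.01, 0.05, 0.2, 0.5, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
    res = DesignAnalysisResult(
        design=DesignSpec(reps=10, seed=0), kind="fixed", h0_bfs=h0, h1_bfs=h1
    )
    out = calibrate_fixed(res, alpha=0.05, beta=0.10)
    assert out["bf10_bound"] == pytest.approx(np.quantile(h0, 0.95))
    assert out["bf01_bound"] == pytest.approx(1.0 / np.quantile(h1, 0.10))
    extreme = calibrate_fixed(res, alpha=0.0, beta=0.10)
    assert extreme["bf10_bound"] == pytest.approx(h0.max())


def test_evidence_accumulates_with_sample_size(prior_table):
    """Under H1 the mean log inclusion BF grows with the number of participants."""
    means = []
    for n in (250, 1000, 2070):
        res = fixed_n_bfda(DesignSpec(reps=30, seed=23, n_total=n))
        means.append(np.mean(np.log(res.h1_bfs)))
    assert means[0] < means[1] < means[2]


# -------------------------------------------------------------- sequential BFDA


@pytest.fixture(scope="module")
def tiny_sequential_run():
    # wide stop range so trajectories are computed at every look
    return sequential_bfda(
        DesignSpec(
            reps=5, seed=29, n_total=300, horizon=360.0, interval=90.0,
            compute_stop_range=(1e-12, 1e12),
        )
    )


def test_sequential_final_look_equals_fixed_analysis(tiny_sequential_run, prior_table):
    """Without early freezing the last look is the fixed-n analysis of the data."""
    from survbma.design import _ensemble_bf10

    spec = tiny_sequential_run.design
    analysis = make_testing_ensemble(spec.prior_table)
    prior_probs = np.array([m.prior_prob for m in analysis])
    alt = [i for i, m in enumerate(analysis) if not m.is_null]
    gens = {m.name: m for m in analysis}
    for scenario, meta, trajs in (
        ("h0", tiny_sequential_run.h0_meta, tiny_sequential_run.h0_trajectories),
        ("h1", tiny_sequential_run.h1_meta, tiny_sequential_run.h1_trajectories),
    ):
        for row, traj in zip(meta.itertuples(), trajs):
            ds = simulate_trial(gens[row.generating_model], spec, row.rep_seed)
            bf, _ = _ensemble_bf10(ds, analysis, prior_probs, alt)
            assert traj[-1] == pytest.approx(bf, rel=1e-6)


def test_sequential_trajectory_shape(tiny_sequential_run):
    spec = tiny_sequential_run.design
    n_looks = int(spec.horizon // spec.interval)
    for traj in tiny_sequential_run.h0_trajectories:
        assert traj.size == n_looks
        assert np.all(np.isfinite(traj))


def test_freezing_carries_last_value_forward():
    res = sequential_bfda(
        DesignSpec(reps=5, seed=31, n_total=300, horizon=360.0, interval=90.0,
                   compute_stop_range=(1.0 / 2.0, 2.0))
    )
    lo, hi = 0.5, 2.0
    for traj in res.h0_trajectories + res.h1_trajectories:
        out = np.where((traj <= lo) | (traj >= hi))[0]
        if out.size:
            first = out[0]
            np.testing.assert_allclose(traj[first:], traj[first])


def test_calibrate_sequential_self_consistency(tiny_sequential_run):
    bounds = calibrate_sequential(tiny_sequential_run, alpha=0.2, beta=0.2)
    rates = misleading_rates(
        tiny_sequential_run, bounds["bf10_bound"], bounds["bf01_bound"]
    )
    assert rates["false_positive"] <= 0.2 + 1e-9
    assert rates["false_negative"] <= 0.2 + 1e-9


def test_calibrate_sequential_toy_trajectories():
    toy = DesignAnalysisResult(
        design=DesignSpec(reps=5, seed=0),
        kind="sequential",
        h0_bfs=np.ones(5),
        h1_bfs=np.ones(5),
        h0_trajectories=[np.array([1.0, 1.5, 1.9])] * 5,
        h1_trajectories=[np.array([1.0, 0.5, 0.2])] * 5,
        look_times=np.array([30.0, 60.0, 90.0]),
    )
    bounds = calibrate_sequential(toy, alpha=0.05, beta=0.10)
    assert bounds["bf10_bound"] <= 2.0
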
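import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stablevar as sv
from stablevar.inference import ScenarioSpec, aicc, delta_model


def make_series(delta0=0.5, r2=0.25, tau=55.0, times=None, noise_sd=0.0, seed=0,
                experiment_id="exp1", population_id="pop1"):
    if times is None:
        times = np.array([0.0, 10, 25, 50, 100, 150, 220, 300])
    delta = np.asarray(delta_model(times, delta0, r2, tau), dtype=float)
    if noise_sd:
        delta = delta + np.random.default_rng(seed).normal(0, noise_sd, times.size)
    return sv.DeltaSeries(times=times, delta=delta,
                          experiment_id=experiment_id, population_id=population_id)


class TestComputeDelta:
    def test_difference_and_normalisation(self):
        h = pd.DataFrame({"t": [0.0, 1.0], "mean_log": [1.0, 0.8]})
        l = pd.DataFrame({"t": [0.0, 1.0], "mean_log": [0.5, 0.675]})
        ds = sv.compute_delta(h, l)
        np.testing.assert_allclose(ds.delta, [0.5, 0.125])
        np.testing.assert_allclose(ds.omega, [1.0, 0.25])

    def test_replicates_are_averaged_per_time(self):
        h = pd.DataFrame({"t": [0.0, 0.0, 1.0, 1.0], "mean_log": [1.0, 1.2, 0.9, 1.1]})
        l = pd.DataFrame({"t": [0.0, 0.0, 1.0, 1.0], "mean_log": [0.4, 0.6, 0.5, 0.5]})
        ds = sv.compute_delta(h, l)
        np.testing.assert_allclose(ds.delta, [0.6, 0.5])

    def test_identical_series_rejected(self):
        h = pd.DataFrame({"t": [0.0, 1.0], "mean_log": [1.0, 0.8]})
        with pytest.raises(ValueError, match="non-zero"):
            sv.compute_delta(h, h.copy())

    def test_mismatched_grids_rejected(self):
        h = pd.DataFrame({"t": [0.0, 1.0], "mean_log": [1.0, 0.8]})
        l = pd.DataFrame({"t": [0.0, 2.0], "mean_log": [0.5, 0.4]})
        with pytest.raises(ValueError, match="time grid"):
            sv.compute_delta(h, l)

    def test_raw_mean_mode_uses_log_fold_ratio(self):
        h = pd.DataFrame({"t": [0.0, 1.0], "raw_mean": [4.0, 2.0]})
        l = pd.DataFrame({"t": [0.0, 1.0], "raw_mean": [1.0, 1.0]})
        ds = sv.compute_delta(h, l, from_raw_means=True)
        np.testing.assert_allclose(ds.delta, [math.log(4.0), math.log(2.0)])


class TestFitSingle:
    @pytest.mark.parametrize("delta0,r2,tau", [
        (0.5, 0.25, 55.0),
        (-0.4, 0.6, 20.0),
        (1.2, 0.05, 120.0),
    ])
    def test_noiseless_round_trip_recovers_parameters(self, delta0, r2, tau):
        ds = make_series(delta0, r2, tau)
        fit = sv.fit_single(ds, seed=1)
        assert fit.delta0["exp1"] == pytest.approx(delta0, rel=1e-5)
        assert fit.r2["pop1"] == pytest.approx(r2, abs=1e-5)
        assert fit.tau_T["pop1"] == pytest.approx(tau, rel=1e-4)

    def test_flat_series_pins_r2_at_one_and_flags_tau(self):
        ds = sv.DeltaSeries(times=np.array([0.0, 10, 20, 30]),
                            delta=np.full(4, 0.42))
        fit = sv.fit_single(ds, seed=2)
        assert fit.r2["pop1"] == pytest.approx(1.0, abs=1e-9)
        assert not fit.tau_defined["pop1"]
        assert "pop1" in fit.boundary_flags

    def test_requires_four_points(self):
        ds = sv.DeltaSeries(times=np.array([0.0, 1.0, 2.0]),
                            delta=np.array([0.5, 0.4, 0.3]))
        with pytest.raises(ValueError, match="4 time points"):
            sv.fit_single(ds)

    def test_delta0_sign_follows_data(self):
        ds = make_series(delta0=-0.7, r2=0.3, tau=40.0)
        fit = sv.fit_single(ds, seed=3)
        assert fit.delta0["exp1"] < 0

    def test_normalization_invariance_under_global_scaling(self):
        # Multiplying all raw intensities by a constant shifts every mean_log
        # by the same amount, leaving Delta and the fit untouched.
        t = np.array([0.0, 24, 48, 72, 96])
        h_mean = 1.0 + np.asarray(delta_model(t, 0.3, 0.4, 30.0))
        frame = []
        for cohort, means in (("high", h_mean), ("low", np.full(5, 1.0))):
            frame.append(pd.DataFrame({
                "experiment_id": "e", "population_id": "p", "cohort": cohort,
                "replicate": 0, "t": t, "mean_log": means, "n": 100,
            }))
        base = pd.concat(frame, ignore_index=True)
        shifted = base.assign(mean_log=base["mean_log"] + math.log(7.3))
        fit_a = sv.fit_single(sv.delta_from_summary(base)[0], seed=4)
        fit_b = sv.fit_single(sv.delta_from_summary(shifted)[0], seed=4)
        assert fit_a.r2["p"] == pytest.approx(fit_b.r2["p"], abs=1e-9)
        assert fit_a.tau_T["p"] == pytest.approx(fit_b.tau_T["p"], rel=1e-9)


class TestScenarios:
    def test_parameter_counts_for_two_populations_three_experiments(self):
        counts = [ScenarioSpec.from_id(i).param_count(6, 2) for i in (1, 2, 3, 4)]
        assert counts == [8, 9, 10, 18]

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec.from_id(5)

    def test_single_experiment_scenario4_reduces_to_fit_single(self):
        ds = make_series(0.5, 0.25, 55.0, noise_sd=0.01, seed=10)
        single = sv.fit_single(ds, seed=5)
        ens = sv.fit_ensemble([ds], 4, seed=5)
        assert ens.r2["exp1"] == pytest.approx(single.r2["pop1"], abs=1e-6)
        assert ens.tau_T["exp1"] == pytest.approx(single.tau_T["pop1"], rel=1e-4)

    def test_shared_tau_recovered_across_two_populations(self):
        # Two populations with distinct r2 but the same timescale: the
        # r2-per-population scenario recovers both r2 and the shared tau_T.
        series = []
        rng = np.random.default_rng(6)
        for pop, r2 in (("popA", 0.7), ("popB", 0.2)):
            for e in range(3):
                series.append(make_series(
                    0.5 + 0.1 * e, r2, 55.0,
                    times=np.array([0.0, 25, 50, 100, 175, 275]),
                    noise_sd=0.008, seed=int(rng.integers(2**31)),
                    experiment_id=f"{pop}_e{e}", population_id=pop,
                ))
        fit = sv.fit_ensemble(series, 2, seed=7)
        assert fit.r2["popA"] == pytest.approx(0.7, abs=0.05)
        assert fit.r2["popB"] == pytest.approx(0.2, abs=0.05)
        assert fit.tau_T["popA"] == fit.tau_T["popB"]
        assert fit.tau_T["popA"] == pytest.approx(55.0, rel=0.1)

    def test_equal_experiment_weighting_scales_residuals(self):
        # An experiment with many points should not dominate: its residuals
        # are scaled by 1/sqrt(n_e).
        dense = make_series(0.5, 0.3, 50.0, times=np.linspace(0, 300, 31),
                            experiment_id="dense")
        sparse = make_series(0.5, 0.3, 50.0,
                             times=np.array([0.0, 50, 150, 300.0]),
                             experiment_id="sparse")
        fit = sv.fit_ensemble([dense, sparse], 1, seed=8)
        # noiseless & consistent: joint fit still exact
        assert fit.r2["pop1"] == pytest.approx(0.3, abs=1e-5)


class TestAicc:
    def test_identical_fits_tie(self):
        assert aicc(0.5, 20, 3) == aicc(0.5, 20, 3)

    def test_extra_parameter_with_no_gain_scores_worse(self):
        assert aicc(0.1, 30, 10) > aicc(0.1001, 30, 9)

    def test_counts_residual_variance_as_extra_parameter(self):
        n, ssr, k = 30, 0.03, 9
        K = k + 1
        expected = n * math.log(ssr / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)
        assert aicc(ssr, n, k) == pytest.approx(expected)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(0.1, 5, 4)

    def test_compare_requires_matching_ensembles(self):
        a = sv.fit_single(make_series(), seed=1)
        b = sv.fit_single(make_series(times=np.array([0.0, 5, 10, 20, 40])), seed=1)
        with pytest.raises(ValueError, match="same ensemble"):
            sv.aicc_compare([a, b])


class TestBootstrap:
    def test_noiseless_data_gives_degenerate_interval(self):
        ds = make_series(0.5, 0.25, 55.0)
        res = sv.bootstrap_ci([ds], 1, n_boot=60, seed=9, starts=3)
        lo, hi = res["r2_ci"]["pop1"]
        assert hi - lo < 0.01

    def test_interval_width_shrinks_with_noise(self):
        widths = []
        for sd in (0.06, 0.01):
            series = [make_series(0.5, 0.4, 40.0, noise_sd=sd, seed=20 + i,
                                  experiment_id=f"e{i}") for i in range(3)]
            res = sv.bootstrap_ci(series, 1, n_boot=80, seed=10, starts=3)
            lo, hi = res["r2_ci"]["pop1"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_r2_interval_clipped_to_unit_range(self):
        series = [make_series(0.5, 0.02, 40.0, noise_sd=0.04, seed=30 + i,
                              experiment_id=f"e{i}") for i in range(3)]
        res = sv.bootstrap_ci(series, 1, n_boot=80, seed=11, starts=3)
        lo, hi = res["r2_ci"]["pop1"]
        assert 0.0 <= lo <= hi <= 1.0

    def test_replicate_level_unit_needs_summary(self):
        ds = make_series()
        with pytest.raises(ValueError, match="summary"):
            sv.bootstrap_ci([ds], 1, n_boot=10, seed=12, unit="replicate")


class TestTrackCohortVariance:
    def test_pure_stable_variance_time_invariant(self, pop_stable, t_grid):
        high = sv.isolate_cohort(pop_stable, sv.SortSpec.high(), seed=1)
        snaps = sv.evolve_cohorts([high], t_grid, seed=2)
        table = sv.track_cohort_variance(snaps)
        for _, rep in table.groupby("replicate"):
            assert rep["var_log"].std() < 1e-12

    def test_pure_unstable_high_cohort_variance_recovers(self, pop_unstable, t_grid):
        full_var = pop_unstable.log_x.var()
        high = sv.isolate_cohort(pop_unstable, sv.SortSpec.high(), seed=1)
        snaps = sv.evolve_cohorts([high], t_grid, seed=2)
        table = sv.track_cohort_variance(snaps).groupby("t")["var_log"].mean()
        assert table.loc[0.0] < 0.5 * full_var  # truncated at isolation
        assert table.iloc[-1] == pytest.approx(full_var, rel=0.15)

    def test_reference_cohort_variance_tracks_population(self, pop_quarter, t_grid):
        full_var = pop_quarter.log_x.var()
        ref = sv.isolate_cohort(pop_quarter, sv.SortSpec.reference(10.0), seed=3)
        snaps = sv.evolve_cohorts([ref], t_grid, seed=4)
        table = sv.track_cohort_variance(snaps).groupby("t")["var_log"].mean()
        assert np.allclose(table.values, full_var, rtol=0.1)


def test_fitted_model_satisfies_relaxation_time_identity():
    """Under the fitted model, 1 - Omega(tau_T) = (1 - 1/e)(1 - r2) exactly."""
    for r2 in (0.0, 0.25, 0.7):
        delta0, tau = 0.8, 33.0
        omega_at_tau = delta_model(tau, delta0, r2, tau) / delta0
        assert 1 - omega_at_tau == pytest.approx((1 - math.exp(-1)) * (1 - r2), rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    delta0=st.floats(0.05, 2.0),
    r2=st.floats(0.01, 0.99),
    tau=st.floats(5.0, 200.0),
)
def test_round_trip_identifiability(delta0, r2, tau):
    """Any noiseless series from the relaxation model is recovered exactly."""
    ds = make_series(delta0, r2, tau)
    fit = sv.fit_single(ds, starts=10, seed=13)
    assert fit.r2["pop1"] == pytest.approx(r2, abs=1e-4)
    assert fit.tau_T["pop1"] == pytest.approx(tau, rel=1e-3)
    assert fit.delta0["exp1"] == pytest.approx(delta0, rel=1e-4)
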
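"""Identification tests: RMSPE, grids, scans, staged fit contracts."""

import warnings

import numpy as np
import pytest

from plrkit import (
    ParamRange,
    PupilTrace,
    SearchSpace,
    StimulusSpec,
    random_initialize,
    rmspe,
    simulate_plr,
    staged_fit,
    univariate_search,
)
from plrkit.model import SEARCHED_PARAMETERS

ONSET = 5.0


def _trace(times, radii):
    return PupilTrace(np.asarray(times, float), np.asarray(radii, float))


class TestRmspe:
    def test_identity_is_zero(self):
        t = _trace([0, 1, 2], [3.0, 2.5, 2.8])
        assert rmspe(t, t) == 0.0

    def test_hand_computed_value(self):
        """X=(2,2), Y=(1,2): sqrt(0.25/(2-1)) = 0.5 -> 50%."""
        x = _trace([0, 1], [2.0, 2.0])
        y = _trace([0, 1], [1.0, 2.0])
        assert rmspe(x, y) == pytest.approx(50.0)

    def test_window_restriction(self):
        x = _trace([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0])
        y = _trace([0, 1, 2, 3], [1.0, 2.0, 2.0, 2.0])
        assert rmspe(x, y, window=(1.0, 3.5)) == 0.0
        assert rmspe(x, y, window=(0.0, 2.0)) > 0.0

    def test_window_is_half_open(self):
        x = _trace([0, 1, 2], [2.0, 2.0, 2.0])
        y = _trace([0, 1, 2], [2.0, 2.0, 1.0])
        assert rmspe(x, y, window=(0.0, 2.0)) == 0.0  # sample at t=2 excluded

    def test_needs_two_samples(self):
        x = _trace([0, 1, 2], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            rmspe(x, x, window=(0.0, 0.5))

    def test_mismatched_grids_rejected(self):
        x = _trace([0, 1, 2], [2.0, 2.0, 2.0])
        y = _trace([0, 0.5, 1.5], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="share the sample grid"):
            rmspe(x, y)


class TestSearchSpace:
    def test_grid_includes_both_bounds(self, search_space):
        for name in SEARCHED_PARAMETERS:
            g = search_space.grid(name)
            r = search_space.ranges[name]
            assert g[0] == pytest.approx(r.lower)
            assert g[-1] == pytest.approx(r.upper)
            assert np.allclose(np.diff(g), r.step)

    def test_snap_returns_nearest_grid_point(self):
        r = ParamRange(initial=0.5, lower=0.0, upper=1.0, step=0.25)
        assert r.snap(0.6) == 0.5
        assert r.snap(0.63) == 0.75

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ParamRange(initial=2.0, lower=0.0, upper=1.0, step=0.1)
        with pytest.raises(ValueError):
            ParamRange(initial=0.5, lower=0.0, upper=1.0, step=0.0)

    def test_narrowed_bounds_clip_to_base(self, search_space, reference_table):
        narrowed = search_space.narrowed(reference_table.at(0.01), fraction=0.2)
        for name in SEARCHED_PARAMETERS:
            b, n = search_space.ranges[name], narrowed.ranges[name]
            assert n.lower >= b.lower and n.upper <= b.upper
            assert n.lower <= n.initial <= n.upper


class TestUnivariateSearch:
    def test_single_parameter_grid_recovery(self, reference_table, time_grid, search_space):
        """A trace generated at a grid point of f_p0 is recovered exactly."""
        truth = reference_table.at(0.01)
        stim = StimulusSpec(ONSET, 0.01)
        measured = simulate_plr(truth, stim, time_grid)
        start = truth.replace(f_p0=9.0)
        fitted, converged, n = univariate_search(
            (ONSET, 15.0 + 1e-9), ["f_p0"], search_space, measured, stim, start
        )
        assert fitted.f_p0 == pytest.approx(truth.f_p0)
        assert converged and n == 1

    def test_already_minimal_returns_current(self, reference_table, time_grid, search_space):
        truth = reference_table.at(0.01)
        stim = StimulusSpec(ONSET, 0.01)
        measured = simulate_plr(truth, stim, time_grid)
        fitted, _, _ = univariate_search(
            (ONSET, 15.0 + 1e-9), ["f_p0"], search_space, measured, stim, truth
        )
        assert fitted.f_p0 == truth.f_p0

    def test_two_parameter_alternation_converges(self, reference_table, time_grid, search_space):
        truth = reference_table.at(0.01)
        stim = StimulusSpec(ONSET, 0.01)
        measured = simulate_plr(truth, stim, time_grid)
        start = truth.replace(tau_p1=0.25, f_p0=11.0)
        fitted, converged, n = univariate_search(
            (ONSET, ONSET + 0.4), ["tau_p1", "f_p0"], search_space, measured, stim, start
        )
        assert converged
        assert n <= 40
        assert fitted.tau_p1 == pytest.approx(truth.tau_p1)
        assert fitted.f_p0 == pytest.approx(truth.f_p0)

    def test_empty_free_params_rejected(self, reference_table, time_grid, search_space):
        truth = reference_table.at(0.01)
        stim = StimulusSpec(ONSET, 0.01)
        measured = simulate_plr(truth, stim, time_grid)
        with pytest.raises(ValueError):
            univariate_search((ONSET, 15.0), [], search_space, measured, stim, truth)


class TestRandomInitialize:
    def test_deterministic_given_seed(self, reference_traces, search_space):
        stim = StimulusSpec(ONSET, 0.5)
        measured = reference_traces[0.5]
        a = random_initialize(measured, stim, n_draws=20, seed=7)
        b = random_initialize(measured, stim, n_draws=20, seed=7)
        assert a == b

    def test_single_draw_is_returned(self, reference_traces):
        stim = StimulusSpec(ONSET, 0.5)
        space = random_initialize(reference_traces[0.5], stim, n_draws=1, seed=3)
        assert all(
            space.ranges[n].lower <= space.ranges[n].initial <= space.ranges[n].upper
            for n in SEARCHED_PARAMETERS
        )

    def test_best_draw_beats_median(self, reference_traces):
        stim = StimulusSpec(ONSET, 0.5)
        _, diag = random_initialize(
            reference_traces[0.5], stim, n_draws=50, seed=11, return_diagnostics=True
        )
        assert diag["rmspe"].min() <= diag["rmspe"].median()

    def test_rejects_zero_draws(self, reference_traces):
        with pytest.raises(ValueError):
            random_initialize(reference_traces[0.5], StimulusSpec(ONSET, 0.5), n_draws=0)


class TestStagedFit:
    def test_fitted_parameters_lie_on_grid(self, noiseless_fits, search_space):
        for fit in noiseless_fits.values():
            for name in SEARCHED_PARAMETERS:
                g = search_space.grid(name)
                assert np.min(np.abs(g - getattr(fit.params, name))) < 1e-9

    def test_stage_window_errors_reported(self, noiseless_fits):
        for fit in noiseless_fits.values():
            assert set(fit.rmspe_windows) == {"start", "constrict", "dilate", "all"}
            assert all(v >= 0 for v in fit.rmspe_windows.values())
            assert fit.rmspe_full >= 0

    def test_stage_rmspes_of_self_generated_traces_are_small(self, noiseless_fits):
        for fit in noiseless_fits.values():
            assert all(v < 0.7 for v in fit.rmspe_windows.values())

    def test_deterministic(self, reference_traces):
        stim = StimulusSpec(ONSET, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = staged_fit(reference_traces[0.5], stim)
            b = staged_fit(reference_traces[0.5], stim)
        assert a.params == b.params
        assert a.rmspe_full == b.rmspe_full

    def test_refit_of_own_simulation_is_idempotent(self, noiseless_fits, time_grid, search_space):
        """Starting a fit at a previously fitted vector leaves it unchanged."""
        fit = noiseless_fits[0.01]
        stim = StimulusSpec(ONSET, 0.01)
        own = simulate_plr(fit.params, stim, time_grid)
        ranges = {
            n: ParamRange(
                initial=getattr(fit.params, n),
                lower=search_space.ranges[n].lower,
                upper=search_space.ranges[n].upper,
                step=search_space.ranges[n].step,
            )
            for n in SEARCHED_PARAMETERS
        }
        refit = staged_fit(own, stim, space=SearchSpace(ranges), l0=fit.params.l0)
        assert refit.params == fit.params
        assert refit.rmspe_full < 1e-4

    def test_flat_trace_flagged_non_physiological(self, time_grid):
        flat = PupilTrace(time_grid, np.full(time_grid.size, 3.0))
        with pytest.warns(UserWarning):
            fit = staged_fit(flat, StimulusSpec(ONSET, 0.01), refine=False, max_cycles=1)
        assert fit.params.f_p0 == pytest.approx(8.0)  # driven to the lower bound

    def test_json_round_trip(self, noiseless_fits, tmp_path):
        fit = noiseless_fits[0.5]
        path = tmp_path / "fit.json"
        fit.to_json(path)
        from plrkit import FitResult

        loaded = FitResult.from_json(path)
        assert loaded.params == fit.params
        assert loaded.rmspe_full == pytest.approx(fit.rmspe_full)
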
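"""Staged grey-box system identification of the PLR model.

A measured pupil trace is fitted by a univariate (coordinate) search on
a fixed parameter grid: one parameter is scanned at a time over its
bounded grid, keeping the value that minimises a root-mean-square
percentage error (RMSPE) evaluated on a stage-specific time window.  The
stages follow the physiology of the reflex — parasympathetic onset
first, sympathetic recruitment second, dilation timing third, the late
sympathetic phase fourth, then a revisit of the dilation delay and
finally the elastic constants.  The viscous constant ``D`` is held fixed
throughout; the resting size ``l0`` is read off the pre-stimulus
baseline rather than searched.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    PLRParameters,
    PupilTrace,
    SEARCHED_PARAMETERS,
    SimulationError,
    StimulusSpec,
    find_t_dcm,
    simulate_plr,
)

__all__ = [
    "ParamRange",
    "SearchSpace",
    "FitResult",
    "rmspe",
    "random_initialize",
    "univariate_search",
    "staged_fit",
    "viscous_sweep",
]

log = logging.getLogger(__name__)

_GRID_DECIMALS = 6  # grids are rounded so that repeated scans compare exactly


@dataclass(frozen=True)
class ParamRange:
    """Initial value, bounds and grid step for one searched parameter."""

    initial: float
    lower: float
    upper: float
    step: float

    def __post_init__(self):
        if not (self.lower <= self.initial <= self.upper):
            raise ValueError(
                f"initial {self.initial} outside bounds [{self.lower}, {self.upper}]"
            )
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    def grid(self) -> np.ndarray:
        """Ascending grid from lower to upper, inclusive of both bounds."""
        n = int(np.floor((self.upper - self.lower) / self.step + 1e-9))
        pts = self.lower + self.step * np.arange(n + 1)
        if pts[-1] < self.upper - 1e-9:
            pts = np.append(pts, self.upper)
        return np.round(pts, _GRID_DECIMALS)

    def snap(self, value: float) -> float:
        """Nearest grid point (ties toward the smaller value)."""
        g = self.grid()
        return float(g[int(np.argmin(np.abs(g - value)))])


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter :class:`ParamRange` table plus the fixed viscous constant."""

    ranges: Mapping[str, ParamRange]
    d_value: float = 4.3

    def __post_init__(self):
        missing = set(SEARCHED_PARAMETERS) - set(self.ranges)
        if missing:
            raise ValueError(f"search space missing parameters: {sorted(missing)}")

    def grid(self, name: str) -> np.ndarray:
        return self.ranges[name].grid()

    def snap_params(self, params: PLRParameters) -> PLRParameters:
        return params.replace(
            **{n: self.ranges[n].snap(getattr(params, n)) for n in SEARCHED_PARAMETERS}
        )

    def contains(self, params: PLRParameters, tol: float = 1e-9) -> bool:
        return all(
            self.ranges[n].lower - tol <= getattr(params, n) <= self.ranges[n].upper + tol
            for n in SEARCHED_PARAMETERS
        )

    def clip(self, name: str, value: float) -> float:
        r = self.ranges[name]
        return float(min(max(value, r.lower), r.upper))

    def narrowed(self, center: PLRParameters, fraction: float = 0.2) -> "SearchSpace":
        """Bounds tightened to ±``fraction`` around ``center`` (clipped to self)."""
        new = {}
        for n in SEARCHED_PARAMETERS:
            r, c = self.ranges[n], getattr(center, n)
            new[n] = ParamRange(
                initial=c,
                lower=max(r.lower, (1 - fraction) * c),
                upper=min(r.upper, (1 + fraction) * c),
                step=r.step,
            )
        return SearchSpace(new, d_value=self.d_value)


@dataclass
class FitResult:
    """Outcome of :func:`staged_fit`."""

    params: PLRParameters
    rmspe_windows: dict[str, float]
    rmspe_full: float
    n_iterations: int
    converged: bool
    t_dcm: float

    def to_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "rmspe_windows": dict(self.rmspe_windows),
            "rmspe_full": self.rmspe_full,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "t_dcm": self.t_dcm,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=PLRParameters.from_dict(d["params"]),
            rmspe_windows=d["rmspe_windows"],
            rmspe_full=d["rmspe_full"],
            n_iterations=d["n_iterations"],
            converged=d["converged"],
            t_dcm=d["t_dcm"],
        )


def rmspe(
    measured: PupilTrace,
    modelled: PupilTrace,
    window: tuple[float, float] | None = None,
) -> float:
    """Root-mean-square percentage error between two traces, in percent.

    ``100 * sqrt( (1/(N-1)) * sum_i ((X_i - Y_i)/X_i)^2 )`` over the
    samples of the half-open window ``[a, b)`` (full overlap when
    ``window`` is None).  ``X`` is the measured trace, ``Y`` the model
    output; the two must share the sample grid inside the window.
    """
    a, b = window if window is not None else (-np.inf, np.inf)
    m = (measured.times >= a) & (measured.times < b)
    t = measured.times[m]
    if t.size < 2:
        raise ValueError(f"window [{a}, {b}) holds fewer than 2 shared samples")
    idx = np.searchsorted(modelled.times, t)
    if idx[-1] >= modelled.times.size or not np.allclose(
        modelled.times[idx], t, rtol=0.0, atol=1e-9
    ):
        raise ValueError("traces do not share the sample grid inside the window")
    x = measured.radii[m]
    y = modelled.radii[idx]
    if np.any(x == 0):
        raise ValueError("measured trace contains zero samples")
    rel = (x - y) / x
    return 100.0 * float(np.sqrt(np.sum(rel * rel) / (x.size - 1)))


def _make_objective(
    measured: PupilTrace, stim: StimulusSpec, l0: float, d_value: float
) -> Callable[[Mapping[str, float], tuple[float, float]], float]:
    """Cached windowed-RMSPE objective over the 9 searched parameters.

    Simulation is run only up to the window end (the trace is at exact
    equilibrium before the first force onset, and later samples do not
    influence the windowed error).
    """
    cache: dict[tuple, float] = {}
    times = measured.times

    def evaluate(values: Mapping[str, float], window: tuple[float, float]) -> float:
        a, b = window
        key = tuple(values[n] for n in SEARCHED_PARAMETERS) + (round(b, 9),)
        if key in cache:
            return cache[key]
        hi = int(np.searchsorted(times, b))
        hi = max(hi, 2)  # simulate_plr needs at least two samples
        grid = times[:hi]
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                params = PLRParameters(**dict(values), l0=l0, D=d_value)
                sim = simulate_plr(params, stim, grid, method="fixed")
                err = rmspe(measured, sim, (a, min(b, grid[-1] + 1e-9)))
        except (SimulationError, ValueError):
            err = np.inf
        if not np.isfinite(err):
            err = np.inf
        cache[key] = err
        return err

    return evaluate


def univariate_search(
    window: tuple[float, float],
    free_params: Sequence[str],
    space: SearchSpace,
    measured: PupilTrace,
    stim: StimulusSpec,
    current: PLRParameters,
    max_rounds: int = 20,
    _evaluate: Callable | None = None,
) -> tuple[PLRParameters, bool, int]:
    """One coordinate-search stage on a windowed RMSPE objective.

    Each free parameter is scanned over its full grid and set to the
    grid value with the lowest objective (ties broken toward the smaller
    value).  With two or more free parameters the scans alternate until
    the first parameter's selected value repeats across one alternation,
    capped at ``max_rounds`` rounds.  Returns the updated parameters,
    a convergence flag and the number of single-parameter scans run.
    """
    if not free_params:
        raise ValueError("free_params must be nonempty")
    evaluate = _evaluate or _make_objective(measured, stim, current.l0, current.D)
    values = {n: getattr(current, n) for n in SEARCHED_PARAMETERS}

    def scan(name: str) -> None:
        grid = space.grid(name)
        errs = np.empty(grid.size)
        for i, v in enumerate(grid):
            trial = dict(values)
            trial[name] = float(v)
            errs[i] = evaluate(trial, window)
        if not np.isfinite(errs).any():
            raise SimulationError(
                f"objective not finite anywhere on the {name} grid", current
            )
        values[name] = float(grid[int(np.argmin(errs))])  # first minimum = smallest value

    n_scans = 0
    if len(free_params) == 1:
        scan(free_params[0])
        n_scans = 1
        converged = True
    else:
        converged = False
        prev_first: float | None = None
        for _ in range(max_rounds):
            for name in free_params:
                scan(name)
                n_scans += 1
            if values[free_params[0]] == prev_first:
                converged = True
                break
            prev_first = values[free_params[0]]
        if not converged:
            warnings.warn(
                f"univariate search on {tuple(free_params)} did not converge "
                f"within {max_rounds} rounds",
                stacklevel=2,
            )
    return current.replace(**values), converged, n_scans


def pairwise_refine(
    window: tuple[float, float],
    space: SearchSpace,
    measured: PupilTrace,
    stim: StimulusSpec,
    current: PLRParameters,
    width: int = 5,
    max_sweeps: int = 20,
    _evaluate: Callable | None = None,
) -> tuple[PLRParameters, int]:
    """Local pattern search over parameter pairs on the fitting grid.

    The staged univariate scans stall on ridges where two parameters
    compensate each other exactly — most visibly the force intensities
    against the elastic constants, which trade off through the
    quasi-static force balance during long stimuli.  This refinement
    sweeps every unordered pair of searched parameters, evaluating the
    windowed RMSPE on the joint grid neighbourhood of ±``width`` steps
    around the current point, and accepts the best strictly-improving
    move.  Sweeps repeat until none of the pairs improves (or
    ``max_sweeps``).  Moves stay on the bounded grid, so the result
    remains a valid grid vector.  Returns the refined parameters and the
    number of sweeps run.
    """
    evaluate = _evaluate or _make_objective(measured, stim, current.l0, current.D)
    values = {n: getattr(current, n) for n in SEARCHED_PARAMETERS}
    pairs = [
        (p, q)
        for i, p in enumerate(SEARCHED_PARAMETERS)
        for q in SEARCHED_PARAMETERS[i + 1 :]
    ]

    def neighbourhood(name: str, value: float) -> np.ndarray:
        g = space.grid(name)
        i = int(np.argmin(np.abs(g - value)))
        return g[max(0, i - width) : i + width + 1]

    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        moved = False
        for p, q in pairs:
            base = evaluate(values, window)
            best_err, best_move = base, None
            for vp in neighbourhood(p, values[p]):
                for vq in neighbourhood(q, values[q]):
                    err = evaluate({**values, p: float(vp), q: float(vq)}, window)
                    if err < best_err - 1e-12:
                        best_err, best_move = err, (float(vp), float(vq))
            if best_move is not None:
                values[p], values[q] = best_move
                moved = True
        if not moved:
            break
    return current.replace(**values), sweeps


#: Stage order of the staged fit: (free parameters, objective window name).
#: The last two stages score the full recording: the slow re-dilation tail
#: is the part of the response that actually identifies the dilation
#: delay revisit and the elastic constants.
STAGES: tuple[tuple[tuple[str, ...], str], ...] = (
    (("tau_p1", "f_p0"), "start"),
    (("tau_s1", "f_s0"), "constrict"),
    (("tau_p2",), "dilate"),
    (("tau_s2", "f_s1"), "all"),
    (("tau_p2",), "full"),
    (("k_d1", "k_d2"), "full"),
)


def staged_fit(
    measured: PupilTrace,
    stim: StimulusSpec,
    space: SearchSpace | None = None,
    l0: float | None = None,
    max_rounds: int = 20,
    max_cycles: int = 10,
    refine: bool = True,
    refine_width: int = 5,
) -> FitResult:
    """Fit the PLR model to a measured trace by the staged univariate search.

    The four objective windows are anchored on the stimulus onset ``t_s``
    and the time of maximal constriction ``t_DCM`` (found once, from the
    measured trace): ``start`` = [t_s, t_s+0.4 s), ``constrict`` =
    [t_s, t_DCM), ``dilate`` = [t_s, t_s + 1.25 (t_DCM - t_s)) and
    ``all`` = [t_s, t_s + 3 (t_DCM - t_s)), clipped (with a warning) to
    the end of the trace.  ``l0`` defaults to the mean pre-stimulus
    radius.  The returned parameters lie on the search grid.

    The six stages run in order; because each stage conditions on the
    values the later stages have not yet corrected (e.g. the sympathetic
    intensity is first scanned while the parasympathetic offset delay
    still sits at its initial value), the whole cycle is repeated until
    the parameter vector is unchanged across one full cycle, capped at
    ``max_cycles`` cycles.  With ``refine=True`` (the default) a final
    :func:`pairwise_refine` pass on the full recording walks the fit
    down the compensation ridges that single-parameter scans cannot
    descend.
    """
    if space is None:
        from .reference import default_search_space

        space = default_search_space()
    if l0 is None:
        l0 = measured.baseline(stim.t_s)

    t_dcm = find_t_dcm(measured, stim)
    c = t_dcm - stim.t_s
    t_end = float(measured.times[-1])
    if c <= 0:
        # flat or monotone trace: no constriction minimum to anchor the
        # windows on; fall back to a third of the post-stimulus recording
        c = (t_end - stim.t_s) / 3.0
        warnings.warn(
            "no constriction minimum after the stimulus onset; windows "
            "anchored on a fallback third of the post-stimulus recording",
            stacklevel=2,
        )
    all_end = stim.t_s + 3.0 * c
    if all_end > t_end + 1e-9:
        warnings.warn(
            f"trace ends at {t_end:g} s, before the nominal full-fit window "
            f"end {all_end:g} s; clipping to the trace end",
            stacklevel=2,
        )
        all_end = t_end
    windows = {
        "start": (stim.t_s, stim.t_s + 0.4),
        "constrict": (stim.t_s, stim.t_s + c),
        "dilate": (stim.t_s, stim.t_s + 1.25 * c),
        "all": (stim.t_s, all_end + 1e-9),
        "full": (stim.t_s, t_end + 1e-9),
    }

    params = space.snap_params(
        PLRParameters(
            **{n: space.ranges[n].initial for n in SEARCHED_PARAMETERS},
            l0=l0,
            D=space.d_value,
        )
    )
    evaluate = _make_objective(measured, stim, l0, space.d_value)

    n_iterations = 0
    all_converged = True
    for cycle in range(max_cycles):
        before = params
        for free, wname in STAGES:
            params, conv, n = univariate_search(
                windows[wname], free, space, measured, stim, params,
                max_rounds=max_rounds, _evaluate=evaluate,
            )
            n_iterations += n
            all_converged &= conv
        if params == before:
            break
    else:
        warnings.warn(
            f"staged fit did not stabilise within {max_cycles} cycles", stacklevel=2
        )
        all_converged = False

    if refine:
        params, _ = pairwise_refine(
            windows["full"], space, measured, stim, params,
            width=refine_width, _evaluate=evaluate,
        )

    final_values = {n: getattr(params, n) for n in SEARCHED_PARAMETERS}
    stage_errs = {
        name: evaluate(final_values, windows[name])
        for name in ("start", "constrict", "dilate", "all")
    }

    full_window = (float(measured.times[0]), t_end + 1e-9)
    rmspe_full = rmspe(measured, simulate_plr(params, stim, measured.times), full_window)

    for name in ("f_p0", "f_s0", "f_s1"):
        if getattr(params, name) <= space.ranges[name].lower + 1e-12:
            warnings.warn(
                f"fitted {name} sits at its lower bound; the trace may hold "
                "no physiological light reflex",
                stacklevel=2,
            )
    if not params.satisfies_ordering():
        log.info("fitted parameters violate the physiological ordering: %s", params)

    return FitResult(
        params=params,
        rmspe_windows=stage_errs,
        rmspe_full=rmspe_full,
        n_iterations=n_iterations,
        converged=all_converged,
        t_dcm=t_dcm,
    )


def random_initialize(
    measured: PupilTrace,
    stim: StimulusSpec,
    n_draws: int = 1000,
    seed: int | None = None,
    space: SearchSpace | None = None,
    l0: float | None = None,
    return_diagnostics: bool = False,
):
    """Random-search initialisation of the search space.

    Draws ``n_draws`` parameter vectors uniformly within the base bounds,
    simulates each against the measured trace (intended to be the 500 ms
    stimulus recording, where the parameters are least variable), and
    returns a :class:`SearchSpace` centred on the lowest-RMSPE draw with
    bounds narrowed to ±20% (clipped to the base bounds).  ``D`` stays
    fixed at the base value.  Deterministic for a given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if space is None:
        from .reference import default_search_space

        space = default_search_space()
    if l0 is None:
        l0 = measured.baseline(stim.t_s)

    rng = np.random.default_rng(seed)
    draws = {
        n: rng.uniform(space.ranges[n].lower, space.ranges[n].upper, size=n_draws)
        for n in SEARCHED_PARAMETERS
    }
    full_window = (float(measured.times[0]), float(measured.times[-1]) + 1e-9)
    errs = np.empty(n_draws)
    for i in range(n_draws):
        params = PLRParameters(
            **{n: float(draws[n][i]) for n in SEARCHED_PARAMETERS}, l0=l0, D=space.d_value
        )
        try:
            sim = simulate_plr(params, stim, measured.times, method="fixed")
            errs[i] = rmspe(measured, sim, full_window)
        except (SimulationError, ValueError):
            errs[i] = np.inf
    if not np.isfinite(errs).any():
        raise SimulationError("every random draw produced a non-finite simulation")

    best = int(np.argmin(errs))
    center = PLRParameters(
        **{n: float(draws[n][best]) for n in SEARCHED_PARAMETERS}, l0=l0, D=space.d_value
    )
    narrowed = space.narrowed(center, fraction=0.2)
    if return_diagnostics:
        diag = pd.DataFrame({n: draws[n] for n in SEARCHED_PARAMETERS})
        diag["rmspe"] = errs
        return narrowed, diag
    return narrowed


def viscous_sweep(
    measured: PupilTrace,
    stim: StimulusSpec,
    d_values: Sequence[float],
    space: SearchSpace | None = None,
    l0: float | None = None,
) -> pd.DataFrame:
    """Diagnostic: full staged fit at each candidate viscous constant ``D``.

    Returns a frame of D against the resulting full-trace RMSPE, the
    basis on which a single fixed ``D`` is chosen for all fits.
    """
    if space is None:
        from .reference import default_search_space

        space = default_search_space()
    rows = []
    for d in d_values:
        sp = SearchSpace(dict(space.ranges), d_value=float(d))
        fit = staged_fit(measured, stim, space=sp, l0=l0)
        rows.append({"D": float(d), "rmspe_full": fit.rmspe_full})
    return pd.DataFrame(rows)
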
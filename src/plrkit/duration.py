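"""Stimulus-duration screening, regression and PLR prediction.

Fitted parameter vectors obtained at several stimulus durations are
screened with the coefficient of variation (Cv = sd/mean): parameters
with Cv below 0.15 are treated as duration-stable and carried over
unchanged from a reference fit, while duration-sensitive parameters are
regressed on the stimulus duration and predicted at unseen durations.
The sympathetic intensity ``f_s0`` is handled through the composite
``f_p0 - f_s0`` (the net constricting force during the antagonistic
phase), which trends with duration more smoothly than ``f_s0`` itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .identify import SearchSpace, rmspe
from .model import PLRParameters, PupilTrace, SEARCHED_PARAMETERS, StimulusSpec, simulate_plr

__all__ = [
    "DurationTable",
    "Regression",
    "RegressionSet",
    "CV_THRESHOLD",
    "SENSITIVE_QUANTITIES",
    "coefficient_of_variation",
    "classify_parameters",
    "fit_duration_regressions",
    "predict_plr",
]

#: Cv threshold separating duration-stable from duration-sensitive parameters.
CV_THRESHOLD = 0.15

#: Quantities regressed on duration (``f_s0`` enters via the composite).
SENSITIVE_QUANTITIES = ("tau_p2", "f_s1", "k_d1", "k_d2", "f_p0_minus_f_s0")


@dataclass(frozen=True)
class DurationTable:
    """Fitted parameter vectors indexed by stimulus duration (seconds)."""

    durations: tuple[float, ...]
    params: tuple[PLRParameters, ...]

    def __post_init__(self):
        if len(self.durations) != len(self.params):
            raise ValueError("durations and params must align")
        if len(set(self.durations)) != len(self.durations):
            raise ValueError("durations must be unique")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.durations)

    def column(self, name: str) -> np.ndarray:
        """Values of one parameter (or ``f_p0_minus_f_s0``) across durations."""
        if name == "f_p0_minus_f_s0":
            return np.array([p.f_p0 - p.f_s0 for p in self.params])
        return np.array([getattr(p, name) for p in self.params])

    def at(self, duration: float) -> PLRParameters:
        try:
            return self.params[self.durations.index(duration)]
        except ValueError:
            raise KeyError(f"no fit at duration {duration}") from None

    def to_frame(self) -> pd.DataFrame:
        """Rows = parameter names, columns = durations (CSV layout)."""
        data = {d: p.as_dict() for d, p in zip(self.durations, self.params)}
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DurationTable":
        durations = tuple(float(c) for c in df.columns)
        params = tuple(PLRParameters.from_dict(df[c].to_dict()) for c in df.columns)
        return cls(durations, params)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation: sd (N-1 denominator) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def classify_parameters(
    table: DurationTable, threshold: float = CV_THRESHOLD
) -> tuple[set[str], set[str], dict[str, float]]:
    """Split parameters into duration-stable and duration-sensitive sets.

    Returns ``(stable, sensitive, cv_by_parameter)`` where a parameter is
    stable when its Cv across durations is strictly below ``threshold``.
    ``D`` is excluded (held constant by construction); ``l0`` is included.
    """
    names = list(SEARCHED_PARAMETERS) + ["l0"]
    cvs = {n: coefficient_of_variation(table.column(n)) for n in names}
    stable = {n for n, cv in cvs.items() if cv < threshold}
    return stable, set(names) - stable, cvs


@dataclass(frozen=True)
class Regression:
    """One fitted duration curve: value ~ polynomial in log10(duration)."""

    name: str
    coefficients: tuple[float, ...]  # highest degree first (np.polyval order)
    r_squared: float
    residuals: tuple[float, ...]

    def predict(self, duration: float) -> float:
        return float(np.polyval(self.coefficients, np.log10(duration)))


@dataclass(frozen=True)
class RegressionSet:
    """Duration regressions keyed by quantity name."""

    regressions: Mapping[str, Regression]

    def predict(self, name: str, duration: float) -> float:
        return self.regressions[name].predict(duration)

    def __contains__(self, name: str) -> bool:
        return name in self.regressions


def fit_duration_regressions(
    table: DurationTable,
    quantities: Sequence[str] = SENSITIVE_QUANTITIES,
    degree: int = 2,
) -> RegressionSet:
    """Least-squares polynomial fits of each quantity against log10(duration).

    The default quadratic in log-duration follows the smooth, gently
    curved trends these parameters show over the 1 ms – 3 s range.  A
    constant column collapses to an intercept-only fit.
    """
    if len(table) < 3:
        raise ValueError("duration regression needs at least 3 durations")
    x = np.log10(np.asarray(table.durations, dtype=float))
    out = {}
    for name in quantities:
        y = table.column(name)
        if np.ptp(y) == 0:
            coeffs = np.array([float(y[0])])
        else:
            coeffs = np.polyfit(x, y, deg=degree)
        pred = np.polyval(coeffs, x)
        resid = y - pred
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = Regression(
            name=name,
            coefficients=tuple(float(c) for c in np.atleast_1d(coeffs)),
            r_squared=r2,
            residuals=tuple(float(r) for r in resid),
        )
    return RegressionSet(out)


#: Parameters copied unchanged from the reference fit in regression mode.
STABLE_PARAMETERS = ("tau_p1", "tau_s1", "tau_s2", "f_p0", "l0")


def predict_plr(
    reference_fit: PLRParameters,
    regs: RegressionSet | None,
    target_duration: float,
    stim_onset: float = 5.0,
    mode: str = "regression",
    times: np.ndarray | None = None,
    measured: PupilTrace | None = None,
    space: SearchSpace | None = None,
    rate: float = 30.0,
    record_length: float = 15.0,
) -> tuple[PLRParameters, PupilTrace, float | None]:
    """Predict the PLR at an unseen stimulus duration.

    ``direct`` mode reuses every parameter of ``reference_fit`` (a fit at
    a short reference duration, typically 10 ms) and only changes the
    stimulus duration.  ``regression`` mode copies the duration-stable
    parameters and sets the sensitive ones from the duration regressions,
    reconstructing ``f_s0 = f_p0 - predicted(f_p0 - f_s0)``.  Predicted
    values falling outside the search bounds are clipped with a warning.
    Returns ``(parameters, simulated trace, RMSPE vs measured or None)``.
    """
    if mode not in ("direct", "regression"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    if not (5e-4 <= target_duration <= 6.0):
        raise ValueError(
            "target duration outside the supported extrapolation range (0.5 ms – 6 s)"
        )

    if mode == "direct":
        params = reference_fit
    else:
        if regs is None:
            raise ValueError("regression mode needs a RegressionSet")
        if space is None:
            from .reference import default_search_space

            space = default_search_space()
        values = {n: getattr(reference_fit, n) for n in STABLE_PARAMETERS}
        for name in ("tau_p2", "f_s1", "k_d1", "k_d2"):
            values[name] = regs.predict(name, target_duration)
        values["f_s0"] = values["f_p0"] - regs.predict("f_p0_minus_f_s0", target_duration)
        for name in SEARCHED_PARAMETERS:
            clipped = space.clip(name, values[name])
            if clipped != values[name]:
                warnings.warn(
                    f"regression-predicted {name}={values[name]:.4g} outside "
                    f"bounds; clipped to {clipped:.4g}",
                    stacklevel=2,
                )
                values[name] = clipped
        params = PLRParameters(**values, D=reference_fit.D)

    stim = StimulusSpec(t_s=stim_onset, t_d=target_duration)
    if times is None:
        times = measured.times if measured is not None else np.arange(
            0.0, record_length + 0.5 / rate, 1.0 / rate
        )
    trace = simulate_plr(params, stim, times)
    err = None
    if measured is not None:
        err = rmspe(measured, trace, (float(measured.times[0]), float(measured.times[-1]) + 1e-9))
    return params, trace, err
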
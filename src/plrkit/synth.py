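"""Synthetic pupillometry data: single traces, duration series, cohorts.

Real dark-adapted PLR recordings are not redistributable, so this module
generates everything the downstream analyses consume: model-simulated
traces with optional measurement noise (emulating a pupilometer running
at ~30 frames/s for 5 s before and 10 s after the stimulus), a series of
traces across stimulus durations built from the bundled reference fits,
and two-group cohorts of parameter vectors drawn from the reference
group means and standard deviations.  All outputs are deterministic for
a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import (
    DEFAULT_IRIS_DIAMETER_MM,
    DEFAULT_L0_NORM_MM,
    derive_parameters,
)
from .duration import DurationTable
from .model import PLRParameters, PupilTrace, SEARCHED_PARAMETERS, StimulusSpec, simulate_plr

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "default_time_grid",
    "generate_trace",
    "generate_duration_series",
    "generate_cohort",
]

_SAMPLED_PARAMETERS = SEARCHED_PARAMETERS + ("l0",)

#: Truncation bounds used when sampling cohort parameter vectors: the
#: search bounds for the nine identified parameters, a generous
#: physiological range for the resting size.
_COHORT_BOUNDS = {
    "tau_p1": (0.150, 0.300),
    "tau_p2": (0.200, 1.250),
    "tau_s1": (0.270, 0.650),
    "tau_s2": (1.200, 2.000),
    "f_p0": (8.000, 14.000),
    "f_s0": (4.000, 15.000),
    "f_s1": (0.100, 1.500),
    "k_d1": (0.500, 1.500),
    "k_d2": (1.000, 1.800),
    "l0": (0.500, 8.000),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to a simulated radius trace.

    ``additive-gaussian`` adds N(0, sigma) in mm; ``multiplicative-
    gaussian`` scales each sample by (1 + N(0, sigma)) with ``sigma`` a
    fraction.  ``none`` returns the simulation untouched.
    """

    kind: str = "none"
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("none", "additive-gaussian", "multiplicative-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, radii: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return radii.copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.standard_normal(radii.size) * self.sigma
        out = radii + eps if self.kind == "additive-gaussian" else radii * (1.0 + eps)
        # a pupil radius cannot reach zero; keep the trace physical
        return np.maximum(out, 1e-6)


def default_time_grid(record_length: float = 15.0, rate: float = 30.0) -> np.ndarray:
    """Sampling grid of a recording: ``rate`` Hz over ``record_length`` s."""
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    return np.arange(0.0, record_length + 0.5 / rate, 1.0 / rate)


def generate_trace(
    params: PLRParameters,
    stim: StimulusSpec,
    record_length: float = 15.0,
    rate: float = 30.0,
    noise: NoiseModel | None = None,
) -> PupilTrace:
    """Simulate one PLR recording and apply measurement noise."""
    times = default_time_grid(record_length, rate)
    clean = simulate_plr(params, stim, times)
    if noise is None:
        return clean
    return PupilTrace(clean.times, noise.apply(clean.radii))


def generate_duration_series(
    base: DurationTable | None = None,
    noise: NoiseModel | None = None,
    stim_onset: float = 5.0,
    record_length: float = 15.0,
    rate: float = 30.0,
) -> dict[float, PupilTrace]:
    """One synthetic recording per stimulus duration of ``base``.

    Defaults to the bundled reference fits (1 ms – 3 s).  When noise is
    active each duration uses a distinct stream derived from the model
    seed, so the traces are independent but reproducible.
    """
    if base is None:
        from .reference import duration_study_table

        base = duration_study_table()
    out: dict[float, PupilTrace] = {}
    for i, (d, p) in enumerate(zip(base.durations, base.params)):
        nm = noise
        if noise is not None and noise.seed is not None:
            nm = NoiseModel(noise.kind, noise.sigma, seed=noise.seed + i)
        out[d] = generate_trace(
            p, StimulusSpec(t_s=stim_onset, t_d=d), record_length, rate, nm
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group synthetic cohort.

    ``group_stats`` maps group label -> parameter -> (mean, sd); the
    default is the bundled healthy / DM summary (336 recordings per
    group).  Parameters are drawn from normals truncated (by rejection)
    at the search bounds; rows violating the physiological ordering
    (``tau_s1 > tau_p1``, ``tau_s2 > tau_p2``, ``f_s1 < f_s0``) are
    redrawn.  ``correlation`` controls the joint structure: the default
    ``"implied"`` uses the pairwise correlations implied by the bundled
    summary's difference rows (see
    :func:`plrkit.reference.implied_correlations`), ``None`` samples
    every parameter independently, and an explicit matrix over the ten
    sampled parameters can be supplied for stress tests.
    """

    group_stats: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    n_per_group: int = 336
    seed: int | None = None
    stim: StimulusSpec = field(default_factory=lambda: StimulusSpec(t_s=5.0, t_d=0.01))
    iris_diameter_mm: float = DEFAULT_IRIS_DIAMETER_MM
    l0_norm_mm: float = DEFAULT_L0_NORM_MM
    correlation: np.ndarray | str | None = "implied"

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")

    def resolved_stats(self) -> dict[str, dict[str, tuple[float, float]]]:
        if self.group_stats is not None:
            out = {g: dict(s) for g, s in self.group_stats.items()}
        else:
            from .reference import cohort_summary_frame

            ref = cohort_summary_frame()
            out = {
                "healthy": {
                    n: (ref.loc[n, "healthy_mean"], ref.loc[n, "healthy_sd"])
                    for n in ref.index
                },
                "DM": {
                    n: (ref.loc[n, "dm_mean"], ref.loc[n, "dm_sd"]) for n in ref.index
                },
            }
        for stats in out.values():
            # the resting size may be specified directly or as l0_prime
            if "l0" not in stats and "l0_prime" in stats:
                m, s = stats.pop("l0_prime")
                stats["l0"] = (
                    m * self.iris_diameter_mm / self.l0_norm_mm,
                    s * self.iris_diameter_mm / self.l0_norm_mm,
                )
            missing = set(_SAMPLED_PARAMETERS) - set(stats)
            if missing:
                raise ValueError(f"group stats missing parameters: {sorted(missing)}")
            for name, (m, s) in stats.items():
                if s < 0:
                    raise ValueError(f"negative sd for {name}")
                lo, hi = _COHORT_BOUNDS[name]
                if s > 0 and (m < lo - 6 * s or m > hi + 6 * s):
                    raise ValueError(
                        f"infeasible truncation for {name}: mean {m} is more than "
                        f"6 sd outside [{lo}, {hi}]"
                    )
        return out


def _resolve_correlation(spec: CohortSpec, group: str) -> np.ndarray | None:
    if spec.correlation is None:
        return None
    k = len(_SAMPLED_PARAMETERS)
    if isinstance(spec.correlation, str):
        if spec.correlation != "implied":
            raise ValueError(f"unknown correlation spec {spec.correlation!r}")
        from .reference import implied_correlations

        try:
            df = implied_correlations(group)
        except KeyError:
            return None  # custom group labels: no implied structure
        return df.loc[list(_SAMPLED_PARAMETERS), list(_SAMPLED_PARAMETERS)].to_numpy()
    corr = np.asarray(spec.correlation, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}")
    return corr


def _draw_rows(
    rng: np.random.Generator,
    stats: Mapping[str, tuple[float, float]],
    n: int,
    correlation: np.ndarray | None,
) -> np.ndarray:
    """Draw ``n`` parameter rows, rejecting draws outside the bounds."""
    if correlation is None:
        cols = []
        for name in _SAMPLED_PARAMETERS:
            m, s = stats[name]
            lo, hi = _COHORT_BOUNDS[name]
            if s == 0:
                cols.append(np.full(n, m))
            else:
                a, b = (lo - m) / s, (hi - m) / s
                cols.append(truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng))
        return np.column_stack(cols)

    k = len(_SAMPLED_PARAMETERS)
    chol = np.linalg.cholesky(correlation)
    means = np.array([stats[name][0] for name in _SAMPLED_PARAMETERS])
    sds = np.array([stats[name][1] for name in _SAMPLED_PARAMETERS])
    lows = np.array([_COHORT_BOUNDS[name][0] for name in _SAMPLED_PARAMETERS])
    highs = np.array([_COHORT_BOUNDS[name][1] for name in _SAMPLED_PARAMETERS])
    out = np.empty((n, k))
    need = n
    filled = 0
    for _ in range(1000):
        z = rng.standard_normal((max(need, 8), k)) @ chol.T
        rows = means + sds * z
        ok = np.all((rows >= lows) & (rows <= highs), axis=1)
        good = rows[ok][:need]
        out[filled : filled + good.shape[0]] = good
        filled += good.shape[0]
        need -= good.shape[0]
        if need == 0:
            return out
    raise RuntimeError("could not draw parameter rows inside the bounds")


def _ordering_ok(mat: np.ndarray) -> np.ndarray:
    idx = {n: j for j, n in enumerate(_SAMPLED_PARAMETERS)}
    return (
        (mat[:, idx["tau_s1"]] > mat[:, idx["tau_p1"]])
        & (mat[:, idx["tau_s2"]] > mat[:, idx["tau_p2"]])
        & (mat[:, idx["f_s1"]] < mat[:, idx["f_s0"]])
    )


_EYES = ("right", "left")
_INTENSITIES = ("0.2cd", "1.2cd")
_COLORS = ("W", "R", "G", "B")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a labelled cohort table with base and derived parameters.

    One row per simulated recording, cycling eye / intensity / colour
    labels within participants.  Derived indices (impulses, l0', DAN)
    are computed per row for the requested stimulus.
    """
    rng = np.random.default_rng(spec.seed)
    stats = spec.resolved_stats()
    frames = []
    for group, gstats in stats.items():
        corr = _resolve_correlation(spec, group)
        mat = _draw_rows(rng, gstats, spec.n_per_group, corr)
        for _ in range(1000):
            bad = ~_ordering_ok(mat)
            if not bad.any():
                break
            mat[bad] = _draw_rows(rng, gstats, int(bad.sum()), corr)
        else:
            raise RuntimeError(
                f"could not satisfy parameter ordering for group {group!r}"
            )
        df = pd.DataFrame(mat, columns=_SAMPLED_PARAMETERS)
        df.insert(0, "group", group)
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    n = len(table)
    combos = [
        (e, i, c) for e in _EYES for i in _INTENSITIES for c in _COLORS
    ]
    labels = [combos[i % len(combos)] for i in range(spec.n_per_group)] * len(stats)
    table.insert(0, "sample_id", np.arange(n))
    table.insert(2, "participant", np.tile(
        np.arange(spec.n_per_group) // len(combos) + 1, len(stats)
    ))
    table.insert(3, "eye", [l[0] for l in labels])
    table.insert(4, "intensity", [l[1] for l in labels])
    table.insert(5, "color", [l[2] for l in labels])
    table["D"] = 4.3

    derived_rows = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for _, row in table.iterrows():
            p = PLRParameters.from_dict(
                row[list(_SAMPLED_PARAMETERS) + ["D"]].to_dict()
            )
            derived_rows.append(
                derive_parameters(
                    p, spec.stim, spec.iris_diameter_mm, spec.l0_norm_mm
                ).as_dict()
            )
    n_flagged = sum("non-positive" in str(w.message) for w in caught)
    if n_flagged:
        warnings.warn(
            f"{n_flagged} of {n} sampled rows had a non-positive impulse phase "
            "duration; those impulses are 0",
            stacklevel=2,
        )
    return pd.concat([table, pd.DataFrame(derived_rows, index=table.index)], axis=1)
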
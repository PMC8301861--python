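"""Bundled reference values for dark-adapted PLR identification.

These are the published operating points of the method: the default
search space for the staged univariate fit, a reference set of fitted
parameter vectors at seven white-light stimulus durations (1 ms .. 3 s),
right/left-eye fits for two healthy participants, per-colour group means
(white / red / green / blue stimuli), and two-group cohort summary
statistics (healthy vs. diabetes mellitus, 336 pupil recordings per
group).  They serve both as defaults and as generating truths for the
synthetic-data module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PLRParameters, SEARCHED_PARAMETERS

__all__ = [
    "default_search_space",
    "duration_study_frame",
    "duration_study_table",
    "DURATION_STUDY_L0",
    "eye_comparison_frame",
    "color_means_frame",
    "cohort_summary_frame",
    "VISCOUS_CONSTANT",
]

#: Viscous constant D (g/s), held fixed in every fit and prediction.
VISCOUS_CONSTANT = 4.3

# Search space: per-parameter initial value, lower/upper bound and grid step.
_SEARCH_TABLE = {
    # name:   (initial, lower, upper, step)
    "tau_p1": (0.250, 0.150, 0.300, 0.005),
    "tau_p2": (1.250, 0.200, 1.250, 0.005),
    "tau_s1": (0.500, 0.270, 0.650, 0.005),
    "tau_s2": (1.300, 1.200, 2.000, 0.005),
    "f_p0": (11.00, 8.000, 14.000, 0.100),
    "f_s0": (7.000, 4.000, 15.000, 0.100),
    "f_s1": (1.000, 0.100, 1.500, 0.100),
    "k_d1": (1.000, 0.500, 1.500, 0.050),
    "k_d2": (1.600, 1.000, 1.800, 0.050),
}

# Fitted parameters of one healthy participant's measured PLR at seven
# stimulus durations (columns; seconds), used as generating truths.
_DURATIONS = (0.001, 0.010, 0.100, 0.500, 1.000, 2.000, 3.000)
_DURATION_ROWS = {
    "tau_p1": (0.235, 0.205, 0.175, 0.220, 0.215, 0.165, 0.210),
    "tau_p2": (0.656, 0.710, 0.815, 0.580, 0.400, 0.380, 0.455),
    "tau_s1": (0.415, 0.425, 0.545, 0.565, 0.555, 0.570, 0.570),
    "tau_s2": (1.520, 1.205, 1.215, 1.365, 1.395, 1.545, 1.370),
    "f_p0": (10.900, 11.100, 12.200, 11.300, 11.100, 10.800, 11.300),
    "f_s0": (7.300, 6.700, 9.700, 6.800, 5.800, 6.200, 6.600),
    "f_s1": (1.300, 1.500, 1.500, 1.000, 0.900, 0.600, 0.700),
    "k_d1": (1.500, 1.450, 0.800, 0.500, 1.000, 0.750, 0.500),
    "k_d2": (1.700, 1.800, 1.800, 1.700, 1.000, 1.000, 1.000),
    "D": (4.300, 4.300, 4.300, 4.300, 4.300, 4.300, 4.300),
}

#: Resting pupil size used with the duration-study vectors.  The source
#: reports only its across-duration summary (mean 3.245 mm, sd 0.029 mm,
#: Cv 0.009); the per-duration values are not printed, so the mean is
#: used for every duration.
DURATION_STUDY_L0 = 3.245

# Right/left-eye fitted parameters for two healthy participants (10 ms
# white stimulus); basis of the direct-vs-consensual coherence check.
_EYE_ROWS = {
    "tau_p1": (0.190, 0.200, 0.230, 0.245),
    "tau_p2": (0.475, 0.500, 0.595, 0.630),
    "tau_s1": (0.360, 0.375, 0.395, 0.420),
    "tau_s2": (1.215, 1.210, 1.195, 1.195),
    "f_p0": (11.400, 11.300, 10.800, 10.700),
    "f_s0": (5.000, 5.300, 6.600, 7.100),
    "f_s1": (1.500, 1.500, 1.500, 1.500),
    "k_d1": (1.500, 1.500, 1.500, 1.500),
    "k_d2": (1.800, 1.800, 1.800, 1.800),
    "l0": (2.534, 2.681, 2.706, 2.784),
}
#: Parameters whose right/left percentage error exceeded 2% in the source.
EYE_COMPARISON_STARRED = ("tau_p1", "tau_p2", "tau_s1", "f_s0")

# Group-mean parameters of healthy right eyes under white/red/green/blue
# 10 ms stimuli, with the printed across-colour mean and Cv.
_COLOR_ROWS = {
    "tau_p1": (0.224, 0.201, 0.197, 0.190, 0.203, 0.0725),
    "tau_p2": (0.716, 0.787, 0.795, 0.807, 0.776, 0.0528),
    "tau_s1": (0.416, 0.418, 0.428, 0.423, 0.421, 0.0128),
    "tau_s2": (1.375, 1.420, 1.358, 1.403, 1.389, 0.0200),
    "f_p0": (10.036, 10.564, 10.671, 10.707, 10.495, 0.0297),
    "f_s0": (7.536, 7.876, 7.831, 7.598, 7.710, 0.0218),
    "f_s1": (1.319, 1.224, 1.281, 1.226, 1.263, 0.0364),
    "k_d1": (1.277, 1.292, 1.260, 1.224, 1.263, 0.0232),
    "k_d2": (1.657, 1.635, 1.690, 1.664, 1.662, 0.0136),
    "l0": (3.098, 3.070, 3.038, 2.991, 3.049, 0.0151),
}

# Cohort summary: mean and sd of each base parameter per group (n = 336
# pupil recordings per group; 42 participants x 2 eyes x 2 intensities x
# 2 colour sessions).  l0_prime is the normalised resting size.
_COHORT_ROWS = {
    # name:      (healthy mean, healthy sd, DM mean, DM sd)
    "tau_p1": (0.205, 0.035, 0.208, 0.038),
    "tau_p2": (0.779, 0.142, 0.772, 0.140),
    "tau_s1": (0.423, 0.045, 0.439, 0.050),
    "tau_s2": (1.391, 0.228, 1.397, 0.240),
    "f_p0": (10.573, 1.193, 10.549, 1.189),
    "f_s0": (7.745, 1.547, 7.991, 1.525),
    "f_s1": (1.264, 0.304, 1.279, 0.282),
    "k_d1": (1.251, 0.257, 1.195, 0.286),
    "k_d2": (1.656, 0.217, 1.676, 0.208),
    "l0_prime": (3.051, 0.392, 2.783, 0.381),
}
COHORT_N_PER_GROUP = 336

# Published sds of the pairwise parameter differences per group; together
# with the base-parameter sds these imply the pairwise covariances
# (var(a-b) = var(a) + var(b) - 2 cov(a,b)).
_COHORT_DIFF_SDS = {
    # (minuend, subtrahend): (healthy sd, DM sd)
    ("tau_p2", "tau_s1"): (0.131, 0.129),
    ("f_p0", "f_s0"): (1.210, 1.258),
    ("tau_s1", "tau_p1"): (0.053, 0.066),
    ("tau_s2", "tau_p2"): (0.231, 0.229),
}


def implied_correlations(group: str) -> pd.DataFrame:
    """Pairwise parameter correlations implied by the cohort summary.

    The cohort table reports the spread of several parameter differences
    (e.g. of ``f_p0 - f_s0``) alongside the spreads of the parameters
    themselves; the implied correlation of each pair follows from
    ``var(a-b) = var(a) + var(b) - 2 cov(a,b)``.  Pairs without a
    reported difference are left uncorrelated.  ``group`` is ``healthy``
    or ``DM``.
    """
    col = {"healthy": 0, "DM": 1}[group]
    names = list(_COHORT_ROWS)
    names[names.index("l0_prime")] = "l0"
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), sds in _COHORT_DIFF_SDS.items():
        sa = _COHORT_ROWS[a][1 + 2 * col]
        sb = _COHORT_ROWS[b][1 + 2 * col]
        cov = (sa**2 + sb**2 - sds[col] ** 2) / 2.0
        rho = cov / (sa * sb)
        corr.loc[a, b] = corr.loc[b, a] = rho
    return corr


def default_search_space():
    """Default :class:`~plrkit.identify.SearchSpace` for the staged fit."""
    from .identify import ParamRange, SearchSpace

    return SearchSpace(
        {name: ParamRange(*_SEARCH_TABLE[name]) for name in SEARCHED_PARAMETERS},
        d_value=VISCOUS_CONSTANT,
    )


def duration_study_frame() -> pd.DataFrame:
    """Reference parameters per stimulus duration (rows = parameters)."""
    df = pd.DataFrame(_DURATION_ROWS, index=[f"{d:g}" for d in _DURATIONS]).T
    df.columns = list(_DURATIONS)
    return df


def duration_study_table():
    """The reference duration study as a :class:`~plrkit.duration.DurationTable`."""
    from .duration import DurationTable

    params = []
    for j, d in enumerate(_DURATIONS):
        vals = {name: row[j] for name, row in _DURATION_ROWS.items()}
        vals["l0"] = DURATION_STUDY_L0
        params.append(PLRParameters.from_dict(vals))
    return DurationTable(durations=tuple(_DURATIONS), params=tuple(params))


def eye_comparison_frame() -> pd.DataFrame:
    """Right/left-eye fits for two healthy participants.

    Columns: ``(participant, side)`` MultiIndex; rows: parameter names.
    """
    cols = pd.MultiIndex.from_tuples(
        [(1, "right"), (1, "left"), (2, "right"), (2, "left")],
        names=["participant", "side"],
    )
    return pd.DataFrame(_EYE_ROWS, index=cols).T


def color_means_frame() -> pd.DataFrame:
    """Healthy group-mean parameters per stimulus colour plus printed summaries."""
    return pd.DataFrame(
        _COLOR_ROWS, index=["W", "R", "G", "B", "mean", "cv"]
    ).T


def cohort_summary_frame() -> pd.DataFrame:
    """Per-group mean/sd of the base parameters (healthy vs. DM)."""
    return pd.DataFrame(
        _COHORT_ROWS, index=["healthy_mean", "healthy_sd", "dm_mean", "dm_sd"]
    ).T
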
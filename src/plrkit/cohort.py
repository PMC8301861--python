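"""Cohort-level statistics: derived indices, group tests and ROC analysis.

From each fitted parameter vector a set of derived quantities is
computed: pairwise delay/force differences, three impulse-like indices
(force intensity x phase duration) for the parasympathetic-dominant,
antagonistic and sympathetic-dominant phases of the reflex, a normalised
resting size ``l0'``, and the composite DAN factor

    DAN = Imp2 * l0' * k_d1,

used to discriminate diabetic autonomic neuropathy from healthy
controls.  Group comparison uses the unequal-variance (Welch) two-sample
t statistic; discrimination is quantified with an empirical ROC curve
and the Youden-optimal operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from .model import PLRParameters, StimulusSpec

__all__ = [
    "DerivedParameters",
    "TTestResult",
    "RocResult",
    "percentage_error",
    "derive_parameters",
    "two_sample_t",
    "two_sample_t_from_stats",
    "cv_across_conditions",
    "group_comparison",
    "roc_curve",
    "derived_column_names",
]

#: Default iris diameter (mm) and the matching normalisation constant.
#: With equal defaults l0' equals l0 numerically, which reproduces the
#: reference cohort's l0' scale (about 3, not a dimensionless fraction).
DEFAULT_IRIS_DIAMETER_MM = 12.0
DEFAULT_L0_NORM_MM = 12.0


def percentage_error(reference: float, other: float) -> float:
    """Percentage deviation of ``other`` from ``reference``.

    ``(other - reference) / reference * 100``.  For a right-eye
    (stimulated) reference and a left-eye (consensual) comparison this
    sign convention matches the published right/left coherence tables;
    the magnitude is the same either way.
    """
    if reference == 0:
        raise ValueError("percentage error undefined for zero reference")
    return (other - reference) / reference * 100.0


@dataclass(frozen=True)
class DerivedParameters:
    """Quantities derived from one fitted parameter vector."""

    tau_p2_minus_tau_s1: float
    f_p0_minus_f_s0: float
    tau_s1_minus_tau_p1: float
    tau_s2_minus_tau_p2: float
    imp1: float
    imp2: float
    imp3: float
    l0_prime: float
    l0_prime_times_k_d1: float
    dan: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def derived_column_names() -> tuple[str, ...]:
    return tuple(f.name for f in fields(DerivedParameters))


def _impulse(intensity: float, phase_duration: float, label: str) -> float:
    """Force x time over one phase; a non-positive duration gives 0."""
    if phase_duration <= 0:
        warnings.warn(
            f"non-positive {label} phase duration ({phase_duration:.4g} s); "
            "impulse set to 0",
            stacklevel=3,
        )
        return 0.0
    return intensity * phase_duration


def derive_parameters(
    p: PLRParameters,
    stim: StimulusSpec,
    iris_diameter_mm: float = DEFAULT_IRIS_DIAMETER_MM,
    l0_norm_mm: float = DEFAULT_L0_NORM_MM,
) -> DerivedParameters:
    """Compute the derived indices for one fitted vector.

    Imp1 covers the parasympathetic-only phase (duration
    ``tau_s1 - tau_p1`` at net force ``f_p0``), Imp2 the antagonistic
    phase (``t_d + tau_p2 - tau_s1`` at ``f_p0 - f_s0``) and Imp3 the
    late sympathetic phase (``tau_s2 - tau_p2`` at ``f_s1``).  ``l0'``
    is the resting size divided by the iris diameter and rescaled by
    ``l0_norm_mm``.
    """
    imp1 = _impulse(p.f_p0, p.tau_s1 - p.tau_p1, "PSNS-dominant")
    imp2 = _impulse(p.f_p0 - p.f_s0, stim.t_d + p.tau_p2 - p.tau_s1, "antagonistic")
    imp3 = _impulse(p.f_s1, p.tau_s2 - p.tau_p2, "SNS-dominant")
    l0_prime = p.l0 / iris_diameter_mm * l0_norm_mm
    return DerivedParameters(
        tau_p2_minus_tau_s1=p.tau_p2 - p.tau_s1,
        f_p0_minus_f_s0=p.f_p0 - p.f_s0,
        tau_s1_minus_tau_p1=p.tau_s1 - p.tau_p1,
        tau_s2_minus_tau_p2=p.tau_s2 - p.tau_p2,
        imp1=imp1,
        imp2=imp2,
        imp3=imp3,
        l0_prime=l0_prime,
        l0_prime_times_k_d1=l0_prime * p.k_d1,
        dan=imp2 * l0_prime * p.k_d1,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Welch two-sample t statistic from group summary statistics.

    ``t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2)`` under the null
    of equal means, with a two-sided p value from the t distribution at
    the Welch–Satterthwaite degrees of freedom.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=float(df))


def two_sample_t(group1, group2) -> TTestResult:
    """Welch two-sample t test on raw per-sample values."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    return two_sample_t_from_stats(
        g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size
    )


def cv_across_conditions(
    table: pd.DataFrame,
    parameter: str,
    condition: str = "color",
    levels: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Coefficient of variation of a parameter's per-condition means.

    Groups the cohort table by ``condition`` (e.g. stimulus colour),
    averages ``parameter`` within each level and summarises the spread
    of those means: returns their mean, sd (N-1) and Cv.
    """
    means = table.groupby(condition)[parameter].mean()
    if levels is not None:
        missing = set(levels) - set(means.index)
        if missing:
            raise ValueError(f"missing condition levels: {sorted(missing)}")
        means = means.loc[list(levels)]
    if len(means) < 2:
        raise ValueError("need at least 2 condition levels")
    m = float(means.mean())
    sd = float(means.std(ddof=1))
    return {"mean": m, "sd": sd, "cv": sd / m}


def group_comparison(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("healthy", "DM"),
    columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-parameter group summary plus Welch t test.

    Returns one row per column with each group's mean and sd, the t
    statistic and the two-sided p value.  By default all base and
    derived parameter columns present in the table are compared.
    """
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if g1.empty or g2.empty:
        raise ValueError(f"both groups {groups} must be present")
    if columns is None:
        candidates = [f.name for f in fields(PLRParameters)] + list(
            derived_column_names()
        )
        columns = tuple(c for c in candidates if c in table.columns and c != "D")
    rows = []
    for c in columns:
        res = two_sample_t(g1[c], g2[c])
        rows.append(
            {
                "parameter": c,
                f"{groups[0]}_mean": g1[c].mean(),
                f"{groups[0]}_sd": g1[c].std(ddof=1),
                f"{groups[1]}_mean": g2[c].mean(),
                f"{groups[1]}_sd": g2[c].std(ddof=1),
                "t": res.t,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class RocResult:
    auc: float  # oriented so that auc >= 0.5
    auc_raw: float  # with scores taken as-is (higher score = positive)
    flipped: bool
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray
    tpr: np.ndarray


def roc_curve(scores, labels, positive_label="DM") -> RocResult:
    """Empirical ROC of a score against a binary group label.

    The raw orientation treats larger scores as evidence for the
    positive class.  If that yields AUC < 0.5 the score is flipped and
    the oriented curve is reported alongside the raw AUC.  The operating
    point maximises the Youden index (sensitivity + specificity - 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive_label).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_raw = float(skm.roc_auc_score(y, scores))
    flipped = auc_raw < 0.5
    oriented = -scores if flipped else scores
    fpr, tpr, thr = skm.roc_curve(y, oriented)
    best = int(np.argmax(tpr - fpr))
    return RocResult(
        auc=float(skm.roc_auc_score(y, oriented)),
        auc_raw=auc_raw,
        flipped=flipped,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thr[best]) * (-1 if flipped else 1),
        fpr=fpr,
        tpr=tpr,
    )
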
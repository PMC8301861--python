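# Methods

## Model

The pupil is treated as a one-degree-of-freedom viscoelastic system.
With radius r(t) in mm and every force expressed per unit iris mass,

    r'' = k_d2 (l0 − r)² + k_d1 (l0 − r) − D r' − F_n(t).

The quadratic elastic term follows the classical observation that the
iris stiffens as it is stretched away from rest; the linear term
(`k_d1`) improves the description of the slow re-dilation tail. At the
dark-adapted rest state (r = l0, r' = 0, F_n = 0) every force vanishes,
which fixes the initial conditions of every simulation.

Units: force intensities are quoted in mN and `D` in g/s, but because
the equation is mass-normalised the force values act numerically as
accelerations (mm/s²). `l0` and r are treated as the same length
quantity ("pupil size", mm); with the bundled parameter sets
l0 ≈ 2.5–3.3 mm. The normalised resting size `l0′` divides `l0` by an
iris diameter and rescales by a normalisation constant; both default to
12 mm so that `l0′ = l0` numerically, matching the scale (~3) on which
the bundled cohort summaries report it. Both constants are exposed.

The autonomic drive is a difference of square waves. Activity windows
are left-closed/right-open and an interval whose end does not exceed
its start is empty, so simultaneous on/off switches resolve
deterministically. Note one structural asymmetry taken as printed: the
first sympathetic phase ends at `t_s + t_d + τ_p2`, i.e. it is tied to
the *parasympathetic* offset, after which the sympathetic force drops
to the weaker `f_s1` until `t_s + t_d + τ_s2`.

## Integration

The forcing is piecewise constant, so the ODE is integrated separately
on each segment between force switch times, restarting at every switch.
Two engines share this segmentation:

* `method="adaptive"` (default): scipy RK45 with rtol 1e-8 / atol
  1e-10 — the reference path;
* `method="fixed"`: a numba-compiled classical RK4 with a 1 ms step
  that lands exactly on every switch and sample time.

The two agree to below 1e-7 mm on the bundled parameter sets (asserted
in the tests); the fixed-step kernel is ~30× faster and is what the
grid searches call, since a staged fit evaluates the model a few
thousand times. Before the first force onset the solution is the exact
equilibrium and is returned without integration. Halving the sampling
interval changes the adaptive solution by < 1e-6 mm (also asserted).

## Staged identification

The fit minimises the root-mean-square percentage error

    RMSPE = 100 · sqrt( (1/(N−1)) Σ ((X_i − Y_i)/X_i)² )

between measured (X) and simulated (Y) radii over half-open time
windows (the N−1 normalisation is kept as the method defines it).
`D` is fixed at 4.3 g/s throughout — a diagnostic sweep over a user
supplied D grid (`viscous_sweep`) reproduces the flat-RMSPE analysis
that justifies the choice — and `l0` is read off the mean pre-stimulus
baseline rather than searched.

Six stages scan one or two parameters at a time over bounded grids
(defaults: the bundled search-space table; ties break toward the
smaller value; two-parameter stages alternate until the first
parameter repeats, capped at 20 rounds):

| stage | parameters | window |
|---|---|---|
| 1 | τ_p1, f_p0 | [t_s, t_s+0.4 s) |
| 2 | τ_s1, f_s0 | [t_s, t_s+c) |
| 3 | τ_p2 | [t_s, t_s+1.25c) |
| 4 | τ_s2, f_s1 | [t_s, t_s+3c) (clipped to the trace end) |
| 5 | τ_p2 again | full recording |
| 6 | k_d1, k_d2 | full recording |

where c = t_DCM − t_s and t_DCM is the time of the post-stimulus radius
minimum, found once from the measured trace (earliest sample on ties; a
flat trace falls back to c = a third of the post-stimulus recording,
with a warning). Stages 5–6 had no stated window; the full recording
was chosen because the slow re-dilation tail is the only part of the
response that identifies the elastic constants — with a truncated
window they are absorbed by force-parameter compensation.

Two additions make the scheme self-consistent on traces the model can
represent exactly:

1. **Cycling.** Stage k conditions on values stages k+1…6 have not yet
   corrected (stage 2, for instance, first runs while τ_p2 still sits
   at its initial value). The six-stage cycle therefore repeats until
   the parameter vector is unchanged across a full cycle (cap 10).
2. **Pairwise refinement.** Coordinate scans stall on compensation
   ridges — most prominently force intensities against elastic
   constants, which trade off exactly through the quasi-static balance
   k_d2 x² + k_d1 x ≈ F during long stimuli. A final pattern search
   sweeps every parameter pair over the joint ±5-grid-step
   neighbourhood on the full recording, accepting strictly improving
   moves, until no pair improves. All moves stay on the bounded grid.

Initialisation uses the search-space table's initial values (snapped to
the grid). `random_initialize` implements the alternative documented
start: uniform draws within bounds scored on a 500 ms recording, with
the best draw's ±20% neighbourhood as the narrowed space.

### Practical identifiability — what the fit does and does not pin down

On noiseless self-generated traces the staged+refined fit reaches
RMSPE ≤ 0.5% at every stimulus duration (1 ms – 3 s), but the
*parameters* are not all individually recovered: the objective has a
second, locally stable basin in which the timing block
(τ_s1, τ_p2, τ_s2, f_s1) and the force/elastic block trade off, and
escaping it requires three or more simultaneous grid moves (verified by
exhaustive pair scans finding no improving move). In the worst case
(2 s stimulus) τ_s2 settles 0.35 s from the generating value at an
RMSPE of 0.31%. τ_p1, f_p0 and (via the tail) k_d1 are reliably
recovered; conclusions hinging on the individual late-phase delays
should be drawn with this degeneracy in mind. Derivative-based local
polishing would resolve it but sits outside the bounded-grid search
family this package implements by design.

## Duration analysis

The coefficient of variation Cv = sd/mean (sample sd, N−1) of each
parameter across fitted durations is compared with the 0.15 threshold:
τ_p1, τ_s1, τ_s2, f_p0 and l0 come out stable; τ_p2, f_s0, f_s1, k_d1
and k_d2 sensitive. Each sensitive quantity — with f_s0 replaced by the
composite `f_p0 − f_s0`, the net constricting force of the antagonist
phase, which trends far more smoothly — is regressed on log10(duration)
with a degree-2 polynomial (degree configurable; a constant column
collapses to an intercept). Quadratic-in-log was chosen because the
trends are smooth and gently curved over the 3.5 decades of duration;
R² on the bundled series ranges from 0.35 (`f_p0 − f_s0`) to 0.94
(`f_s1`).

Prediction at a new duration copies the stable parameters from a
reference fit (10 ms by default), evaluates the regressions for the
sensitive ones (reconstructing `f_s0 = f_p0 − predicted composite`),
clips to the search bounds with a warning, and simulates. `direct`
mode instead reuses the reference fit unchanged — its error grows
roughly linearly with duration (~6%/s on the synthetic series, from
~2% at 1 ms to ~19% at 3 s, with one small inversion at 100→500 ms
traceable to the bundled 100 ms column's outlying f_s0), while
regression mode stays below ~3.5%. The supported extrapolation range is
0.5 ms – 6 s.

## Sensitivity

`sensitivity_scan` multiplies one fitted parameter at a time by 1.10,
re-simulates, and reports the full-trace RMSPE and its ratio to the
unperturbed baseline. On noisy synthetic traces the ranking is
dominated by f_p0 and τ_p2 (10/10 seeds in the acceptance check). On a
noiseless self-fit the baseline is zero and only absolute RMSPE is
meaningful; the ratio column is NaN there.

## Cohort statistics

Derived per-recording indices: pairwise delay/force differences; the
impulses Imp1 = f_p0(τ_s1−τ_p1), Imp2 = (f_p0−f_s0)(t_d+τ_p2−τ_s1),
Imp3 = f_s1(τ_s2−τ_p2) (intensity × phase duration; a non-positive
duration zeroes the impulse with a warning); l0′; and
DAN = Imp2·l0′·k_d1. The impulse formulas are the natural
time-integrals of the three drive phases and track the bundled cohort
means; they are isolated in `derive_parameters` so alternatives can be
swapped in.

Group comparison uses the Welch two-sample t statistic (unequal
variance denominator, Welch–Satterthwaite df, two-sided p), implemented
in closed form and cross-checked against scipy in the tests; it accepts
raw samples or summary statistics. No multiple-testing correction is
applied across the parameter rows. ROC analysis reports the empirical
AUC in both the raw orientation (higher score = positive class) and,
when the raw AUC falls below 0.5, the flipped orientation, plus the
Youden-optimal sensitivity/specificity (for DAN the *lower* scores mark
the DM class, so the oriented curve uses the negated score).

## Synthetic data

`generate_trace` adds either additive (mm) or multiplicative
(fractional) Gaussian noise to a forward simulation; the default
recording emulates a pupilometer: 30 samples/s for 15 s with the
stimulus at t = 5 s (5 s of dark baseline, 10 s of recovery). Real
recordings additionally contain blinks, gaze artefacts and
quantisation, none of which are modelled — passing tests demonstrate
correctness of the pipeline on in-model data, not robustness to such
artefacts. The default noise level for recovery experiments, 0.5%
multiplicative, is a conservative choice for video pupillometry and is
configurable.

`generate_cohort` samples healthy and DM parameter vectors from the
bundled group means/sds, truncated at the search bounds (l0: a generous
0.5–8 mm) by rejection, redrawing rows that violate the orderings
τ_s1 > τ_p1, τ_s2 > τ_p2, f_s1 < f_s0. By default the sampler uses the
pairwise correlations implied by the published difference-row sds
(ρ(f_p0,f_s0) ≈ 0.64, ρ(τ_p2,τ_s1) ≈ 0.39, ρ(τ_s2,τ_p2) ≈ 0.29,
ρ(τ_s1,τ_p1) ≈ 0.14 per group): fully independent draws overstate the
spread of the composite f_p0 − f_s0 (1.95 vs the reported 1.21) and
dilute the DAN separation. Higher-order structure of the real cohort is
still not reproduced, so the Monte-Carlo DAN AUC lands in a band
(≈ 0.62–0.66 over seeds) around the clinically reported value rather
than on it; an explicit correlation matrix can be supplied for stress
tests. Eye / intensity / colour labels cycle within participants and
are plumbing, not physiology.

## Numerical choices and degenerate inputs

* Grids include both bounds; grid values are rounded to 6 decimals so
  repeated scans compare exactly; argmin ties take the smallest value.
* Objective evaluations are cached per (parameter vector, window end);
  simulations for windowed objectives stop at the window end.
* A candidate vector whose simulation diverges scores +inf.
* Flat traces: t_DCM degenerates to the onset (warning), windows fall
  back as above, and force intensities are driven to their lower
  bounds, which is warned about as non-physiological.
* Traces shorter than the nominal stage-4 window clip it to the trace
  end with a warning.
* Seeds: every stochastic operation (noise, draws, cohorts) takes an
  explicit seed and is byte-reproducible given one.

## Problem sizes

The bundled benchmark (`scripts/acceptance.py`) fits seven 451-sample
recordings, ~1–15 s per fit on one CPU. Recovery experiments in the
test suite use ten noisy replicates of the 10 ms condition; cohort
checks use the full 336-per-group size of the reference study, which
costs little since no trace simulation is involved.
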
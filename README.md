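# plrkit

Grey-box modelling and system identification of the **pupillary light
reflex (PLR)** — the constriction of the pupil after a light flash and
its slow re-dilation back to the dark-adapted resting size.

The reflex is driven by the two branches of the autonomic nervous
system: the parasympathetic branch constricts the pupil, the
sympathetic branch dilates it. Because both branches act on one easily
measured effector, a mechanistic model of the reflex can turn a
30 Hz pupillometry trace into interpretable estimates of autonomic
drive — of interest, for example, in screening for diabetic autonomic
neuropathy, where the sympathetic innervation of the dilator muscle
degenerates early.

## The model

The pupil radius r(t) (mm) obeys a second-order force balance per unit
iris mass:

    r'' = k_d2 (l0 − r)² + k_d1 (l0 − r) − D r' − F_n(t)

with a nonlinear elastic restoring force (constants `k_d1`, `k_d2`),
viscous damping `D` (fixed at 4.3 g/s), dark-adapted resting size `l0`,
and the net autonomic drive `F_n = F_p − F_s` built from square-wave
pulses:

* parasympathetic: intensity `f_p0` on `[t_s+τ_p1, t_s+t_d+τ_p2)`,
* sympathetic: `f_s0` on `[t_s+τ_s1, t_s+t_d+τ_p2)`, then a weaker
  `f_s1` on `[t_s+t_d+τ_p2, t_s+t_d+τ_s2)`,

where `t_s` is the stimulus onset and `t_d` its duration. The eleven
parameters are identified from a measured trace by a **staged
univariate grid search**: each stage scans one or two parameters over a
bounded grid, minimising the root-mean-square percentage error (RMSPE)
on a physiologically chosen time window (early constriction →
constriction → dilation onset → late dilation), the stage cycle repeats
until stable, and a final pairwise grid refinement walks the fit down
the ridges on which single-parameter scans stall.

On top of the fitter the package provides:

* **duration analysis** — coefficient-of-variation screening
  (Cv < 0.15) splits parameters into duration-stable and
  duration-sensitive sets; the sensitive ones are regressed on
  log-duration so the PLR at unseen stimulus durations can be predicted
  from a single 10 ms fit;
* **sensitivity analysis** — one-at-a-time +10% perturbation of each
  fitted parameter;
* **cohort statistics** — impulse indices for the three phases of the
  reflex (`Imp1 = f_p0(τ_s1−τ_p1)` etc.), Welch two-sample t tests,
  and ROC analysis of the composite score `DAN = Imp2 · l0′ · k_d1`;
* **synthetic data** — noisy traces, duration series and two-group
  (healthy / diabetes mellitus) cohorts generated from bundled
  published summary statistics, so every analysis is runnable without
  access to clinical recordings.

## Worked example

Fit a noisy synthetic 10 ms recording (stimulus at t = 5 s, 30 Hz,
0.5% multiplicative noise) and derive the autonomic indices:

```python
import warnings
from plrkit import (NoiseModel, StimulusSpec, generate_trace, staged_fit,
                    derive_parameters)
from plrkit.reference import duration_study_table

truth = duration_study_table().at(0.01)          # bundled 10 ms reference fit
stim = StimulusSpec(t_s=5.0, t_d=0.01)
trace = generate_trace(truth, stim,
                       noise=NoiseModel("multiplicative-gaussian", 0.005, seed=7))
fit = staged_fit(trace, stim)

print(f"full-trace RMSPE: {fit.rmspe_full:.3f}%")
d = derive_parameters(fit.params, stim)
print(f"Imp1 {d.imp1:.3f}  Imp2 {d.imp2:.3f}  Imp3 {d.imp3:.3f}  DAN {d.dan:.3f}")
```

which prints

```
full-trace RMSPE: 0.461%
Imp1 2.408  Imp2 1.293  Imp3 0.756  DAN 6.286
```

i.e. the model reproduces the noisy trace to within half a percent, and
the three impulses quantify how strongly the parasympathetic-dominant,
antagonistic and sympathetic-dominant phases of the reflex were driven
(the fitted delays land within a few grid steps of the generating
values; see `docs/methods.md` on the identifiability limits of the
timing parameters).

The same operations are available from the shell:

```sh
plr synth trace --duration 0.01 --noise multiplicative-gaussian --seed 7 --out trace.csv
plr fit --trace trace.csv --stimulus trace.yaml --out fit.json
plr sensitivity --fit fit.json --trace trace.csv --stimulus trace.yaml
plr synth cohort --n 336 --seed 1 --out cohort.csv
plr stats --cohort cohort.csv --out comparison.csv
plr roc --cohort cohort.csv --score dan
```

## Layout

```
src/plrkit/
  model.py       forward ODE model, forces, constriction minimum
  identify.py    RMSPE, search space, staged fit, refinement, random init
  duration.py    Cv screening, duration regressions, PLR prediction
  sensitivity.py one-at-a-time perturbation scan
  cohort.py      derived indices, Welch t, ROC / DAN factor
  synth.py       synthetic traces, duration series, cohorts
  reference.py   bundled published parameter tables and summaries
  io.py          trace CSV, stimulus sidecars, parameter files
  cli.py         `plr` command-line interface
```
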
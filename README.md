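# rotorelax

Quantitative analysis chain for small multimodal MRI group studies of
Parkinson's disease (PD) and idiopathic REM-sleep behavior disorder (iRBD):
rotating-frame relaxometry map fitting, resting-state functional
connectivity with motion censoring, and heteroscedastic group statistics —
driven end to end by a synthetic digital-phantom generator with known
ground truth.

## The problem

Rotating-frame relaxation times — adiabatic T<sub>1ρ</sub> and
T<sub>2ρ</sub>, and non-adiabatic RAFF4 (Relaxation Along a Fictitious
Field, rank 4) — are sensitive probes of neuronal integrity, iron and
myelin in subcortical gray matter, and have shown promise for detecting
prodromal synucleinopathy (iRBD) and early PD in ways diffusion metrics do
not. A typical study fits voxelwise relaxation models on pulse-train-weighted
series, averages them over FreeSurfer-style ROI labels, computes seed-based
functional connectivity and regional homogeneity from resting-state BOLD
with aggressive motion control, and compares the per-ROI metrics across
small groups whose variances (and ages) differ. `rotorelax` implements that
chain as a tested, reusable library for anyone who wants to analyse such
data — or to study the chain's statistical behaviour on simulated cohorts
before scanning one.

## Models

**Relaxometry.** For T<sub>1ρ</sub>/T<sub>2ρ</sub>, the signal after a
pulse train of total duration *t* follows
S(t) = M₀·exp(−t/T), fitted per voxel by bounded nonlinear least squares
(2 parameters). RAFF4 relaxes toward a steady state: the paired decay and
recovery series

  S_d(t) = M_ss + (M₀ − M_ss)·e^(−t/T),  S_r(t) = M_ss − (M_z + M_ss)·e^(−t/T)

are fitted jointly (4 parameters: M₀, M_ss, M_z, T). Train durations come
from an acquisition schedule (pulse/packet duration × counts, e.g.
6 ms × {0,4,8,12,16} → 0–96 ms).

**Connectivity.** Frames whose motion-parameter derivative norm exceeds
0.33 mm are censored along with each previous frame; nuisance regression
(Legendre 0–2, out-of-band sines/cosines for 0.01–0.1 Hz band-pass, motion
+ derivatives, 5 aCompCor components from eroded WM and CSF) runs on kept
frames only, and the residual degrees of freedom are DOF = kept − rank.
Seed-based correlations become standard scores via
**Z = arctanh(r)·√(DOF − 3)**; each seed's network is the cluster-filtered
(p < 0.0005, ≥ 20 voxels) one-sample t-test mask over control-group Z maps,
and *network strength* is the mean Z inside it. Regional homogeneity (ReHo)
is Kendall's W over each voxel and its 18 nearest neighbours, z-scored over
the brain.

**Statistics.** Each ROI × metric is compared PD vs control and iRBD vs
control by linear models with group-specific variances (Welch /
Satterthwaite without covariates; two-step feasible GLS with age — plus
mean FD for functional metrics — as covariates), with Holm correction over
the 2 contrasts and Benjamini–Hochberg FDR over the 7 outcomes.

## Worked example

Run the scaled-down demonstration pipeline (compact phantom, 10 controls +
3 iRBD + 3 PD, full 502-volume BOLD runs; about five minutes):

```bash
rotorelax run-all --demo --seed 1 --out-dir runs/demo
```

The run directory contains NIfTI maps and networks, per-subject censor
masks, and CSV tables. With seed 1 the amygdala T<sub>1ρ</sub> comparison
in `results.csv` reads:

```
    contrast  age_adjusted  estimate     se   p_raw  p_holm
  PD-control         False     12.95   8.01  0.2289  0.2289
iRBD-control         False     12.71   3.34  0.0096  0.0193
  PD-control          True      7.97   4.41  0.2650  0.2650
iRBD-control          True      8.04   2.46  0.0269  0.0538
```

Patients' amygdalar T<sub>1ρ</sub> is ~13 ms longer than controls'
(controls 151.3 ± 7.1 ms, iRBD 164.0 ± 4.3 ms, PD 164.3 ± 13.3 ms in
`group_summary.csv`); after age adjustment the estimate attenuates to
~8 ms because the patient groups are ~9 years older and T<sub>1ρ</sub>
lengthens with age — exactly the confound structure the generator plants.
`conn_summary.csv` shows every subject retained ≥ 20 DOF after censoring
(26.1 on average) at a mean framewise displacement of 0.16 mm.

The same machinery is scriptable:

```python
from rotorelax import relaxometry as rx
from rotorelax.synth import default_phantom_spec, default_cohort_spec, \
    generate_phantom, simulate_relaxation_series

labels, truth = generate_phantom(default_phantom_spec(),
                                 default_cohort_spec(seed=0), 0)
series = simulate_relaxation_series(truth, rx.T1RHO_SCHEDULE, 1.0, seed=0)
pmap = rx.fit_parameter_map(series, rx.T1RHO_SCHEDULE, labels > 0)
table = rx.roi_summarize(pmap, labels,
                         default_phantom_spec().label_lookup(), "T1rho")
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its deliberate simplifications, numerical choices, and known limitations.
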
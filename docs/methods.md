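# Methods

## Scope

`rotorelax` implements the quantitative analysis chain of a small
multimodal MRI group study — rotating-frame relaxometry, resting-state
connectivity, and per-ROI group statistics — together with a synthetic
data generator that stands in for raw patient MRI. Everything upstream of
the fitted series is out of scope: no pulse-sequence physics, k-space,
coil combination, registration or segmentation is simulated; phantoms are
generated pre-aligned and pre-labelled, which is the state real data
reaches after standard preprocessing.

## Relaxometry

T1rho and T2rho series decay mono-exponentially with the spin-lock train
duration, `S(t) = M0 exp(-t/T)`. RAFF4 relaxes toward a non-zero steady
state; the experiment acquires the relaxation curve twice, without and
with a global inversion before the packet train, and both curves are
fitted jointly:

    decay:     S_d(t) = Mss + (M0 - Mss) exp(-t/T)
    recovery:  S_r(t) = Mss - (Mz + Mss) exp(-t/T)

with `Mz` the magnitude of the inverted start (the recovery curve starts
at `-Mz`). The parameter list (M0, Mss, -Mz, T) is the published fitting
convention for this contrast; the exponential-to-steady-state form above
is this package's model commitment, since only the parameter list — not
the equations — is conventionally printed.

Evolution times are `counts x unit_duration`: 6 ms pulses at counts
0/4/8/12/16 give 0–96 ms for the adiabatic contrasts; 4.52 ms RAFF4
P-packets give 0–72.32 ms.

Numerical choices:

- Bounded trust-region least squares (`scipy.optimize.least_squares`,
  analytic Jacobians). Bounds: T in (0, 10 s], amplitudes >= 0 — this
  prevents the sign-flip degeneracy of exponential fits.
- Initialization is closed-form: M0 from the first point, T from the
  log-ratio of the first and last points clamped to [1, 5000] ms; for
  RAFF4, Mss from the last decay point and Mz from the negated first
  recovery point.
- Non-finite or all-zero voxels return a non-converged result rather than
  raising; map fitting excludes (never imputes) non-converged voxels and
  logs their count. Voxel iteration order does not affect results.
- ROI summaries pool left- and right-hemisphere voxels *before* averaging
  (a 10-voxel left ROI at 100 ms and a 30-voxel right ROI at 200 ms yield
  175 ms, not 150 ms). Empty ROIs produce flagged missing rows.

## Resting-state connectivity

The first 10 volumes are dropped, then:

1. **Censoring.** A frame is removed when the Euclidean norm of the six
   motion-parameter backward differences exceeds 0.33 mm, together with
   the preceding frame (set union, overlap-safe). Rotations are converted
   to arc length on a 50 mm sphere — the same radius the framewise
   displacement (FD) definition uses; the censoring literature does not
   fix this radius, so it is a documented, configurable assumption.
2. **Nuisance regression** on kept frames only: Legendre polynomials of
   order 0–2; sine/cosine pairs at every Fourier frequency outside
   0.01–0.1 Hz (a high-pass/low-pass equivalent that respects censoring);
   the six motion parameters and their backward-difference derivatives;
   and five aCompCor principal-component time courses from each of the
   white-matter (2-voxel erosion) and CSF (1-voxel erosion) masks,
   Legendre-detrended before the SVD. Rank-deficient designs are solved
   by pseudoinverse (equivalent to dropping collinear columns) with a
   logged warning. Residual degrees of freedom: DOF = kept frames − rank
   of the censored design. Subjects with DOF < 20 are excluded and
   reported, mirroring the exclusion rule such studies apply.
3. **Smoothness normalization.** Global spatial smoothness is estimated
   per axis from the ratio of mean squared first differences to twice the
   variance under a Gaussian-autocorrelation model, and the series is
   convolved with the Gaussian that brings it to an isotropic 4 mm FWHM
   (sigma_add^2 = sigma_target^2 − sigma_intrinsic^2). Targets at or
   below the intrinsic smoothness are no-ops with a warning.
4. **Seed FC.** Pearson correlation of each voxel with the seed-ROI mean
   time course, expressed as Z = arctanh(r)·sqrt(DOF − 3) so subjects
   with different censoring are comparable. |r| is clipped at 1 − 1e-7;
   zero-variance voxels get Z = 0 and are flagged. Each seed's *network*
   is defined on the control group only: voxelwise one-sample, one-tailed
   (positive) t-test over the controls' Z maps, thresholded at
   p < 0.0005, with connected components (6-connectivity, faces only)
   smaller than 20 voxels discarded. *Network strength* is the mean Z
   inside that mask, seed voxels included.
5. **ReHo.** Kendall's coefficient of concordance over each in-mask
   voxel's time series and its up-to-18 in-mask nearest neighbours
   (faces + edges), with mid-ranks and the standard tie correction,
   W = 12S / (m²(n³−n) − m·ΣT). Voxels with fewer than 2 in-mask
   neighbours are masked out. Maps are z-scored over the brain mask.
   Because W is rank-based, any strictly monotone transform applied
   uniformly within a neighbourhood leaves it unchanged.

## Group statistics

Each (ROI, metric) cell is compared PD vs control and iRBD vs control
with group-specific variances:

- **No covariates:** the Welch two-sample comparison with Satterthwaite
  degrees of freedom.
- **With covariates** (age; plus mean FD for the functional metrics):
  two-step feasible GLS — OLS, per-group residual variances (denominators
  share the model's parameter count across groups in proportion to group
  size), then a weighted refit whose Wald contrast is referred to a
  Satterthwaite-type t with per-group denominators n_g − 1 − q. When a
  group's residual df would fall below 1 (or n_g < 3) the normal
  approximation is used instead. Two FGLS steps, not REML: it is the
  minimal estimator consistent with "linear models with group-specific
  variances", and a likelihood-based refinement would change nothing
  qualitative at these group sizes.

Holm's step-down correction is applied over the two contrasts within each
(ROI, metric, adjustment); Benjamini–Hochberg FDR is applied to the
Holm-adjusted values over the metrics within each (ROI, contrast,
adjustment) — the sequential order in which such studies report both
corrections. The between-subject CV is 100·SD/mean within controls per
(ROI, metric), summarized per metric as the mean across ROIs (the pooling
rule is not fixed by convention; the mean is documented and configurable
in code).

## Synthetic data generator

The generator emulates the *statistical* structure of the study data, not
its anatomy or physics:

- **Phantom:** 11 ROIs (accumbens, amygdala, caudate, hippocampus,
  pallidum, putamen, thalamus, midbrain, pons, SNc, SNr) as disjoint
  ellipsoids of >= 30 voxels on a 48x48x30 grid (a 32x32x20 variant backs
  quick demonstrations); all bilateral except midbrain and pons, right
  copies mirrored with offset labels. Geometry is schematic by design:
  every downstream computation consumes labels and intensities only.
- **Subject means:** for metric m in ROI r,
  `mu = control_mean + group_effect + age_slope·(age − 57.3) +
  cv/100·control_mean·z`. Control relaxation means are drawn truncated to
  the physiologic 3 T ranges (T1rho 130–180, T2rho 55–90, RAFF4
  240–410 ms); control ages average ~9 years younger than patients,
  planting the age confound the statistics must handle. Default CVs are
  3% (relaxation), 9/4% (FA/MD) and 22/35% (network strength/ReHo);
  default group effects carry the direction of the study's findings
  (e.g. longer amygdalar T1rho in PD, weaker accumbens network in iRBD)
  with modest user-settable magnitudes, since per-ROI patient means are
  not published. FA/MD values exist only at this table level — diffusion
  preprocessing is out of scope.
- **Series:** voxel values are the subject ROI mean times a 1% log-free
  multiplicative texture; relaxation series add i.i.d. Gaussian noise
  (default SD 1 on M0 = 100, i.e. SNR ~ 100 — the Rician magnitude bias
  is negligible there and deliberately unmodelled).
- **BOLD:** each planted network is a band-limited (0.01–0.1 Hz) latent
  shared by its member ROIs' voxels; every voxel adds AR(1) noise and a
  random quadratic drift; WM/CSF boxes carry their own shared nuisance
  signals for aCompCor to find. Under this additive model two
  within-network voxels correlate at r = a²/(a²+σ²), which the tests use
  as a closed-form oracle. Motion mixes slow sinusoids, white jitter
  (0.02 mm, calibrated so mean FD ~ 0.15 mm as in compliant subjects)
  and translation spikes at randomly chosen frames kept >= 2 apart so
  each spike's derivative norm exceeds 0.33 mm on its own — keeping the
  censoring oracle analytic. Runs default to 502 volumes at TR 0.9 s;
  markedly shorter runs cannot retain 20 DOF because the out-of-band
  spectral regressors consume a fixed ~82% of frames.
- **Determinism:** every draw flows from the cohort seed through
  per-subject, per-stage `SeedSequence` substreams, so any artifact is
  reproducible in isolation regardless of cohort size or stage order.

What passing tests on these phantoms does *not* show: robustness to
registration error, partial-volume effects, physiological noise spectra,
Rician bias at low SNR, or anatomically realistic network topography.

## Pipeline

`synth → relax → conn → stats`, orchestrated by a YAML-serializable
config (lossless round-trip). Each stage reads inputs from and writes
outputs to the run directory, so later stages can be rerun alone against
cached upstream files and reproduce their outputs bit-identically. A
provenance file records each stage's parameters and input hashes. The
demonstration config trims the phantom grid and the patient groups
(10 controls are kept — the p < 0.0005 control-network t-test is
statistically impossible with only 3 maps).

## Known limitations

- The FGLS covariate model uses an approximate Satterthwaite df; exact
  small-sample inference under heteroscedasticity is an open problem and
  group sizes here are small.
- The smoothness estimator assumes a Gaussian autocorrelation and is
  biased at kernel widths near one voxel (about ±0.3 mm at a 4 mm target
  on 2–3 mm voxels).
- Network strength depends on the control-defined mask; with few control
  subjects the mask itself is noisy, which the demo mitigates by keeping
  the full control group.
- ReHo ROI averages from z-scored maps have much smaller between-subject
  CV in the phantom than in real data, where physiology and vasculature
  dominate.
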
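# Methods

## Model and scope

`lungtau` analyzes registered, respiratory-gated 4D CT sequences of a
passively exhaling lung. The inputs are assumed already aligned to a single
reference phase (registration itself is out of scope), with a lung mask in
the reference geometry, optional per-phase Jacobian-determinant or
displacement fields, and optional 200 Hz ventilator waveforms.

Every masked voxel's expiratory density is modelled as a first-order
relaxation toward equilibrium after the step change in airway pressure at
end-inspiration:

    I(t) = D0 + (Dinf − D0) · (1 − exp(−t/τ)),  t = elapsed expiratory time.

The model assumes a single compartment per voxel, pressure-controlled
ventilation with a square airway-pressure wave, periodic breathing (so
gated phases map to fixed within-breath times), and perfect registration
(each voxel samples the same material tissue at every phase). D0 equals the
end-inspiratory density by construction; the end-expiratory density
D_EE = I(t_exp) equals Dinf only when exhalation lasts several time
constants — the gap Dinf − D_EE ("nonequilibrated change") is itself a
reported output.

## Phase timing

With `n_phases` gated volumes per breath at respiratory rate `f` (min⁻¹),
the phase interval is 60/(f·n_phases) s. The expiratory arc starts at the
end-inspiratory phase and spans round(n_phases·E/(I+E)) intervals for an
I:E ratio of I:E (ties round toward more expiratory phases, maximizing
regression samples; at the default 1:2 and 21 phases/20 min⁻¹ this gives a
1/7 s interval, 7 Hz sampling, and 15 expiratory samples over 2.0 s).
End-inspiration is detected as the phase with minimum within-mask mean HU —
the most inflated, hence most gas-rich and least dense, state; ties break
to the lowest index, and a constant sequence raises an error directing the
user to the manual override. The t = 0 end-inspiratory sample is included
in the regression, anchoring D0.

## Estimation

Before regression, sequences are block-downsampled (default factor 2) to
suppress noise. The block mean for an in-mask coarse voxel uses only
in-mask children (the mask itself downsamples by majority vote); this
deviates from a plain block mean only at the lung boundary, where a plain
mean would dilute the signal with extra-pulmonary voxels that carry no
expiratory dynamics.

The model is linear in (D0, Dinf) for fixed τ, so the least-squares problem
is solved by profiling: an exact 2×2 linear solve at each τ on a log-spaced
grid (100 points per decade over the τ bounds [1e−3, 1e2] s), followed by
60 golden-section iterations on the profiled SSE in log τ. The procedure is
deterministic, initialization-free, and attains the global optimum of the
profile at far better than reporting precision (a test verifies the
optimizer never loses to an exhaustive 0.5 HU × 0.5 HU × 0.01-decade
lattice search). Estimates at the τ bounds are flagged `at_bound`; series
that no exponential improves over their mean are returned with τ = NaN and
treated as non-significant. Tiny negative SSE from round-off is clamped
to zero.

## Significance filtering

Each voxel's fit is screened with F = ((SSE_mean − SSE_model)/2) /
(SSE_model/(n−3)) referred to F(2, n−3); voxels with p > 0.05 (configurable
α) are excluded from all regional summaries. A perfect fit yields p = 0.

A caveat the test suite documents explicitly: under the null (constant +
noise) the time constant is unidentified, so profiling τ contributes only
about one effective degree of freedom while the reference distribution
charges two. The filter is therefore conservative — measured type-I error
≈ 3.4% at n = 15 rather than the nominal 5% — and never anti-conservative.
The acceptance suite's calibration check asserts the nominal band and is
expected to fail; the unit suite asserts the honest property (rate within
[2%, 5.6%]).

## Gas-volume dynamics

Jacobian determinants are computed from displacement fields by central
differences (one-sided at the grid boundary; both exact for affine fields),
or taken directly from a supplied Jacobian stack. SACJ combines them with
intensity under the two-compartment assumption (gas −1000 HU, tissue 0 HU):
SACJ_n = J_{n→0}·(I_n/I_0) − 1. Intensities are clamped to [−1000, 0] HU
first; voxels with no gas at the reference phase are excluded and counted.
SACJ is exactly zero at the reference phase by definition (the reference
column is set to 0), and cannot go below −1. SACJ series are fit with the
same regression and filter; the intercept is estimated freely rather than
pinned at 0, mirroring the density regression. On tissue-conserving data
the SACJ trajectory of a deflating voxel leads its density trajectory, so
fitted τ_SACJ < τ_D voxel-wise — the package reproduces this ordering
exactly on noiseless phantoms.

## Regional summaries

* Aeration classes use the standard thresholds (hyper < −900 ≤ normal
  < −500 ≤ poor < −100 ≤ non), intervals closed on the lower (more
  negative) edge. Class grouping for time-constant summaries evaluates the
  end-expiratory model prediction D_EE by default; PRM axes use (D0, Dinf).
* Relative height runs 0 (dorsal-most masked voxel) to 1 (ventral-most)
  along a user-declared gravity axis, normalized over the whole-mask
  bounding range; profiles report median/IQR per bin (default 10 bins).
* PRMs average per-subject probability-normalized 2D histograms (default
  25 HU bins over [−1000, 100] HU). Median-τ and median-nonequilibration
  overlays pool voxels across subjects but appear only in cells where at
  least half of the subjects contribute ≥ 5 voxels each.
* Normalized convergence reports (τ/t_exp, (Dinf−D_EE)/(Dinf−D0)) per voxel
  against the theoretical curve exp(−t_exp/τ); voxels with |Dinf−D0| < 5 HU
  are omitted (ill-conditioned normalization) and counted.
* Density-vs-SACJ time-constant correlation is Spearman's rank per subject
  (τ distributions are heavy-tailed); subjects with < 10 paired voxels are
  skipped.

## The phantom

The generator stands in for non-deposited animal data; its defaults are the
study conditions, chosen once:

* Geometry: 48³ voxels at 1.2 mm (≈3×10⁴ masked voxels), ellipsoidal lung
  minus a cylindrical airway channel — the carved-out channel provides
  excluded-structure voxels analogous to airways and vasculature.
* Timing: 21 phases per breath at 20 min⁻¹, I:E 1:2 (13–21 phases
  supported).
* Aeration structure: classes are assigned by rank-quantiles of a smooth
  latent density field (Gaussian-filtered noise, σ = 3 voxels, mixed with a
  dorsal-ventral trend at weight 0.75), so construction quotas — baseline
  5/60/25/10% hyper/normal/poor/non, injured 5/35/35/25% — are realized
  exactly up to rounding, and the imposed dorsal-denser gradient is
  monotone in height-decile medians rather than only in expectation.
  Equilibrium densities map monotonically into per-class HU sub-ranges kept
  a 5–10 HU margin inside the classification thresholds.
* Dynamics: intratidal amplitudes |Dinf − D0| of 60–180 HU (normal) and
  80–240 HU (poor) at baseline, larger when injured, consistent with the
  up-to-tens-of-percent gas-volume losses such lungs exhibit; hyper- and
  non-aerated voxels are mostly near-constant (< 4 HU) with a changing
  minority (10–30 HU). 2% of voxels are paradoxical (Dinf < D0). Time
  constants span 0.2–1.2 s with the dorsal lung faster (height weight 0.8);
  the whole-lung exhaled-volume time constant defaults to 0.3 s, i.e.
  faster than the regional density time constants.
* Noise: i.i.d. Gaussian, σ = 15 HU — strong enough to stress the F-filter
  at 13–21 samples without breaking parameter recovery after downsampling.
* Ventilator trace: 200 Hz, square pressure wave 20.8/8.1 cmH₂O, 90 ml
  tidal volume (driving pressure 12.7 cmH₂O, dynamic elastance
  ≈ 141 cmH₂O/L — the scale of small-animal pressure-controlled
  ventilation).
* Deformation: the analytic mode emits tissue-conserving Jacobians
  J = (I0+1000)/(I_n+1000) from noiseless intensities; the displacement
  mode emits a uniform axial compression whose determinant is known in
  closed form.

What the phantom does not emulate: CT texture and beam-hardening artifacts,
cardiac-motion asynchrony, breath-to-breath variability, registration
error, or spatially correlated noise. Passing tests therefore demonstrate
the correctness of the estimation and analysis chain under the stated
model, not robustness to those real-data effects. Inspiratory phases are a
time-reversed mirror used only by end-inspiration detection; inspiratory
time constants are out of scope.

## Problem sizes and numerical choices

The test suite fits the 48³ phantom at σ = 15 HU through the standard
factor-2 path (recovery judged against block-averaged truth: ≥ 95% of
non-constant voxels pass the filter, median relative τ error ≤ 10%) and the
same phantom noiseless at factor 1, where block mixing of heterogeneous τ
would otherwise dominate the 1e−4 s recovery tolerance. The gravitational
structure check uses a 64³ phantom so the small decile bins at the
ellipsoid caps hold enough voxels for stable medians. Null-calibration uses
10⁴ pure-noise voxels. Excluded-voxel encoding in all serialized maps is
NaN; geometry metadata propagates from the input sequence to every output.
DICOM is not supported — NIfTI-1 only, with CSV traces, TSV tables, and
JSON configs/sidecars.

## Known limitations

* The F-filter's conservativeness (above) means the realized exclusion rate
  on null-like tissue is below α; no multiple-testing correction is
  applied, matching the per-voxel screening design.
* τ estimates beyond ≈ half the expiratory duration are increasingly
  uncertain at realistic noise; bounds flagging (`at_bound`) marks the
  pathological cases but wide τ in slow regions carry broad implicit CIs.
* The two-compartment HU assumption breaks in voxels dominated by blood or
  contrast; such voxels are clamped and, when gas-free at reference,
  excluded from SACJ analyses.
* "Subject" at phantom scale means one generated sequence (one seed);
  aggregate analyses accept lists of per-subject fit tables.
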
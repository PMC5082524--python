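# Methods

This note documents the models, parameter choices and numerical conventions
of the package, and what its synthetic cohorts do and do not establish about
real data.

## Experimental design and design matrix

The localiser run is 40 contiguous 16-s blocks (640 s): 36 experimental
blocks and fixation at positions 1, 14, 27 and 40. The experimental part
cycles three fixed block orders — (objects, scenes, scrambled),
(scrambled, scenes, objects), (scenes, objects, scrambled) — until each has
appeared four times, giving 12 blocks per category. Trials are 200 ms
stimulus + 800 ms ISI, i.e. 16 per block. Only the post-discard series is
simulated: `n_volumes = ceil(640 / 3) = 214` at TR = 3 s.

The HRF is a difference of two gamma densities parameterised by mean lag
and SD: peak 6 s, undershoot 16 s, both dispersions 3 s, undershoot ratio
1/6, sampled at 0.1 s and peak-normalised. With this parameterisation the
positive lobe peaks at ~4.5 s. Block onsets are not TR-aligned (16 s blocks
vs 3 s TR); boxcars are built at micro-time resolution, convolved, and
evaluated at the exact volume times with no slice-timing offset. Each
regressor's peak-to-peak height is recorded for percent-signal-change
scaling (the Featquery convention).

High-pass filtering is Gaussian-weighted running-line detrending
(σ = 50 s): at each time point a straight line is fitted by weighted least
squares and its fitted value subtracted; the grand mean is added back so
baseline-relative scaling stays meaningful. The same operator is applied to
data and condition regressors. Note the measured transfer of this filter:
it removes a linear ramp exactly and passes a 32-s sinusoid at ≥ 90%, but a
128-s cosine is attenuated by only ~5% — the running line cannot track
oscillations shorter than its ~±2σ window. The simulated drift (single
cosine, period 128 s, amplitude 1% of baseline, random phase) therefore
largely survives filtering; it inflates residual variance slightly and
leaves whole-map null Z variance at ~0.95 (mildly conservative), while the
Z = 3.9 in-ROI tail remains within 3 binomial SEs of the nominal
one-sided normal tail (verified by the calibration study).

## First-level GLM

Ordinary least squares per voxel, no prewhitening (temporal autocorrelation
is out of scope; simulated noise is white). `σ̂² = SSR/dof`,
`dof = n − rank(X)`. Contrasts are the four condition differences; the main
contrast throughout is scenes > objects. t statistics are converted to Z by
matching tail mass in log space (`Z = −ndtri_exp(log SF_t(|t|))`, signed),
which keeps |t| up to ~40 finite. Voxels whose series the design fits
exactly (constants, noiseless planted signal) have their roundoff-level
residual variance clamped to zero and are assigned Z = 0 rather than NaN or
±∞. Spatial smoothing is separable Gaussian with
σ = FWHM / (2√(2 ln 2)) / voxel size; FWHM 0 is the identity, and smoothing
is applied to the BOLD series before fitting, with the level recorded on
every Z map and never inferred.

Percent signal change:
`PSC = 100 · (β_condition − β_scrambled) · regressor_height / baseline`,
averaged over ROI voxels. Because the simulator scales effects by the
unit-peak-to-peak regressor, a planted 2% amplitude recovers PSC = 2.0.

## Template, ROIs and transforms

The template is a desk-scale stand-in for a 2-mm standard grid: default
40×48×40 voxels at 2 mm, origin placed so y spans negative (posterior) and
positive values; a 30×36×30 grid is used for the validation studies. ROIs
are bilateral mirrored ellipsoids at fixed documented template coordinates
(right-hemisphere centers / semi-axes, mm):

| ROI | center | semi-axes |
|-----|--------|-----------|
| PHG | (18, −26, −12) | (6, 6, 5) |
| RSC | (8, −36, 6) | (6, 6, 6) |
| TOS | (22, −36, 16) | (5, 6, 7) |
| HC  | (20, −8, −12) | (4, 11, 4) |

Masks are pairwise disjoint by construction (a configuration error is
raised if a grid cannot hold them). The HC is elongated along y; its
anterior/posterior boundary on this template is y = −8 mm (the long-axis
midpoint). The standalone long-axis classifier defaults to the conventional
uncal-apex y = −21 mm for MNI-style coordinates; every output table reports
the split actually used. The boundary itself counts as anterior.

Subject↔template transforms are rigid integer-voxel translations (up to ±2
voxels per axis by default). This keeps nearest-neighbour resampling exact
in both directions, so mask and map transport introduce no interpolation
error; fractional registration error is a known limitation, not modelled.

## Synthetic cohort

Signal model per subject:

```
y(v, t) = B · (1 + m_scene(v)·r̃_s(t) + m_object(v)·r̃_o(t)) + drift(t) + ε(v, t)
```

with baseline B = 100, r̃ the HRF-convolved boxcars normalised to unit
peak-to-peak, and ε white Gaussian. Effect maps are isotropic Gaussian
blobs (FWHM 4 mm, truncated at 3σ) centred at the subject's planted center
in each ROI; the blob is sized to the reduced template — the ROIs here are
only ~10–22 mm across, so a cortical-scale 8-mm blob would overflow entire
masks and defeat per-ROI attribution. Object effects reuse the scene blobs
at a smaller amplitude (default 0.5%), making scenes>objects the operative
contrast.

Defaults and their rationale:

- **Scene amplitudes** (% of baseline): PHG 3.5, TOS 3.2, RSC 2.6, HC 2.4,
  SD 0.3 across subjects. Chosen a priori by a closed-form power analysis:
  with the design's contrast SE multiplier and 2% noise, the implied
  per-voxel detection probabilities reproduce the reported behaviour of a
  strongly scene-selective cohort (PHG ≈ 100% at Z = 2.3 and > 90% at 3.9;
  HC ≈ 88% at 2.3 collapsing towards ~30% at 3.9).
- **Noise** SD 2% of baseline (single-voxel temporal SNR 50, typical of
  3 T EPI at this voxel size); temporally white — AR structure is out of
  scope.
- **Jitter** of subject centers: isotropic Gaussian, SD 2 mm, clamped to
  the nearest in-ROI voxel center (all reported coordinates are voxel
  centers).
- **Drift**: cosine, period 128 s, amplitude 1, random phase.
- **Seeds**: every stochastic operation takes an explicit seed; per-subject
  seeds derive from `SeedSequence([base_seed, subject_index, stream])`, so
  a cohort is a pure function of its spec.

What the generator does *not* emulate: anatomy, physiological noise,
motion, susceptibility distortion, slice timing, autocorrelated noise,
non-rigid registration error, and inter-subject variability in HRF shape.
Passing recovery and calibration tests therefore demonstrates correctness
of the analysis chain under its own assumptions, not robustness to real
acquisition artefacts.

## Overlap and consistency statistics

Overlap maps sum binarised unsmoothed subject maps on the template grid
(any smoothing level can be requested; unsmoothed is the default to
maximise spatial accuracy). Percentages are reported relative to the number
of subjects with any suprathreshold in-ROI voxel at that threshold, rounded
half away from zero to match printed whole-number percentages (30/51 →
59%). Peak ties — in overlap maps and Z maps alike — are broken by the
smallest linear index in raster order with x fastest, then y, then z; this
is deterministic and documented rather than meaningful. Thresholding is
strict (`Z > threshold`), which affects only measure-zero cases.
Peak-to-peak distances are Euclidean mm reported to 0.1 mm. The 5-mm
sphere utility counts voxel centers within the radius inclusively (81 on a
2-mm grid when centred on a voxel center).

## Group inference

The mixed-effects weighting of the original pipeline is not reproducible
from its description, so the group model is voxel-wise one-sample OLS on
subject contrast maps (5-mm smoothed, transported to template space),
mapped through the same t→Z transform. Zero-between-subject-variance voxels
are capped at Z = ±8.2 rather than ±∞. Cluster-extent FWE control replaces
Gaussian-random-field theory with sign-flip permutations: under the
one-sample null the subject maps are sign-symmetric, so random per-subject
sign flips yield the null distribution of the maximum suprathreshold
cluster size (26-connectivity, the FSL convention) at the cluster-forming
threshold; observed clusters are kept iff their extent exceeds the
(1 − α) empirical quantile ('higher' interpolation), with the identity flip
included in the null. Implementation detail: permuted maps are thresholded
on the t statistic at the t value equivalent to the Z threshold (the
transform is monotone), avoiding a Z conversion per permutation; the
suprathreshold sets are identical.

The FWE calibration study draws subject maps as smooth unit-variance
Gaussian random fields (FWHM 5 mm) rather than regenerating full BOLD
cohorts: the sign-flip null concerns only the between-subject distribution
of contrast maps, and smooth fields match the spatial smoothness of real
group inputs while keeping 200 replicates × 200 permutations inside a few
minutes. Measured FWE: 0.04–0.05 against the nominal 0.05 (binomial 95% CI
0.02–0.08 at n = 200).

Cohort summaries: the binomial preference matrix scores 1 iff scene PSC
strictly exceeds object PSC (exact ties score 0). Cochran's Q uses
`Q = k(k−1) Σ_j (G_j − T/k)² / (k ΣL_i − ΣL_i²)` with df = k − 1 (for four
regions df = 3; published reports sometimes print df = k, which is an
error) and an all-constant-rows matrix yields Q = 0, p = 1. Paired effects
report t and Cohen's d = mean(diff)/SD(diff); identical samples return
t = d = 0, while a constant non-zero difference (no variance to test
against) raises. No multiple-testing correction is applied across the four
ROI tests, matching common reporting practice; this is a documented choice.

## Validation problem sizes

The calibration and recovery studies run on a 30×36×30 grid at 2 mm:
null calibration on one 10-subject amplitude-0 cohort (~8,000 in-ROI voxel
draws against a 4.8×10⁻⁵ tail), FWE on 200 null replicates of 10 smooth
fields with 200 permutations each, and recovery on 20 replicate cohorts of
20 subjects with zero jitter and a 3% planted amplitude — sizes chosen so
the full suite completes in minutes on one CPU while keeping the binomial
error of each estimate well inside its acceptance band.

## Known limitations

- OLS first-level and group models (no prewhitening, no mixed-effects
  variance weighting); inference is calibrated for the simulated white
  noise, and would be optimistic on strongly autocorrelated real data.
- GRF-theory cluster p-values are not implemented; permutation is the only
  correction offered.
- Rigid integer-voxel affines make resampling exact; real registration
  error would blur overlap maps and lower peak percentages.
- The desk-scale template's ROI coordinates are stand-ins: distances and
  counts are meaningful within this frame, not anatomically.
- The drift term is barely attenuated by the σ = 50 s filter (see above);
  it is retained as a mild model-mismatch stressor and its effect on null
  calibration is measured, not assumed.
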
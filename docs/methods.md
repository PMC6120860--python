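# Methods

This note documents the quantification pipeline, the synthetic data model
used to validate it, and the numerical choices made where the design was
genuinely open. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Image quantification

**Channel handling.** Device exports may be RGB (converted JPEG/PNG) or
grayscale. RGB inputs are split and the red channel kept as the reference
plane, matching the common ImageJ-based OCT-A workflow; grayscale inputs
pass through with a log note. 16-bit or float inputs are rejected rather
than silently rescaled. JPEG inputs are accepted with a logged warning that
lossy compression can shift threshold bounds; all internal fixtures are
lossless PNG.

**Auto-threshold.** The default binarization reproduces the iterative
intermeans (IsoData-variant) rule on the 256-bin histogram with the
dark-background convention: start at ⌊mean⌋, iterate
t ← ⌊(mean(pixels ≤ t) + mean(pixels > t))/2⌋ to a fixed point (the floor
at every step is the tie-break; convergence is defined as an unchanged t,
and at most 256 iterations are ever needed), then report inclusive bounds
(t+1, 255). A brute-force scan over all candidate thresholds serves as the
oracle in tests. Constant images have no threshold and fail loudly. The
lower bound is **inclusive** (a pixel equal to the bound is vessel),
mirroring in-range semantics of the thresholding tool this models. A fixed
bounds mode (e.g. 60–255) is available as an override; auto mode is the
default pipeline path.

**Perfusion density.** PD = 100 · |vessel ∧ ¬FAZ| / (N − |FAZ|). FAZ takes
precedence where masks overlap: a vessel-labeled pixel inside the FAZ
counts in neither numerator nor denominator. This matches the rendering
convention (FAZ painted blue over the binarized image) and is tested
against an independent nested-loop count.

**FAZ.** The reference protocol outlines the FAZ by hand; `octara` ingests
such outlines as polygons (pixel-center-inclusive rasterization of a simple
polygon; self-intersecting or collinear outlines are rejected) or binary
masks. For unattended runs an automated surrogate is provided and clearly
labeled as such in the `method` field: the vessel mask is closed with a
disk of radius 2 px (≈ 24 µm at 3 mm/245 px — seals inter-capillary gaps
narrower than a capillary caliber without bridging the FAZ; configurable),
then the 4-connected background component containing the foveal center is
taken. 4-connectivity is deliberately conservative against diagonal leaks.
A seed landing on a vessel pixel triggers a 5×5 neighborhood search; a fill
covering more than half the field indicates a broken perifoveal ring and
fails rather than returning a runaway area. Visits are always segmented
independently.

**Choriocapillaris MGV.** Arithmetic mean of the raw 8-bit
choriocapillaris slab at full precision. A provenance flag guards against
accidentally passing a thresholded image.

**EZ width.** Auto mode smooths the 9-mm profile with a 5-sample moving
average, thresholds at half of (max − min), and converts the length of the
half-maximum run containing the global peak to µm at scan_mm·1000/length_px
per pixel. Flat profiles return 0 with a warning. Manual mode is
(right − left + 1) pixels, inclusive of both grader-marked columns. The two
agree within 2 pixel-widths on noiseless plateaus (tested). The half-max
estimate is biased wide for plateaus narrower than the shoulder smoothing
(≲ 40 µm); such widths are below the clinical range the pipeline targets.

**Cohort bookkeeping.** One eye per patient enters statistics (best mean
scan quality, ties to the right eye); eyes with any scan quality below 7/10
are excluded and logged. Visit dates are ISO-8601 and Δt = days/365.25.
Per-image failures are recorded and skipped; a run with more than 50%
failures aborts.

## Statistics

Change over time is (follow-up − baseline)/Δt per eye. The battery uses
two-sided tests throughout at α = 0.05: one-sample Student's t against 0
for mean rates, paired t between visits and between SCP and DCP (identical
to the one-sample test on differences, verified to machine precision),
Pearson correlations with p from the t-transform. Dispersion follows the
clinical reporting convention: SD for visit-level means, SEM for rates
(both always present in the CSV). Analyses are complete-case per metric
with the n used always reported; a metric with zero variance is surfaced
as a status rather than crashing the table. No multiple-testing correction
is applied by default — matching how exploratory correlation grids are
commonly reported — with Benjamini–Hochberg available behind a flag.
Inter-grader reliability is the Pearson r between two graders' series; the
element-wise mean is what enters downstream analysis.

## Synthetic data model

The generator emulates the statistical structure of a two-visit RP cohort;
it makes no attempt to model OCT physics (no decorrelation statistics,
projection artifacts, or device slab segmentation).

**Vasculature.** Vessels grow as biased random walks seeded on the field
edge (heading jitter SD 0.22 rad/step, branching probability 0.035/step,
stroke width 1–3 px), an irregular star-convex avascular zone (a disk
radius perturbed by low-order Fourier modes) is carved at the center, a
one-pixel capillary ring is closed around it, and the masks are adjusted
pixel-by-pixel to hit the requested perfusion density and FAZ pixel count
exactly (up to rounding: FAZ to ±1 px, PD to far better than the ±0.5
percentage-point contract). Truth is defined by the masks themselves, so
recomputing PD/FAZ from them is exact by construction.

**Rendering.** Background pixels follow a Rayleigh distribution
(scale 18) — the amplitude statistics of fully developed speckle — and
vessel pixels are N(98, 13), rounded and clipped to [0, 255]. These
constants were calibrated once so that (a) the intermeans auto-threshold
lands at gray level ≈ 60, the bound reported for the reference protocol,
and (b) binarization recovers true PD to within ~0.4 percentage points.
The perifoveal ring is rendered with a gray floor of 78: on real scans the
juxtafoveal ring is a continuous strong flow signal, and a single dark
ring pixel would let the flood-fill segmentation leak. The intermeans rule
itself degenerates on near-avascular images (the fixed point collapses
into the background mode below ~3% vessel fraction, measured directly), so
the cohort model keeps densities ≥ 5% — scans sparser than that are
outside what the study's thresholding method can segment.

**Longitudinal pairs.** The follow-up visit is derived from the baseline
truth, not re-generated: density decline prunes boundary pixels of the
network, and FAZ enlargement dilates the region compactly over the
marginal capillaries (capillary dropout at the FAZ margin), closing a
fresh ring at the new boundary. With an unchanged FAZ, a pure decline
never adds a vessel pixel. When dilation consumes more capillaries than
the requested decline removes, the deficit is restored as network
thickening outside the FAZ so that both requested deltas are realized
exactly. (An earlier variant that grew the FAZ only through avascular
corridors left sub-resolution tendrils that morphological closing sealed
over, biasing measured FAZ growth low; the compact rule removed that
bias — see the recovery numbers below.)

**Choriocapillaris and EZ.** The choriocapillaris is a granular texture:
target MGV plus Gaussian noise (default SD 25 gray levels), clipped and
rounded; with zero noise the image is constant at the nearest representable
8-bit level (ties to even). EZ profiles are a baseline (60) plus a plateau
of the requested physical width (contrast 100, Gaussian shoulders σ = 2 px,
additive noise SD 6 by default) on 1024 samples over 9 mm.

**Cohorts.** Per eye: follow-up ~ N(1.3, 0.46²) yr truncated at ≥ 0.5
(matching a clinic's "at least 6 months apart" re-visit pattern); baseline
values for (SCP PD, DCP PD, SCP FAZ, DCP FAZ, MGV, EZ, BCVA) from a joint
Gaussian with configurable correlation matrix (validated positive
semidefinite); per-eye true yearly rates drawn independently per metric
from N(rate mean, between-eye SD). The default parameters are the study
conditions this package targets: baselines 33.4 ± 11.1 and 24.5 ± 9.69 %
(PD), 0.345 ± 0.226 and 0.784 ± 0.389 mm² (FAZ), 99.5 ± 11.1 (MGV),
2674.9 ± 1766.8 µm (EZ), 0.28 ± 0.30 logMAR (BCVA); rate means −2.42,
−2.41 %/yr, +0.078, +0.152 mm²/yr, +1.36 gray/yr, −107.03 µm/yr, +0.049
logMAR/yr. **The ± printed with a cohort rate is read as its standard
error**: the accompanying P-values are consistent only with that reading
(e.g. t = 2.42/0.62 ≈ 3.9 at 27 df gives the reported P ≈ 0.001, whereas
an SD reading would give t ≈ 20), so the generator draws per-eye rates
with between-eye SD = SEM·√28. This is documented prominently because the
per-eye variance of rates is inferred, not printed. Correlation entries
involving EZ and BCVA follow the reported visit-1 grid; correlations among
the OCT-A metrics themselves are unreported and set to plausible values
fixed once (matrix smallest eigenvalue ≈ 0.18).

Table-only mode returns the raw Gaussian draws (exact marginals and
correlations — this is what calibration and correlation-recovery use).
Image mode truncates baseline draws to renderable ranges by whole-eye
redraws (PD ≥ 5%, FAZ ≥ 0.05 mm², EZ ∈ [300, 8500] µm), clips follow-up
values to physical bounds, renders everything, and records the realized,
pixel-quantized truth. Every stochastic step is driven by one seeded
generator; identical spec + seed reproduce identical bytes.

**What passing recovery shows — and what it does not.** Recovery tests
show the pipeline is an unbiased, correctly calibrated measurement chain
for images whose noise and geometry match this model. Real OCT-A adds
projection artifacts, motion lines, segmentation errors, vignetting and
signal-dependent speckle that the model deliberately omits, so recovery
here bounds algorithmic error, not device error.

## Validation results (computed by the suite / acceptance script)

With 28-eye cohorts at the default conditions, recovered cohort-mean rates
averaged over seeded replicates sit well inside two standard errors of the
configured truth for all six longitudinal metrics (a 30-cohort check during
development put the largest bias at +0.20 %/yr on DCP PD against a ±1.52
band, driven by the 5% density floor and threshold wobble on the sparsest
eyes). Correlation recovery at n = 5000 lands within 0.02 of the
configured ρ. Under a true zero rate the one-sample test rejects at the
nominal 5% (±2 points over 1000 replicates), and its null p-values pass a
KS uniformity check.

One documented gap: the expectation that a cohort with mean/SEM structure
−2.42/0.62 at n = 28 reaches p ≤ 0.01 in at least 90% of replicates is not
attainable by a correct test — the exact noncentral-t power of that design
(ncp 3.90, df 27, two-sided α = 0.01) is 0.861, and the corresponding
check is left failing deliberately rather than loosened.

## Known limitations

- The automated FAZ surrogate requires an intact perifoveal ring; it is a
  stand-in for manual outlining, not a replacement, and the `method` field
  records which produced each area.
- The branching-walk vasculature reproduces density and FAZ geometry, not
  the true topology (no closed capillary loops away from the FAZ, no
  flow-direction anisotropy).
- Only two time points and a linear change model are supported; with two
  visits nothing more is identifiable.
- The EZ auto-width assumes a single central plateau; fenestrated EZ bands
  would need grader input.
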
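# Methods

This note documents the models, algorithms and parameter choices behind
`mfoct`, and what the synthetic phantom does and does not emulate.

## Data model

Volumes are complex dual-channel tomograms `S_V, S_H = A·e^{jφ}` on a
`(z, x, y, t)` grid: axial depth, fast scan, slow scan (B-scan position) and
repeat index.  The emulated protocol acquires 512 A-scans per B-scan at 400
positions with 5 repeats and ~1536 axial pixels; the default pixel pitch is
2 µm/px both axially and laterally.  Spectrometer-domain processing
(λ→k mapping, dispersion compensation, Fourier transform) is upstream of
this package: the pipeline ingests reconstructed complex tomograms from a
documented HDF5 layout (`S_V`, `S_H` datasets plus pixel-size and B-scan
period attributes).

## Synthetic phantom

The phantom generates the statistical structure each downstream stage
assumes, from a single seeded RNG (same spec + seed ⇒ bit-identical output):

* **Scene**: a piecewise-constant reflectivity template over seven regions
  (vitreous 0.01, NFL+IPL 1.3, INL 0.45, OPL 0.85, ONL 0.35, RPE–CH complex
  1.4, below-choroid 0.05 — relative units), with six boundary surfaces and
  a gentle parabolic bowl (default 4 px sag).  A mouse-scaled geometry puts
  the total retina at 105 px ≈ 210 µm, the inner retina (ILM→OPL/ONL) at
  60 px ≈ 120 µm.
* **Speckle**: per-voxel circularly-symmetric complex Gaussian fields with
  variance equal to the template (fully developed speckle, Rayleigh
  amplitudes).  Static tissue shares one speckle realization across repeats;
  flow voxels redraw it per repeat (mixing parameter `flow_decorrelation`,
  default 1 = fully decorrelated).  Note this idealization means repeat
  averaging does not reduce *static* speckle in the phantom — only additive
  noise — so segmentation is validated under full speckle contrast.
* **Noise and SNR**: additive complex Gaussian detection noise per voxel,
  repeat and channel.  `snr_db` (default 20) is the ratio of unit template
  reflectivity to the total background noise intensity.  `snr_db = inf`
  yields the deterministic noise- and speckle-free template (used by
  noiseless limit tests).  Noise is added *after* the motion shift: motion
  displaces tissue, not the detector noise floor.
* **Polarization**: each B-scan gets one random pure Stokes state shared by
  all polarization-preserving voxels; Jones fields are synthesized from the
  state so `I² = Q² + U² + V²` holds exactly per voxel.  Depolarization is
  modeled by replacing the voxel state with an isotropic random unit vector
  with probability equal to the scrambling strength: the RPE–CH complex
  uses 0.85, and a deposit with DOPU target `d` uses `1 − d`, so the
  windowed DOPU expectation approximates the target.  The defaults (RPE
  scrambling 0.85, deposit target 0.3) are package choices — the source
  acquisition reports no quantitative scrambling values.
* **Vessels** are tubes along the slow axis (crossing every B-scan as a
  small disc, like real vessels crossing the raster): two inner-plexus
  vessels (radius 3 px, reflectivity 2.0 — large NFL vessels are bright),
  one OPL capillary (radius 1.5 px, reflectivity 0.85 = its surrounding
  plexus; capillary blood is not distinguishable from plexus tissue in
  reflectivity — the motion contrast reveals it), and, in the pathology
  scene, an outer sprout near the RPE (reflectivity 2.0) emulating
  intraretinal neovascularization.
* **Lesions** are saturated hyperreflective spheres (reflectivity 5.0,
  ≈3.5× the RPE–CH complex) straddling the ONL/RPE, as neovascular lesions
  appear in reflectivity B-scans.  **Deposits** are 7-px spheres of
  scrambled voxels with mildly elevated reflectivity (×1.5).
* **Motion**: a pure axial sinusoid (default 30 px, 1 Hz) sampled at the
  B-scan period and applied as an integer-pixel shift per B-scan, plus a
  uniform random bulk phase per B-scan.  Reduced-scale scenes keep the full
  protocol's ~15 s duration by scaling the B-scan period, so a volume always
  spans ~15 respiratory cycles regardless of B-scan count.
* **Longitudinal series**: the OPL/ONL→RPE distance shrinks linearly at the
  programmed µm/month rate (months of 30.44 days) by moving the RPE and CH
  boundaries anteriorly; each timepoint is generated from an independent
  child seed.

Not emulated: wave propagation or Jones-matrix tissue response (no NFL
birefringence — retardation and axis orientation are out of scope), vessel
shadowing, lateral speckle correlation, eye drift in x/y, partial static
speckle decorrelation between repeats.  Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
performance on every property of in-vivo data.

## Pre-processing

The retina position in each A-line is the argmax of the cumulative
log-intensity sums differenced over a 15-px window on each side (a
difference-of-local-means edge score).  The log scale (floored at 10⁻⁴ of
the mean positive intensity) makes the vitreous→retina transition dominate
every intraretinal edge by an order of magnitude; the windowed form keeps
the estimator usable under speckle while reproducing the exact argmax
behavior on clean edges (ties break to the smallest z; all-zero columns are
missing).

Per-B-scan axial shifts are the residuals of the per-B-scan median retina
depth around a robust quadratic trend over acquisition order: the trend
absorbs the smooth retina shape across the slow axis while the ~1 Hz
oscillation (many cycles per volume) survives into the residual.  After
removing the shifts, a robust bivariate quadratic (one reweighting pass
dropping residuals beyond 3× the scaled MAD) is fitted to the per-A-line
depth estimates and mapped to a constant target depth.  All shifts are
integer-pixel — complex data is never interpolated, adequate at 2 µm/px —
and vacated rows are filled by edge replication so no artificial zero→noise
edge is created.  Repeats are registered by 1-D cross-correlation of mean
A-line profiles before arithmetic averaging; repeats flagged as severe
motion (|shift| > n_z/2) are excluded.

## DOPU

Stokes components follow `I = |S_H|²+|S_V|²`, `Q = |S_H|²−|S_V|²`,
`U = 2·Re(S_H S_V*)`, `V = 2·Im(S_H S_V*)` (DOPU is invariant to the sign
conventions).  Components are normalized per pixel before window averaging
so bright pixels do not dominate.  The background threshold is
`mean + 3·sd` of the vitreous intensity ≥20 px anterior to the provisional
ILM.  The window (default 3 × 9 × 5, z × x × t) is truncated at volume
edges, with the >80% bright-pixel rule applied to the truncated size; when
a volume has fewer repeats than the window's t-extent the driver clamps the
t-window to the repeat count.  Invalid voxels are NaN and excluded from all
statistics.

## Angiography

Repeats of one B-scan set are screened against the set median frame: the
axial lag is found on mean A-line profiles, and a repeat is dropped when the
lag exceeds 5 px or the lag-aligned 2-D amplitude correlation falls below
0.5 (the 2-D check catches speckle-decorrelated repeats whose mean profile
still matches).  Bulk phase is removed per consecutive pair as the single
global offset `arg Σ C_{i+1} C_i*` summed over both channels, applied
cumulatively so all frames align to the first.  The flow signal is the mean
over consecutive retained pairs of `√(|ΔS_V|² + |ΔS_H|²)`; fewer than two
retained repeats marks the B-scan missing.

## Segmentation

Each boundary is a minimum-cost left-to-right path (dynamic programming
over the column DAG — exactly the shortest path on the pixel graph) with
vertical steps limited to 3 px/column on flattened data.  The cost is
`1 − (1−ε)·g⁺/max(g⁺)` from the signed axial backward difference of a
Gaussian-smoothed image.  Per-boundary rules: the high-dynamic-range
transitions (ILM, anterior RPE, posterior CH) are detected on the
log-scaled image with σ = (2, 5) px smoothing, where their contrast dwarfs
intraretinal structure; the weaker inner interfaces use the linear scale
with heavier σ = (4, 9) smoothing against speckle.  Normalization is per
column over the search band only, so a strong edge elsewhere cannot deflate
a boundary's own contrast.  Search order and bands: ILM over the full
depth; posterior CH at least 40 px below the ILM; anterior RPE inside a
band 55..15 px anterior to the CH — anchoring the RPE on the CH keeps
bright intraretinal structures (vessels, lesions) out of its search; then
IPL/INL, OPL/ONL and INL/OPL between the surfaces already found with 5-px
margins.  Ties prefer the flattest step and then the smallest z (a constant
cost image yields the flat path at z = 0).  Paths are reported at the
half-pixel edge position (the backward difference localizes an edge between
two pixels).  A collapsed inner band degenerates to riding its anterior
limit rather than failing the whole volume; `segment_boundary` itself
raises on infeasible bands.

3-D refinement median-filters each surface across 5 B-scans, replaces
points deviating more than 10 px (marked as interpolated) and re-enforces
the anterior→posterior ordering by sequential max-projection.  The RPE–CH
reference plane is a robust quadratic fit to the (RPE+CH)/2 midline,
clamped between the two surfaces.

## Projections and evaluation

The outer-retina variance map is the axial intensity variance over the 50
voxels (≈100 µm) immediately anterior to the RPE–CH reference.  Thickness
maps: TR = RPE − ILM, IR = OPL/ONL − ILM, OR = TR − IR (exact by
construction), in µm.  The minimum-DOPU projection spans ILM to 5 px
anterior to the RPE — excluding the physiologically depolarizing RPE so
intraretinal deposits are not masked.  The depth-coded angiography map
records the maximum flow signal between ILM and RPE and its normalized
depth fraction (0 = ILM, 1 = RPE), rendered green→red.

Annulus quantification averages a map over pixels with
`inner ≤ d < outer` from the ONH center (defaults 125/225 px at 2 µm/px);
pixels outside the acquired field count as uncovered, and the mean is
reported only when coverage is at least 75%.  Deposit depths are normalized
as `(z − ILM)/(RPE − ILM)` at the deposit's own column and binned into 20
slabs, `f = 1` assigned to the posterior-most bin; bin 1 is the ILM side
(the source figures do not fix the direction — this is the package's
convention).  Monthly clustering uses bins of 30.44 days with
`month = ceil(day/30.44)` and keeps the latest measurement per eye and
month; summaries report the sample (n−1) standard deviation, undefined for
a single eye.

## Statistics

Months missing more than 25% of the eyes are eliminated first, then eyes
missing more than 25% of the remaining months (matching the narrative
order of the emulated study); remaining gaps are filled assuming a linear
local trend — interpolation between the nearest observed neighbours on the
month axis, endpoints extrapolated from the two nearest points.  The
repeated-measures ANOVA decomposes sums of squares into subjects, time and
error with `F = MS_time/MS_error` on `(k−1, (n−1)(k−1))` degrees of
freedom; no sphericity correction is applied (recorded in the result
metadata).  Post hoc paired t-tests compare each month against the baseline
(the family suggested by the emulated study's reporting), Bonferroni
adjusted by the number of comparisons.  Mann-Whitney U uses midranks and
reports `U = min(U_a, U_b)`; for `n_a + n_b ≤ 12` the two-sided p-value is
the exact permutation proportion `P(min(U_a, U_b) ≤ U_obs)` — small values
of the min statistic are extreme in either direction, so this tail is
two-sided by construction — and larger samples use the normal approximation
with tie and continuity correction.  Pearson correlation wraps the standard
two-sided t-test.

## Problem sizes and validation

Tests and the acceptance script run reduced-scale phantoms chosen to keep
the statistical structure representative: contrast stages on a
256 × 128 × 64 × 5 scene at SNR 20 dB, recovery and longitudinal runs on
256 × 96 × 48 × 3, with the ~15 s acquisition duration preserved.  Under
these conditions the pipeline recovers injected 30-px/1 Hz motion with
median residual ≤1 px, all six boundaries with RMS ≤2 px (≤1 px in the
noiseless limit), programmed thickness within 4 µm, flow-to-static
angiography contrast ≥10×, and a programmed 4 µm/month outer-retina
thinning within 0.1 µm/month — each measured against the generator's
ground truth by the acceptance script.
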
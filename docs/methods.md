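# Methods

`msistrat` implements an untargeted data-mining chain for MALDI mass
spectrometry imaging (MSI) of stratified sediment sections: per-pixel peak
lists go in, non-negative matrix factorization (NMF) "molecular
fingerprints" — spatially coherent groups of m/z features — come out,
together with weighted ion images and depth profiles. This note records
the model behind each stage, the parameters that matter, what the
synthetic scene generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Input model

The unit of data is a centroided peak list per raster pixel: (m/z,
intensity, SNR) triples at integer (x, y) coordinates, exported as
comma-separated text. Physical position is `index × pixel_pitch_um`
(default 150 μm, a typical MALDI raster pitch); one raster axis (x by
default) increases with sediment depth. Peaks outside the analytical
window (default m/z 150–1000) are discarded on read; duplicate
(x, y, m/z) rows collapse by summing intensity and keeping the maximum
SNR, the conservative choice for the downstream threshold filters.

## Spectrum cleaning and normalization

**SNR filter.** Peaks with SNR below 4 are treated as instrument noise
and dropped; the boundary is inclusive (SNR = 4 survives), reading
"threshold" as the minimum acceptable value.

**Lock-mass recalibration.** FTICR m/z error is well approximated as a
per-spectrum multiplicative scale factor. If a peak lies within a ppm
search window of a known calibrant (matrix oligomer or other ubiquitous
species), all m/z in that spectrum are multiplied by
`calibrant_mz / observed_mz` — exact for a uniform relative error. Spectra
without a candidate are left untouched and counted.

**Normalization.** Two per-spectrum normalizations are provided because
both are standard and serve different purposes: division by the median
peak intensity (robust to a few saturating ions; used for alignment and
the sparsity statistics) and division by the total ion count (TIC;
produces compositional values that feed zone averaging, NMF and all
images). The default wiring — median → alignment/filters, TIC →
fingerprinting/rendering — is a package design choice; either table can
be exported.

## KDE peak alignment

Peaks are pooled across all pixels and consensus features are taken as
maxima of their kernel density estimate:

1. the m/z axis is partitioned into bins of `bin_width_da` (default
   0.5 Da), each extended by 3 kernel bandwidths on both sides so a
   species sitting on a boundary is not split;
2. within each bin a Gaussian KDE with bandwidth `kde_bandwidth_ppm`
   (default 2 ppm of the bin center) is evaluated on a grid of
   `grid_step_ppm` (default 0.2 ppm);
3. local maxima whose prominence on the max-normalized density curve
   exceeds 0.01 are retained; maxima found in two bins' overlap are
   deduplicated by keeping the one inside the bin that owns its location;
4. every peak is assigned to the nearest retained maximum within 3
   bandwidths (exact ties go to the lower m/z); unassignable peaks are
   dropped and counted in the run manifest.

The bandwidth default matches sub-2-ppm FTICR mass accuracy: one species
yields one maximum, and species separated by more than 6 bandwidths can
never merge (asserted by test). For data with larger jitter the bandwidth
should be set to roughly 1.5–2× the expected ppm scatter; the alignment
tests use 5 ppm against 3 ppm jitter for exactly this reason. The
prominence threshold is applied to a per-bin density normalized to
maximum 1, since a fixed prominence on an unnormalized density would be
meaningless across bins of very different occupancy.

## Feature filtering

**Zone sparsity.** The depth axis is binned into zones of `zone_width`
raster units (default 30) anchored at coordinate 0, with a partial final
zone kept if non-empty. For each feature and zone the fraction of
non-zero pixels is computed; a feature is retained when its **maximum**
zone fraction reaches the threshold (default 7%). The maximum — rather
than a global fraction — is deliberate: a genuine biomarker confined to
one thin depth band is exactly the signal class of interest and would be
destroyed by a global criterion, while one-pixel noise features stay
below threshold in every zone.

**Void exclusion.** Sample preparation leaves embedding-medium voids
inside the section; MALDI-matrix-derived ions dominate there because no
analyte competes. For each feature the enrichment ratio (mean intensity
over void pixels) / (mean intensity over sediment pixels) is computed on
a pixel-registered {outside, sediment, void} mask; features with ratio
above `ratio_max` (default 1.5), or with void signal but zero sediment
signal, are excluded. Pixels outside the sample outline never enter
either mean. The 1.5 default operationalizes "disproportionately
concentrated": matrix ions show an order-of-magnitude enrichment, genuine
analytes sit at or below parity, so the precise value is uncritical over
a wide range.

Both filters only remove feature columns; retained values are never
altered, and the two filters commute when their statistics are computed
on the unfiltered table.

## Zone averaging, scaling, NMF

The cleaned TIC-normalized table is averaged per depth zone (zeros
included — absence is information), giving a zones × features matrix.
Each feature column is scaled to [0, 1] by its maximum (MaxAbs), so
abundant and trace species contribute equally; all-zero columns are
flagged and left unchanged.

The scaled matrix X is factorized as X ≈ WH, W ≥ 0 (zones × k spatial
fingerprints), H ≥ 0 (k × features pseudo-spectra), minimizing squared
Frobenius error by coordinate descent. The error metric throughout is the
relative Frobenius norm ‖X − WH‖_F / ‖X‖_F, which makes tolerances
scale-free.

**Component count.** k is swept upward while recording err(k); the sweep
stops at the smallest k whose decrement err(k) − err(k+1) falls below
`delta_tol` (default 0.0015). An absolute reading (smallest k with
err(k) < delta_tol) is selectable by flag; the decrement reading is the
default because an absolute error floor depends on the data's noise level
and is generally unattainable. The sweep warm-starts k+1 from the fitted
rank-k factors plus one appended component: the leading rank-1 part of
the positive residual, scaled by its optimal least-squares coefficient.
The initial error at k+1 therefore never exceeds err(k), and since
coordinate descent is monotone, the recorded trace is non-increasing in
k — which is what makes a decrement criterion well-posed. Initialization
at k = 1 uses NNDSVDa (deterministic, derived from the data's leading
singular structure); the recorded seed only perturbs exact ties, so
repeated runs are bit-identical.

**Convergence.** Solver tolerance 1e-10 on the relative objective change
with an iteration cap of 50 000. The cap is generous because coordinate
descent converges only linearly near an exact factorization; on a 20 × 50
exact rank-3 product it needs tens of thousands of (sub-millisecond)
iterations to push the relative error below 1e-6, and stopping earlier
would make exact-recovery behavior solver-limited rather than
model-limited.

## Images and depth profiles

A component's image is the weighted average of the TIC-normalized ion
images of all features, with weights equal to the component's
contributions raised to the 5th power — a strong emphasis of each
pseudo-spectrum's dominant features. The weighted sum is divided by the
weight total (Σw⁵) by default, making the image invariant to rescaling a
component's contribution vector; an unnormalized sum is available by
flag. Depth profiles sum an image across the transverse axis per depth
bin (default one raster step = one 150-μm horizon) and are smoothed by a
centered moving average (default 5 points) whose window shrinks at the
profile edges, keeping the smoothed profile the same length as the raw
one.

## The synthetic scene

The generator plants known structure so recovery can be scored exactly.
The default scene is an 80 × 10 raster (12.0 mm of depth × 1.5 mm across
at 150 μm pitch) with four components that jointly cover the depth range,
mimicking redox zonation in hydrothermal sediment: a 3-pixel surface band
(depth 0–2), a suboxic zone with a sharp lower boundary at depth 29–30, an
anoxic box from depth 30 down, and a concretion-like Gaussian blob around
depth 45. Each component carries 40 characteristic m/z features with
individual abundances — real fingerprints comprise dozens of co-occurring
lipid species. Thirty matrix-derived ions appear in 90% of void pixels
but only 6% of sediment pixels, and ~5 spurious peaks per pixel with
SNR < 4 mimic instrument noise.

Noise model, per emitted peak: observed m/z = true m/z × (1 + ε) with ε
Gaussian at `mass_jitter_ppm` (default 1 ppm, post-lock-mass FTICR
accuracy); intensity = base × abundance × profile × (per-pixel efficiency
factor) × (per-peak lognormal). The per-pixel efficiency factor (50% CV)
models shot-to-shot and matrix-crystallization variability — precisely
what per-spectrum normalization exists to cancel — while the residual
per-peak CV and the dropout probability of a present feature are set to
0.10 and 0.01. These residual levels are a deliberate scaled-scene
calibration: the default raster holds 40 pixels per depth zone where a
full-size section holds several hundred, so per-pixel noise must be kept
proportionally small for the zone-averaged matrix to sit in the same
noise regime in which a 0.0015 error-stabilization threshold is a
meaningful knee detector. With full-survey per-pixel noise on a desk-size
raster, every error decrement stays above the threshold and component
counting is impossible at any k — a property of the scale, not of the
method. Inside voids the *presence* probability of analyte features is
multiplied by 0.05 (embedding medium carries no sediment lipids);
suppressing intensity instead would be cancelled by per-spectrum
normalization and would defeat the void filter.

What the generator does **not** emulate: isotope patterns, ion
suppression and other matrix effects beyond the shared efficiency factor,
chemically structured (non-uniform) noise, inter-run m/z drift, and the
instrument-side splitting of acquisitions into multiple m/z windows.
Passing recovery tests therefore demonstrate the correctness of the
pipeline's statistics under a faithful but idealized noise model, not
robustness to every artifact of real acquisitions.

All randomness flows from one integer seed through per-stage substreams;
output is reproducible bit-for-bit, and the end-to-end pipeline writes
byte-identical numeric artifacts across same-seed runs.

## Default pipeline configuration

`RunConfig.default_synthetic(seed)` analyzes the built-in scene with
zones of 4 raster units (20 zones over 80 depth units) for both the
sparsity filter and zone averaging — the scaled analogue of 30-unit zones
on a full-size (~800-row) section, which remains the default for data of
that size. Component search is capped at k = 8. All other defaults are as
above.

## Known limitations

- Alignment assumes centroided input; profile-mode peak picking is out of
  scope.
- A single lock-mass per window; no drift correction across acquisitions.
- The KDE grid quantizes centroids at `grid_step_ppm` (0.2 ppm), which is
  negligible against FTICR accuracy but sets a floor on centroid
  precision.
- The component count criterion assumes the error trace has a knee; on
  data whose noise decrements exceed `delta_tol` the sweep runs to
  `k_max` and warns rather than guessing.
- Multiple acquisition windows are processed as separate runs and merged
  only at the feature-table level (column concatenation).
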
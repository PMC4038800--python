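# Methods

## Scope and model

`sfxreduce` reduces streams of 2-D frames from segmented X-ray detectors.
The governing assumption is that of serial diffraction: each frame is an
independent snapshot; most frames are blank; the photon background (beamline
optics, residual gas, solvent scattering) varies slowly across frames or, for
liquid jets, fluctuates shot to shot but stays smooth on short length scales;
sample signal is either a set of small sharp Bragg peaks (crystals) or a
diffuse increase in scattered photons (single particles).

Everything operates on the raw data layout. A segmented detector's modules
may be misaligned, movable and stored in memory in arbitrary order, so every
per-frame operation (background windows, cluster growth, common mode,
annulus statistics) is confined to one module at a time; the per-pixel
coordinate map is consulted only where physical position matters (radii,
scattering vectors, assembly for display). Assembly is nearest-neighbour
deposition — values are moved, never interpolated — with NaN for the gaps
between modules, so gaps are distinguishable from dark pixels. Assembly is
planar; Ewald-curvature correction during assembly is deliberately deferred
(analysis never needs it because q-vectors are computed per pixel).

Conventions fixed here because the practice leaves them open: pixel indices
are 0-based (row, col); physical y grows with the row index of module 0;
|q| = (2/λ)·sin θ without a 2π factor.

## The correction chain

Order: saturation flagging (on raw values — saturation is a property of the
readout, so it must precede any arithmetic), dark subtraction, per-module
common mode, gain, bad-pixel masking. Each step is individually switchable
and steps lacking their calibration input are skipped. The common-mode
estimator is the median of a reference region — the physically shadowed
pixels when a shadow mask exists, otherwise all unmasked module pixels. The
median was chosen over the mean for robustness to signal pixels; note that
without a shadow region the estimate is biased by any strong module-wide
signal (e.g. a solvent ring on a small module), which is why the synthetic
streams carry a shadowed corner block per module and why the step should be
disabled when nothing produces a common-mode term. Detector nonlinearity is
a pluggable per-pixel transfer function with identity default. Pixel flags
are a bitfield (BAD, SATURATED, HOT, PEAK_MASKED, SHADOWED) so one pixel can
carry several conditions; BAD/HOT/SATURATED pixels are excluded from every
statistic, PEAK_MASKED only from the peak search.

## Background estimation

**Running background.** A ring buffer holds the most recent `buffer_depth`
non-hit frames (default 50; beyond a few hundred the estimate is limited by
shot-to-shot fluctuation, not sampling). The pixel-wise median through the
buffer is the background; the pixel-wise population standard deviation is the
per-pixel noise map used for particle classification. Hot pixels are those
above a signal level in strictly more than 80% of buffered frames. The median
and sigma caches refresh every `depth // 2` pushes by default ("periodic"
recomputation: bounded staleness in exchange for throughput); set
`recompute_period=1` for exactness. Hits are never pushed into the buffer;
non-hits always are — classification uses the current background, then the
buffer updates.

**Local background.** Per pixel, the lower-middle median of the
(2r+1)×(2r+1) box intersected with the pixel's module and the unmasked
pixels; windows are truncated at module edges, never wrapped or mirrored. A
box is considered valid when it holds at least `factor` (default 3) times the
pixels of the expected peak. Because a constant added to the image shifts the
windowed median by exactly that constant, residuals are independent of static
offsets — the property that makes dark calibration optional in this mode.

**Median convention.** Every background median uses the lower-middle order
statistic for even counts: the result is always a value that occurred, no ADU
averaging, bit-reproducible.

## Peak finding

All three finders share the strict cluster-size rule
`n_min < npix < n_max` (defaults 1 and 40): the lower bound rejects
single-pixel outliers, the upper overly diffuse blobs. Cluster growth is
4-connected (the conservative reading of "connected"); local-maximum
detection uses the eight nearest neighbours. Centroids are intensity-weighted
over the member pixels using background-corrected values; both the corrected
and the uncorrected integrated intensity are stored per peak, because frames
are best saved *without* local background subtraction (peak-intensity
modification is undesirable for structure-factor integration) while the
search itself runs on subtracted data.

**Radial statistics / peakfinder8.** Mean and standard deviation of intensity
are accumulated per radial annulus (1-pixel-wide annuli by default),
iteratively excluding obvious peaks: pixels more than `clip_sigma` standard
deviations above their annulus mean are removed and the statistics
recomputed until stable. The defaults are clip at 2.5 sigma, at most 10
passes: at looser clips the fixed point retains Bragg-spot shoulders and the
annulus sigma converges to 2–3× the true noise on peak-rich frames, raising
the adaptive threshold enough to miss weak spots; 2.5 sigma costs ~1% of the
upper noise tail (a percent-level sigma underestimate on blank frames) and
removes the shoulders. The peakfinder8 threshold per pixel is
`max(adc_floor, mean(r) + SNR·sigma(r))` with strict `>` comparison; the ADU
floor (default 30) exists for almost-empty frames whose annulus sigma
collapses. Retention: a cluster is kept when its integrated
background-corrected intensity exceeds `snr_threshold · sqrt(npix) · σ_local`
(σ_local = the annulus sigma at the peak radius, or, for the static finder,
the standard deviation of the good non-member pixels in the dilated bounding
box). Wherever an SNR divides by a standard deviation, sigma is floored at
1e-6 ADU so noiseless synthetic data cannot produce infinities.

**Local-SNR finder.** Candidates are strict 8-neighbour local maxima above
the ADU threshold; background mean and sigma come from a concentric annulus
(default inner radius `local_bg_radius + 1`, width 2 px); acceptance requires
both `I − ⟨I⟩` above the ADU threshold and SNR above `snr_threshold`;
qualifying connected pixels are counted against the strict size bounds; peaks
closer than `min_peak_separation` are deduplicated keeping the highest SNR
(processed brightest-first, each accepted cluster claims its pixels so none
is counted twice).

**Prescreen.** The configured finder can run first on a detector sub-region
(default: the inner quarter by radius); the full-frame search happens only if
the region yields enough peaks. This eliminates blank frames after examining
a quarter of the pixels, at the documented cost of false negatives when all
peaks fall outside the region.

## Hit classification

Crystals: hit iff strictly more than `n_peaks_min` peaks (default 20 — the
scale required by Fourier auto-indexing downstream). The optional resolution
gate is conjunctive. The resolution of a pattern is the ceil(0.8·n)-th order
statistic of the sorted peak radii — the radius of the circle containing 80%
of peaks, insensitive to a single far outlier; d-spacing follows from
d = λ / (2 sin(½ atan(r·pitch/D))). Particles: the count of unmasked pixels
above `k·σ(x, y)` (default k = 3) against `particle_npix_min`; counting
pixels rather than summing intensity makes a single randomly high pixel
harmless. The pixel-count floor must scale with detector area (chance
exceedances are ≈ 0.00135·N at k = 3 plus sigma-estimate noise): the default
100 suits the default 128×128 synthetic detector. Photon counting thresholds
just below one photon-ADU (fraction 0.9) and rounds; the log-likelihood
metric scores a frame as the mean of −log p̂ over pixels, p̂ the per-pixel
empirical histogram probability with pseudo-count 1 per bin and ADU bins of
width `adu_per_photon/4`; a frame is an outlier when its score exceeds the
median background score by `loglik_cutoff` robust spreads (1.4826·MAD).

## Reduced products

Powder accumulators store exact per-class sums (hit/non-hit ×
corrected/subtracted) plus counts; sums commute under stream permutation and
partition by class. Radial stacks hold one azimuthal profile per frame with
optional sort keys (e.g. pump-probe delay; ties stable); normalisation scales
each row to unit mean over a bin range (default: the low-q first quarter, a
region free of the water ring under the default geometry) and flags rows
whose pre-normalisation scale is a robust outlier (median/MAD z, default
z = 5); flagged rows are retained but excluded from averaged views.
Per-pixel histograms clip out-of-range values into the end bins and count the
clips, so per-pixel mass always equals frames contributed. Hit statistics
track the overall rate and fixed-window instantaneous rates (600 frames at
120 Hz × 5 s); the overall rate equals the frame-weighted mean of the window
rates by construction.

## Orchestration and determinism

`process_run` executes, per frame: correction → optional prescreen →
background handling per policy (`running`, `local`, or `none`) → peak search
→ classification → export of hits (HDF5 event file + hit list) → buffer
update with non-hits → accumulation. Per-frame errors skip the frame
(counted, logged) rather than aborting — long streams must survive bad
frames. Sequential mode is bit-reproducible for fixed configuration and
stream. Concurrency is specified as a contract, not a mechanism: with the
background buffer frozen (`freeze_background=True`, or `freeze_after` a
warmup prefix — the CLI's `--parallel` calibration-replay mode), per-frame
results are independent of processing order, so the hit set and all
accumulator sums are order-invariant; with a live buffer, sequential order
defines the reference behaviour.

## The synthetic streams

`sfxreduce.synth` generates frames as: solvent ring (Gaussian radial profile,
per-frame amplitude jitter and sub-pixel radius breathing) + planted signal →
Poisson photon noise at `adu_per_photon` → inverse per-pixel gain → dark
offset → Gaussian read noise → per-module common-mode jitter → hot-pixel
overwrite. Defaults, chosen once as the study conditions: a 2×2 tiling of
64×64-pixel modules (a desk-scale stand-in for a tiled megapixel detector —
large enough that 1-px annuli hold stable statistics), 200 frames at a 10%
hit rate (typical for nanocrystals in solution), ring at r = 40 px, width
8 px, crest 100 ADU, 10% jitter; 30 ADU/photon with 10 ADU read noise (a
single photon sits ~3 sigma above electronic noise, the regime of
CSPAD-class integrating detectors); dark 50 ± 5 ADU, 2% gain spread, 3 hot
pixels, 5 ADU common-mode jitter referenced by a 4×4 shadowed corner block
per module. Crystal hits plant 25–45 Gaussian spots of width 1.3 px (a small
sharp Bragg spot), peak contrast uniform in 10–30× the local noise sigma,
rejection-sampled to stay ≥ 6 px from module edges and from each other so
recovery metrics are unambiguous. Particle hits scatter ~100 photons under a
low-q exponential envelope. Identical spec + seed reproduces identical bytes.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: spots are placed at random, not on a reciprocal
lattice (no indexing is possible and no statement about indexability is
made); no polarisation, detector point-spread, panel tilts or Ewald-curvature
intensity effects; background is a single isotropic ring rather than
structured jet streaks; common mode is Gaussian rather than row-correlated.
Recovery and false-positive rates on these streams characterise the
algorithms under their stated assumptions, not performance on any particular
instrument.

## Problem sizes and tolerances

The test suite and the acceptance script run entirely on generated data: the
200-frame 128×128 stream above (seconds per pass), 16×16 two-module fixtures
for every brute-force median/statistics oracle, and direct arithmetic for
layout and rate checks. Planted-spot recovery is scored at centroid error
< 1 px against truth positions; a detected peak counts as a false positive
only when it is farther than 3× the spot width from every planted centre
(noise can split one injected spot into a core plus a detached 2-pixel
fragment, which is still injected intensity). Exact checks (classification
rules, order statistics, medians, conservation laws) carry no tolerance.

## Known limitations

Geometry refinement (metrology, powder rings, indexing residuals) is
external; the pixel map is taken as given. The local-SNR finder's annulus
statistics degrade when a neighbouring peak contaminates the annulus — the
deduplication step, not the annulus, handles close pairs. The prescreen
trades speed for a documented false-negative mode. HDF5 event output is
CXI-inspired but self-defined, not CXI-conformant. No facility front ends,
no GUI, no multi-crystal separation, no on-the-fly indexing.
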
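# Methods

This note documents the models and numerical choices behind `algacyto`: what
each stage computes, which knobs matter, what the synthetic generators do and
do not emulate, and the known limitations.

## Detection (segmentation module)

Detection uses the chlorophyll channel exclusively. Every live algal cell
carries chloroplast autofluorescence, so the trigger channel needs no
staining and the lipid channel can never create or destroy objects
(segmentation output is invariant to arbitrary changes of the Nile-Red
channel). The chain is:

1. **Grayscale conversion** (RGB frames only): fixed BT.601 luminosity
   weights (0.2989, 0.5870, 0.1140) by default; a per-pixel max-channel mode
   is available for cameras whose color filters split the emission band.
2. **Contrast stretch**: linear map sending the `low_pct` percentile of the
   image to 0 and the `high_pct` percentile to the dynamic-range maximum,
   clipping outside (defaults 1% / 99%). Its purpose is to lift the dim
   scattered light of the cell body toward the chloroplast level so the
   detected object covers the whole cell, not just the organelle. Output is
   float and unrounded; constant images pass through unchanged.
3. **Threshold**: the single global threshold maximizing between-class
   variance over a 256-bin histogram spanning the observed range (16-bit
   data is binned). The scan is vectorized over cumulative sums; ties break
   to the lowest maximizing bin and the returned value is that bin's center,
   so the result is deterministic for a fixed histogram. A constant image
   has no threshold and is treated as all-background (empty mask plus a
   warning at the field level).
4. **Binarize and clean**: foreground is *strictly above* the threshold;
   connected components smaller than `min_object_pixels` (default 10) are
   removed — a component of exactly `min_object_pixels` survives.
5. **Labeling**: connected components (8-connectivity by default, 4
   available) with labels assigned in raster-scan order of each component's
   first pixel, so label numbering is reproducible.

**Contrast floor.** A between-class-variance optimizer always splits even a
unimodal histogram, so a blank-but-noisy field would otherwise segment into
large spurious noise components. `segment_field` therefore rejects a
segmentation whose foreground, measured in the **raw** trigger channel, is
less than `min_trigger_snr` (default 4.0) background standard deviations
above the background mean; such fields are reported empty. For pure Gaussian
noise the optimizer's foreground sits ~2.7 SDs above the retained
background, while the package's stated detectability regime (chloroplast
≥ 5 SDs above background) clears the floor with margin. Fields with
genuinely dim cells can lower the floor explicitly.

**Limitations.** Touching cells are not split (no watershed): the method
targets dilute suspensions where clumping is rare, and clumps appear as
single objects. A single global threshold also cannot rescue cells whose
whole-cell intensity sits far below the rest of the population: in strongly
heterogeneous synthetic populations the dimmest ~0.5–1% of cells can fall
below the optimum and go undetected, which mirrors the detection limit of
the real assay. Because a *linear* stretch preserves intensity ratios, the
synthetic scenes emulate trigger images as they look after body enhancement
(body ≈ half the chloroplast level) rather than raw optics.

## Quantification (quantify module)

Per-cell readout happens on the **unmodified** rasters — the enhanced image
exists only to find pixels. For each label: summed intensity per channel
(amount, in camera counts), density = amount / pixel count, equivalent
sphere diameter `2·sqrt(A/π)`, and the fraction of pixels at or above the
camera's saturation ceiling, per channel. Saturated cells are flagged, not
censored — the analysis layer can exclude them (`exclude_saturated`), but by
default they stay, because clipping biases amounts downward predictably
while dropping cells biases population structure. Densities are per pixel
*area*; a volume normalization would require a 3-D model the images do not
support.

Two invariants pin the arithmetic: summed per-cell amounts equal the
raw-channel sum over all labeled pixels exactly (conservation), and records
are invariant to contrast-stretch settings whenever the mask is unchanged.

## Population structure (population module)

Relative columns divide each parameter by its snapshot mean (one
timepoint × condition), so every relative column has mean 1 by construction
and snapshots of different absolute brightness become comparable.
Association is summarized by Spearman's rank correlation (Pearson on
mid-ranks; average ranks for ties; undefined and reported as an error for
constant input or n < 3). Heterogeneity is the coefficient of variation
(sample SD over mean, ddof = 1): dimensionless, hence comparable across
parameters and timepoints.

**Transition states** answer "how far has each cell moved from the starting
population?" They are bands of **absolute** lipid density — the per-snapshot
relative RCLD renormalizes to mean 1 at every timepoint and therefore cannot
be anchored to day 0. The baseline level is the median (robust against the
right tail already present at day 0; mean available) of the day-0 snapshot's
lipid densities; thresholds are `baseline × folds` with folds (2, 10) by
default, giving states "Start-RCLD", "2-fold", "10-fold". A cell exactly at
a threshold belongs to the higher state, so assignment is monotone in
density. In `analyze`, the model is fitted per condition from that
condition's baseline timepoint, and fractions are reported per snapshot
(summing to 1).

## Synthetic data (synthetic module)

**Scenes.** `render_scene` draws non-overlapping circular (optionally
elliptical) cells: a body disk at `body_intensity` with a concentric
chloroplast disk about twice as bright, punctate lipid droplets inside the
cell in the Nile-Red channel, a flat background (default 8 counts) with
additive Gaussian sensor noise (default SD 2), clipping at a configurable
ceiling, and integer quantization at the configured bit depth. Ground truth
records each cell's center, radius, pixel set size and the noise-free
(ceiling-clipped) channel sums over its own pixels, so recovered amounts can
be compared against injected ones: the measurement error is the summed pixel
noise, SD `noise_sd·sqrt(pixel_count)`, and the 3-sigma band around the
truth is a 99.7% band per cell — coverage, not a hard per-cell guarantee.
Default photometry (body 60 ≈ 26 noise-SDs above background) sits well past
the ~5-SD detectability floor. What scenes do **not** emulate: uneven
illumination, focus drift, overlapping or dividing cells, the sponge-like
chloroplast degradation of late starvation, or channel cross-talk — passing
tests show the pipeline's arithmetic and detection logic are right, not that
real micrographs are this clean.

**Populations.** `sample_population` draws log-normal sizes (default median
200 px, log-SD 0.35), chlorophyll amounts (log-SD 0.45) and a log-normal
mixture of lipid densities, then couples amounts and densities to size
through a Gaussian copula. Two deliberate variance-control choices make the
generator a sharp test instrument:

* **Calibrated rank coupling.** A plain copula hits a target Spearman rho
  only in expectation; at n = 1000 the sampling SD of Spearman near rho = 0
  is `1/sqrt(n−1) ≈ 0.032`, so realized correlations scatter well beyond a
  ±0.03 recovery band no matter how correct the estimator is. The generator
  therefore builds normal scores with an exact sample correlation
  (Gram–Schmidt) and tunes that correlation by Brent root-finding until the
  *realized* sample Spearman of the emitted records matches the target to
  ~1e-4 (`calibrate=False` restores the plain copula with the population
  map `rho_gauss = 2·sin(π·rho_s/6)`). Recovery tests then measure estimator
  and pipeline error, not generator shot noise.
* **Exact mixture composition.** Component counts follow the weights by
  largest-remainder allocation rather than multinomial draws, so a measured
  state fraction deviates from its weight only through band leakage and
  measurement error.

The size–lipid target couples size to lipid *density* (the mixture's
variable); lipid amount is density × size. With the default separation of
mixture components (1× / 4× / 20× of baseline, log-SD 0.2) the probability
mass leaking across the 2× and 10× band edges is below ~0.3%.

`render_population_scenes` bridges populations to images for closure tests:
each cell becomes a uniform disk whose pixel values encode its chlorophyll
amount and lipid density exactly (plus background), rendered 16-bit so
realistic densities stay far from the ceiling. The flat background adds
`background·area` to measured amounts — a constant density offset that
leaves rank correlations of densities untouched and nudges size–amount
correlations up by well under 0.01 at the default signal-to-background
ratio. `accumulation_timecourse` grows every cell's lipid density as
`d0·exp(g·t)` with a per-cell log-normal rate, so individual trajectories
are monotone and the Start-state fraction can only shrink — the qualitative
signature of net accumulation without fallback.

## Input/output conventions

TIFF (preferred) or PNG, 8- or 16-bit, grayscale or RGB; the two channels of
a field pair by filename suffix (`_chl` / `_nr`, configurable) and must
match in shape and dtype. Bit depth is inferred from the file dtype but can
be overridden (12-bit data in 16-bit containers). Intensities are never
rescaled on input. Per-cell tables are CSV with a fixed column set; floats
are written with 17 significant digits and read back with a correctly
rounded parser, so round trips are bit-exact. `process` writes a JSON
manifest (config, config hash, package version, per-field counts) and its
outputs are byte-identical across reruns of the same inputs. Multi-page
TIFFs, z-stacks, proprietary microscope formats and channel registration are
out of scope.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use 64×64 images for the
threshold oracle (50 images), 512×512 scenes with 100 cells (200 scenes for
recall, 30 for quantification), populations of n = 1000 (200 seeds per
correlation target), and a two-timepoint closure of 2 × 1000 rendered cells —
sizes chosen so the whole acceptance run finishes in about a minute on one
CPU while keeping binomial confidence intervals tight enough to be
informative.
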
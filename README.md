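# algacyto

Microscopic cytometry for microalgae: single-cell quantification of
chlorophyll and neutral lipids from paired epi-fluorescence images, and the
population-structure statistics built on top of it.

## The problem

Bulk assays of algal lipid production (solvent extraction, spectroscopy)
report one mean value per culture and silently assume a homogeneous
population. During nitrogen starvation — the standard stimulus for
triacylglycerol (TAG) accumulation — algal cultures are anything but
homogeneous: individual cells start lipid synthesis at different times and
the suspension can split into subpopulations with very different lipid
content. `algacyto` implements a simple, unsupervised image-cytometry
pipeline that phenotypes every cell in a wide-field fluorescence image pair:

* **chlorophyll channel** — the intrinsic chloroplast autofluorescence is the
  *trigger signal* used to detect cells; contrast enhancement lifts the dim
  light scattered in the non-fluorescent cell body so the detected object
  covers the whole cell;
* **Nile-Red channel** — the lipophilic dye stains neutral lipids (TAG) and
  is read out per detected cell from the unmodified raw image.

## Method

For each field of view the chlorophyll channel is converted to grayscale,
contrast-stretched between two percentiles, and reduced to binary with a
single global threshold `t*` chosen by maximizing the between-class variance
of the gray-level histogram,

```
t* = argmax_t  w0(t) · w1(t) · (mu0(t) − mu1(t))²
```

where `w0, w1` are the background/foreground masses and `mu0, mu1` their
mean gray levels. Tiny components are removed, connected components become
cells, and each cell's pixel coordinates are read back from the *unmodified*
channels, giving per cell: size (pixel count), equivalent sphere diameter
`2·sqrt(A/π)`, summed chlorophyll and lipid amounts, and the corresponding
densities (amount per pixel, an intracellular concentration proxy).

The population layer rescales each parameter by its snapshot mean, producing
the dimensionless per-cell columns RCS, RCCA, RCLA, RCCD, RCLD (relative
cellular size / chlorophyll amount / lipid amount / chlorophyll density /
lipid density, each with mean 1 by construction), and computes Spearman rank
correlations between them, cell-to-cell heterogeneity (coefficient of
variation), and *transition states*: bands of absolute lipid density at fold
multiples (default 2× and 10×) of the day-0 population median, used to track
how cells move toward high lipid content over a starvation time course.

Because no public dataset accompanies the method, the package ships a
first-class synthetic generator (`algacyto.synthetic`) producing
ground-truthed image scenes and populations with prescribed size
distributions, rank couplings (via a sample-calibrated Gaussian copula) and
lipid-density mixtures, so every stage is testable end to end.

## Worked example

`examples/full_pipeline.py` renders two timepoints of a known population to
TIFF pairs (day 0, and a starved day 8 split 0.5/0.1/0.4 across the
Start/2-fold/10-fold lipid bands), processes the directory and analyzes the
combined cell table:

```
wrote 8 TIFF field pairs to a temporary directory
processed 8 fields -> 796 cells in the combined table

per-timepoint population summary:
 timepoint  n_cells  rho_rcs_rcca  rho_rcs_rcld  frac_start_rcld  frac_2_fold  frac_10_fold
       0.0      397         0.966        -0.000            1.000          0.0         0.000
       8.0      399         0.966        -0.003            0.499          0.1         0.401
```

`rho_rcs_rcca` is the Spearman correlation between relative cell size and
relative chlorophyll amount: the generator's strong 0.96 coupling is
recovered from the images. `rho_rcs_rcld` near zero shows lipid density is
independent of cell size, and the day-8 state fractions recover the injected
mixture weights. The other examples (`segment_and_measure.py`,
`population_structure.py`, `transition_states.py`) each exercise one layer
and print what the numbers mean.

The same flow is available from the shell:

```
algacyto simulate --spec scene.json --out fields/
algacyto process  --input fields/ --out run/
algacyto analyze  --cells run/cells.csv --baseline-time 0 --folds 2,10 --out analysis/
```

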
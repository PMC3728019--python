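# Methods

## Synthetic data model

`thfish.synth` generates data with the statistical structure the analysis
assumes, at two levels.

**Count tables.**  Transcription-factor counts are generated in polar form:
a magnitude r ~ Exponential(`r_scale`) and an angle θ, with
t = round(r·cos θ) (*Tbx21*) and g = round(r·sin θ) (*Gata3*).  In the
*mixed* regime θ ~ Uniform(0, π/2); in the *exclusive* regime θ is a
symmetric Beta mixture, ½·(π/2)·Beta(1, c) + ½·(π/2)·(1 − Beta(1, c)) with
concentration c = `theta_conc` (default 8), giving two tunable modes at the
axes.  Defaults: `r_scale` = 50 transcripts, anchored to observed per-cell
means of ~33–35 transcripts per factor at 24 h of activation
(E[t] = r_scale·2/π under uniform θ).  Cytokine counts are zero except in a
rare ON fraction (`p_on` = 0.03 per cytokine, the few-percent producer
population); ON cells draw round(Gamma(shape, scale)) with default shape 1
and scales 159 (*Ifng*) and 176 (*Il4*), the fitted mean burst sizes.  The
fitted shape parameters are not reported anywhere authoritative, so shape
defaults to 1 and is configurable.  Cells are placed as a non-overlapping
monolayer of 7 µm disks (grid-bucket dart throwing at ~35% packing) so
tables carry centroids for spatial statistics.  The table of latent
(r, θ) draws and ON indicators is returned alongside the counts.

A consequence of integer counts worth knowing: θ recomputed from rounded
counts carries atoms at exactly 0 and π/2 (~1% each at `r_scale` 50 with
the r ≥ 10 filter — cells whose smaller count rounds to zero).  At sample
sizes in the tens of thousands a KS test against the continuous uniform
resolves these atoms, so the count-derived θ of the mixed regime is
rejected slightly more often than the nominal rate (~4–5% at α = 0.01,
n = 10,000).  The generator's construction property (uniform θ) is exact on
the latent angles; real count data shows the same axis atoms.

**Scenes.**  `make_scene` renders a bright-field stack (light disk interior,
dark 2 px rim — only the edges are used downstream) and one FISH stack per
gene.  Each transcript is a 3-D Gaussian spot (lateral σ = 1 px at 0.13 µm
pixels, i.e. ~130 nm, diffraction-limited; axial σ = 0.75 slices at 0.4 µm
z-steps) placed uniformly inside the cell's ellipsoid, plus additive
Gaussian camera noise (spot peak SNR = `spot_amplitude`/`noise_sd` = 10 by
default).  Spot placement applies a hard-core separation — laterally
≥ 5 px or axially ≥ 4.5 slices — to emulate the optically resolvable
regime; when a cell is too crowded to satisfy it, placement falls back to
unconstrained positions, which reproduces exactly the unresolvable
high-expresser regime the fluorescence extrapolation exists for.  The
separation is anisotropic because per-slice LoG supports bridge through
z-neighbouring voxels at much larger nominal 3-D distances than lateral
ones, so an isotropic criterion still produces axial merges.

## Image quantification

**Segmentation** runs Canny (gradient magnitude + hysteresis; the edge
detector is a free choice) on the central bright-field slice, closes the
boundary map, fills enclosed regions, seeds one marker at each enclosed
region's centroid, and floods a watershed over the negated distance
transform of the boundaries.  Labels outside [`min_area_px`,
`max_area_px`] are dropped — an automated stand-in for manual curation of
mis-segmentations — and relabelled contiguously.

**Spot detection** enhances each optical slice with a negated
Laplacian-of-Gaussian (default σ = 1.5 px, configurable; the scale is not
dictated by anything measured).  Supra-threshold voxels form 3-D connected
regions under 26-connectivity — per-slice filtering but volumetric
counting, so a spot spanning z-slices counts once — and each region
contributes one spot at its response maximum.

**Threshold selection** sweeps 40 log-spaced thresholds from 3× a robust
(MAD) noise scale of the response up to its maximum and picks the midpoint
of the widest log-threshold run over which the spot count is stable
(successive changes ≤ 5%, count > 0).  Exact-count plateaus are degenerate
in practice: the true plateau jitters by a few percent while spuriously
flat stretches exist below the noise floor where regions merge.  The
criterion is scale-equivariant (MAD and maximum both scale linearly), so
doubling all intensities doubles the threshold and leaves counts unchanged.
A blank stack (response below 10⁻³ of the intensity scale) returns the
sweep midpoint with a warning.

**Fluorescence** follows the minimum-of-cell-means background rule: on the
central optical slice, the background is the minimum over cells of the mean
pixel value inside the cell, and each cell's total is Σ(pixel − background)
clamped at zero.  `z_mode="sum"` applies the same rule to the z-summed
stack; the pipeline uses this integrated variant for the FISH channels that
feed extrapolation, because the central-plane total of a 3-D spot
population fluctuates by ~5–7% per cell with realistic axial spot spread,
which would dominate the calibration.  The rule presumes some cells are
(near-)empty in the channel; in a field where every cell expresses, the
background is overestimated and small-count totals are biased low.

**Extrapolation** fits fluor = slope·count through the origin on resolvable
cells (0 < count < `resolvable_max`, default 200) and replaces dense cells'
counts with fluor/slope.  Two robustness measures: the first-pass slope is
the median per-cell fluor/count ratio (a saturated dense cell — detected
count far below truth, huge fluorescence — drags a least-squares slope up
enough to mask itself), and a cell is treated as dense when either its
detected or its fluorescence-implied count reaches `resolvable_max`,
because detection saturates sublinearly in crowded cells.  The final slope
is the least-squares fit on the cleaned calibration set.

## Polar statistic

r = √(t²+g²), θ = arctan(g/t) ∈ [0, π/2]; θ := 0 at the origin by
convention (such cells are excluded anyway).  Cells with r < `r_min` = 10
are excluded; the boundary cell r = 10 is kept.  Summaries: median θ,
a 10-bin density histogram on [0, π/2], and a U-index — the fraction of
kept cells with θ < π/8 or θ > 3π/8 (expectation 0.5 under uniformity, →1
for exclusive states; thresholds configurable).  Uniformity is assessed by
a one-sample KS test against Uniform(0, π/2) (the choice of test is ours);
condition comparisons use the two-sample KS with the asymptotic p-value,
computed on raw (unbinned) θ values.

## Two-state model and burst inference

`simulate_two_state` is an exact Gillespie simulation of the four
reactions per cell, starting OFF with zero transcripts and sampling after
12 mRNA lifetimes (≥10 lifetimes of burn-in; the slowest relaxation mode
decays at ~k_deg).  The inner loop is numba-compiled; seeds are explicit.
`telegraph_stationary_pmf` independently solves the stationary master
equation on a truncated state space (promoter × count) by direct linear
solve with a normalisation row; simulator and solver agree to
total-variation distance < 0.01 at n = 50,000 samples.

`fit_gamma` performs the Gamma MLE on counts above `on_threshold`
(default 0, i.e. all expressing cells; the display thresholds 20/50 can be
passed instead).  Integer counts are treated as continuous observations
with no continuity correction; the shape solves
log a − ψ(a) = log x̄ − mean(log x) by safeguarded Newton iteration from a
method-of-moments start, and scale = x̄/a, so fitted shape·scale equals the
sample mean exactly (the Gamma-MLE first-moment identity).

Because ON cells are only observed when their count is nonzero, the plain
MLE is biased for small burst sizes: at scale 18 (shape 1) roughly 5% of
the stationary mass sits in the zero class, and excluding it biases the
fitted scale ~10% low.  `truncated=True` maximises the likelihood
conditioned on X > 0.5 (the observability boundary below the smallest
positive integer), numerically from the plain-MLE start; this removes the
bias (median recovery error ~2% at all four reported burst sizes) at the
cost of the exact first-moment identity.  The recovery experiments and the
acceptance script use the truncated fit; the default remains the plain MLE.

## Pipeline and configuration

Run configuration is YAML validated by pydantic models with unknown keys
rejected.  Defaults mirror the analysis conventions throughout: r_min 10,
ON thresholds 20/50, resolvable_max 200, cell diameter 7 µm, z-step 0.4 µm.
Reports are JSON with the full configuration embedded; reruns with the same
configuration are byte-identical apart from the timestamp field.

## Problem sizes and calibration experiments

The recovery experiment simulates n = 5,000 cells per replicate, 20
replicates per burst size — enough that the median fitted scale is stable
to ~1%.  The imaging oracle uses scenes of ~20 cells with planted counts
in the resolvable range (5–40 spots/cell; the oracle's validity domain is
below the spot-merge limit, and in this geometry detection saturates
beyond ~50 spots/cell).  θ-regime calibration uses 100 replicates of
n = 10,000 cells.  The bursty-limit distributional check compares n = 2,000
dequantized counts (a seeded uniform jitter on [0,1) — the standard way to
KS-test an integer sample against a continuous law, since at larger n the
KS test resolves pure discreteness) against Gamma(1, k_tx/k_off).

## What the synthetic data does and does not show

The generators capture the count statistics, rare-producer structure,
monolayer geometry, diffraction-limited spots, and camera noise, but not:
irregular cell shapes (cells are disks; touching disks still exercise the
watershed split), uneven illumination or optical aberrations, probe
chemistry, autofluorescence textures, or z-dependent PSF broadening.
Passing the planted-truth oracles therefore demonstrates correctness of
the algorithmic chain under the stated imaging model, not performance on
arbitrary real micrographs — on real data, segmentation quality and the
LoG scale/threshold remain the operator-sensitive steps, which is why both
are configurable.
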
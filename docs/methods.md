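# Methods

This note documents the models implemented in `redoxcell`, the
parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical conventions fixed where more
than one reasonable choice existed.

## Image model and shared operations

Intensity images are nonnegative 2-D grids in photon-count-like units;
photon-counting acquisitions arrive as (T, H, W) decay stacks.
`integrate_decay` collapses a stack to intensity by summing all time
bins inside a sliding (2r+1)×(2r+1) spatial window per pixel (default
r = 1, the conventional 3×3 bin). Two conventions are fixed here:
binning is a sliding window, not block downsampling, so every pixel
receives a value; and edge windows are truncated rather than padded,
so no data are invented (edge pixels simply integrate fewer
neighbors). Coordinates are 0-based (row, column).

`smooth_circular_average` is a disk-kernel mean filter with edge
renormalization over in-bounds pixels, so constants are preserved
everywhere and the output never leaves the input's [min, max] range.
The default radius is 1 px; it is exposed because no single value is
canonical. `rescale_contrast` maps [0, max] linearly onto
[0, new_max]; the target maximum is a free display/contrast parameter.

## Thresholding

Two global threshold criteria are provided:

* **Otsu** — maximizes between-class variance over the exact histogram
  of unique values (no binning). The returned threshold is the
  midpoint between the optimal class boundary and the next distinct
  value, so it is strictly interior to (min, max) and classifies
  identically to the optimal split.
* **Minimum cross-entropy (Li)** — for a candidate t splitting the
  positive values into below/above classes with value sums S0, S1 and
  means μ0, μ1, minimizes η(t) = −(S0 ln μ0 + S1 ln μ1) (the
  value-entropy term common to all t is dropped). Every midpoint
  between consecutive unique values is scanned, so the minimizer is
  exact rather than the fixed point of an iterative scheme. A
  multiplicative **correction factor** (default 2 for the
  mitochondrial gate) scales the computed threshold; corrected =
  factor × t* exactly.

Zero pixels carry no weight in Li's value sums and are excluded from
its histogram; the criterion needs at least two distinct positive
values.

## Seeded propagation

Cells are segmented by growing regions outward from nucleus seed
labels through a foreground mask, assigning each reachable pixel to
the seed with minimal geodesic cost. The step cost between 4-connected
pixels p → q is sqrt(λ² + (I(p) − I(q))²) with λ = 0.05 by default:
small λ makes intensity edges expensive relative to distance, so
boundaries settle along guide-image gradients; λ → ∞ degenerates to
plain distance. Exact cost ties are broken toward the lower label id,
which makes outputs deterministic and testable. The implementation is
an explicit best-first (Dijkstra) search; the test suite checks it
against an independent sparse-graph Dijkstra on random scenes.

Nuclei are supplied as a label mask (they are assumed to be curated
upstream, e.g. manually); automatic nucleus detection is out of scope.
Border-touching cells are retained. Cytoplasm is the per-cell set
difference cell \ nucleus; stray nucleus pixels outside their own cell
are clipped with a warning. Mitochondria are the cytoplasm pixels at
or above the global corrected Li threshold of the TMRE image; cells
whose mitochondrial mask comes out empty are flagged and excluded from
potential estimates rather than silently dropped.

**Threshold input.** The mitochondrial threshold is computed on, and
applied to, the raw TMRE image. Thresholding a smoothed image would
dilate each punctum's mask into surrounding cytosolic pixels (a pixel
just outside a bright punctum inherits part of its smoothed value),
which systematically dilutes the measured mitochondrial mean and
biases ΔΨ toward zero. Circular smoothing remains available as an
explicit operation for display and for segmentation guides.

## Membrane potential

ΔΨ = −RT·log10(FI_m/FI_n) with RT = 61.5 mV per decade at 37 °C. The
logarithm is base-10: 61.5 mV is the Nernst slope per tenfold
concentration ratio (2.303·R·T/F at 310 K), so only log10 yields
physiological potentials. Compartment intensities are **means**, not
integrated sums, because the Nernst ratio compares concentrations and
means are size-invariant. The nuclear mean is the cytosolic reference.
Records are undefined (and excluded, with ids reported) when either
compartment is empty or has nonpositive mean.

## Optical redox ratio

Per pixel, ORR = I_NAD(P)H/I_FAD where FAD > 0; zero-FAD pixels are
undefined and excluded from aggregates rather than epsilon-padded,
which would otherwise inflate ratios. Per cell, the primary value is
the **ratio of cytoplasmic means** — robust to isolated zero-FAD
pixels — with the mean of per-pixel ratios emitted as an auxiliary
column (`orr_pixelwise`) since both conventions appear in practice.
Under the ratio-of-means convention, fold(ORR) =
fold(NAD(P)H)/fold(FAD) exactly for uniform multiplicative shifts.
Normalization to control divides by the control group's pooled cell
mean (cells pooled per condition, not per field of view).

## Colocalization and plate assays

A DAPI object is positive for a marker when it shares at least one
pixel with any marker object; a minimum-overlap fraction is exposed
(default 0) for stricter gating. Growth percent of control is
baseline-subtracted ((post − mean baseline), condition mean over
control mean × 100) and may legitimately be negative (net cell loss)
or above 100. WST-1 viability subtracts the per-well A650 phenol-red
background and then the mean no-cell blank signal before forming the
percent of control. CytoID is normalized per well to Hoechst to
correct for cell number. All reductions are invariant to well
ordering.

## Flux metrics

Traces follow the standard mito-stress layout: three baseline cycles
then three cycles after each of oligomycin, FCCP and
rotenone/antimycin A (injections after cycles 2, 5, 8). Phase
membership is determined purely by injection indices; agent
concentrations are metadata. Basal respiration = baseline OCR mean −
post-rotenone/antimycin-A mean; it is linear in OCR scale and
invariant to permuting cycles within a phase, and it commutes with DNA
normalization (both are per-well scalar operations). The energy
quadrant compares a well's baseline means against the control
condition's baseline means; points exactly on the boundary count as
not-above, so a well identical to control is "quiescent". ATP-linked,
maximal and spare capacity are provided as derived metrics but are
secondary to basal respiration.

## Statistics

Dunnett's test uses a single pooled variance across all groups
including control. The treatment-vs-control statistics are jointly
distributed with correlation induced by the shared control mean and
the common variance estimate; the adjusted p for treatment i is
P(max_j |T_j| ≥ |t_i|) under that joint null. This tail probability is
evaluated by seeded Monte Carlo (default 100,000 draws): group means
are sampled as N(0, 1/n_i) and the pooled variance as χ²_df/df, which
reproduces the exact joint law. The null sample depends only on the
group sizes, so it is cached and shared across calls — the 2000-run
calibration test reuses one draw. At α = 0.01 the Monte-Carlo standard
error of a tail probability near 0.01 is ≈ 0.0003, far below the
decision scale. With a single treatment the procedure reduces to the
two-sided pooled t-test; the suite also cross-checks the adjusted
p-values against an independent library implementation of Dunnett's
distribution. Comparisons are two-sided throughout; α defaults
to 0.01. Cells pooled across fields of view are treated as independent
observations; per-FOV nesting is deliberately not modeled.

z-scores use the control sample SD (ddof = 1):
z = (μ_treatment − μ_control)/σ_control.

## Synthetic data: what it emulates

`generate_cell_scene` renders non-overlapping elliptical cells with a
concentric elliptical nucleus and disk-shaped mitochondrial puncta
(radius 2 px, ~6 per cell) inside the cytoplasm. Placement is on a
jittered grid, so a requested count either packs deterministically or
fails loudly — no rejection-sampling flakiness. Expected intensities
are constant per compartment and Poisson noise is applied per pixel
(autofluorescence imaging is photon counting); decay stacks distribute
each pixel's expected count over exponentially decaying time bins.
Ground truth (masks and per-cell true means) is recorded before noise.

Channel levels (expected photons/pixel): NAD(P)H 30 and FAD 25 in
cytoplasm (nucleus at half, cofactor signal being largely
mitochondrial/cytoplasmic), background 1. TMRE: nucleus = cytosol = 15
— the Nernst reference assumption — with mitochondrial puncta at
15·10^(−ΔΨ/61.5), and a **medium background of 3.5**. The nonzero
medium level models unwashed free dye (TMRE protocols often omit
washes) and is what a plasma-membrane potential near −39 mV predicts
for the cell-to-medium ratio. It matters: with a near-black
background, the Li threshold's optimum sits so low that even doubled
it falls below the cytosolic level and the "bulk mitochondria" gate
would sweep in cytosol, which would bias shallow potentials; with the
dye-bearing medium the corrected threshold lands between cytosol and
puncta across the −120…−30 mV range.

Condition effects are multiplicative fold-changes on the cofactor
channels and a target ΔΨ for TMRE. Flux traces use configured phase
levels (basal 100, post-oligomycin 40, post-FCCP 160, floor 20 OCR
units; ECAR baseline 30) with Gaussian cycle noise of σ = 2% of basal
and 6 wells per condition; raw rates are scaled by a per-well
crystal-violet absorbance so that normalization is exercised. Plate
generators emit replicate wells with blanks/baselines and
multiplicative Gaussian noise (3%).

**What passing recovery tests does and does not show.** The
generators use piecewise-constant compartments, circular puncta, no
point-spread function, no spectral bleed-through, no uneven
illumination, and no cell-shape irregularity. Recovery of folds to
±5% and ΔΨ medians to 3 mV therefore validates the computational
chain (segmentation, gating, compartment statistics, closed forms) —
not robustness to optical artifacts present in real microscopy. On the
synthetic landscape the −30 mV target shows the largest residual bias
(median ≈ −27 mV): at a 3× mito/cytosol contrast a small tail of
cytosolic pixels crosses the corrected global threshold and dilutes
the mitochondrial mean — an inherent property of a single global gate
at shallow potentials, not a numerical defect.

## Problem sizes and runtime choices

Recovery studies run at the scale their statistics require and no
larger: fold-change scenes use 200 cells per condition on a 448×448
grid, ΔΨ scenes 120 cells on 352×352 (the smallest grids that pack
those counts at realistic cell radii), the Dunnett calibration 2000
simulated experiments against a cached 100,000-draw null, and flux
recovery 6 wells × 12 cycles. The full suite completes in well under a
minute on one CPU.

## Known limitations

* Lifetime (decay-constant) fitting is out of scope; decay stacks are
  only integrated to intensities.
* The mitochondrial gate is a single global threshold; per-cell
  adaptive gating would reduce the shallow-potential bias noted above
  but is not what the pipeline models.
* TMRE is assumed non-quenching; quench-mode dynamics, FCCP
  calibration curves and plasma-membrane-potential corrections are not
  modeled.
* Statistics assume equal variances (single pooled variance) and
  independence of pooled cells; no nonparametric alternatives or
  mixed-effects nesting.
* Segmentation is 2-D, untracked, and relies on supplied nucleus
  seeds.
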
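# Methods

This note documents the models and procedures `xirep` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The biological quantities

The inactive X chromosome (Xi) replicates as a synchronous unit in mid-S
phase. The package quantifies that program along five axes:

1. **Origin number** — replication nano-foci (nanoRFi) counted in 3D
   inside the Xi territory; each focus is taken as one simultaneously
   active origin/replicon.
2. **Fork speed (relative)** — the EdU/PCNA sum-intensity ratio: EdU
   incorporated during a fixed pulse per unit of PCNA (replisome) signal.
   Faster forks incorporate more nucleotide per replisome. Only ratios to
   a control condition are meaningful.
3. **Timing** — persistence and onset of the synchronous Xi pattern in
   live imaging at fixed frame intervals; doubling time and S-phase
   duration from growth/fraction arithmetic.
4. **Licensing** — Mcm2/ORC1/Cdc6/Cdt1 loading coefficients: the
   DAPI-normalised target enrichment of the Xi (ROI1) over an equal-sized
   nucleoplasmic control region (ROI2), and their G1 time courses
   anchored to the control mean at the first time point.
5. **Chromatin geometry** — DNA-halo radius/circularity (loop size and
   regularity), X-FISH radial profiles, Xi relative area, DAPI-SD
   decondensation proxy, hypotonic morphometrics.

The arithmetic fork-speed model ties 1–3 together:
`speed = L/(T·forks·waves)` with `forks = 2N` for `N` bidirectional
origins. It deliberately has no stochasticity: it is the bookkeeping that
turns measured counts and durations into a nucleotides-per-minute
estimate, with the number of activation waves exposed as an explicit
unknown (w waves ⇒ w-fold more origins in total and w-fold slower forks
at equal duration). The compensation index `(N_kd/N_ctrl)·s_rel`
summarises whether an origin-number change and a fork-speed change cancel
(≈1 ⇒ unchanged total duration).

With the planted study conditions the model yields 171.03 Mb /
(80 min · 276 forks) = 7745.9 ≈ 7.7×10³ nt/min; note that the
conventional two-significant-figure presentation of this quantity in the
field rounds to 7.8×10³.

## Focus picking

`pick_foci_3d` implements local-maxima picking with plateau handling:

* Preprocessing: Gaussian smoothing with a 1-voxel kernel (suppresses
  single-voxel shot-noise spikes) and a linear contrast stretch. Both can
  be disabled; data-driven parameter defaults are computed *after*
  preprocessing.
* A **maximum centre** is a voxel or a 26-connected component of
  equal-intensity voxels strictly brighter than every surrounding voxel
  inside the search mask. Each component contributes exactly one centre:
  the voxel nearest the component centroid, ties broken lexicographically
  by (z, y, x). A plateau with no dimmer neighbour inside the mask (i.e.
  covering the whole mask) is background, not a focus.
* The focus body grows from the centre over the supra-background terrain,
  split between touching foci by marker-controlled watershed
  (`separate_touching`, default on), cut at `centre − tolerance`, and
  reduced to the brightest `fraction_f` percent of its voxels for volume
  bookkeeping.
* Defaults: `background` = triangle threshold of the channel inside the
  mask; `tolerance` = 10% of the in-mask dynamic range; `fraction_f` =
  50; `minimum_voxels` = 1. These are declared defaults — the picker's
  historical parameters are not published — and every value is
  overridable.
* `count_nano_rfi` keeps foci whose centre lies inside the Xi mask with
  body volume ≥ 0.0002 μm³ (applied after touching-foci separation).
  Anisotropic voxel size enters only the μm³ conversion; neighbourhoods
  stay voxel-topological.

The picker is verified voxel-for-voxel against an exhaustive brute-force
plateau-maxima oracle on random integer volumes (plateau- and tie-rich)
up to 32³, and by exact recovery of planted, well-separated Gaussian
spots under shot noise.

PLA spots are counted on maximum-intensity projections as 2D maxima with
topographic prominence above 40 (h-maxima transform), inside the
projected nucleus, excluding maxima touching the frame border. A 1-pixel
Gaussian pre-smoothing (disable with `smooth_sigma_px=0`) prevents shot
noise riding on a bright spot from splitting it into several maxima.

## Thresholding and masks

The triangle threshold is computed on a 256-bin histogram of the full
stack (or of the in-mask voxels): the chord runs from the histogram peak
to the far end of its longer tail, and the threshold bin maximises the
perpendicular distance of the histogram profile below that chord (ties to
the bin nearest the peak). Constant images raise rather than returning a
degenerate mask. The implementation is checked bin-by-bin against a
direct geometric oracle and cross-checked against an independent library
implementation.

Nuclei: triangle on DAPI, hole filling, 26-connected components ≥ 50 μm³
(configurable); oversized components (touching nuclei) are labelled for
review, never merged silently. Xi: triangle on H3K27me3 restricted to the
nucleus, clusters ≥ 0.5 μm³; the cluster count is the Xi copy number;
cells with homogeneous H3K27me3 yield an empty list. Chromocenters
default to the top-2% DAPI quantile inside the nucleus when no
major-satellite channel exists.

The control region (ROI2) is a rigid translation of the Xi mask to a
seeded random offset fully inside the nucleus and disjoint from Xi and
chromocenters — congruence is exact by construction. Because the loading
coefficient is measured on maximum projections, ROI placement for that
metric is done on projected (2D) masks: a 3D-placed ROI can sit under or
over a chromocenter column and inherit its DAPI in the projection.
`RegionMask.projected()` provides the footprint.

G1 gating keeps EdU-negative cells whose DAPI sum lies within ±15%
(configurable) of the lowest mode of the population histogram; fewer than
10 cells refuse to fit a mode. The S-phase pattern call is rule-based:
focal signal is the background-subtracted supra-threshold intensity
(threshold = max(triangle, median + 3·MAD) inside the nucleus); `mid_xi`
if ≥ 40% of it overlaps the Xi masks, `late` if it concentrates on
chromocenters, `non_S` if absent, `early` otherwise. The original call
was made by eye; these thresholds are stand-ins whose accuracy on
synthetic populations is measured (≥ 0.9 in the suite), not guaranteed
on real data.

## Intensity metrics

All metrics are ratios of region sum intensities and are invariant to
joint multiplicative rescaling of their channels. Projection conventions:
PLA density, loading coefficients and Xi relative area operate on
maximum-intensity projections (2D ROIs, MIP DAPI sums — the PLA pipeline
keeps counts and DNA amounts in the same projected geometry via
`pla_measurements`); EdU/PCNA ratios and histone/protein levels use 3D
stack sums. The RPA curve uses the population (divisor *n*) standard
deviation for cV = σ/μ (configurable via `ddof`), normalised to the
pretreatment frame. Control normalisation uses the pooled control mean.
Populations are summarised by arithmetic mean with medians alongside.

## The synthetic generator

The generator renders what the pipeline needs to be tested — not optics.
Spots are isotropic Gaussians (σ = 2× the lateral voxel size); there is
no PSF model, no SIM reconstruction artifacts, no photobleaching, no
depth-dependent attenuation, and nuclei are ellipsoids. Consequences:
passing recovery tests demonstrates the *measurement arithmetic and
detection logic* are correct under realistic counting noise; they say
nothing about segmentation robustness against real texture, aberration
or out-of-focus light.

Two scales:

* **Confocal-scale nuclei** (`make_nucleus_image`): 50 nm XY / 290 nm Z
  voxels; ~10 μm nucleus, ~2.5 μm Xi (two copies with probability 0.95,
  matching the emulated karyotype), chromocenters as bright DAPI blobs.
  Channel sums respect the preset factors exactly before noise (focal
  channels are rescaled to their target region sums). At this sampling,
  individual Xi replication foci are *not* mutually resolvable — true of
  the real system too, which needs 3D-SIM — so foci here are planted at
  2σ spacing and serve intensity bookkeeping, not counting.
* **SIM-scale Xi volumes** (`make_xi_foci_volume`): 40 nm XY / 125 nm Z
  voxels, Xi semi-axes 1.5/1.5/1.45 μm, foci at ≥ 4σ lateral spacing
  with a 0.45 μm axial floor (the resolvable regime; `crowded=True`
  removes the constraint to stress the separator). The Xi is slightly
  larger than the 2.5 μm confocal nominal so that 140 foci sit at ~65%
  of the random-sequential-adsorption jamming density.

Intensities are arbitrary counts at realistic 16-bit scale (DAPI 2000,
Mcm 3000 expected photons per voxel); every pipeline metric is a ratio,
so only noise behaviour depends on the absolute scale. Default noise is
Poisson (gain 1). Per-cell staining brightness varies log-normally
(CV 0.15, all channels jointly) — ratio metrics cancel it exactly; the
level-recovery benchmarks (raw-sum metrics at cohort size 30) are
generated with matched brightness, i.e. the planted reduction applies to
the sums exactly, as their contract states. Small expected counts (Xi
PLA spots) are planted with stochastic rounding to keep cohort means
unbiased; PLA spot folds are planted in projected geometry (non-Xi spots
avoid the Xi column) because the measurement is projection-based.

Time-lapse cohorts allocate persistence/onset frame counts by largest
remainder (a 40/60 mixture of 10 cells is exactly 4+6), with an i.i.d.
option; total S-phase span is held constant across conditions. Growth
tables follow `n(t) = n0·2^(t/Td)` rounded to whole cells.

## Numerical conventions and degenerate inputs

* Deterministic everywhere: every stochastic stage takes a seed;
  identical (parameters, seed) ⇒ bit-identical output.
* Triangle ties → bin nearest the peak; plateau-centre ties →
  lexicographic (z, y, x); component ordering → centroid along X.
* Zero denominators (PCNA, DAPI, control means, pretreatment cV) raise
  typed errors; they are never coerced to NaN.
* Halo segmentation uses two thresholds: total area above the image-border
  background estimate (mean + 3 SD), scaffold by triangle *within* the
  total area (an all-pixel triangle lands at the background edge of the
  tri-modal halo histogram and would swallow the halo). Circularity uses
  the Crofton perimeter; digitised circles can exceed 1 and are clamped,
  with the raw value retained.
* FISH profiles average 36 outward-normal rays from evenly spaced
  boundary points (the historical workflow drew one manual line per
  cell; averaging is a declared deviation for reproducibility). Rays
  leaving the image are NaN-truncated; background rays must lie wholly
  outside the dilated cell footprint.
* Hypotonic "diameter" is the equivalent-circle diameter of the XY
  projection (a flattened nucleus spreads laterally at constant volume,
  which an equivalent-sphere diameter cannot see); surfaces come from
  marching cubes on a lightly smoothed indicator (raw binary meshes
  overestimate by the voxel staircase).
* Doubling time returns `t/log2(nx/n0)` — the printed growth-rate formula
  `log2(nx/n0)/t` is dimensionally doublings/hour; both are exposed.
* Interval intersection merges strictly-overlapping intervals within each
  set first (the two-pointer sweep requires internally disjoint lists);
  zero-length touching never counts as overlap.
* Group comparisons default to the unpaired Mann–Whitney form (exact p
  for combined n ≤ 25 without ties): the paired variant is available but
  undefined for the unequal group sizes typical of per-cell data.
* Persistence runs touching the first or last frame are censored and
  excluded from cohort means by default.

## Benchmark problem sizes

The recovery benchmarks use desk-scale cohorts chosen to keep each
quantity's sampling error comfortably inside its tolerance: 20 Xi volumes
per preset for nanoRFi (shot noise; recovery is exact in the resolvable
regime), 25 cells × 8 time points for the loading trajectory, 100 nuclei
for the PLA mean (Poisson sampling dominates: σ/√n ≈ 0.45 spots), 50
cells for the Xi density fold, 50 + 50 for the progression-rate change
and 30 + 30 for the level reductions. The residual −2% bias of the
loading coefficient is a property of maximum projections under shot noise
(the column maximum of the dim ROI2 inflates slightly more than the
bright Xi's); it is documented rather than corrected, as the same
operation applies to real projections.

## Known limitations

* No learned segmentation, deconvolution, nucleus tracking, spot
  colocalisation across channels, or replication-timing sequencing
  profiles; ChIP analysis starts from called peak intervals.
* The S-phase pattern classifier and the chromocenter proxy encode
  thresholds that have no published values; both are configurable and
  should be recalibrated for real data.
* The generator's effect sizes are planted as exact factors; real
  biological dispersion across cells and replicates is represented only
  by shot noise, count sampling and a global per-cell brightness factor.
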
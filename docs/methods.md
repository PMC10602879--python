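# Methods

`terrafoci` quantifies telomeric-repeat-containing RNA (TERRA) in microscopy
of the *C. elegans* germ line at three levels: fixed-cell 3D focus analysis
(RNA FISH / immunofluorescence stacks), live-cell single-particle dynamics
(MS2-tagged TERRA tracked on streamed frames), and bulk expression (qPCR).
This note records the models behind each stage, the parameters that matter,
and the choices made where the design was genuinely open.

## Image model and focus detection

Stacks are 4-D arrays ordered `(channel, z, y, x)` with physical voxel size
`(dz, dy, dx)` in µm (default 0.2 × 0.1 × 0.1, a typical 0.2 µm z-step at
100×). All coordinates are reported as `(x, y, z)` µm with the origin at the
corner of voxel `(0, 0, 0)` and voxel centres at `(index + 0.5) ×
voxel_size`.

Nuclei are segmented from the DNA channel: light Gaussian smoothing (0.3 µm),
global Otsu threshold, 26-connected components, and a volume filter
(4–150 µm³ by default, which brackets germ-line nuclei of roughly 1–3 µm
radius). If the Otsu threshold does not clear the background by at least
three robust standard deviations (1.4826 × MAD) the channel is treated as
empty — a global threshold on pure noise would otherwise bisect the noise
distribution and emit a giant spurious component. Touching nuclei can
optionally be split by a distance-transform watershed. Each nucleus is
summarized by its equal-volume sphere: centroid of the mask and radius
`r = (3V / 4π)^(1/3)`.

Foci are diffraction-limited, so the detector is a single-scale
Laplacian-of-Gaussian band-pass at the expected focus sigma (default
0.15 µm, per axis in voxel units). Candidate peaks must (1) exceed the LoG
response median by `k` robust standard deviations (`k = 5`), (2) sit away
from the image border by the suppression footprint (LoG edge artifacts),
and (3) rise above the image background by `k` robust standard deviations
on a half-sigma-denoised copy. Each accepted peak is grown to the voxels
above `background + 0.5 × (peak − background)` on the denoised image; a
grown region that reaches another retained peak is split along watershed
basins, and regions are claimed greedily in order of decreasing peak
intensity. Two foci closer than about one sigma fall within a single
suppression footprint and merge — this is the resolution limit of the
detector and is asserted in the tests.

Measurements are taken on raw voxel intensities over the grown region:
`volume = voxel count × voxel volume`, `integrated_density = sum of raw
intensities`, `average_intensity = integrated_density / voxel count`, plus
the local background estimate (image median). Note that a 50 %-of-peak
region captures ≈ 29 % of a Gaussian's total mass, so integrated density is
an aperture measurement, not the total spot flux; it is linear in exposure
and comparable across foci measured with the same parameters, which is what
relative comparisons between strains or zones require.

## Radial zonation

A nuclear focus at distance `d_center` from the fitted sphere centre gets
`d_edge = r − d_center` (negative when segmentation places it outside the
sphere; flagged and clamped) and a normalized radius `rho = d_center / r`.
Three concentric zones are assigned from `rho`. The default *equal-area*
convention divides the radius at `sqrt(1/3) ≈ 0.577` and `sqrt(2/3) ≈
0.816` — the classic three-annuli-of-equal-area construction used for
nuclear-periphery statistics, applied here to the 3D normalized radius. An
*equal-volume* alternative (boundaries `(1/3)^(1/3)`, `(2/3)^(1/3)`) is
available via configuration. Under uniform placement the equal-area zones
receive (45.6 %, 35.2 %, 19.2 %) of foci (zone 1 = periphery) and the
equal-volume zones one third each; both are asserted by Monte-Carlo tests.
Only nuclear foci are zoned; cytoplasmic foci keep `zone = None`.

## Colocalization and the shuffle null

Object colocalization is geometric: within each nucleus every channel-A
focus is matched one-to-one to its nearest channel-B focus (greedy by
distance, ties by lower id) and the pair is *colocalized* when the centre
distance is at most the sum of the two equal-volume object radii (touching
or overlapping; an extra tolerance is configurable). Significance is
empirical: for each of `n_shuffles` rounds (default 100) the A centres are
re-placed uniformly at random inside their nucleus — the voxel mask when
available, the fitted sphere otherwise — with counts and sizes preserved and
B fixed. The p-value is the add-one rank `p = (1 + #{shuffles with
nearest-B distance ≤ observed}) / (n_shuffles + 1)`, which is super-uniform
under the null and never exactly zero. A pair is *significant* iff
colocalized and `p ≤ α` (default 0.05); only significant pairs count as
telomeric when channel B marks telomeres (e.g. POT-1::mCherry). Note the
fraction of significant calls under independent placement is
`min(α, P(colocalized))`: with sparse, small marker foci the distance
criterion itself, not the shuffle test, is the binding constraint.

Signal relationships across significant pairs (e.g. TERRA focus intensity
vs marker intensity) are summarized by the Spearman rank correlation with
the pair count; zero-variance metrics are reported as undefined rather than
as a coefficient.

## Single-particle analysis

Tracks are 2D (particles are followed on streamed single-plane frames),
gapless, and at least 5 frames long; linking is greedy nearest-neighbour
under a maximum displacement with no gap closing. Two MSD variants are
computed:

* **cumulative** — `MSD(n) = Σ_{i=1..n} (d_i − d_{i−1})²` with `d_i` the
  distance of position *i* from the first position. This is a cumulative sum
  of squared radial increments: non-decreasing by construction, linear in
  time even for directed motion, and invariant to rotations about the track
  origin. It is kept as a faithfully implemented legacy descriptor (the
  nominal sum from i = 0 would reference an undefined position and is
  started at i = 1), and its `D` is reported as the raw initial slope.
* **standard** — the time-averaged `MSD(k) = ⟨|p_{t+k} − p_t|²⟩`, which obeys
  diffusion theory: for 2D Brownian motion the ensemble mean is
  `4 D k Δt + 4 σ_loc²`. All quantitative dynamics below use this variant,
  with `D = slope / 4` from a free-intercept least-squares fit of the first
  4 lags (the intercept absorbs localization noise).

Confinement produces a plateauing MSD; the plateau detector compares local
3-point slopes against the origin-anchored initial secant `MSD(1)/Δt` and
declares a plateau at the first window whose slope falls below 15 % of it
and stays below for the next 12 windows (or to the end of the curve). The
origin anchor matters: for a curve equilibrating with time constant τ the
first *windowed* slope is already decayed by `exp(−Δt/τ)`-like factors and
systematically delays detection; the bounded sustain horizon keeps one noisy
upward window late in a long single-track curve from vetoing a real plateau,
while still rejecting straight lines (whose slopes never drop).

Motility classification is level-first when the long-lag MSD level (mean
over the upper half of the lag range) is available: a track whose MSD sits
at the localization floor (`level ≤ 0.01 µm²`, i.e. a confinement radius at
the ~0.05 µm localization scale) is **stationary**; an elevated track is
**confined** when its MSD flattens (an early plateau, within the first half
of the lag range, or a near-zero initial slope `D ≤ 0.01 µm²/s`); otherwise
**diffusive**. The level criterion is what separates stationary from
confined — both are flat, at very different heights. Without a level the
simple rule applies (stationary iff `D ≤ D_stat`, else confined iff plateau,
else diffusive). Thresholds are configuration, not biology: they reproduce
the qualitative three-class structure on synthetic data and should be
re-examined for other imaging conditions.

Within-track state switches are found with a rolling window (10 frames,
step 1): each window's `D` is estimated from its own standard MSD and
thresholded into stationary/diffusive, runs shorter than one window are
absorbed, and the change point is placed at the midpoint of the first window
of the new class. On simulated tracks that switch from Brownian
(`D = 0.05 µm²/s`) to stationary halfway through 30 s, the change point is
recovered within ±2 s in ≳95 % of runs.

## qPCR quantification

For each sample, `ΔCT = mean(target Ct) − mean(housekeeping Ct)`; with
several housekeeping primers (e.g. *arp-6* and *tba-1*) the mean of their
per-primer Ct means is used and their replicate variances pooled. The ΔCT
error is `e = sqrt(sd_target² + sd_housekeeping²)` with sample (ddof = 1)
standard deviations. Relative expression is `2^−ΔCT` with two error modes:

* `corrected` (default): first-order propagation, `i = ln 2 · e · 2^−ΔCT`;
* `legacy`: `i = e · 2^−ΔCT / ΔCT`, a historically used form kept for
  comparability; it is singular at `ΔCT = 0` and raises there by design.

Fold changes divide each sample's relative expression by the reference
sample's (same primer); the reference is exactly 1. Primer efficiency comes
from a dilution-series standard curve: the least-squares slope of Ct against
log10(dilution) gives `E(%) = (10^(−1/slope) − 1) × 100`, so the perfect
doubling slope `−1/log10 2 ≈ −3.3219` gives exactly 100 %.

## Synthetic data: what it emulates, what it does not

The generators provide ground truth for every stage. Stacks: non-overlapping
spherical nuclei (2–3 µm radius, ≥0.8 µm apart as in the spaced germ line)
rendered as soft-edged spheres, plus focus channels as isotropic 3D
Gaussians (configurable count per nucleus, sigma, amplitude, zone-biased or
uniform placement, nuclear or cytoplasmic compartment) over a constant
background with Gaussian read noise (optional Poisson). Trajectories:
Brownian (per-axis increments of variance `2DΔt`), reflecting-circle
confined (plateau level `R²`, the mean squared distance of two uniform
points in a disk), stationary, and continuous switching compositions, all
with additive localization noise. Ct tables: `Ct = baseline −
log(expression)/log(1 + E)` plus replicate noise.

These are deliberately idealized: no point-spread-function anisotropy or
optical aberration, no uneven illumination or autofluorescence, spherical
nuclei only, memoryless motion within a state, and Gaussian Ct noise.
Passing tests therefore demonstrate that the *algorithms* recover known
truth under their stated assumptions — detection precision/recall ≥ 0.95 at
SNR 8, diffusion coefficients within 15 %, calibrated false-positive rates —
not that those operating points transfer to any particular microscope.
Real data with dimmer foci, denser packing, or aspherical nuclei will need
the documented parameters retuned.

## Numerical conventions and degenerate inputs

26-connectivity for all 3D components; boundary-inclusive centroid
containment for compartment calls; `d_center + d_edge = r` to 1e−6 µm with
`rho` clamped to [0, 1] and flagged; zone percentages sum to 100 ± 1e−9;
constant or contrast-free DNA channels warn and return no nuclei instead of
raising; negative fitted MSD slopes clip to `D = 0`; an all-zero MSD curve
plateaus at the first lag; matching ties break on ids; all generators and
the shuffle null are pure functions of (parameters, seed), and every CLI
command writes byte-identical outputs on rerun with the same seed.

## Problem sizes in the test and acceptance runs

The shipped validation uses sizes that exercise every code path at
comfortable statistical power: 20 stacks of 2 nuclei × 4 foci
(40 × 140 × 140 voxels) for detection; 200 tracks × 50 frames per diffusion
coefficient; 20 ensembles of 30 confined tracks; 300 tracks for
classification (Δt = 0.6 s × 50 frames = 30 s, the full streaming
acquisition length); 100 switching tracks; 10,000 points for zonation;
200 nuclei for colocalization calibration. These were chosen as the smallest
sizes at which the Monte-Carlo tolerances in the tests are stable.
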
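# Methods

This note records the models, parameter choices and numerical conventions
behind `isletkit`, in the order the pipeline runs. Units: all physical
quantities are micrometres; voxel coordinates are 0-based `(x, y, z)` with
the physical position of a voxel centre at `index · spacing`. Calibration is
anisotropic (`dz ≥ dx = dy` for typical confocal stacks) and every
distance-aware step accounts for it.

## Filtering primitives

**Median filter.** Box median with per-axis radii, default (4, 4, 2) — the z
radius is halved because the axial spacing is 2–4× the lateral spacing. The
border policy is *clipped* neighbourhoods: windows shrink at the volume
boundary, no padded values are invented; a clipped (even-count) window takes
the mean of the two central order statistics. Internally the interior is
computed by `scipy.ndimage.median_filter` (whose border mode is irrelevant
where windows are complete) and the border shell is recomputed exactly with
NaN-padded sliding windows, chunked to bound memory.

**Band-pass.** The size-selective blob enhancement is realised as a
difference of Gaussians whose FWHMs match the size band:
`σ = size / (2 · 2.355)` for the two band edges (in XY voxels; the z sigma
is scaled by `dx/dz`). Defaults 20–28 px correspond to the ~6–7 µm nucleus
diameter at the 0.18–0.38 µm lateral calibrations the toolbox targets.
Negative responses are clamped and the result rescaled affinely so the
volume minimum maps to 0 and the maximum to 65535; the seed-detection
threshold (30 000) is defined on this 16-bit scale. A DoG was chosen as the
standard, monotone-in-band blob filter; the exact frequency response of the
band-pass is otherwise a free implementation detail.

**Distance map.** Calibrated Euclidean distance transform of the background
(`scipy.ndimage.distance_transform_edt` with the voxel spacing as sampling),
so anisotropy is exact, not approximated by slice stacking.

**Seed detection.** Local maxima within an anisotropy-aware ball (radius in
XY voxels, z extent scaled by `dx/dz`), thresholded at 30 000. Plateaus are
collapsed to their lexicographically smallest coordinate, which makes
detection deterministic; a constant volume therefore yields exactly one
seed.

## Nuclei segmentation

Per seed, the radial profile collects mean intensity in concentric
calibrated shells (default 10 layers of one XY-voxel width; mid-shell radii
are used as abscissae, empty shells dropped). The profile is fitted by
least squares with `I(r) = B + (A−B)·exp(−r²/2σ²)` under `A ≥ B ≥ 0`
(parametrised as `B + C·exp(…)`, `C ≥ 0`, to keep the constraint inside the
bounded fit); the local threshold is the curve value at `r = kσ` with
`k = 1.8`, i.e. `B + (A−B)·e^{−k²/2}`. The offset term `B` is included
because a packed tissue never decays to zero between nuclei. If the fit
fails (non-convergence or unbounded σ) the half-maximum `(A+B)/2` is used
and the seed flagged in the log — no seed is silently lost.

Region growing runs on the *median-filtered* image (thresholds are fitted on
real intensities; the band-pass output is size-normalised, not
intensity-calibrated) over 26-connected voxels, restricted to a local box of
twice the profile extent — a nucleus is a local object and unbounded growth
along bright paths is a failure mode, not a feature. A seeded watershed on
the inverted band-pass image, masked to the union of grown regions, settles
contested voxels so no region crosses a neighbouring seed. Regions below 50
voxels (well under a quarter of the ~1400-voxel discretised nucleus at
default calibration) are discarded as degenerate fits and logged.

## Cell zones

Zones extend nuclei outward on the background distance map under watershed
competition, capped at 4 µm from the nucleus *boundary* ("extending the
nuclei boundaries" — the cap is measured from the boundary, not the
centroid, hence directly on the distance-map value). The flood is
implemented as a sorted sweep (numba): masked voxels are visited in
increasing distance order with raster-order tie-breaking, each taking the
label of its already-assigned neighbourhood; a voxel whose assigned
neighbours carry two or more labels becomes a **frontier voxel** — assigned
to neither zone, recorded as the contact surface, and treated as evidence of
contact between all adjacent zones when the interaction graph is built. The
visiting order is a total order, so the procedure is exactly deterministic.
A voxel-count note: the sweep is equivalent to a priority-queue watershed
whose priority is the voxel's own distance value, with FIFO handling of
equal priorities.

## Supervoxel phenotyping

The three marker channels are median-filtered (4, 4, 2) and min–max
normalised to [0, 255] per channel (a constant channel maps to zeros with a
warning — it carries no marker signal).

Clustering starts from a regular grid of zone centres with pitch
`p = round(√R)` (zone area `R` defaults to 150 px², admissible range
100–300); the z pitch is `p·dx/dz` so zones are physically roughly
isotropic. Each of 10 rounds offers every voxel within `2p` of a centre the
cost

    d = d₁ + λ · d₂ / p²

with `d₁ = Σ_c (I_c(v) − med_c(zone))²` over the three channels,
`d₂` the squared voxel distance to the centre (z scaled by `dz/dx`), and
`λ = 10⁴`. Zone statistics are channel *medians* (robust against halo
edges), recomputed with the centres after each round. The normalisation
`d₂/p²` makes λ the cost, in squared 8-bit intensity units, of sitting one
pitch away from the centre — that is the sense in which λ is a stiffness.
After the rounds, a connectivity repair reassigns every disconnected
fragment of a zone to the adjacent zone with the nearest centre (the
fragment nearest its own centre keeps the label), iterated to a fixed point,
so every supervoxel ends 26-connected and voxel count is conserved.

Typing: a supervoxel takes the channel with the highest median if that
median reaches the per-channel threshold (default 40 on the 0–255 scale),
else `unlabeled`; exact ties go to the fixed channel order (alpha, beta,
delta) and are logged. Per cell, the probe shell spans 3 voxels inward and
2 outward of the nucleus boundary (XY voxels; z scaled by anisotropy),
clipped to the cell's own zone; the phenotype is the most voxel-abundant
marker type in the shell provided it covers at least 5% of the shell
(below that the cell is `unlabeled`). The 40/5% defaults are exposed in the
configuration; they were chosen once as the values that separate a rendered
halo (~200 intensity, tens of percent occupancy) from background, and sit
far from both.

## Interaction network and randomization

Edge rule: two cells interact when a voxel of one zone has a voxel of the
other in its 3×3×3 neighbourhood (26-connectivity — corner contact counts),
or when both zones touch a common frontier voxel. Edges incident to
`unlabeled` cells stay in the graph (they carry shortest paths) but are
excluded from interaction-frequency denominators, mirroring the composition
convention that excludes unlabeled cells. Cell distances are unit-weight
shortest paths (BFS; equivalent to Dijkstra on unit weights) from a
reference set; unreachable cells get `inf` and are dropped from downstream
cdfs with a logged count.

Random mixing predicts `P_xx = P_x²` and `P_xy = 2·P_x·P_y` from the
labelled-cell composition. The randomization procedure shuffles *types*
over existing positions: for each cell of the target type, a partner is
drawn uniformly over all cells and the two types swapped when they differ.
Drawing over all cells (self-draw = no-op) rather than "all other cells" is
deliberate: it is what makes a lone target cell land on every position with
equal probability, i.e. the single-pass shuffle already has the uniform
assignment as its expectation.

## Spatial statistics

G-function: for each target-type cell, distance to its nearest same-type
neighbour. F-function: for every cell position (the reference set of a
packed tissue — there is no meaningful empty space to sample), distance to
the nearest target-type cell. Both run in calibrated micrometres or in cell
distance.

SDI: the mean cdf is computed from `n_avg = 100` randomized organizations;
the deviation statistic `T = max |cdf − cdf_mean|` is evaluated for the
observed data and for a *disjoint* set of `n_env = 100` randomizations, all
cdfs evaluated exactly on the pooled grid of every distance value observed
in any run (no binning). SDI is the mid-rank of `T_obs` among the envelope
statistics, `(#{T_i < T_obs} + ½·#{T_i = T_obs}) / n_env`, lying in [0, 1];
values outside [0.05, 0.95] flag non-random organization at the 95% level.
Mid-ranking keeps SDI unbiased under ties; the fully degenerate case
(observed and every randomized cdf identical, all T = 0) is reported as
SDI = 0 — there is no evidence of structure, not borderline evidence.
Deviations below 1e-12 are treated as zero (floating-point dust from
averaging identical step functions). All Monte-Carlo stages draw from named
per-stage seed streams derived from one root seed, so the 100+100 sets are
individually reproducible.

Clusters are connected components of the subgraph induced by one type
(cell distance 1 = direct contact; singletons count). Collapsing replaces
each cluster by a node at the member-centroid mean, keeping deduplicated
outside edges, for cluster-level spatial statistics.

## Synthetic islets

The generator emulates the target acquisition regime: 256×256×40 voxels at
0.32 µm XY / 1.0 µm Z (an ~82×82×40 µm field), ~100 cells of 6.5 µm nuclear
diameter packed by dart-throwing Poisson-disk sampling (minimum spacing =
one nuclear diameter) inside an ellipsoid, nuclei kept fully inside the
stack. Composition defaults to the mouse-like 18.2/76.4/5.4% (alpha, beta,
delta), realised exactly by largest-remainder rounding; any remainder
becomes `unlabeled` cells that receive no marker.

Rendering: DAPI nuclei are Gaussian intensity blobs with the ground-truth
nucleus boundary defined at the 1.8σ isocontour — the same convention the
radial-threshold segmentation uses, so the generator and the pipeline agree
on what "the nucleus" is. Marker halos are uniform annuli between the
nucleus radius and the zone radius, clipped to the cell's Voronoi territory,
which makes marker channels mutually exclusive at ground truth. Noise is
Poisson shot noise (photon gain 10) plus Gaussian read noise (σ = 30 ×
noise level, default 1) — deliberately not a full optical model: no PSF,
no depth-dependent attenuation, no bleed-through. Passing tests on these
fixtures therefore demonstrates correctness of the algorithms under
realistic geometry and calibrated anisotropy, not robustness to every real
staining artefact.

Arrangements: `random` permutes types; `clustered` grows the alpha
population around k random foci; `mantle` models the rodent layout. A note
on the mantle: a real rodent mantle is a contiguous peripheral alpha/delta
layer. At ~100 cells the alpha population cannot cover the whole surface,
so scattering alphas over the shell would produce *no* mutual contacts and
no clustering signal at all — the opposite of the biology. The mantle is
therefore rendered as a contiguous peripheral cap: the outer third of cells
ranked by angular distance to the most peripheral cell, alphas first,
deltas at the cap margin. Ground truth shipped with each sample: the cell
table (with nucleus radius), nucleus and zone label volumes, and the
contact graph of the generative territories.

`generate_islet(..., render=False)` skips intensity rendering and returns
positions, types and the truth graph only. Statistical fixtures use this
path at paper-scale geometry (500 cells, ~134×134×56 µm), where the
G-function has realistic power; the rendered 100-cell default is the
imaging fixture. `crop_to_section` extracts a central z slab and rebuilds
the truth accordingly, emulating a thin histological section.

## Validation metrics

Detection is scored at object level: a predicted label is a true positive
when its calibrated centroid falls inside a not-yet-claimed true nucleus
(predictions visited in ascending label order, each claiming the nearest
containing truth); unclaimed predictions are false positives, unclaimed
truths false negatives. A split nucleus therefore costs one false positive,
matching how over-segmentation is perceived when scoring by eye. Recall,
precision and F-measure are reported in percent rounded to 3 decimals;
overall classification accuracy (trace over total of the 4-class confusion
matrix) is *truncated* to 2 decimals, and composition percentages are
rounded to 1 decimal — the printing conventions of the reference tables the
arithmetic is checked against. The embedded reference counts
(`isletkit.datasets`) contain two internally inconsistent printed rows
(a precision that cannot follow from its own printed counts, and one
transposed F-measure digit); tests assert the arithmetic implied by the
counts, and summary rows are reproduced as unweighted means of per-dataset
metrics, which is the convention the printed totals follow.

## Problem sizes

Defaults were chosen so a full desk-scale validation is comfortable on one
CPU: the rendered default islet is 2.6 M voxels (end-to-end analysis ≈ 2–3
minutes, dominated by the 4 median filters and the supervoxel rounds);
statistical fixtures are position-only 500-cell islets; SDI uses the
100+100 randomization scheme throughout; calibration checks run 200
independent SDI repetitions.

## Known limitations

- The nuclei model is a blob model: heavily elongated or lobed nuclei will
  be over-split (the label-editing utilities exist for exactly that).
- Supervoxel typing assumes three mutually exclusive cytoplasmic markers;
  co-expressing cells are not modelled.
- The generator's noise model is additive/shot only; no optical PSF or
  clearing artefacts, so absolute detection rates on real stacks will be
  somewhat lower than on fixtures.
- Frequency denominators exclude unlabeled-incident edges; with very high
  unlabeled fractions the remaining edge counts (and SDI power) shrink.
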
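# isletkit

Single-cell-resolution analysis of 3D tissue organization, built around the
islet of Langerhans. Given a 4-channel confocal stack — a nuclear stain
(DAPI) plus cytoplasmic markers for the three major endocrine cell types
(glucagon/alpha, insulin/beta, somatostatin/delta) — the toolbox answers the
questions a tissue biologist actually asks: *where is every cell, what type
is it, which cells touch, and is the arrangement random?*

It is aimed at quantitative microscopists and islet biologists who want an
automated, scriptable replacement for slice-by-slice manual scoring, and it
ships with a ground-truthed synthetic islet generator so every stage can be
validated without any imaging data.

## The pipeline

1. **Nuclei segmentation.** The nuclear channel is cleaned with a 3D median
   filter (radius 4–4–2 in x–y–z), enhanced with a size-selective band-pass
   (20–28 px, matching the ~6–7 µm nucleus diameter) rescaled to 16 bits,
   and seeded from local intensity maxima (radius 4, threshold 30 000). For
   each seed the radial profile of mean intensity in concentric calibrated
   shells is fitted with a Gaussian `I(r) = B + (A−B)·exp(−r²/2σ²)`; the
   value at `r = 1.8 σ` becomes that seed's local threshold for region
   growing, and a seeded watershed keeps touching nuclei apart.
2. **Cell zones.** With no membrane stain, each cell's plausible extent is a
   radius-constrained Voronoi territory: the calibrated background distance
   map is flooded outward from nucleus surfaces, under competition between
   neighbours, up to 4 µm from the nucleus boundary. Voxels reached by two
   nuclei simultaneously become *frontier* voxels — the contact surface.
3. **Supervoxel phenotyping.** The three marker channels are median-filtered,
   normalised to [0, 255] and clustered into compact supervoxels by an
   iterative local assignment with cost `d = d₁ + λ·d₂/p²` (intensity
   distance `d₁`, squared spatial distance `d₂`, grid pitch `p`, stiffness
   `λ = 10⁴`), using per-zone channel *medians*. Each supervoxel takes the
   type of its strongest channel (or `unlabeled` below threshold); each cell
   reads its phenotype from the typed voxels in a shell around its nucleus
   (3 voxels inward, 2 outward, clipped to its own zone).
4. **Interaction network.** Cells are graph vertices; an edge joins two cells
   whose zones touch under 26-connectivity (or share a frontier voxel).
   *Cell distance* is the hop count on this graph: direct contact = 1.
5. **Spatial statistics.** G-function (nearest same-type neighbour cdf) and
   F-function (all-cells-to-nearest-target cdf), in Euclidean µm or in cell
   distance. The null model shuffles cell *types* over existing positions —
   never inventing positions inside a packed tissue. The Spatial
   Distribution Index (SDI) is the rank of `T = max |cdf_obs − cdf_rand|`
   within 100 randomized organizations (mean cdf from a separate set of
   100); SDI outside [0.05, 0.95] flags non-random organization. Homotypic
   and heterotypic contact frequencies are compared with the random-mixing
   expectations `P_xx = P_x²`, `P_xy = 2·P_x·P_y`, and same-type clusters
   (components at cell distance 1) can be collapsed to single nodes for
   cluster-level statistics.

## Worked example

```python
from isletkit import IsletSpec, generate_islet
from isletkit.pipeline import PipelineConfig, analyze_sample

# 60-cell synthetic islet with alphas aggregated around 2 foci
sample = generate_islet(IsletSpec(n_cells=60, shape=(192, 192, 32),
                                  arrangement="clustered", n_clusters=2, seed=11))
bundle = analyze_sample(sample.volumes, PipelineConfig(seed=11))
summary = bundle["summary"]
```

The summary printed for this run:

```
composition_pct: {'alpha': 18.3, 'beta': 76.7, 'delta': 5.0}
mean_degree: 9.03
observed:    {'alpha-alpha': 0.100, 'alpha-beta': 0.236, ..., 'beta-beta': 0.554}
theoretical: {'alpha-alpha': 0.034, 'alpha-beta': 0.281, ..., 'beta-beta': 0.588}
sdi: {'F_euclidean_um': 1.0, 'F_cell_graph': 1.0,
      'G_euclidean_um': 0.99, 'G_cell_graph': 0.755}
cluster_sizes: [11]
```

Reading it: the pipeline recovered the seeded composition (18/77/5%); each
cell touches ~9 neighbours; alpha–alpha contacts run at 10% where random
mixing predicts 3.4%, and the G/F SDI values sit at the top of the
randomized envelope — the alpha population is organized non-randomly, as
built: all 11 alphas form a single contact cluster.

The same stages are available from the shell:

```sh
isletkit simulate --seed 3 --out islet.tif --truth truth.csv
isletkit segment-nuclei --in islet.tif --channel 0 --out nuclei.tif
isletkit cell-zones --nuclei nuclei.tif --radius-um 4 --out zones.tif
isletkit phenotype --stack islet.tif --nuclei nuclei.tif --zones zones.tif --out cells.csv
isletkit network --zones zones.tif --cells cells.csv --out-edges edges.csv
isletkit spatial-stats --cells cells.csv --graph edges.csv --type alpha --function G --out stats.json
isletkit run-all --stack islet.tif --out-dir results/
```

## Layout

| module | contents |
| --- | --- |
| `isletkit.core` | calibrated volumes, median/band-pass filters, distance maps, seed detection |
| `isletkit.io` | calibrated TIFF I/O (volumes, 16-bit label images) |
| `isletkit.nuclei` | radial-profile thresholds, seeded segmentation, label editing |
| `isletkit.zones` | radius-constrained zone watershed with frontier voxels |
| `isletkit.supervoxels` / `.phenotyping` | SLIC-style clustering, zone typing, cell phenotypes |
| `isletkit.network` | contact graph, interaction frequencies, type shuffling, cell distances |
| `isletkit.spatial` | F/G functions, SDI, cluster analysis |
| `isletkit.metrics` | object-level detection and classification scoring |
| `isletkit.synthetic` | ground-truthed islet generator (random / mantle / clustered) |
| `isletkit.pipeline` / `.cli` | configuration, orchestration, command line |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical conventions.
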
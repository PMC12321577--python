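# gliometry

Quantitative image analysis of regional astrocyte identity in the mouse
septum, packaged as a tested, reusable pipeline with a synthetic-microscopy
simulator providing complete ground truth.

Astrocytes of the medial septum (MS) and the lateral septum (LS, with its
dorsal/intermediate/ventral subdivisions dLS, iLS, vLS) differ in
developmental lineage, morphology and synaptic environment. Establishing
those differences from confocal images requires a battery of cell-level
measurements, each of which this package implements:

- **Morphometry** — distance from the nucleus to the tip of the longest
  branch; length-to-width ratio `L/W` where `L` is the maximum Feret
  diameter of the arbor footprint and `W` its extent perpendicular to the
  Feret axis; orientation `θ = arccos |u·m| ∈ [0°, 90°]` of the elongation
  axis `u` against the midline axis `m`, with pie-chart binning; territory
  area/volume (convex hull × stack depth); Sholl intersection profiles.
- **Synaptic puncta** — 3-D Laplacian-of-Gaussian spot detection of pre-
  and postsynaptic markers (e.g. vGlut1/PSD95, vGAT/gephyrin), greedy
  globally-nearest one-to-one colocalization within a distance threshold
  (default 0.5 µm), and colocalized-synapse density per mm³ within
  astrocyte territories. The chance-pairing rate of independent channels
  has the closed form `1 − exp(−λ·(4/3)πr³)`.
- **RNAscope counts** — puncta-per-nucleus assignment and per-region
  transcript densities normalized to the MS.
- **Lineage census** — marker⁺/⁻ classification of nuclei (threshold =
  background mean + 3 s.d.) and regional lineage fractions such as the
  proportion of Sox9⁺ astrocytes carrying a lineage reporter.
- **Statistics** — one-way ANOVA with Tukey–Kramer multiple comparisons
  (`q_ij = |x̄_i − x̄_j| / √(MS_w/2 · (1/n_i + 1/n_j))`), and mean ± s.e.m.
  / box-plot summaries.

Because the corresponding real image sets are not publicly deposited, every
operator is validated by **parameter recovery on synthetic images**: the
`synth` module renders arbors whose branch directions follow a von Mises
law about the midline (concentration κ; κ = 0 isotropic, LS-like; large κ
midline-aligned, MS-like), DAPI-like nuclei, PSF-convolved spot channels
with a controlled truly-colocalized fraction, and per-region marker
mosaics — all with recorded ground truth.

## Worked example

Render eight single astrocytes with fixed 40 µm branches (κ = 8 about the
midline), then segment, skeletonize and measure each:

```python
from gliometry.synth import SynthConfig
from gliometry.pipeline import measure_rendered_cells

df = measure_rendered_cells(
    SynthConfig(seed=1, branch_length_sd_um=0.0, noise_sd=0.0), n_cells=8
)
print(df[["cell_id", "longest_branch_um", "lw_ratio", "orientation_deg"]].round(2))
```

```
 cell_id  longest_branch_um  lw_ratio  orientation_deg
       0              40.07      1.75             1.56
       1              39.90      3.03            19.47
       2              39.97      1.89             8.41
       ...
```

The measured longest branch recovers the generated 40 µm within a voxel,
and the orientations concentrate near the midline (all < 30°), as expected
for κ = 8. A two-group comparison of MS-like versus LS-like simulations:

```python
from gliometry.stats import one_way_anova, summarize

ms = measure_rendered_cells(SynthConfig(seed=1, orientation_kappa=8.0), n_cells=10)
ls = measure_rendered_cells(SynthConfig(seed=2, orientation_kappa=0.0,
                                        branch_length_mean_um=25.0), n_cells=10)
groups = {"MS": ms["longest_branch_um"], "LS": ls["longest_branch_um"]}
res = one_way_anova(groups)
```

prints `ANOVA F = 105.76, p = 5.79e-09` with group summaries
`MS: mean = 51.6 um, s.e.m. = 0.80, n = 10` and
`LS: mean = 34.4 um, s.e.m. = 1.47, n = 10` — the simulated MS cells are
longer, and the pooled test detects it.

## Command line

```sh
gliometry simulate --seed 1 --out-dir run/        # scene + ground truth
gliometry segment  --stack run/stack.ome.tif --atlas run/atlas.tif --out-dir run/seg
gliometry measure  --stack run/stack.ome.tif --atlas run/atlas.tif --out-dir run/morpho
gliometry puncta   --stack spots.ome.tif --out-dir run/puncta
gliometry census   --stack run/stack.ome.tif --atlas run/atlas.tif --out-dir run/census
gliometry report   --morphometry run/morpho/morphometry.csv --out-dir run/stats
```

Every command writes a `manifest.json` (config hash, seed, version);
`simulate` output is byte-identical for a given seed and configuration.

## Layout

```
src/gliometry/
  io.py            TIFF/OME-TIFF stacks, region atlas, CSV tables, TOML config
  synth.py         ground-truth simulator (arbors, nuclei, puncta, census)
  segmentation.py  nucleus detection, arbor masks, skeletons, territories
  morphometry.py   longest branch, L/W ratio, orientation, binning, Sholl
  puncta.py        spot detection, colocalization, density statistics
  census.py        marker classification, lineage fractions, cell density
  stats.py         one-way ANOVA, Tukey-Kramer HSD, summaries
  pipeline.py      end-to-end workflows
  cli.py           `gliometry` command group
docs/methods.md    model, parameter and design documentation
```
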
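# orgoquant

Quantification of glioblastoma (GB) invasion into brain organoids from
confrontation-assay microscopy, plus single-cell migration statistics from
time-lapse tracks.

## The problem

In a confrontation assay a patient-derived GB organoid (tumor cells labeled
with GFP or another fluorophore) is co-cultured with a brain organoid (BO)
until the two spheres merge. Tumor cells then invade the brain compartment in
two distinct modes: the contiguous tumor mass advances and *replaces* brain
tissue, and individual cells *detach* and migrate through the brain tissue.
`orgoquant` turns a two-channel image of such a merged pair into three
numbers, and a table of cell trajectories into per-cell invasion speeds and
behavioral events.

### Invasion metrics

The merged cluster outline is segmented by seeded region growing on the
reference (brightfield) channel, split at its concave "neck" into two arcs,
and one ellipse is fitted per arc — a brain ellipse B and a tumor ellipse.
With R the rasterized pixel set of B ("BO area") and the GFP channel
thresholded and labeled into a core mass vs detached components:

- **competition ratio** = |core ∩ R| / |R| — fraction of the brain organoid
  replaced by the contiguous tumor mass,
- **single-cell ratio** = |detached ∩ R| / |R| — area fraction occupied by
  tumor components not connected to the core,
- **total invasion** = their sum (exact by construction).

Every quantity is a ratio of pixel counts, never an analytic area. Treatment
effects are summarized as percent inhibition, 100 × (1 − treated/control),
over replicate means.

### Track statistics

Trajectories are cut into consecutive non-overlapping 40-minute windows; the
path length in each window (sum of step distances) converts to a speed in
µm/h, one data point per window. The package also detects boundary
reversals — a cell reaching the organoid margin and turning back — and
screens divisions for the "go and grow" signature (daughters leaving the
division site in opposite directions).

A synthetic-data module renders confrontation scenes with pixel-exact ground
truth and simulates persistent random walks with reflecting organoid
boundaries, mitotic pauses and division events, so the entire pipeline is
testable without microscopy data.

## Worked example

```python
import orgoquant as oq

# render a synthetic confrontation scene: 30% of the brain lobe replaced,
# 5% covered by 12 detached cells
stack, truth = oq.render_scene(oq.SceneSpec(seed=1))
print(f"truth    competition={truth.competition_realized:.4f} "
      f"single={truth.single_fraction_realized:.4f} n_cells={truth.n_single_cells}")

hints = oq.ImageHints(seed_rc=(128, 158),          # region-growing seed (row, col)
                      brain_xy=truth.brain_center_xy,
                      tumor_xy=truth.tumor_center_xy)
m = oq.quantify_image(stack, hints).metrics
print(f"measured competition={m.competition_ratio:.4f} "
      f"single={m.single_cell_ratio:.4f} total={m.total_invasion:.4f} "
      f"n_cells={m.n_single_cells}")
```

prints

```
truth    competition=0.3000 single=0.0500 n_cells=12
measured competition=0.2844 single=0.0505 total=0.3349 n_cells=12
```

The measured competition ratio recovers the generated 0.30 to within the
fitted-ellipse discretization error (~0.016 here), the single-cell ratio and
detached-cell count are recovered almost exactly, and total invasion is the
exact sum of the two ratios.

The same pipeline is available from the shell:

```sh
orgoquant simulate --out-dir demo --seed 1            # scene + tracks + truth
orgoquant quantify demo/scene.ome.tif --out-dir demo/metrics \
    --hints-file hints.json                           # metrics.csv + QC overlays
orgoquant trackstats demo/tracks.csv --out-dir demo/speeds
```

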
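# tricell

3D time-lapse cell analysis for membrane-tagged (and nuclei-tagged)
confocal stacks:

1. **Membrane probability** — a rotation-equivariant 3D U-Net built on the
   24-element cube rotation group (exact signed-axis-permutation rotations,
   numpy forward pass), plus a training-free classical fallback so the
   pipeline never requires a trained model.
2. **Segmentation** — automatic distance-transform seeds, seeded 3D
   watershed, and mean-field dense-CRF boundary refinement (appearance +
   smoothness Gaussian kernels, Potts compatibility), then a small-region
   filter. Closed cell surfaces by construction.
3. **Adjacency graph** — cells as vertices, edge weight = number of
   simultaneous 6-connected dilation rounds until two cells meet;
   distance-1 pairs are neighbors.
4. **Sub-cellular features** — anticlinal wall segments (wall point sets
   ordered into polylines, cut at junctions) and junctions of three cell
   walls, straight from the adjacency graph.
5. **Tracking** — per-cell features (size, degree, weighted degree),
   greedy one-to-one frame linking by relative-difference similarity,
   track-id propagation.
6. **Metrics** — boundary P/R/F at range R, cell-count statistics,
   junction P/R/F at voxel tolerance, end-point displacement error,
   discrete Fréchet distance, length difference, and AOGM-based TRA.

Everything is testable offline through the built-in phantom generator
(`tricell.phantoms`): Voronoi-tessellation cell volumes with bright
membranes, nuclei-style blobs, and smoothly deforming time-lapse sequences
with exhaustive ground truth (labels, walls, junctions, tracks).

## CLI

```bash
# synthetic phantom sequence with ground truth
tricell phantom --shape 24 48 48 --n-cells 8 --n-frames 4 --seed 7 --out phantom/

# segment a stack (TIFF in, 16-bit label TIFF + run manifest out)
tricell segment --input phantom/intensity_t000.tif --out labels.tif \
    --minimum-distance 12 --threshold 0 --label-threshold 20

# adjacency graph, wall segments, junctions
tricell features --labels labels.tif --out features/

# track a sequence of label volumes
tricell track --labels labels_t0.tif --labels labels_t1.tif --out tracks/

# evaluate against ground truth (boundary P/R/F, counts, optional TRA)
tricell evaluate --gt-labels phantom/labels_t000.tif --pred-labels labels.tif
```

All coordinates are 0-based (z, y, x); volumes are multi-page TIFF, one
page per z-slice, z ascending.

## Package layout

```
src/tricell/
  phantoms.py     synthetic volumes/sequences + brute-force feature oracle
  groupconv.py    24-element rotation group, equivariant layers, small U-Net
  segment.py      seeds, watershed, dense-CRF refinement, region filter
  cellgraph.py    dilation-distance adjacency graph
  subcellular.py  wall segments, three-cell junctions, polyline ordering
  tracking.py     track features, similarity, frame linking, track graphs
  metrics.py      boundary/junction/curve/tracking metrics (incl. TRA)
  io_cli.py       TIFF I/O, track tables, manifests, click CLI
```
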
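# cellgraph3d

Quantifying cell–cell interactions and marker polarization in 3D
multi-channel immunofluorescence volumes (e.g. CyCIF stacks, where each
channel maps one protein marker across the tissue).

Given a multi-channel volume and a table of labeled cell centers, the
package answers two questions a spatial-biology analyst asks constantly:

* **Which pairs of cells are candidate interactions, and what do the
  markers do between them?**  Cells become nodes of a *cell graph*: a 3D
  Delaunay triangulation pruned to the **Gabriel graph** — edge {a, b}
  survives only if no third cell center lies strictly inside the open ball
  with diameter ab, formalizing the intuition that two cells only interact
  when nothing sits directly between them.  For each edge the package
  integrates voxel intensities inside a **cylinder** (constant radius r) or
  **bicone** (apexes at the two cell centers, radius r at the midpoint)
  around the edge, projecting each in-shape voxel onto the edge and
  averaging per position, which yields a 1D **interaction profile** per
  channel, min–max normalized to [0, 1].  Profiles of an immune synapse
  show co-localized checkpoint markers (e.g. PD1/PDL1) peaking between the
  two membranes.

* **Is a marker polarized around a given cell?**  All voxels within radius
  r of a cell center are projected orthogonally onto a viewing plane and
  binned into 12 angular sectors (a clock face, 30° each, clockwise from a
  configurable "north"), producing a per-channel **polarization profile**
  whose argmax sector points at the direction of concentration.

Edges are compared by a per-channel profile distance

    W_p(P, Q) = ( (1/n) Σ_{i=1..n} |X_i − Y_i|^p )^(1/p),   p = 1 by default,

summed over channels after resampling both profiles to a common length by
linear interpolation; ranking all edges against a reference edge surfaces
interactions with a matching marker signature.  A classical 1D Wasserstein
variant (CDF-based, phase-shift tolerant) is available via
`metric="wasserstein1d"`.

A fully synthetic data generator plants cells, interactions and
polarization directions with known ground truth so that every stage is
verifiable without external data.

## Worked example

```python
import numpy as np
import cellgraph3d as cg

# a scaled synthetic emulation of a melanoma CyCIF stack:
# 8 channels, 256x256x55 voxels, 20 cells, with a planted PD1-PDL1
# immune synapse, a separated-centers PD1/PDL1 edge, and a CD8A-polarized cell
vol, truth = cg.case_study_fixture(seed=17)
graph = cg.build_graph(truth.centers, vol.spacing)
print(f"graph: {len(graph.nodes)} cells, {len(graph.edges)} candidate interactions")

shape = cg.ShapeSpec("cylinder", radius=25, radius_unit="voxel")
profiles = {e: cg.compute_interaction_profile(vol, graph, e, shape)
            for e in graph.sorted_edges()}

(synapse,) = truth.planted_edges("two-cell-co-localization")
ranking = cg.rank_edges(synapse, profiles, channels=["PD1", "PDL1"])
for entry in ranking.entries[:3]:
    print(f"edge {entry.edge}: distance {entry.total:.3f}")

planted = truth.planted_polarizations[0]
center = truth.centers.position_of(planted.node) * np.asarray(truth.spacing)
pol = cg.compute_polarization(vol, center, 2.8, channels=["CD8A"])
print(f"CD8A argmax sector around cell {planted.node}: "
      f"{pol.argmax_sector('CD8A')} (planted: {planted.expected_sector})")
```

prints

```
graph: 20 cells, 31 candidate interactions
edge (0, 1): distance 0.000
edge (11, 15): distance 0.511
edge (4, 9): distance 0.667
CD8A argmax sector around cell 0: 3 (planted: 3)
```

The planted synapse edge (0, 1) ranks first at distance 0 (it is the
reference itself); ordinary edges follow at moderate distances, and the
planted separated-centers edge — PD1/PDL1 expressed in the two cell bodies
but not engaged at the contact — ranks last (distance 1.101 in this run).
The CD8A polarization argmax recovers the planted direction (100° →
sector 3, i.e. roughly 3 o'clock).

## Command line

The same workflow is scriptable:

```sh
cellgraph3d simulate --seed 17 --out-volume vol.ome.tif \
    --out-centers centers.csv --out-truth truth.json
cellgraph3d build-graph --centers centers.csv --volume vol.ome.tif --out graph.json
cellgraph3d profile --volume vol.ome.tif --graph graph.json --edges all \
    --shape cylinder --radius 25 --radius-unit voxel --out profiles.json
cellgraph3d rank --profiles profiles.json --reference 0-1 \
    --channels PD1,PDL1 --out ranking.json
cellgraph3d polarize --volume vol.ome.tif --graph graph.json --nodes 0 \
    --radius 13 --radius-unit voxel --out polarization.json
```

`simulate` without `--config` produces the built-in case-study emulation; a
YAML plan (keys `dims`, `spacing`, `n_cells`, `cell_radius_um`, `markers`,
`planted_pairs`, `background`, `noise_sd`) drives custom volumes — each
`markers` entry is `{channel, kind, cells|edge, amplitude, theta0_deg,
kappa}` with `kind` one of `nuclear`, `membrane`, `interaction`,
`colocalization`, `separated`, `polarized`.

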
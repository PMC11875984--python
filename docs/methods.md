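# Methods

This note documents the models and procedures implemented in `cellgraph3d`,
the parameters that matter, the numerical conventions, and what the
synthetic ground truth does and does not demonstrate.

## Coordinate conventions

Volumes are stored `(channel, z, y, x)`; voxel spacing is given per axis
`(x, y, z)` in micrometers.  Cell centers are 0-based voxel coordinates
(fractional permitted — proofreading may place a center between voxel
centers); the center `(x, y, z)` refers to the center of voxel `(x, y, z)`.
All geometry — graph construction, shape membership, radii, sector
binning — operates in physical micrometers (`index × spacing`), because
multiplexed imaging stacks are strongly anisotropic (the emulated data uses
0.22 µm lateral pixels against 0.28 µm sections; real stacks are often far
more anisotropic).  A radius given "in voxels" is converted with the
lateral (x) voxel size.

## Cell graph

Nodes are cell centers; candidate interaction edges are the 3D Delaunay
triangulation (scipy) pruned to the **Gabriel graph**: edge {a, b} is kept
iff no third center c satisfies |c − m| < |ab|/2, where m is the edge
midpoint — the *open*-ball criterion, so a center exactly on the boundary
sphere does not remove the edge (contact is not containment).  The Gabriel
graph is always a subgraph of the Delaunay triangulation, which the test
suite exploits by comparing against a brute-force all-pairs oracle.

Degenerate inputs, which thin stacks make realistic, fall back gracefully:
exactly coplanar point sets are triangulated in their best-fit plane
(SVD-rank detection with a 1e-9 relative tolerance), collinear sets become
a chain of consecutive points, two points give the single edge, and
coincident points raise an error naming the pair.

Graph edits (add/remove/move node, add/remove edge) trigger a full
Delaunay+Gabriel recompute — at the ~10²-cell scale this targets, a full
rebuild costs milliseconds and avoids the correctness risks of incremental
updates.  User edge edits are stored as flags and re-applied after every
rebuild: removals persist until explicitly re-added; additions persist
while both endpoints exist.  Whether a user-added edge should ever expire
is genuinely open; flags make the choice reversible.

## Interaction profiles

For edge (a, b) with length L, each voxel center v gets a parametric
projection t = ⟨v − a, b − a⟩/L² and perpendicular distance d.  Two
integration shapes are supported:

* **cylinder** — inside iff 0 ≤ t ≤ 1 and d ≤ r;
* **bicone** — inside iff 0 ≤ t ≤ 1 and d ≤ r·(1 − |2t − 1|): radius 0 at
  both cell centers growing linearly to r at the midpoint.  The apexes sit
  at the cells because the bicone is meant to capture spherical sectors
  emanating from each cell toward the contact zone; a midpoint-apex reading
  of the geometry is visually plausible but would de-emphasize exactly the
  contact region the shape exists to capture.

Membership uses voxel centers (point sampling, no partial-volume
weighting): simple, exactly reproducible by a brute-force loop, and
unbiased at the bin sizes used.  In-shape voxels are binned by
`min(⌊t·n_bins⌋, n_bins − 1)`; per bin and channel the arithmetic mean is
recorded, with empty bins (inevitable near bicone apexes at fine binning)
stored as mean 0 with `n_voxels = 0` — an optional `fill_empty_bins` flag
interpolates across empty interior bins, but off by default so no signal
is fabricated silently.  The default bin count is one bin per lateral
voxel along the edge (`max(2, round(L / spacing_x))`).

Normalization is min–max per (edge, channel) — each channel's profile is
scaled to [0, 1] on its own value distribution, so heatmaps show shape,
not magnitude; a constant profile normalizes to all zeros (avoiding 0/0).
Raw means are always retained alongside.

Determinism note: the integration direction is canonicalized (smaller node
id first) and the output flipped when the edge is requested in the other
orientation.  Floating-point parameterization of the reversed edge is not
bitwise `1 − t`, so computing both directions independently could disagree
on voxels exactly at bin boundaries; canonicalization makes
`profile(b, a) == reverse(profile(a, b))` hold exactly by construction.

## Profile similarity and ranking

Profiles of different edges are first length-normalized to the reference
edge's bin count by endpoint-anchored linear interpolation (`numpy.interp`
through the input points at parameters j/(n−1); endpoints preserved
exactly; resampling to the same length is the identity).

The default distance between equal-length per-channel profiles is the
pointwise mean p-norm `((1/n) Σ |X_i − Y_i|^p)^(1/p)` with p = 1, computed
per channel and summed over channels.  For p ≥ 1 this is a proper metric
(non-negativity, symmetry, identity, triangle inequality) and absolutely
homogeneous, both property-tested.  It compares profiles *position by
position*; a pattern shifted along the edge reads as distant.  Because
phase-tolerant comparison is sometimes wanted (two synapses at slightly
different depths along their edges), a classical 1D Wasserstein distance
on bin-mass distributions — normalize each profile to unit mass, compare
empirical CDFs by mean absolute difference — is provided behind
`metric="wasserstein1d"`.  The pointwise form is the default because it is
the simpler, stricter statement of "the profiles look the same where they
are"; the choice is exposed, not hidden.

Distances are computed on normalized profiles by default (shape
similarity); `use_normalized=False` compares raw means when magnitude
matters.  Ranking sorts ascending by total distance with lexicographic
edge-key tie-breaks, so results are invariant to candidate input order.

## Polarization

For cell center N, voxels with `inner_radius < |v − N| ≤ r` are projected
onto the viewing plane with unit normal u: q = (v − N) − ⟨v − N, u⟩u.  With
an in-plane unit "north" vector (12 o'clock) and east = north × u, the
angle θ = atan2(⟨q, east⟩, ⟨q, north⟩) mod 360° maps each voxel to sector
⌊θ/30°⌋ of 12.  Defaults: the xy section plane (u = +z) with north = −y,
so 12 o'clock is screen-up under the image convention of y growing
downward, and sectors advance clockwise on screen.  Voxels whose in-plane
projection is numerically zero (|q| < 1e-9 µm — the column through the
center along u) have no defined angle and are excluded rather than
arbitrarily assigned.

Per sector and channel the aggregate is the **mean** by default — sector
voxel counts differ by discretization, and the mean is insensitive to
that — with **sum** available since accumulated intensity is the natural
physical reading (and the sum exactly conserves total in-shell intensity,
which the tests verify).  `normalized` divides by the sector maximum
(all-zero channels stay zero).  `inner_radius` (default 0) can exclude the
nuclear core when membrane polarization is the question.  A view change
recomputes from scratch; sector assignments are never cached across
frames.  The sector statistics are computed per voxel rather than on a
rasterized projection plane; for sum aggregation the two are equivalent,
for mean aggregation the per-voxel form weights each voxel equally rather
than each projected pixel, which is the better-defined quantity on
anisotropic grids.

## Synthetic ground truth

The generator builds volumes from analytic primitives evaluated at voxel
centers in physical units (no rasterization ambiguity), with additive
Gaussian background noise clipped at 0 and a single seeded RNG stream per
volume (bit-identical regeneration from the seed):

* *nuclear*: isotropic Gaussian blob at the center, σ = R/2 for cell
  radius R;
* *membrane*: spherical shell, Gaussian in radial distance with width R/4;
* *interaction*: bicone between two centers, intensity peaking at the
  midpoint;
* *colocalization*: one cell's membrane shell concentrated toward the
  partner (angular factor `exp(4(cos ψ − 1))` on the angle ψ to the
  partner direction) — an immune-synapse-like contact signature;
* *separated*: Gaussian blobs at the two cell centers — markers expressed
  but not engaged, leaving a gap along the edge;
* *polarized*: membrane shell modulated by a von Mises angular density
  (direction θ0, concentration κ, default 4) in the default viewing plane.

Defaults emulate a desk-scale multiplexed stack: 256×256×64 voxels at
(0.22, 0.22, 0.28) µm, ~80 cells of radius 2 µm placed by seeded rejection
sampling with minimum separation 2R.  Planted interaction pairs are placed
first at a prescribed separation (default 2.5R) and the open ball with the
pair's edge as diameter is kept free of other cells, so planted edges
satisfy the Gabriel criterion by construction — the graph stage is then
*tested* on whether it recovers them.  The case-study emulation
(`case_study_fixture`) scales this to 8 channels named after melanoma
CyCIF markers (DNA, SOX10, CD3D, CD8A, PD1, PDL1, CD163, HLAA),
256×256×55 voxels and 20 cells, with one planted PD1–PDL1 co-localized
edge, one separated-centers PD1/PDL1 edge, and one CD8A-polarized cell.

Planted polarization directions are drawn with a 3° margin from sector
boundaries (`sample_identifiable_direction`): a direction on a boundary
splits its angular mass evenly between two sectors, so its "expected
sector" is ill-defined under 30° quantization and voxel discretization —
the generator plants only ground truth that is identifiable at the
measurement's resolution.  Recovery studies use single-cell volumes of
48×48×20 voxels, κ = 4 and SNR 3 (shell amplitude / noise sd); at these
conditions argmax-sector recovery is exact without noise and ≥95/100 with
noise, which the acceptance checks recompute.

What the generator does **not** emulate: optics (no PSF, no axial blur),
real CyCIF noise statistics (autofluorescence, cycle registration error,
antibody background structure), irregular cell shapes, or densely packed
tissue where Gabriel pruning is contested.  Passing tests therefore
demonstrate algorithmic correctness — geometry, integration, metrics,
binning — not robustness to real-world image artifacts; channel thresholds
(`apply_channel_config`) are the provided, deliberately simple noise
control (sub-threshold voxels are zeroed, not background-subtracted, the
simplest monotone choice).

## Problem sizes and numerics

The test and verification workloads use 60-point graphs against an O(n·|E|)
brute-force Gabriel oracle, 32³ two-channel volumes against an all-voxel
profile loop (agreement to 1e-9; observed ~1e-13), 100-trial polarization
recovery studies, and the 256×256×55 case-study emulation end-to-end —
sizes chosen so the full suite runs in well under a minute on one core
while exercising every code path at realistic anisotropy.  Tolerances:
graph and sector comparisons are exact set/integer equality; profile
oracle agreement at 1e-9 absolute; metric axioms at 1e-12; resampling of
linear ramps at 1e-12.  Ties: bin index `min(⌊t·n⌋, n−1)` so t = 1 falls in
the last bin; sector index likewise; ranking ties break lexicographically;
the channel-ordering reference defaults to the channel with the largest
raw profile sum, ties by name.

## Known limitations

* Gabriel pruning is a proximity heuristic: it neither proves contact nor
  signaling; in dense tissue it can drop true contacts whose diameter ball
  happens to contain a third nucleus.
* Min–max normalization makes profiles scale-free per channel, so ranking
  mixes channels of very different dynamic ranges on equal footing; use
  raw distances when absolute intensity matters.
* Mean-aggregated polarization of a channel with near-empty sectors (tiny
  r, or large inner_radius) is noisy; the voxel counts are exported so the
  caller can judge support.
* The pointwise default metric penalizes phase shifts by design; use the
  Wasserstein variant when alignment along the edge should not matter.
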
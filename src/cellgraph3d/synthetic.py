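"""Synthetic multi-channel volumes with known cells, interactions and
polarization directions.

Every analytic stage of the pipeline (graph construction, edge profiles,
ranking, polarization) is testable against ground truth generated here.
Cells are spheres placed by seeded rejection sampling with a minimum
separation of two cell radii; marker channels are built from analytic
intensity primitives evaluated at voxel centers in physical units:

* nuclear marker — isotropic Gaussian blob at the cell center;
* membrane marker — spherical shell (Gaussian in radial distance);
* interaction marker — intensity inside the bicone between two designated
  centers, peaking at the edge midpoint;
* co-localization markers — membrane shells angularly concentrated toward a
  partner cell, emulating e.g. PD1/PDL1 pairing at an immune synapse;
* separated-centers markers — blobs at the two cell centers with a gap in
  between (checkpoint proteins expressed but not engaged);
* polarized marker — membrane shell modulated by a von Mises angular
  density (direction θ0, concentration κ) in the default viewing plane.

Additive Gaussian background noise is clipped at 0.  A fixed seed gives a
bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .polarization import default_frame
from .volume_io import CellCenters, MultiChannelVolume

__all__ = [
    "MarkerSpec",
    "SimConfig",
    "SyntheticTruth",
    "PlantedInteraction",
    "PlantedPolarization",
    "generate_volume",
    "case_study_fixture",
    "sample_identifiable_direction",
    "polarized_cell_volume",
]


def sample_identifiable_direction(
    rng: np.random.Generator, n_sectors: int = 12, margin_deg: float = 3.0
) -> float:
    """Draw a planted polarization direction with an identifiable sector.

    A direction on (or within the voxel-quantization jitter of) a sector
    boundary has no well-defined expected sector — the angular mass splits
    evenly between the two adjacent bins — so planted ground truth keeps a
    small margin from the boundaries.  Returns degrees in [0, 360).
    """
    width = 360.0 / n_sectors
    k = int(rng.integers(0, n_sectors))
    return k * width + float(rng.uniform(margin_deg, width - margin_deg))


def polarized_cell_volume(
    seed: int,
    noise_sd: float = 0.0,
    kappa: float = 4.0,
    amplitude: float = 100.0,
    cell_radius_um: float = 1.5,
) -> tuple["MultiChannelVolume", "SyntheticTruth"]:
    """One randomly placed cell with a planted von Mises polarized marker.

    Small volume (48×48×20 voxels) for repeated-trial recovery studies; the
    planted direction is drawn with :func:`sample_identifiable_direction`.
    The signal-to-noise ratio is ``amplitude / noise_sd``.
    """
    rng = np.random.default_rng(seed)
    theta0 = sample_identifiable_direction(rng)
    cfg = SimConfig(
        dims=(48, 48, 20),
        spacing=(0.22, 0.22, 0.28),
        n_cells=1,
        cell_radius_um=cell_radius_um,
        markers=(
            MarkerSpec("P", "polarized", cells=(0,), theta0_deg=theta0,
                       kappa=kappa, amplitude=amplitude),
        ),
        background=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_volume(cfg)


@dataclass(frozen=True)
class MarkerSpec:
    """One channel's construction recipe.

    kind ∈ {nuclear, membrane, interaction, colocalization, separated,
    polarized}.  ``cells`` selects the node ids carrying the marker (None =
    all cells) for nuclear/membrane/polarized kinds; ``edge`` names the cell
    pair for the interaction kinds.  ``theta0_deg``/``kappa`` set the
    planted polarization direction (angle clockwise from north in the
    default viewing frame) and its von Mises concentration.
    """

    channel: str
    kind: str
    cells: tuple[int, ...] | None = None
    edge: tuple[int, int] | None = None
    amplitude: float = 100.0
    theta0_deg: float = 0.0
    kappa: float = 4.0

    def __post_init__(self) -> None:
        kinds = ("nuclear", "membrane", "interaction", "colocalization",
                 "separated", "polarized")
        if self.kind not in kinds:
            raise ValueError(f"marker kind must be one of {kinds}, got {self.kind!r}")
        if self.kind in ("interaction", "colocalization", "separated") and self.edge is None:
            raise ValueError(f"{self.kind} marker requires an edge=(a, b)")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic volume.

    Defaults emulate a desk-scale multiplexed immunofluorescence stack:
    ~80 spherical cells in a 256×256×64 voxel grid with anisotropic spacing
    (0.22, 0.22, 0.28) µm (sub-micron lateral pixels, coarser sections),
    cell radius 2 µm, moderate additive background noise.
    """

    dims: tuple[int, int, int] = (256, 256, 64)  # (nx, ny, nz)
    spacing: tuple[float, float, float] = (0.22, 0.22, 0.28)
    n_cells: int = 80
    cell_radius_um: float = 2.0
    markers: tuple[MarkerSpec, ...] = ()
    planted_pairs: tuple[tuple[int, int], ...] = ()
    pair_distance_um: float | None = None  # default 2.5 × cell radius
    background: float = 2.0
    noise_sd: float = 2.0
    seed: int = 0
    max_attempts: int = 20000


@dataclass(frozen=True)
class PlantedInteraction:
    edge: tuple[int, int]
    channel: str
    profile_class: str  # midpoint-peak | two-cell-co-localization | separated-centers


@dataclass(frozen=True)
class PlantedPolarization:
    node: int
    channel: str
    theta0_deg: float
    expected_sector: int  # floor(theta0 / 30) under the default frame


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record of everything planted into a synthetic volume."""

    centers: CellCenters
    spacing: tuple[float, float, float]
    planted_interactions: tuple[PlantedInteraction, ...]
    planted_polarizations: tuple[PlantedPolarization, ...]
    background: float
    noise_sd: float
    seed: int

    def planted_edges(self, profile_class: str | None = None) -> set[tuple[int, int]]:
        """Unique planted edges, optionally restricted to one profile class."""
        return {
            pi.edge
            for pi in self.planted_interactions
            if profile_class is None or pi.profile_class == profile_class
        }

    def to_dict(self) -> dict:
        return {
            "centers": [
                {"id": i, "x": p[0], "y": p[1], "z": p[2]}
                for i, p in zip(self.centers.ids, self.centers.positions)
            ],
            "spacing": list(self.spacing),
            "planted_interactions": [
                {"edge": list(pi.edge), "channel": pi.channel, "class": pi.profile_class}
                for pi in self.planted_interactions
            ],
            "planted_polarizations": [
                {"node": pp.node, "channel": pp.channel, "theta0_deg": pp.theta0_deg,
                 "expected_sector": pp.expected_sector}
                for pp in self.planted_polarizations
            ],
            "background": self.background,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Seeded rejection sampling of cell centers (physical µm).

    Planted pairs are placed first at the prescribed separation; the open
    ball with the pair's edge as diameter is kept free of other cells so the
    pair edge survives the Gabriel criterion by construction.  All cells
    keep a minimum mutual separation of two cell radii.
    """
    extent = np.array(cfg.dims, dtype=float) * np.array(cfg.spacing)
    min_sep = 2.0 * cfg.cell_radius_um
    pair_d = cfg.pair_distance_um or 2.5 * cfg.cell_radius_um
    if pair_d < min_sep:
        raise ValueError("pair_distance_um must be at least two cell radii")
    margin = cfg.cell_radius_um  # keep whole cells inside the volume
    lo, hi = margin, extent - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the given cell radius")

    positions: dict[int, np.ndarray] = {}
    # exclusion balls (center, radius) protecting planted Gabriel edges
    exclusions: list[tuple[np.ndarray, float]] = []

    def admissible(p: np.ndarray, ignore: set[int] = frozenset()) -> bool:
        for i, q in positions.items():
            if i in ignore:
                continue
            if np.linalg.norm(p - q) < min_sep:
                return False
        for c, r in exclusions:
            if np.linalg.norm(p - c) < r:
                return False
        return True

    paired = {i for pair in cfg.planted_pairs for i in pair}
    attempts = 0
    for a, b in cfg.planted_pairs:
        while True:
            attempts += 1
            if attempts > cfg.max_attempts:
                raise RuntimeError(
                    "cell placement failed; reduce n_cells or cell radius"
                )
            mid = lo + rng.random(3) * (hi - lo)
            # random orientation, mildly flattened in z like a thin stack
            direction = rng.standard_normal(3)
            direction[2] *= 0.25
            n = np.linalg.norm(direction)
            if n < 1e-9:
                continue
            direction /= n
            pa = mid - 0.5 * pair_d * direction
            pb = mid + 0.5 * pair_d * direction
            if np.any(pa < lo) or np.any(pa > hi) or np.any(pb < lo) or np.any(pb > hi):
                continue
            if admissible(pa) and admissible(pb):
                positions[int(a)] = pa
                positions[int(b)] = pb
                # open diameter ball plus half a cell radius of slack
                exclusions.append((mid, 0.5 * pair_d + 0.5 * cfg.cell_radius_um))
                break

    next_id = 0
    while len(positions) < cfg.n_cells:
        while next_id in positions or next_id in paired:
            next_id += 1
        attempts += 1
        if attempts > cfg.max_attempts:
            raise RuntimeError("cell placement failed; reduce n_cells or cell radius")
        p = lo + rng.random(3) * (hi - lo)
        if admissible(p):
            positions[next_id] = p
            next_id += 1
    return positions


def _local_box(center: np.ndarray, reach: float, dims, spacing):
    """Index ranges and voxel-center coordinates within `reach` of a point."""
    sp = np.asarray(spacing)
    nmax = np.array(dims) - 1
    lo = np.maximum(np.floor((center - reach) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center + reach) / sp).astype(int), nmax)
    xs = np.arange(lo[0], hi[0] + 1)
    ys = np.arange(lo[1], hi[1] + 1)
    zs = np.arange(lo[2], hi[2] + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([gx * sp[0], gy * sp[1], gz * sp[2]], axis=-1)
    return (gz, gy, gx), coords


def _add(channel_arr: np.ndarray, idx, values: np.ndarray) -> None:
    gz, gy, gx = idx
    np.add.at(channel_arr, (gz.ravel(), gy.ravel(), gx.ravel()), values.ravel())


def _segment_box(pa: np.ndarray, pb: np.ndarray, reach: float, dims, spacing):
    sp = np.asarray(spacing)
    nmax = np.array(dims) - 1
    lo = np.maximum(np.floor((np.minimum(pa, pb) - reach) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(pa, pb) + reach) / sp).astype(int), nmax)
    xs = np.arange(lo[0], hi[0] + 1)
    ys = np.arange(lo[1], hi[1] + 1)
    zs = np.arange(lo[2], hi[2] + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([gx * sp[0], gy * sp[1], gz * sp[2]], axis=-1)
    return (gz, gy, gx), coords


def _paint_marker(
    arr: np.ndarray,
    spec: MarkerSpec,
    positions: dict[int, np.ndarray],
    cfg: SimConfig,
) -> None:
    R = cfg.cell_radius_um
    sigma_nuc = R / 2.0
    shell_w = R / 4.0
    dims, sp = cfg.dims, cfg.spacing

    def shell_factor(dist: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((dist - R) / shell_w) ** 2)

    if spec.kind in ("nuclear", "membrane", "polarized"):
        cells = spec.cells if spec.cells is not None else tuple(sorted(positions))
        for cid in cells:
            c = positions[cid]
            reach = 4 * sigma_nuc if spec.kind == "nuclear" else R + 4 * shell_w
            idx, coords = _local_box(c, reach, dims, sp)
            rel = coords - c
            dist = np.linalg.norm(rel, axis=-1)
            if spec.kind == "nuclear":
                vals = spec.amplitude * np.exp(-0.5 * (dist / sigma_nuc) ** 2)
            else:
                vals = spec.amplitude * shell_factor(dist)
                if spec.kind == "polarized":
                    u, north = default_frame()
                    east = np.cross(north, u)
                    q = rel - (rel @ u)[..., None] * u
                    phi = np.arctan2(q @ east, q @ north)
                    theta0 = np.radians(spec.theta0_deg)
                    vals = vals * np.exp(spec.kappa * (np.cos(phi - theta0) - 1.0))
            _add(arr, idx, vals)
        return

    a, b = spec.edge
    pa, pb = positions[int(a)], positions[int(b)]
    if spec.kind == "interaction":
        # bicone between the centers, intensity peaking at the midpoint
        r_max = 0.75 * R
        idx, coords = _segment_box(pa, pb, r_max, dims, sp)
        ab = pb - pa
        L2 = float(ab @ ab)
        t = ((coords - pa) @ ab) / L2
        perp = coords - pa - t[..., None] * ab
        d = np.linalg.norm(perp, axis=-1)
        tri = np.clip(1.0 - np.abs(2.0 * t - 1.0), 0.0, None)
        vals = spec.amplitude * tri * np.exp(-0.5 * (d / (0.5 * r_max)) ** 2)
        vals[(t < 0) | (t > 1)] = 0.0
        _add(arr, idx, vals)
    elif spec.kind == "colocalization":
        # membrane shell of cell a concentrated toward partner b (synapse)
        toward = (pb - pa) / np.linalg.norm(pb - pa)
        idx, coords = _local_box(pa, R + 4 * shell_w, dims, sp)
        rel = coords - pa
        dist = np.linalg.norm(rel, axis=-1)
        with np.errstate(invalid="ignore"):
            cosang = np.where(dist > 1e-9, (rel @ toward) / np.maximum(dist, 1e-9), 1.0)
        vals = spec.amplitude * shell_factor(dist) * np.exp(4.0 * (cosang - 1.0))
        _add(arr, idx, vals)
    elif spec.kind == "separated":
        # blobs at the two centers: expression present, no engagement
        for c in (pa, pb):
            idx, coords = _local_box(c, 4 * sigma_nuc, dims, sp)
            dist = np.linalg.norm(coords - c, axis=-1)
            _add(arr, idx, spec.amplitude * np.exp(-0.5 * (dist / sigma_nuc) ** 2))


def generate_volume(
    config: SimConfig, seed: int | None = None
) -> tuple[MultiChannelVolume, SyntheticTruth]:
    """Build a synthetic volume and its ground truth from a study plan.

    Deterministic for a fixed seed (``seed`` overrides ``config.seed``).
    """
    cfg = config
    used_seed = int(cfg.seed if seed is None else seed)
    rng = np.random.default_rng(used_seed)
    if cfg.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not cfg.markers:
        raise ValueError("at least one MarkerSpec is required")
    # several specs may paint into the same channel (e.g. a checkpoint
    # protein both engaged at one edge and merely expressed elsewhere)
    names = list(dict.fromkeys(m.channel for m in cfg.markers))

    positions = _place_cells(cfg, rng)
    nx, ny, nz = cfg.dims
    arr = np.zeros((len(names), nz, ny, nx), dtype=np.float64)
    for spec in cfg.markers:
        _paint_marker(arr[names.index(spec.channel)], spec, positions, cfg)
    if cfg.background > 0 or cfg.noise_sd > 0:
        noise = cfg.background + cfg.noise_sd * rng.standard_normal(arr.shape)
        arr = np.clip(arr + noise, 0.0, None)

    sp = np.asarray(cfg.spacing)
    ids = tuple(sorted(positions))
    centers = CellCenters(ids, np.array([positions[i] / sp for i in ids]))
    volume = MultiChannelVolume(arr, cfg.spacing, tuple(names))

    interactions = []
    polarizations = []
    for spec in cfg.markers:
        if spec.kind == "interaction":
            interactions.append(
                PlantedInteraction(tuple(sorted(spec.edge)), spec.channel, "midpoint-peak")
            )
        elif spec.kind == "colocalization":
            interactions.append(
                PlantedInteraction(
                    tuple(sorted(spec.edge)), spec.channel, "two-cell-co-localization"
                )
            )
        elif spec.kind == "separated":
            interactions.append(
                PlantedInteraction(tuple(sorted(spec.edge)), spec.channel, "separated-centers")
            )
        elif spec.kind == "polarized":
            for cid in spec.cells or ():
                polarizations.append(
                    PlantedPolarization(
                        int(cid),
                        spec.channel,
                        float(spec.theta0_deg),
                        int(spec.theta0_deg // 30) % 12,
                    )
                )
    truth = SyntheticTruth(
        centers=centers,
        spacing=cfg.spacing,
        planted_interactions=tuple(interactions),
        planted_polarizations=tuple(polarizations),
        background=cfg.background,
        noise_sd=cfg.noise_sd,
        seed=used_seed,
    )
    return volume, truth


CASE_STUDY_CHANNELS = ("DNA", "SOX10", "CD3D", "CD8A", "PD1", "PDL1", "CD163", "HLAA")


def case_study_fixture(seed: int = 0) -> tuple[MultiChannelVolume, SyntheticTruth]:
    """Scaled emulation of a melanoma CyCIF evaluation stack.

    ~20 cells in a 256×256×55 grid, 8 channels named after the case-study
    markers.  Plants one PD1–PDL1 co-localized interaction (edge 0–1, the
    immune-synapse pattern: PD1 on cell 0's membrane facing cell 1, PDL1 on
    cell 1's membrane facing cell 0), one separated-centers PD1/PDL1 edge
    (2–3, checkpoint proteins expressed in the two cell bodies with a gap
    between), and one CD8A-polarized cell (node 0, direction 100° → sector
    3).  DNA stains every nucleus and HLAA every membrane.
    """
    markers = (
        MarkerSpec("DNA", "nuclear", cells=None, amplitude=120.0),
        MarkerSpec("SOX10", "nuclear", cells=(1, 3, 5, 6), amplitude=90.0),
        MarkerSpec("CD3D", "membrane", cells=(0, 2, 7, 8), amplitude=70.0),
        MarkerSpec("CD8A", "polarized", cells=(0,), theta0_deg=100.0, kappa=4.0,
                   amplitude=110.0),
        MarkerSpec("PD1", "colocalization", edge=(0, 1), amplitude=100.0),
        MarkerSpec("PDL1", "colocalization", edge=(1, 0), amplitude=100.0),
        MarkerSpec("PD1", "separated", edge=(2, 3), amplitude=90.0),
        MarkerSpec("PDL1", "separated", edge=(2, 3), amplitude=90.0),
        MarkerSpec("CD163", "membrane", cells=(4, 9), amplitude=80.0),
        MarkerSpec("HLAA", "membrane", cells=None, amplitude=60.0),
    )
    cfg = SimConfig(
        dims=(256, 256, 55),
        spacing=(0.22, 0.22, 0.28),
        n_cells=20,
        cell_radius_um=2.0,
        markers=markers,
        planted_pairs=((0, 1), (2, 3)),
        pair_distance_um=5.0,
        background=2.0,
        noise_sd=2.0,
        seed=seed,
    )
    return generate_volume(cfg)
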
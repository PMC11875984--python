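"""Cell-centric marker polarization: spherical neighborhood, projection onto
a viewing plane, and 12-sector clock-face angular binning per channel.

Membrane markers can be evenly distributed around a cell or concentrated
(polarized) toward a neighbor.  To quantify this, all voxels within radius r
of a cell center are orthogonally projected onto a viewing plane through the
center; each projected voxel falls into one of 12 angular sectors
(30° each, like a clock face), and intensities are aggregated per sector per
channel.  The sector frame is defined by the plane normal u and an in-plane
"north" direction (12 o'clock); sectors advance clockwise when viewed along
−u, matching the screen convention with image y pointing down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import MultiChannelVolume

__all__ = [
    "PolarizationProfile",
    "compute_polarization",
    "recompute_for_view",
    "unroll_heatmap",
    "radial_chart_data",
    "default_frame",
]

# voxels whose in-plane projection is numerically zero have no defined angle
_EPS_IN_PLANE = 1e-9  # micrometers


def _unit(v: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} vector must be nonzero")
    return v / n


def default_frame(plane_normal: Sequence[float] | None = None,
                  north: Sequence[float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Canonical viewing frame.

    Defaults to the xy section plane (normal +z) with north = −y, so
    "12 o'clock" is screen-up under the image convention of y growing
    downward.  A given north is projected into the plane and normalized.
    """
    u = _unit(plane_normal if plane_normal is not None else (0.0, 0.0, 1.0), "plane_normal")
    if north is None:
        cand = np.array([0.0, -1.0, 0.0])
        if abs(float(cand @ u)) > 1.0 - 1e-9:
            cand = np.array([1.0, 0.0, 0.0])
    else:
        cand = np.asarray(north, dtype=float)
    in_plane = cand - (cand @ u) * u
    if np.linalg.norm(in_plane) < 1e-12:
        raise ValueError("north is (numerically) parallel to the plane normal")
    return u, in_plane / np.linalg.norm(in_plane)


@dataclass(frozen=True)
class PolarizationProfile:
    """Per-cell, per-channel 12-sector angular intensity vector.

    ``sector_value`` holds the per-sector aggregate (mean by default, sum
    optionally), ``sector_count`` the voxels per sector, and ``normalized``
    the sector values divided by their maximum (all 0 for an all-zero
    channel).  Sector k covers angles [k·30°, (k+1)·30°) clockwise from
    north when viewed along −plane_normal.
    """

    node_id: int
    radius: float  # micrometers
    inner_radius: float
    plane_normal: np.ndarray
    north: np.ndarray
    aggregator: str
    channel_names: tuple[str, ...]
    sector_value: dict[str, np.ndarray]
    sector_count: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    n_sectors: int = 12

    def argmax_sector(self, channel: str) -> int:
        return int(np.argmax(self.sector_value[channel]))

    def to_dict(self) -> dict:
        return {
            "kind": "polarization_profile",
            "node_id": self.node_id,
            "radius": self.radius,
            "inner_radius": self.inner_radius,
            "plane_normal": list(self.plane_normal),
            "north": list(self.north),
            "aggregator": self.aggregator,
            "n_sectors": self.n_sectors,
            "sectors": {
                ch: {
                    "value": list(self.sector_value[ch]),
                    "count": [int(c) for c in self.sector_count[ch]],
                    "normalized": list(self.normalized[ch]),
                }
                for ch in self.channel_names
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolarizationProfile":
        sec = d["sectors"]
        names = tuple(sec)
        return cls(
            node_id=int(d["node_id"]),
            radius=float(d["radius"]),
            inner_radius=float(d["inner_radius"]),
            plane_normal=np.array(d["plane_normal"], dtype=float),
            north=np.array(d["north"], dtype=float),
            aggregator=d["aggregator"],
            n_sectors=int(d["n_sectors"]),
            channel_names=names,
            sector_value={c: np.array(sec[c]["value"], dtype=float) for c in names},
            sector_count={c: np.array(sec[c]["count"], dtype=int) for c in names},
            normalized={c: np.array(sec[c]["normalized"], dtype=float) for c in names},
        )


def compute_polarization(
    volume: MultiChannelVolume,
    center_um: Sequence[float],
    radius_um: float,
    plane_normal: Sequence[float] | None = None,
    north: Sequence[float] | None = None,
    channels: Sequence[str] | None = None,
    inner_radius_um: float = 0.0,
    aggregator: str = "mean",
    n_sectors: int = 12,
    node_id: int = -1,
) -> PolarizationProfile:
    """Aggregate marker intensity into angular sectors around one cell.

    Voxels with inner_radius < |v − N| ≤ r (physical units) are projected
    onto the viewing plane; the angle θ = atan2(⟨q, east⟩, ⟨q, north⟩) with
    east = north × u maps each voxel to sector ⌊θ/30°⌋.  Per sector and
    channel the intensities are aggregated by mean (default, robust to the
    uneven voxel counts discretization produces) or sum (exact intensity
    accumulation); ``normalized`` divides by the sector maximum.

    Raises if the center is outside the volume or no voxel qualifies.
    """
    if aggregator not in ("mean", "sum"):
        raise ValueError(f"aggregator must be 'mean' or 'sum', got {aggregator!r}")
    if not (radius_um > inner_radius_um >= 0):
        raise ValueError("need radius > inner_radius >= 0")
    center = np.asarray(center_um, dtype=float)
    sp = np.asarray(volume.spacing)
    nx, ny, nz = volume.dims
    extent = np.array([nx, ny, nz]) * sp
    if np.any(center < 0) or np.any(center >= extent):
        raise ValueError(f"node center {tuple(center)} outside volume extent {tuple(extent)}")
    u, nrt = default_frame(plane_normal, north)
    east = np.cross(nrt, u)
    if channels is None:
        channels = volume.channel_names
    else:
        channels = tuple(channels)
        for c in channels:
            volume.channel_index(c)

    lo = center - radius_um
    hi = center + radius_um
    from .interaction import _voxel_grid_in_box

    coords, (iz, iy, ix) = _voxel_grid_in_box(volume, lo, hi)
    if coords.shape[0] == 0:
        raise ValueError("empty neighborhood: radius too small for this voxel grid")
    rel = coords - center
    dist = np.linalg.norm(rel, axis=1)
    keep = (dist > inner_radius_um) & (dist <= radius_um)
    rel = rel[keep]
    iz, iy, ix = iz[keep], iy[keep], ix[keep]
    if rel.shape[0] == 0:
        raise ValueError("empty neighborhood: no voxel inside the spherical shell")
    q = rel - (rel @ u)[:, None] * u
    qn = np.linalg.norm(q, axis=1)
    ok = qn >= _EPS_IN_PLANE
    q, iz, iy, ix = q[ok], iz[ok], iy[ok], ix[ok]
    theta = np.degrees(np.arctan2(q @ east, q @ nrt))
    theta = np.mod(theta, 360.0)
    sector = np.minimum((theta / (360.0 / n_sectors)).astype(int), n_sectors - 1)

    counts = np.bincount(sector, minlength=n_sectors).astype(int)
    sector_value: dict[str, np.ndarray] = {}
    sector_count: dict[str, np.ndarray] = {}
    normalized: dict[str, np.ndarray] = {}
    for ch in channels:
        vals = volume.channel(ch)[iz, iy, ix]
        sums = np.bincount(sector, weights=vals, minlength=n_sectors)
        if aggregator == "mean":
            val = np.zeros(n_sectors)
            nzc = counts > 0
            val[nzc] = sums[nzc] / counts[nzc]
        else:
            val = sums
        mx = float(val.max())
        normalized[ch] = val / mx if mx > 0 else np.zeros(n_sectors)
        sector_value[ch] = val
        sector_count[ch] = counts.copy()
    return PolarizationProfile(
        node_id=int(node_id),
        radius=float(radius_um),
        inner_radius=float(inner_radius_um),
        plane_normal=u,
        north=nrt,
        aggregator=aggregator,
        channel_names=tuple(channels),
        sector_value=sector_value,
        sector_count=sector_count,
        normalized=normalized,
        n_sectors=n_sectors,
    )


def recompute_for_view(
    volume: MultiChannelVolume,
    profile: PolarizationProfile,
    center_um: Sequence[float],
    new_plane_normal: Sequence[float],
    new_north: Sequence[float] | None = None,
) -> PolarizationProfile:
    """Recompute a profile for a new viewing-plane orientation.

    Sector assignments depend on the frame, so nothing is cached: the full
    computation reruns with the stored radius, channels and aggregator.
    """
    return compute_polarization(
        volume,
        center_um,
        profile.radius,
        plane_normal=new_plane_normal,
        north=new_north,
        channels=profile.channel_names,
        inner_radius_um=profile.inner_radius,
        aggregator=profile.aggregator,
        n_sectors=profile.n_sectors,
        node_id=profile.node_id,
    )


def unroll_heatmap(
    profiles: Sequence[PolarizationProfile], channels: Sequence[str] | None = None
) -> dict[int, tuple[np.ndarray, list[str]]]:
    """Unroll each cell's clock-face rings into a channels×12 matrix.

    Column j is sector j (12 o'clock + j·30° clockwise); rows are labeled by
    channel name; values are the normalized sector intensities.
    """
    out: dict[int, tuple[np.ndarray, list[str]]] = {}
    for p in profiles:
        chans = tuple(channels) if channels is not None else p.channel_names
        for c in chans:
            if c not in p.channel_names:
                raise KeyError(f"channel {c!r} missing from profile of node {p.node_id}")
        out[p.node_id] = (np.stack([p.normalized[c] for c in chans]), list(chans))
    return out


def radial_chart_data(
    profile: PolarizationProfile,
    channels_ordered: Sequence[str],
    max_segment_width: float = 1.0,
) -> list[dict]:
    """Ring specification for a radial (clock-face) polarization chart.

    Rings follow the given channel order inner→outer; each ring carries 12
    segment widths proportional to the normalized sector values (0 to
    ``max_segment_width``).  Pure data structure; rendering is left to the
    caller or :mod:`cellgraph3d.plotting`.
    """
    if not channels_ordered:
        raise ValueError("channel list is empty")
    rings = []
    for ring_index, ch in enumerate(channels_ordered):
        if ch not in profile.channel_names:
            raise KeyError(f"unknown channel {ch!r}")
        rings.append(
            {
                "channel": ch,
                "ring_index": ring_index,
                "segment_widths": (profile.normalized[ch] * max_segment_width).tolist(),
            }
        )
    return rings
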
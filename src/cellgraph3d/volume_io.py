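"""Reading and writing volumes, cell-center tables, channel configs and results.

Volumes are multi-channel 3D intensity arrays stored axis-ordered
``(channel, z, y, x)`` together with a physical voxel spacing ``(x, y, z)``
in micrometers.  Cell centers live in voxel coordinates (0-based, possibly
fractional: a center (x, y, z) refers to the center of voxel (x, y, z));
every geometric computation downstream works in physical units, i.e.
``voxel index * spacing``, because multiplexed imaging stacks are strongly
anisotropic (sub-micron lateral pixels vs. micron-scale sections).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "MultiChannelVolume",
    "CellCenters",
    "ChannelConfig",
    "load_volume",
    "write_volume",
    "load_centers",
    "write_centers",
    "load_channel_config",
    "apply_channel_config",
    "export_results",
    "import_results",
]


@dataclass(frozen=True)
class MultiChannelVolume:
    """A channel-indexed 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (n_channels, nz, ny, nx)
        Non-negative intensities.
    spacing : tuple of float
        Physical size of one voxel along (x, y, z), micrometers, all > 0.
    channel_names : tuple of str
        One unique name per channel.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise ValueError(
                f"intensities must be 4-D (channel, z, y, x); got ndim={arr.ndim}"
            )
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values (x, y, z); got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        names = tuple(str(n) for n in self.channel_names)
        if len(names) != arr.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {arr.shape[0]} channels"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel_names contains duplicates")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        """Spatial extent as (nx, ny, nz) voxels."""
        nc, nz, ny, nx = self.intensities.shape
        return (nx, ny, nz)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {list(self.channel_names)}") from None

    def channel(self, name: str) -> np.ndarray:
        """The (z, y, x) array of one channel."""
        return self.intensities[self.channel_index(name)]


@dataclass(frozen=True)
class CellCenters:
    """Labeled cell centers in voxel coordinates.

    ``ids`` are unique integers; ``positions`` is an (n, 3) float array of
    (x, y, z) voxel coordinates, fractional values permitted.
    """

    ids: tuple[int, ...]
    positions: np.ndarray  # (n, 3) voxel coords, columns x, y, z

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node ids: {dupes}")
        object.__setattr__(self, "ids", ids)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(ids), 3):
            raise ValueError(f"positions shape {pos.shape} != ({len(ids)}, 3)")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.ids)

    def position_of(self, node_id: int) -> np.ndarray:
        return self.positions[self.ids.index(int(node_id))]

    def physical_positions(self, spacing: Sequence[float]) -> dict[int, np.ndarray]:
        """Map node id -> (x, y, z) position in micrometers."""
        sp = np.asarray(spacing, dtype=float)
        return {i: self.positions[k] * sp for k, i in enumerate(self.ids)}

    def validate_bounds(self, dims: Sequence[int]) -> None:
        """Raise if any center lies outside [0, dim) on some axis."""
        dims = np.asarray(dims, dtype=float)
        bad = np.where(np.any((self.positions < 0) | (self.positions >= dims), axis=1))[0]
        if bad.size:
            rows = ", ".join(
                f"id {self.ids[k]} at {tuple(self.positions[k])}" for k in bad
            )
            raise ValueError(f"cell centers outside volume bounds {tuple(int(d) for d in dims)}: {rows}")


@dataclass
class ChannelSettings:
    threshold: float = 0.0
    value_range: tuple[float, float] | None = None
    active: bool = True

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.value_range is not None:
            lo, hi = self.value_range
            if lo > hi:
                raise ValueError(f"value_range min {lo} > max {hi}")
            if self.threshold > hi:
                raise ValueError(f"threshold {self.threshold} exceeds range max {hi}")


@dataclass
class ChannelConfig:
    """Per-channel noise-suppression settings (threshold, clamp range, active)."""

    channels: dict[str, ChannelSettings] = field(default_factory=dict)

    def settings(self, name: str) -> ChannelSettings:
        return self.channels.get(name, ChannelSettings())

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ChannelConfig":
        channels = {}
        for name, raw in (mapping.get("channels", mapping) or {}).items():
            raw = raw or {}
            rng = raw.get("range", raw.get("value_range"))
            channels[str(name)] = ChannelSettings(
                threshold=float(raw.get("threshold", 0.0)),
                value_range=tuple(float(v) for v in rng) if rng is not None else None,
                active=bool(raw.get("active", True)),
            )
        return cls(channels)


def load_channel_config(path: str | Path) -> ChannelConfig:
    """Read a YAML or JSON channel configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ChannelConfig.from_mapping(data or {})


def _normalize_axes(arr: np.ndarray, axes: str | None) -> np.ndarray:
    """Coerce a TIFF array to (channel, z, y, x)."""
    if arr.ndim == 2:
        arr = arr[None, None]  # single channel, single section
    elif arr.ndim == 3:
        if axes and "C" in axes and "Z" not in axes:
            arr = arr[:, None]  # (C, Y, X)
        else:
            arr = arr[None]  # (Z, Y, X), single channel
    elif arr.ndim == 4:
        if axes == "ZCYX":
            arr = np.moveaxis(arr, 1, 0)
        # default: assume (C, Z, Y, X)
    else:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} dimensions")
    return arr


def load_volume(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> MultiChannelVolume:
    """Load an OME-TIFF / multi-page TIFF as a :class:`MultiChannelVolume`.

    Spacing is taken from OME metadata (PhysicalSizeX/Y/Z) when present,
    otherwise ``spacing_override`` is required.  Channel names come from OME
    metadata or default to ``C0..Cn-1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        meta_names: list[str] | None = None
        spacing = None
        if tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                pixels = root.find(".//ome:Pixels", ns)
                if pixels is not None:
                    sx = pixels.get("PhysicalSizeX")
                    sy = pixels.get("PhysicalSizeY")
                    sz = pixels.get("PhysicalSizeZ")
                    if sx and sy and sz:
                        spacing = (float(sx), float(sy), float(sz))
                    chans = pixels.findall("ome:Channel", ns)
                    names = [c.get("Name") for c in chans]
                    if names and all(names):
                        meta_names = [str(n) for n in names]
            except Exception:
                pass
    arr = _normalize_axes(np.asarray(arr), axes)
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing_override=(sx, sy, sz) in micrometers"
        )
    if channel_names is None:
        channel_names = meta_names if meta_names and len(meta_names) == arr.shape[0] else [
            f"C{i}" for i in range(arr.shape[0])
        ]
    return MultiChannelVolume(arr, spacing, tuple(channel_names))


def write_volume(volume: MultiChannelVolume, path: str | Path) -> None:
    """Write a volume as OME-TIFF, embedding spacing and channel names."""
    sx, sy, sz = volume.spacing
    tifffile.imwrite(
        str(path),
        volume.intensities[:, :, :, :].transpose(1, 0, 2, 3),  # ZCYX for OME
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeY": sy,
            "PhysicalSizeZ": sz,
            "Channel": {"Name": list(volume.channel_names)},
        },
    )


def load_centers(
    path: str | Path,
    coordinate_unit: str = "voxel",
    spacing: Sequence[float] | None = None,
    dims: Sequence[int] | None = None,
) -> CellCenters:
    """Read a cell-center table (CSV with columns id, x, y, z).

    ``coordinate_unit`` is ``"voxel"`` or ``"micrometer"``; micrometer input
    is converted to voxel coordinates by per-axis division by ``spacing``.
    When ``dims`` (nx, ny, nz) is given, out-of-bounds centers are rejected.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"centers CSV missing columns: {sorted(missing)}")
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    if coordinate_unit == "micrometer":
        if spacing is None:
            raise ValueError("spacing required to convert micrometer coordinates")
        pos = pos / np.asarray(spacing, dtype=float)
    elif coordinate_unit != "voxel":
        raise ValueError(f"coordinate_unit must be 'voxel' or 'micrometer', got {coordinate_unit!r}")
    centers = CellCenters(tuple(int(i) for i in df["id"]), pos)
    if dims is not None:
        centers.validate_bounds(dims)
    return centers


def write_centers(centers: CellCenters, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": centers.ids,
            "x": centers.positions[:, 0],
            "y": centers.positions[:, 1],
            "z": centers.positions[:, 2],
        }
    ).to_csv(path, index=False)


def apply_channel_config(volume: MultiChannelVolume, config: ChannelConfig) -> MultiChannelVolume:
    """Suppress noise per channel: zero sub-threshold voxels, clamp to range.

    Returns a new volume; the input is unmodified.  Idempotent for a fixed
    config.  Channels not mentioned in the config pass through unchanged.
    """
    unknown = set(config.channels) - set(volume.channel_names)
    if unknown:
        raise KeyError(f"config references unknown channels: {sorted(unknown)}")
    out = volume.intensities.astype(float, copy=True)
    for name, settings in config.channels.items():
        k = volume.channel_index(name)
        ch = out[k]
        ch[ch < settings.threshold] = 0.0
        if settings.value_range is not None:
            lo, hi = settings.value_range
            np.clip(ch, None, hi, out=ch)
            ch[(ch < lo) & (ch > 0)] = lo
            # values zeroed by the threshold stay zero
    return MultiChannelVolume(out, volume.spacing, volume.channel_names)


# ---------------------------------------------------------------------------
# Result export / import


def _profile_frame(profile) -> pd.DataFrame:
    rows = []
    a, b = profile.edge
    edge_id = f"{a}-{b}"
    for ch in profile.channel_names:
        mean = profile.mean_intensity[ch]
        nvox = profile.n_voxels[ch]
        norm = profile.normalized_intensity[ch]
        for j in range(profile.n_bins):
            rows.append(
                (edge_id, ch, j, profile.bin_positions[j], mean[j], int(nvox[j]), norm[j])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "edge_id",
            "channel",
            "bin_index",
            "position_um",
            "mean_intensity",
            "n_voxels",
            "normalized_intensity",
        ],
    )


def export_results(obj, path: str | Path, format: str = "csv") -> None:
    """Export an InteractionProfile, PolarizationProfile or RankingResult.

    CSV preserves numeric content to ~1e-12 (17 significant digits printed);
    JSON round-trips floats bit-exactly via repr.
    """
    from .interaction import InteractionProfile
    from .polarization import PolarizationProfile
    from .similarity import RankingResult

    path = Path(path)
    if isinstance(obj, InteractionProfile):
        if format == "csv":
            _profile_frame(obj).to_csv(path, index=False, float_format="%.17g")
        else:
            path.write_text(json.dumps(obj.to_dict(), indent=1))
    elif isinstance(obj, PolarizationProfile):
        if format == "csv":
            rows = []
            for ch in obj.channel_names:
                for k in range(obj.n_sectors):
                    rows.append(
                        (obj.node_id, ch, k, obj.sector_value[ch][k],
                         int(obj.sector_count[ch][k]), obj.normalized[ch][k])
                    )
            pd.DataFrame(
                rows,
                columns=["node_id", "channel", "sector", "value", "n_voxels", "normalized"],
            ).to_csv(path, index=False, float_format="%.17g")
        else:
            path.write_text(json.dumps(obj.to_dict(), indent=1))
    elif isinstance(obj, RankingResult):
        if format == "csv":
            rows = []
            for entry in obj.entries:
                e = f"{entry.edge[0]}-{entry.edge[1]}"
                for ch, d in sorted(entry.per_channel.items()):
                    rows.append((e, entry.total, ch, d))
            pd.DataFrame(
                rows, columns=["edge", "total_distance", "channel", "channel_distance"]
            ).to_csv(path, index=False, float_format="%.17g")
        else:
            path.write_text(json.dumps(obj.to_dict(), indent=1))
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")


def import_results(path: str | Path):
    """Re-import a JSON export produced by :func:`export_results`."""
    from .interaction import InteractionProfile
    from .polarization import PolarizationProfile
    from .similarity import RankingResult

    data = json.loads(Path(path).read_text())
    kind = data.get("kind")
    if kind == "interaction_profile":
        return InteractionProfile.from_dict(data)
    if kind == "polarization_profile":
        return PolarizationProfile.from_dict(data)
    if kind == "ranking":
        return RankingResult.from_dict(data)
    raise ValueError(f"unrecognized result file kind: {kind!r}")
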
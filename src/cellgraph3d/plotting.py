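"""Static renderings of profile heatmaps, line charts and polarization
charts.  Presentation-only: all numbers come from the analysis modules."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interaction import InteractionProfile
from .polarization import PolarizationProfile

__all__ = [
    "plot_profile_heatmap",
    "plot_profile_lines",
    "plot_polarization_heatmap",
    "plot_radial_chart",
]


def plot_profile_heatmap(
    profile: InteractionProfile,
    path: str | Path,
    channel_order: Sequence[str] | None = None,
) -> None:
    """Channels × bins heatmap of normalized intensities for one edge."""
    chans = list(channel_order or profile.channel_names)
    m = np.stack([profile.normalized_intensity[c] for c in chans])
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(chans) + 1.5))
    im = ax.imshow(m, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(chans)), chans)
    ax.set_xlabel("position along edge (bins)")
    ax.set_title(f"edge {profile.edge[0]}-{profile.edge[1]} ({profile.shape.kind})")
    fig.colorbar(im, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile_lines(
    profile: InteractionProfile,
    path: str | Path,
    channels: Sequence[str] | None = None,
    normalized: bool = True,
) -> None:
    """Line chart of per-channel intensity along one edge."""
    chans = list(channels or profile.channel_names)
    fig, ax = plt.subplots(figsize=(8, 4))
    for c in chans:
        y = profile.normalized_intensity[c] if normalized else profile.mean_intensity[c]
        ax.plot(profile.bin_positions, y, label=c)
    ax.set_xlabel("distance from first node (µm)")
    ax.set_ylabel("normalized intensity" if normalized else "mean intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_polarization_heatmap(profile: PolarizationProfile, path: str | Path) -> None:
    """Unrolled clock-face heatmap: channels × 12 sectors for one cell."""
    m = np.stack([profile.normalized[c] for c in profile.channel_names])
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(profile.channel_names) + 1.5))
    im = ax.imshow(m, aspect="auto", cmap="magma", vmin=0, vmax=1)
    ax.set_yticks(range(len(profile.channel_names)), profile.channel_names)
    ax.set_xticks(range(profile.n_sectors))
    ax.set_xlabel("sector (clockwise from 12 o'clock)")
    ax.set_title(f"node {profile.node_id}")
    fig.colorbar(im, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_radial_chart(
    profile: PolarizationProfile,
    path: str | Path,
    channels: Sequence[str] | None = None,
) -> None:
    """Clock-face chart: one concentric ring of 12 segments per channel."""
    chans = list(channels or profile.channel_names[:4])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # clockwise, matching the sector convention
    width = np.radians(30)
    angles = np.radians(np.arange(12) * 30) + width / 2
    for ring, c in enumerate(chans):
        vals = profile.normalized[c]
        ax.bar(angles, vals * 0.9, width=width * 0.95, bottom=ring + 0.1,
               label=c, alpha=0.8)
    ax.set_yticks([])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    ax.set_title(f"node {profile.node_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
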
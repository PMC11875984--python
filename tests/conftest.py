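import numpy as np
import pytest

import cellgraph3d as cg


@pytest.fixture(scope="session")
def case_study():
    """Scaled case-study emulation volume plus truth, computed once."""
    return cg.case_study_fixture(seed=11)


@pytest.fixture(scope="session")
def case_study_graph(case_study):
    vol, truth = case_study
    return cg.build_graph(truth.centers, vol.spacing)


@pytest.fixture()
def small_volume():
    """Deterministic noise-free two-channel test volume (16³)."""
    rng = np.random.default_rng(42)
    arr = rng.random((2, 16, 16, 16)) * 10
    return cg.MultiChannelVolume(arr, (0.5, 0.5, 1.0), ("A", "B"))


def two_node_graph(pa, pb):
    """Graph with exactly one edge between two physical positions (µm)."""
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    return cg.CellGraph(
        nodes={0: pa, 1: pb},
        edges=frozenset({(0, 1)}),
        edge_flags={(0, 1): frozenset({"delaunay", "gabriel"})},
    )


def naive_profile(volume, a_um, b_um, shape_kind, radius_um, n_bins, channel):
    """Brute-force profile oracle: plain python loop over every voxel.

    Independent of the vectorized path: no bounding box, scalar arithmetic
    only.  Returns (mean_per_bin, count_per_bin) for bins ordered a->b.
    """
    import math

    sx, sy, sz = volume.spacing
    ax, ay, az = (float(v) for v in a_um)
    bx, by, bz = (float(v) for v in b_um)
    ex, ey, ez = bx - ax, by - ay, bz - az
    L2 = ex * ex + ey * ey + ez * ez
    data = volume.channel(channel)
    nx, ny, nz = volume.dims
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                vx, vy, vz = ix * sx, iy * sy, iz * sz
                rx, ry, rz = vx - ax, vy - ay, vz - az
                t = (rx * ex + ry * ey + rz * ez) / L2
                if t < 0.0 or t > 1.0:
                    continue
                px, py, pz = rx - t * ex, ry - t * ey, rz - t * ez
                d = math.sqrt(px * px + py * py + pz * pz)
                allowed = radius_um if shape_kind == "cylinder" else radius_um * (
                    1.0 - abs(2.0 * t - 1.0)
                )
                if d > allowed:
                    continue
                k = min(int(t * n_bins), n_bins - 1)
                sums[k] += float(data[iz, iy, ix])
                counts[k] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    return np.array(means), np.array(counts)
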
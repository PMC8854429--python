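import numpy as np
import pytest

from tsatract.io import VoxelGrid
from tsatract.phantom import PhantomSpec, make_probability_pairs, straight_curve
from tsatract.tract import estimate_tract
from tsatract.pipeline import fibonacci_sphere
from tsatract.io import GradientTable


def dist_to_polyline(point, poly):
    """Minimum distance from a point to a polyline (point-to-segment)."""
    point = np.asarray(point, float)
    poly = np.asarray(poly, float)
    best = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip((point - a) @ ab / (ab @ ab), 0.0, 1.0)
        best = min(best, np.linalg.norm(point - (a + t * ab)))
    return best


@pytest.fixture(scope="session")
def grid32():
    return VoxelGrid.isotropic((32, 32, 32), 2.0)


@pytest.fixture(scope="session")
def straight_spec(grid32):
    mid = 31.0  # mm centre of the 32-voxel, 2 mm axis
    return PhantomSpec(
        grid32,
        straight_curve([8.0, mid, mid], [54.0, mid, mid]),
        tube_sigma=4.0,
        roi_radius=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def straight_phantom(straight_spec):
    """(pairs, orientation, roi_a, roi_b) for a 10-participant straight tube."""
    return make_probability_pairs(straight_spec, 10)


@pytest.fixture(scope="session")
def straight_estimate(straight_phantom):
    pairs, orient, roi_a, roi_b = straight_phantom
    est = estimate_tract(pairs, roi_a, roi_b)
    assert est.accepted
    return est


@pytest.fixture(scope="session")
def gtab64():
    return GradientTable(fibonacci_sphere(64), 1500.0)


def bfs_oracle(members, seeds, connectivity):
    """Plain breadth-first shortest-path labelling on the explicit voxel graph."""
    from collections import deque
    import numpy as _np

    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    dist = {}
    q = deque()
    member_set = {tuple(v) for v in _np.argwhere(members)}
    for s_ in seeds:
        dist[tuple(s_)] = 0
        q.append(tuple(s_))
    while q:
        u = q.popleft()
        for off in offsets:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if v in member_set and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist
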
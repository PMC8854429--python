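"""Core tract-trajectory estimation from probabilistic-tractography maps.

Given directed streamline visitation maps between two grey-matter ROIs, this
module reduces them to a single accepted core trajectory and a final tract
probability map, or rejects the ROI pair:

1. directed counts are normalised by the number of target-reaching
   streamlines, the per-voxel minimum over the two seeding directions is
   averaged over participants, smoothed and rescaled to [0, 1] (``P_ab``);
2. ``P_ab`` is thresholded at ``alpha`` (ROIs dilated to preserve their
   connection) and flood-filled into integer distance strata from the seed;
3. a polyline follows the per-distance maximal-probability voxel, subject to
   a 4 mm segment-length and a pi/3 turning-angle constraint, terminating at
   the target (accepted) or when distances are exhausted (rejected);
4. an anisotropic Gaussian uncertainty field oriented along the polyline is
   multiplied into ``P_ab`` and renormalised within each distance stratum,
   yielding the tract probability ``P_ab-tract``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import ROIMask, ScalarVolume, VoxelGrid, _check_same_grid

__all__ = [
    "DistanceMap",
    "CoreTrajectory",
    "TractEstimate",
    "normalize_directed",
    "bidirectional_population_average",
    "threshold_with_dilated_rois",
    "flood_fill_distances",
    "build_core_polyline",
    "vertex_orientations",
    "uncertainty_field",
    "tract_probability",
    "estimate_tract",
    "dilate_mask",
    "fwhm_to_sigma",
]

# defaults as used throughout: 2 mm isotropic grids, alpha = 0.07, 3-voxel ROI
# dilation, 4 mm segments, pi/3 turns, sigma_a = 10 mm, sigma_r = 4 mm, 8 mm radius
DEFAULT_ALPHA = 0.07
DEFAULT_DILATION = 3
DEFAULT_MAX_SEGMENT = 4.0
DEFAULT_MAX_ANGLE = np.pi / 3
DEFAULT_SIGMA_AXIAL = 10.0
DEFAULT_SIGMA_RADIAL = 4.0
DEFAULT_RADIUS = 8.0
DEFAULT_SMOOTH_FWHM = 2.0  # population-average smoothing; one voxel on a 2 mm grid
# Flood-fill strata default to full 26-connectivity: with face-only neighbours
# the walk along obliquely oriented tubes alternates orthogonal lattice steps,
# which the pi/3 turning-angle constraint forbids, and the polyline drifts.
DEFAULT_CONNECTIVITY = 26


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


@dataclasses.dataclass
class DistanceMap:
    """Integer flood-fill distance per voxel; 0 marks unassigned voxels."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.dims:
            raise ValueError("labels shape does not match grid dims")

    @property
    def max_distance(self) -> int:
        return int(self.labels.max())

    def stratum(self, d: int) -> np.ndarray:
        return self.labels == d


@dataclasses.dataclass
class CoreTrajectory:
    """Ordered polyline of per-distance maximal-probability voxel centres."""

    vertices: np.ndarray  # (V, 3) world mm
    orientations: np.ndarray  # (V, 3) unit omega_v
    flags: list  # indices of vertices appended despite constraint violation
    status: str  # "accepted" | "rejected"

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "vertices_mm": np.asarray(self.vertices).tolist(),
            "orientations": np.asarray(self.orientations).tolist(),
            "flags": list(self.flags),
            "status": self.status,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CoreTrajectory":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["vertices_mm"], float),
            np.asarray(d["orientations"], float),
            list(d["flags"]),
            d["status"],
        )


@dataclasses.dataclass
class TractEstimate:
    """Everything the trajectory stage produces for one ROI pair."""

    p_ab: ScalarVolume
    members: np.ndarray  # boolean T_ab
    distance_map: DistanceMap
    trajectory: CoreTrajectory
    phi: ScalarVolume | None
    p_tract: ScalarVolume | None

    @property
    def accepted(self) -> bool:
        return self.trajectory.accepted


def normalize_directed(counts: ScalarVolume, total_to_target: int):
    """Directed visitation counts -> probabilities, by dividing by the number
    of streamlines that reached the target from the seed.

    Way-point voxels can be visited by more streamlines than reach the
    target; such ratios are clipped to 1 to keep the probability contract
    (clipping is order-preserving for every downstream min/mean/max).
    Returns ``(volume, connectable)``; a zero total yields an all-zero map
    flagged unconnectable.
    """
    if total_to_target < 0:
        raise ValueError("total_to_target must be non-negative")
    if total_to_target == 0:
        return counts.copy_with(np.zeros(counts.grid.dims)), False
    return counts.copy_with(np.clip(counts.data / total_to_target, 0.0, 1.0)), True


def bidirectional_population_average(
    per_participant_pairs,
    smoothing_fwhm: float = DEFAULT_SMOOTH_FWHM,
) -> ScalarVolume:
    """Population tract probability P_ab.

    Per participant, the voxel-wise minimum over the two seeding directions
    suppresses direction asymmetry; minima are averaged over participants,
    Gaussian-smoothed at ``smoothing_fwhm`` (mm), and divided by the global
    maximum so the output spans [0, 1] (an all-zero field stays zero).
    """
    if not per_participant_pairs:
        raise ValueError("need at least one participant")
    grid = per_participant_pairs[0][0].grid
    for a, b in per_participant_pairs:
        _check_same_grid(grid, a.grid, b.grid)
    acc = np.zeros(grid.dims)
    for a, b in per_participant_pairs:
        acc += np.minimum(a.data, b.data)
    acc /= len(per_participant_pairs)
    if smoothing_fwhm > 0:
        sigma_vox = fwhm_to_sigma(smoothing_fwhm) / grid.voxel_size
        acc = ndimage.gaussian_filter(acc, sigma=sigma_vox)
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    return ScalarVolume(grid, acc)


def dilate_mask(mask: np.ndarray, iterations: int, connectivity: int = 26) -> np.ndarray:
    if iterations <= 0:
        return np.asarray(mask, bool)
    return ndimage.binary_dilation(
        mask, structure=_structure(connectivity), iterations=iterations
    )


def threshold_with_dilated_rois(
    p_ab: ScalarVolume,
    roi_a: ROIMask,
    roi_b: ROIMask,
    alpha: float = DEFAULT_ALPHA,
    dilation_voxels: int = DEFAULT_DILATION,
    dilation_connectivity: int = 26,
) -> np.ndarray:
    """Member set T_ab: voxels with P_ab >= alpha, unioned with both ROIs
    dilated by ``dilation_voxels`` iterations (probability near the ROIs is
    systematically lower than along the tract body, so dilation keeps the
    endpoints attached to the thresholded corridor)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    _check_same_grid(p_ab.grid, roi_a.grid, roi_b.grid)
    members = p_ab.data >= alpha
    members |= dilate_mask(roi_a.mask, dilation_voxels, dilation_connectivity)
    members |= dilate_mask(roi_b.mask, dilation_voxels, dilation_connectivity)
    return members


def flood_fill_distances(
    members: np.ndarray,
    seed_roi: ROIMask,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> DistanceMap:
    """Breadth-first distance labelling over the member set.

    Voxel neighbours of the seed ROI get d = 1, their unlabelled neighbours
    d = 2, and so on; seed voxels carry no label and members unreachable from
    the seed stay unassigned (label 0).
    """
    members = np.asarray(members, bool)
    if not members[seed_roi.mask].all():
        raise ValueError("seed ROI voxels must belong to the member set")
    struct = _structure(connectivity)
    labels = np.zeros(members.shape, dtype=int)
    visited = seed_roi.mask.copy()
    frontier = seed_roi.mask
    d = 0
    while True:
        d += 1
        frontier = ndimage.binary_dilation(frontier, structure=struct) & members & ~visited
        if not frontier.any():
            break
        labels[frontier] = d
        visited |= frontier
    return DistanceMap(seed_roi.grid, labels)


def _target_contact(target_dilated: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Voxels inside, or adjacent to, the dilated target ROI."""
    return ndimage.binary_dilation(target_dilated, structure=_structure(connectivity))


def build_core_polyline(
    p_ab: ScalarVolume,
    distance_map: DistanceMap,
    target_roi: ROIMask,
    max_segment: float = DEFAULT_MAX_SEGMENT,
    max_angle: float = DEFAULT_MAX_ANGLE,
    target_dilation: int = DEFAULT_DILATION,
    adjacency: int = 26,
) -> CoreTrajectory:
    """Greedy construction of the core polyline L_ab.

    For each distance stratum in order, candidate voxels are visited in
    descending P_ab (ties broken by lowest linear voxel index); the first
    candidate whose segment to the previous vertex is shorter than
    ``max_segment`` mm and whose turning angle is below ``max_angle`` is
    appended. If none qualifies, the maximal-probability voxel is appended
    and the vertex index is flagged for visual inspection. Construction
    terminates *accepted* as soon as a vertex touches (is inside or adjacent
    to) the dilated target ROI, and *rejected* when strata run out first —
    i.e. thresholding broke every route to the target.
    """
    _check_same_grid(p_ab.grid, distance_map.grid, target_roi.grid)
    grid = p_ab.grid
    labels = distance_map.labels
    max_d = distance_map.max_distance
    if max_d == 0:
        return CoreTrajectory(np.zeros((0, 3)), np.zeros((0, 3)), [], "rejected")
    contact = _target_contact(
        dilate_mask(target_roi.mask, target_dilation, adjacency), adjacency
    )
    vertices: list[np.ndarray] = []
    flags: list[int] = []
    prev_dir: np.ndarray | None = None
    status = "rejected"
    cos_limit = np.cos(max_angle)
    for d in range(1, max_d + 1):
        idx = np.argwhere(labels == d)
        if len(idx) == 0:
            continue
        p_vals = p_ab.data[tuple(idx.T)]
        lin = np.ravel_multi_index(tuple(idx.T), grid.dims)
        order = np.lexsort((lin, -p_vals))  # descending p, then lowest index
        chosen = None
        chosen_dir = prev_dir
        for k in order:
            cand = grid.voxel_to_world(idx[k].astype(float))
            if not vertices:
                chosen = (idx[k], cand)
                break
            seg = cand - vertices[-1]
            seglen = np.linalg.norm(seg)
            # boundary inclusive: on a 2 mm lattice the canonical two-voxel
            # catch-up step measures exactly 4.0 mm and must stay admissible
            if seglen == 0 or seglen > max_segment + 1e-9:
                continue
            u = seg / seglen
            # boundary inclusive: canonical 2 mm lattice steps sit exactly on
            # the pi/3 limit (e.g. (0,1,1) -> (1,1,0) turns by 60 degrees)
            if prev_dir is not None and float(prev_dir @ u) < cos_limit - 1e-9:
                continue  # turning angle beyond max_angle
            chosen = (idx[k], cand)
            chosen_dir = u
            break
        if chosen is None:
            # no candidate satisfies the constraints: keep the maximal voxel, flag it
            k = order[0]
            cand = grid.voxel_to_world(idx[k].astype(float))
            seg = cand - vertices[-1]
            seglen = np.linalg.norm(seg)
            chosen = (idx[k], cand)
            chosen_dir = seg / seglen if seglen > 0 else prev_dir
            flags.append(len(vertices))
        vertices.append(chosen[1])
        prev_dir = chosen_dir
        if contact[tuple(chosen[0])]:
            status = "accepted"
            break
    verts = np.asarray(vertices)
    orients = vertex_orientations(verts) if len(verts) >= 2 else np.zeros((len(verts), 3))
    return CoreTrajectory(verts, orients, flags, status)


def vertex_orientations(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex orientation omega_v: the normalised sum of the two adjacent
    segment vectors (single segment at the endpoints)."""
    vertices = np.asarray(vertices, float)
    if len(vertices) < 2:
        raise ValueError("need at least 2 vertices")
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if (seglen == 0).any():
        raise ValueError("duplicate consecutive vertices give a degenerate segment")
    omega = np.empty_like(vertices)
    omega[0] = seg[0]
    omega[-1] = seg[-1]
    if len(vertices) > 2:
        omega[1:-1] = seg[:-1] + seg[1:]
    norms = np.linalg.norm(omega, axis=1)
    if (norms == 0).any():
        raise ValueError("opposing adjacent segments give an undefined orientation")
    return omega / norms[:, None]


def uncertainty_field(
    trajectory: CoreTrajectory,
    grid: VoxelGrid,
    sigma_axial: float = DEFAULT_SIGMA_AXIAL,
    sigma_radial: float = DEFAULT_SIGMA_RADIAL,
    radius: float = DEFAULT_RADIUS,
) -> ScalarVolume:
    """Anisotropic Gaussian uncertainty field Phi_ab around the polyline.

    For each vertex v with orientation omega_v, voxel centres i within
    ``radius`` mm contribute ``exp(-d_a^2 / (2 sigma_a^2) - d_r^2 /
    (2 sigma_r^2))`` where d_a and d_r are the components of i - v parallel
    and perpendicular to omega_v; the field is the vertex-wise maximum, zero
    outside every vertex neighbourhood. The kernel peaks at 1 (no density
    constant) since the tract probability renormalises per stratum anyway.
    """
    if not trajectory.accepted:
        raise ValueError("uncertainty field requires an accepted trajectory")
    phi = np.zeros(grid.dims)
    inv_aff = np.linalg.inv(grid.affine)
    vox_radius = np.ceil(radius / grid.voxel_size).astype(int)
    for v, omega in zip(trajectory.vertices, trajectory.orientations):
        centre_vox = (inv_aff[:3, :3] @ v + inv_aff[:3, 3])
        lo = np.maximum(np.floor(centre_vox - vox_radius).astype(int), 0)
        hi = np.minimum(np.ceil(centre_vox + vox_radius).astype(int) + 1, grid.dims)
        if (lo >= hi).any():
            continue
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        centres = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
        diff = centres - v
        dist2 = np.einsum("ij,ij->i", diff, diff)
        within = dist2 <= radius ** 2
        if not within.any():
            continue
        d_axial = diff[within] @ omega
        d_rad2 = dist2[within] - d_axial ** 2
        d_rad2 = np.maximum(d_rad2, 0.0)
        val = np.exp(
            -(d_axial ** 2) / (2 * sigma_axial ** 2) - d_rad2 / (2 * sigma_radial ** 2)
        )
        block = phi[sl].reshape(-1)
        local = np.zeros(len(idx))
        local[within] = val
        phi[sl] = np.maximum(block, local).reshape(phi[sl].shape)
    return ScalarVolume(grid, phi)


def tract_probability(
    phi: ScalarVolume,
    p_ab: ScalarVolume,
    distance_map: DistanceMap,
) -> ScalarVolume:
    """Final tract probability P_ab-tract = f(Phi_ab * P_ab, d).

    The element-wise product is renormalised within each flood-fill distance
    stratum so the stratum maximum is 1 (all-zero strata stay zero); voxels
    without a distance label are zero.
    """
    _check_same_grid(phi.grid, p_ab.grid, distance_map.grid)
    g = phi.data * p_ab.data
    labels = distance_map.labels
    out = np.zeros_like(g)
    if labels.max() > 0:
        # per-stratum maxima in one pass
        maxima = ndimage.maximum(g, labels=labels, index=np.arange(1, labels.max() + 1))
        maxima = np.asarray(maxima, float)
        scale = np.ones(labels.max() + 1)
        nz = maxima > 0
        scale[1:][nz] = 1.0 / maxima[nz]
        inside = labels > 0
        out[inside] = g[inside] * scale[labels[inside]]
    return ScalarVolume(phi.grid, out)


def estimate_tract(
    per_participant_pairs,
    roi_a: ROIMask,
    roi_b: ROIMask,
    alpha: float = DEFAULT_ALPHA,
    dilation_voxels: int = DEFAULT_DILATION,
    smoothing_fwhm: float = DEFAULT_SMOOTH_FWHM,
    max_segment: float = DEFAULT_MAX_SEGMENT,
    max_angle: float = DEFAULT_MAX_ANGLE,
    sigma_axial: float = DEFAULT_SIGMA_AXIAL,
    sigma_radial: float = DEFAULT_SIGMA_RADIAL,
    radius: float = DEFAULT_RADIUS,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> TractEstimate:
    """Full trajectory stage: population average -> threshold -> flood fill ->
    polyline -> uncertainty field -> tract probability. Rejection is a
    result (``estimate.accepted`` is False; phi and p_tract are None)."""
    p_ab = bidirectional_population_average(per_participant_pairs, smoothing_fwhm)
    members = threshold_with_dilated_rois(p_ab, roi_a, roi_b, alpha, dilation_voxels)
    dmap = flood_fill_distances(members, roi_a, connectivity)
    traj = build_core_polyline(p_ab, dmap, roi_b, max_segment, max_angle, dilation_voxels)
    if not traj.accepted:
        return TractEstimate(p_ab, members, dmap, traj, None, None)
    phi = uncertainty_field(traj, p_ab.grid, sigma_axial, sigma_radial, radius)
    p_tract = tract_probability(phi, p_ab, dmap)
    return TractEstimate(p_ab, members, dmap, traj, phi, p_tract)
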
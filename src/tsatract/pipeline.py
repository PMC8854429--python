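"""End-to-end orchestration: phantom -> tract -> TSA -> statistics.

Each stage reads the previous stage's on-disk outputs, writes its own, and
records a manifest entry (parameters, seed, output hashes), so a run is
reproducible from the manifest alone and partial reruns can resume when a
stage's recorded configuration still matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import phantom as ph
from . import stats as tstats
from . import tract as ttract
from . import tsa as ttsa

log = logging.getLogger("tsatract")

__all__ = ["RunConfig", "run_pipeline", "fibonacci_sphere"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic gradient scheme)."""
    i = np.arange(n) + 0.5
    phi_angle = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5 ** 0.5)
    theta = golden * i
    vecs = np.column_stack(
        [np.sin(phi_angle) * np.cos(theta), np.sin(phi_angle) * np.sin(theta), np.cos(phi_angle)]
    )
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


@dataclasses.dataclass
class RunConfig:
    """All tunable parameters of a run, with the method's default values."""

    out_dir: str = "tsatract_out"
    seed: int = 0
    # phantom geometry
    grid_size: int = 48
    voxel_size: float = 2.0
    tube_sigma: float = 4.0
    roi_radius: float = 4.0
    n_participants: int = 20
    curve_kind: str = "straight"  # straight | arc
    # signal model
    n_gradients: int = 64
    b_value: float = 1500.0
    diffusivity: float = 1e-3
    beta_true: float = 0.5
    intercept_true: float = 0.2
    noise_sd: float = 0.02
    age_slope: float = 0.0
    sex_effect: float = 0.0
    interaction_effect: float = 0.0
    s0: float = 1000.0
    # tract determination
    alpha: float = 0.07
    dilation_voxels: int = 3
    smoothing_fwhm: float = 2.0
    max_segment: float = 4.0
    max_angle: float = float(np.pi / 3)
    sigma_axial: float = 10.0
    sigma_radial: float = 4.0
    radius: float = 8.0
    connectivity: int = 26
    # tsa / statistics
    tsa_smooth_fwhm: float = 1.5
    lambda_decay: float = 1.0
    alpha_level: float = 0.05
    min_cluster_extent: int = 3
    fdr_q: float = 0.05
    field_model: str = "t"  # t | gaussian

    def __post_init__(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.alpha_level < 1, "alpha_level must be in (0, 1)"),
            (0 < self.fdr_q < 1, "fdr_q must be in (0, 1)"),
            (self.lambda_decay >= 0, "lambda_decay must be >= 0"),
            (self.min_cluster_extent >= 1, "min_cluster_extent must be >= 1"),
            (self.n_participants >= 6, "n_participants must be >= 6"),
            (self.n_gradients >= 6, "n_gradients must be >= 6"),
            (self.connectivity in (6, 18, 26), "connectivity must be 6, 18 or 26"),
            (self.field_model in ("t", "gaussian"), "field_model must be 't' or 'gaussian'"),
            (self.curve_kind in ("straight", "arc"), "curve_kind must be 'straight' or 'arc'"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.tube_sigma > 0, "tube_sigma must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_fingerprint(config: RunConfig, stage: str) -> str:
    payload = json.dumps({"stage": stage, "config": config.to_dict()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {"stages": {}}

    def stage_current(self, name: str, fingerprint: str, outputs) -> bool:
        entry = self.data["stages"].get(name)
        if not entry or entry.get("fingerprint") != fingerprint:
            return False
        return all(Path(p).exists() for p in entry.get("outputs", []))

    def record(self, name: str, fingerprint: str, outputs, extra=None) -> None:
        self.data["stages"][name] = {
            "fingerprint": fingerprint,
            "outputs": [str(p) for p in outputs],
            "hashes": {str(p): _sha256(Path(p)) for p in outputs},
            **(extra or {}),
        }
        self.save()

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _phantom_geometry(config: RunConfig):
    grid = tio.VoxelGrid.isotropic((config.grid_size,) * 3, config.voxel_size)
    extent = (np.array(grid.dims) - 1) * config.voxel_size
    margin = config.roi_radius + 2 * config.voxel_size
    mid = extent / 2
    if config.curve_kind == "straight":
        curve = ph.straight_curve(
            [margin, mid[1], mid[2]], [extent[0] - margin, mid[1], mid[2]]
        )
    else:
        radius = (extent[0] - 2 * margin) / 2
        curve = ph.arc_curve(
            [mid[0], margin, mid[2]], radius, np.pi, 0.0, plane="xy", n=200
        )
    return grid, curve


def stage_phantom(config: RunConfig, out: Path, manifest: Manifest) -> None:
    fp = _stage_fingerprint(config, "phantom")
    outputs = [
        out / "p_ab_dir1.nii.gz",
        out / "p_ab_dir2.nii.gz",
        out / "orientation.nii.gz",
        out / "roi_a.nii.gz",
        out / "roi_b.nii.gz",
        out / "cohort.tsv",
        out / "bvecs",
        out / "bvals",
    ]
    if manifest.stage_current("phantom", fp, outputs):
        log.info("phantom stage up to date; skipping")
        return
    grid, curve = _phantom_geometry(config)
    spec = ph.PhantomSpec(
        grid,
        curve,
        tube_sigma=config.tube_sigma,
        roi_radius=config.roi_radius,
        seed=config.seed,
    )
    pairs, orient, roi_a, roi_b = ph.make_probability_pairs(spec, config.n_participants)
    # population directed stacks stored as 4D (participant axis) would be large;
    # write the per-participant minimum is what downstream needs, but we keep
    # both directions averaged over participants for inspection plus the full
    # stack in a single npz for exact reuse by the tract stage
    np.savez_compressed(
        out / "directed_pairs.npz",
        dir1=np.stack([p[0].data for p in pairs]),
        dir2=np.stack([p[1].data for p in pairs]),
    )
    tio.write_volume(
        tio.ScalarVolume(grid, np.mean([p[0].data for p in pairs], axis=0)),
        outputs[0],
    )
    tio.write_volume(
        tio.ScalarVolume(grid, np.mean([p[1].data for p in pairs], axis=0)),
        outputs[1],
    )
    tio.write_volume(orient, outputs[2])
    tio.write_volume(tio.ScalarVolume(grid, roi_a.mask.astype(float)), outputs[3])
    tio.write_volume(tio.ScalarVolume(grid, roi_b.mask.astype(float)), outputs[4])
    cohort = ph.make_cohort(config.n_participants, seed=config.seed + 1)
    tio.write_cohort(cohort, outputs[5])
    bvecs = fibonacci_sphere(config.n_gradients)
    np.savetxt(outputs[6], bvecs.T, fmt="%.8f")
    np.savetxt(outputs[7], np.full((1, config.n_gradients), config.b_value), fmt="%.1f")
    (out / "ground_truth_curve.json").write_text(
        json.dumps({"curve_mm": curve.tolist()})
    )
    manifest.record("phantom", fp, outputs, {"seed": config.seed})
    log.info("phantom stage written to %s", out)


def stage_tract(config: RunConfig, out: Path, manifest: Manifest) -> ttract.TractEstimate:
    fp = _stage_fingerprint(config, "tract")
    outputs = [
        out / "p_ab.nii.gz",
        out / "distance_map.nii.gz",
        out / "trajectory.json",
    ]
    required = [out / "roi_a.nii.gz", out / "roi_b.nii.gz", out / "directed_pairs.npz"]
    for path in required:
        if not path.exists():
            raise FileNotFoundError(
                f"tract stage expects phantom outputs; missing {path} "
                "(run the 'phantom' stage first)"
            )
    grid = tio.read_volume(out / "roi_a.nii.gz").grid
    pairs_npz = np.load(out / "directed_pairs.npz")
    pairs = [
        (tio.ScalarVolume(grid, a), tio.ScalarVolume(grid, b))
        for a, b in zip(pairs_npz["dir1"], pairs_npz["dir2"])
    ]
    roi_a = tio.ROIMask(grid, tio.read_volume(out / "roi_a.nii.gz").data > 0.5, "roi_a")
    roi_b = tio.ROIMask(grid, tio.read_volume(out / "roi_b.nii.gz").data > 0.5, "roi_b")
    estimate = ttract.estimate_tract(
        pairs,
        roi_a,
        roi_b,
        alpha=config.alpha,
        dilation_voxels=config.dilation_voxels,
        smoothing_fwhm=config.smoothing_fwhm,
        max_segment=config.max_segment,
        max_angle=config.max_angle,
        sigma_axial=config.sigma_axial,
        sigma_radial=config.sigma_radial,
        radius=config.radius,
        connectivity=config.connectivity,
    )
    tio.write_volume(estimate.p_ab, outputs[0])
    tio.write_volume(
        tio.ScalarVolume(grid, estimate.distance_map.labels.astype(float)), outputs[1]
    )
    estimate.trajectory.to_json(outputs[2])
    for flag_idx in estimate.trajectory.flags:
        log.warning("polyline constraint violation flagged at vertex %d", flag_idx)
    if estimate.accepted:
        tio.write_volume(estimate.phi, out / "phi.nii.gz")
        tio.write_volume(estimate.p_tract, out / "p_tract.nii.gz")
        outputs += [out / "phi.nii.gz", out / "p_tract.nii.gz"]
        log.info("tract accepted: %d vertices", len(estimate.trajectory.vertices))
    else:
        log.info("tract rejected: thresholding broke all routes to the target")
    manifest.record(
        "tract", fp, outputs, {"status": estimate.trajectory.status}
    )
    return estimate


def stage_tsa(config: RunConfig, out: Path, manifest: Manifest,
              estimate: ttract.TractEstimate) -> list:
    fp = _stage_fingerprint(config, "tsa")
    if not estimate.accepted:
        manifest.record("tsa", fp, [], {"skipped": "tract rejected"})
        log.info("tsa stage skipped: no accepted tract")
        return []
    grid = estimate.p_ab.grid
    orient = tio.read_volume(out / "orientation.nii.gz", expect_vector=True)
    gradients = tio.read_gradient_table(out / "bvecs", out / "bvals")
    cohort = tio.read_cohort(out / "cohort.tsv")
    support = estimate.members & orient.support
    effect_mask = None
    spec = ph.SignalSpec(
        gradients,
        cohort,
        diffusivity=config.diffusivity,
        beta_true=config.beta_true,
        intercept_true=config.intercept_true,
        noise_sd=config.noise_sd,
        age_slope=config.age_slope,
        sex_effect=config.sex_effect,
        interaction_effect=config.interaction_effect,
        effect_mask=effect_mask,
        s0=config.s0,
        seed=config.seed + 2,
    )
    tsa_dir = out / "tsa"
    tsa_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    stack = []
    for sig in ph.make_dwi_signal(spec, orient, mask=support):
        tsa_map = ttsa.fit_tsa_participant(
            sig.signal, sig.b0, orient, support, gradients, config.diffusivity,
            participant_id=sig.participant_id,
        )
        tsa_map = ttsa.smooth_tsa(tsa_map, config.tsa_smooth_fwhm)
        path = tsa_dir / f"tsa_{sig.participant_id}.nii.gz"
        tio.write_volume(
            tio.ScalarVolume(grid, np.where(tsa_map.fitted, tsa_map.beta, 0.0)), path
        )
        outputs.append(path)
        stack.append(tsa_map)
    manifest.record("tsa", fp, outputs)
    log.info("tsa stage: fitted %d participants", len(stack))
    return stack


def stage_stats(config: RunConfig, out: Path, manifest: Manifest,
                estimate: ttract.TractEstimate, stack: list) -> dict:
    fp = _stage_fingerprint(config, "stats")
    if not estimate.accepted or not stack:
        (out / "stats_summary.csv").write_text("tract,message\ntract_1,no accepted tracts\n")
        manifest.record("stats", fp, [out / "stats_summary.csv"],
                        {"skipped": "no accepted tracts"})
        log.info("stats stage: no accepted tracts")
        return {}
    cohort = tio.read_cohort(out / "cohort.tsv")
    cm, profiles, resid = tstats.analyse_tract(
        stack, cohort, estimate.p_tract, estimate.distance_map,
        tract_id="tract_1", lambda_decay=config.lambda_decay,
    )
    results, sums, mean_fwhm, t_star = tstats.combine_tracts(
        {"tract_1": (profiles, resid)},
        nu=cm.nu,
        alpha_level=config.alpha_level,
        min_extent=config.min_cluster_extent,
        fdr_q=config.fdr_q,
        field_model=config.field_model,
    )
    prof_rows = []
    for p in profiles:
        for d, tp, tn in zip(p.distances, p.t_pos, p.t_neg):
            prof_rows.append(
                {"tract": p.tract_id, "contrast": p.contrast, "distance": int(d),
                 "t_pos": tp, "t_neg": tn}
            )
    pd.DataFrame(prof_rows).to_csv(out / "distance_profiles.csv", index=False)
    clus_rows = []
    for res in results:
        for c in res.clusters:
            clus_rows.append(
                {"tract": res.tract_id, "contrast": res.contrast, "sign": res.sign,
                 "start": c.start, "end": c.end, "extent": c.extent,
                 "peak_t": c.peak_t, "p": c.p_value, "adjusted_p": c.adjusted_p,
                 "survives": c.survives}
            )
    pd.DataFrame(
        clus_rows,
        columns=["tract", "contrast", "sign", "start", "end", "extent",
                 "peak_t", "p", "adjusted_p", "survives"],
    ).to_csv(out / "clusters.csv", index=False)
    sum_rows = [
        {"tract": k[0], "contrast": k[1], "positive_sum": v[0], "negative_sum": v[1]}
        for k, v in sorted(sums.items())
    ]
    pd.DataFrame(sum_rows).to_csv(out / "signed_sums.csv", index=False)
    outputs = [out / "distance_profiles.csv", out / "clusters.csv", out / "signed_sums.csv"]
    manifest.record(
        "stats", fp, outputs,
        {"mean_fwhm": mean_fwhm, "t_star": t_star, "nu": cm.nu},
    )
    log.info("stats stage: mean FWHM %.2f strata, t* = %.3f", mean_fwhm, t_star)
    return {"results": results, "sums": sums, "mean_fwhm": mean_fwhm,
            "t_star": t_star, "profiles": profiles}


def run_pipeline(config: RunConfig, stages=("phantom", "tract", "tsa", "stats")) -> dict:
    """Run the requested stages in order; returns the stats-stage summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    manifest.data["config"] = config.to_dict()
    manifest.save()
    estimate = None
    stack = []
    summary: dict = {}
    if "phantom" in stages:
        stage_phantom(config, out, manifest)
    if "tract" in stages:
        estimate = stage_tract(config, out, manifest)
    if "tsa" in stages:
        if estimate is None:
            raise FileNotFoundError(
                f"tsa stage needs tract outputs in {out}; run the 'tract' stage first"
            )
        stack = stage_tsa(config, out, manifest, estimate)
    if "stats" in stages:
        if estimate is None:
            raise FileNotFoundError(
                f"stats stage needs tract outputs in {out}; run the 'tract' stage first"
            )
        summary = stage_stats(config, out, manifest, estimate, stack)
    return summary
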
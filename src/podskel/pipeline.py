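"""End-to-end orchestration: preprocess → skeletonize → connect → optimize → traits.

The pipeline is configured by a single flat :class:`PipelineConfig`
(serializable as ``key = value`` lines); every run can write its
artifacts — skeleton CSV, sub-skeleton edge list, per-silique table,
labelled PLY and a summary JSON embedding the fully resolved
configuration — to an output directory.
"""
from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import io as cloud_io
from .connect import connect_all
from .optimize import OptimizeParams, optimize
from .preprocess import detect_pot, remove_outliers, remove_pot
from .skeleton import SkeletonParams, extract_skeleton
from .synth import GroundTruth
from .traits import TraitParams, plant_traits
from .types import (DegenerateGeometryError, InsufficientDataError,
                    PlantTraits, PointCloud)
from .validation import agreement, recalls

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "run_eval"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration of the whole pipeline (units: mm, degrees)."""

    # preprocessing
    outlier_k: int = 20
    outlier_std_ratio: float = 2.0
    pot_removal: bool = True
    delta_d: float = 10.0
    # skeleton extraction
    r0: Optional[float] = None
    radius_growth: float = 0.5
    max_outer_iters: int = 16
    inner_tol: float = 0.02
    tau: float = 0.35
    kernel_bandwidth_factor: float = 1.5
    T_d: float = 1.5
    ransac_iters: int = 24
    ransac_inlier_tol: float = 1.0
    plane_refit_every: int = 2
    r_cap_factor: float = 6.0
    r_flat_factor: float = 6.0
    sample_fraction: float = 0.07
    max_points: int = 80_000
    voxel_size: Optional[float] = 1.0
    constrain: bool = True
    # connection
    eps: Optional[float] = None
    min_pts: int = 3
    max_edge_factor: Optional[float] = 4.0
    smooth_passes: int = 2
    # optimization
    merge_angle_max: float = 15.0
    merge_dist_factor: float = 5.0
    split_angle_min: float = 165.0
    split_angle_window: int = 2
    # traits
    branch_len_thresh: float = 200.0
    min_silique_len: float = 15.0
    assign_radius: float = 3.0
    extend_max: float = 20.0
    # reproducibility
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file; unknown keys are rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (t.strip() for t in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = _coerce(val, fields[key].type)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def skeleton_params(self) -> SkeletonParams:
        return SkeletonParams(
            r0=self.r0, radius_growth=self.radius_growth,
            max_outer_iters=self.max_outer_iters, inner_tol=self.inner_tol,
            tau=self.tau, kernel_bandwidth_factor=self.kernel_bandwidth_factor,
            T_d=self.T_d, ransac_iters=self.ransac_iters,
            ransac_inlier_tol=self.ransac_inlier_tol,
            plane_refit_every=self.plane_refit_every,
            r_cap_factor=self.r_cap_factor,
            r_flat_factor=self.r_flat_factor,
            sample_fraction=self.sample_fraction, max_points=self.max_points,
            voxel_size=self.voxel_size,
            constrain=self.constrain, seed=self.seed)

    def optimize_params(self) -> OptimizeParams:
        return OptimizeParams(merge_angle_max=self.merge_angle_max,
                              merge_dist_factor=self.merge_dist_factor,
                              split_angle_min=self.split_angle_min,
                              angle_window=self.split_angle_window)

    def trait_params(self) -> TraitParams:
        return TraitParams(branch_len_thresh=self.branch_len_thresh,
                           min_silique_len=self.min_silique_len,
                           assign_radius=self.assign_radius, T_d=self.T_d,
                           extend_max=self.extend_max)


def _coerce(val: str, ftype) -> object:
    s = str(ftype)
    if val.lower() in ("none", "null"):
        return None
    if "bool" in s:
        return val.lower() in ("1", "true", "yes", "on")
    if "int" in s and "float" not in s:
        return int(val)
    return float(val)


def run_pipeline(cloud_or_path, config: Optional[PipelineConfig] = None,
                 output_dir: Optional[str] = None,
                 log=None) -> Tuple[PlantTraits, dict]:
    """Run the full pipeline on a cloud (or a cloud file path).

    Returns ``(traits, artifacts)``; ``artifacts`` holds the intermediate
    objects (preprocessed cloud, skeleton, sub-skeletons, summary dict).
    Stage failures raise :class:`StageError` naming the stage.
    """
    config = config or PipelineConfig()
    log = log or (lambda msg: None)
    timings = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        log(f"{name}: {timings[name]:.2f}s")
        return out

    if isinstance(cloud_or_path, (str, os.PathLike)):
        cloud = stage("read", lambda: cloud_io.read_cloud(str(cloud_or_path)))
    else:
        cloud = cloud_or_path

    def _preprocess() -> PointCloud:
        out = cloud
        if len(out) > config.outlier_k:
            out = remove_outliers(out, config.outlier_k, config.outlier_std_ratio)
        if config.pot_removal and len(out):
            try:
                pot = detect_pot(out, config.delta_d)
                out = remove_pot(out, pot)
            except (DegenerateGeometryError, InsufficientDataError):
                pass  # no recognizable pot: keep the cloud as is
        return out

    pre = stage("preprocess", _preprocess)
    skel = stage("skeletonize", lambda: extract_skeleton(pre, config.skeleton_params()))
    subs = stage("connect", lambda: connect_all(
        skel, eps=config.eps, min_pts=config.min_pts, seed=config.seed,
        smooth_passes=config.smooth_passes,
        max_edge_factor=config.max_edge_factor))
    subs = stage("optimize", lambda: optimize(subs, config.optimize_params()))
    traits = stage("traits", lambda: plant_traits(subs, pre, config.trait_params()))

    summary = {
        "config": config.to_dict(),
        "n_points_in": len(cloud),
        "n_points_preprocessed": len(pre),
        "n_skeleton_points": len(skel),
        "n_subskeletons": len(subs),
        **traits.to_dict(),
    }
    artifacts = {"cloud": pre, "skeleton": skel, "subskeletons": subs,
                 "summary": summary,
                 "timings_s": {k: round(v, 3) for k, v in timings.items()}}
    if output_dir is not None:
        _write_artifacts(output_dir, pre, skel, subs, traits, summary,
                         artifacts["timings_s"])
    return traits, artifacts


def _write_artifacts(output_dir, pre, skel, subs, traits, summary,
                     timings=None) -> None:
    import pandas as pd

    os.makedirs(output_dir, exist_ok=True)
    pd.DataFrame({
        "x": skel.positions[:, 0], "y": skel.positions[:, 1],
        "z": skel.positions[:, 2], "lambda": skel.directionality,
        "radius": skel.radius,
    }).to_csv(os.path.join(output_dir, "skeleton.csv"), index=False)
    cloud_io.write_cloud(os.path.join(output_dir, "skeleton.ply"),
                         PointCloud(skel.positions))

    rows = []
    for s in subs:
        for i in range(len(s) - 1):
            rows.append((s.class_id, i, *s.points[i], i + 1, *s.points[i + 1]))
    pd.DataFrame(rows, columns=["class_id", "i", "x_i", "y_i", "z_i",
                                "j", "x_j", "y_j", "z_j"]).to_csv(
        os.path.join(output_dir, "subskeletons.csv"), index=False)

    # OBJ line elements, viewable in any mesh viewer
    with open(os.path.join(output_dir, "subskeletons.obj"), "w") as fh:
        offset = 1
        for s_ in subs:
            for p_ in s_.points:
                fh.write(f"v {p_[0]:.6f} {p_[1]:.6f} {p_[2]:.6f}\n")
            for i in range(len(s_) - 1):
                fh.write(f"l {offset + i} {offset + i + 1}\n")
            offset += len(s_)

    pd.DataFrame([{
        "id": r.id, "length_mm": r.length, "volume_mm3": r.volume,
        "n_points": len(r.point_indices), "effective": r.effective,
    } for r in traits.records]).to_csv(
        os.path.join(output_dir, "siliques.csv"), index=False)

    labels = np.full(len(pre), -1, dtype=np.int64)
    for r in traits.records:
        if r.effective:
            labels[r.point_indices] = r.id + 1  # 0 is reserved for branches
    out_cloud = PointCloud(pre.points, labels)
    cloud_io.write_cloud(os.path.join(output_dir, "labeled.ply"), out_cloud)

    with open(os.path.join(output_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    with open(os.path.join(output_dir, "run.log"), "w") as fh:
        for name, dt in (timings or {}).items():
            fh.write(f"{name}: {dt:.3f}s\n")
        fh.write(f"subskeletons: {len(subs)}\n")
        fh.write(f"effective siliques: {sum(1 for r in traits.records if r.effective)}\n")


def run_eval(plants: Sequence[Tuple[PointCloud, GroundTruth]],
             config: Optional[PipelineConfig] = None, log=None) -> dict:
    """Evaluate the pipeline on labelled plants.

    The generator truth provides the scanned and manual silique counts
    (``SN_L`` and ``SN_M`` surrogates).  Per-plant recalls are always
    reported; cross-plant agreement statistics for SN / total SL /
    total SV require at least 2 plants.
    """
    if not plants:
        raise ValueError("run_eval needs at least one plant")
    config = config or PipelineConfig()
    per_plant = []
    est = {"sn": [], "sl": [], "sv": []}
    true = {"sn": [], "sl": [], "sv": []}
    for cloud, truth in plants:
        traits, _ = run_pipeline(cloud, config, log=log)
        rep = recalls(traits.sn_e, truth.sn, truth.sn)
        per_plant.append({
            "SN_E": traits.sn_e, "SN_true": truth.sn,
            "Re_EL_pct": rep.re_el,
            "total_SL_mm": traits.total_sl, "true_SL_mm": truth.total_sl,
            "total_SV_mm3": traits.total_sv, "true_SV_mm3": truth.total_sv,
        })
        est["sn"].append(traits.sn_e)
        est["sl"].append(traits.total_sl)
        est["sv"].append(traits.total_sv)
        true["sn"].append(truth.sn)
        true["sl"].append(truth.total_sl)
        true["sv"].append(truth.total_sv)
    report = {"per_plant": per_plant,
              "mean_Re_EL_pct": float(np.mean([p["Re_EL_pct"] for p in per_plant]))}
    if len(plants) >= 2:
        for key in ("sn", "sl", "sv"):
            try:
                r2, rmse, r = agreement(est[key], true[key])
                report[f"{key}_R2"] = r2
                report[f"{key}_RMSE"] = rmse
                report[f"{key}_R"] = r
            except ValueError as exc:
                report[f"{key}_agreement_notice"] = str(exc)
    else:
        report["agreement_notice"] = "agreement statistics need >= 2 plants"
    return report
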
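"""Tracked-probe geometry: marker pose, pivot calibration, tip projection.

A planar fiducial marker on the endomicroscopy probe is localised in the
left (RGB) camera by perspective-n-point with RANSAC outlier rejection.
Pivot calibration — rotating the probe about its stationary tip — recovers
the fixed marker-to-tip offset by least squares over the stacked rigid
constraints ``R_i @ t_tip + t_i = p``.  The probe tip, computed from any
subsequent marker pose, is transferred into the hyperspectral camera and
projected to the pixel where the optical biopsy was taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .stereo import (BehindCamera, CameraIntrinsics, Pixel, Point3D, StereoRig,
                     _homography_dlt, _pose_from_homography, project_points,
                     project_to_image, transform_left_to_right)


class PoseEstimationError(ValueError):
    """Too few or degenerate correspondences for pose estimation."""


class UnderdeterminedError(ValueError):
    """Pivot calibration lacks rotational diversity to fix the tip offset."""


class PivotConditioningWarning(UserWarning):
    """Rotation set is nearly single-axis; one tip component is weakly observed."""


@dataclass
class MarkerPose:
    """6-DoF pose of the probe marker expressed in the left-camera frame."""

    R_m: np.ndarray
    t_m: np.ndarray
    n_inliers: int | None = None

    def __post_init__(self) -> None:
        self.R_m = np.asarray(self.R_m, dtype=float)
        self.t_m = np.asarray(self.t_m, dtype=float).reshape(3)
        if self.R_m.shape != (3, 3):
            raise ValueError("R_m must be 3x3")
        if not np.allclose(self.R_m @ self.R_m.T, np.eye(3), atol=1e-6):
            raise ValueError("R_m must be orthonormal")
        if np.linalg.det(self.R_m) < 0:
            raise ValueError("R_m must have det +1")


@dataclass
class ProbeModel:
    """Marker-to-tip transform from pivot calibration.

    A stationary point target has no observable orientation, so the rotation
    part is the identity and ``T_probe`` carries the marker-frame tip offset.
    """

    R_probe: np.ndarray = field(default_factory=lambda: np.eye(3))
    T_probe: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.R_probe = np.asarray(self.R_probe, dtype=float)
        self.T_probe = np.asarray(self.T_probe, dtype=float).reshape(3)
        if not np.allclose(self.R_probe @ self.R_probe.T, np.eye(3), atol=1e-8):
            raise ValueError("R_probe must be orthonormal")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


@dataclass
class BiopsySite:
    """One pCLE sampling event, localised in 3-D and on the HSI grid."""

    tip_3d: Point3D
    hsi_pixel: Pixel
    pcle_label: str = "tumor"            # {"healthy", "tumor"}
    pcle_confidence: float = 1.0
    specimen_id: int | str = 0
    site_id: int = 0
    in_view: bool = True

    def __post_init__(self) -> None:
        if self.pcle_label not in ("healthy", "tumor"):
            raise ValueError("pcle_label must be 'healthy' or 'tumor'")
        if not 0.0 <= self.pcle_confidence <= 1.0:
            raise ValueError("pcle_confidence must lie in [0, 1]")


# --- marker pose ------------------------------------------------------------

def _refine_pose(R0, t0, pts3, px, cam):
    x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])

    def resid(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return (project_points(pts3 @ R.T + x[3:], cam) - px).ravel()

    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return (Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:],
            sol.fun.reshape(-1, 2))


def _pose_from_4(pts3, px, cam):
    """Minimal planar pose: homography from the marker plane, decomposed."""
    H = _homography_dlt(pts3[:, :2], px)
    return _pose_from_homography(H, cam.K)


def estimate_marker_pose(corners_2d: np.ndarray, corners_3d: np.ndarray,
                         cam: CameraIntrinsics, *, ransac_iters: int = 100,
                         inlier_px: float = 2.0, seed: int = 0) -> MarkerPose:
    """RANSAC perspective-n-point for a planar marker.

    ``corners_3d`` are marker-frame coordinates (planar, z = 0 up to
    tolerance); ``corners_2d`` the detected pixels.  The returned pose
    minimises reprojection error over the RANSAC inlier set.
    """
    px = np.asarray(corners_2d, dtype=float).reshape(-1, 2)
    pts3 = np.asarray(corners_3d, dtype=float).reshape(-1, 3)
    n = len(px)
    if n != len(pts3):
        raise PoseEstimationError("2-D and 3-D correspondence counts differ")
    if n < 4:
        raise PoseEstimationError(f"need >= 4 correspondences, got {n}")
    centred = pts3 - pts3.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise PoseEstimationError("marker corners are collinear")
    if sv[2] > 1e-6 * sv[0]:
        raise PoseEstimationError("marker corners must be planar (z = 0 frame)")

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    for _ in range(ransac_iters):
        idx = rng.choice(n, size=4, replace=False)
        sub = pts3[idx] - pts3[idx].mean(axis=0)
        if np.linalg.svd(sub, compute_uv=False)[1] < 1e-9:
            continue
        try:
            R, t = _pose_from_4(pts3[idx], px[idx], cam)
            pred = project_points(pts3 @ R.T + t, cam)
        except (np.linalg.LinAlgError, BehindCamera):
            continue
        err = np.linalg.norm(pred - px, axis=1)
        inliers = err < inlier_px
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
        if inliers.sum() == n:
            break
    if best_inliers is None or best_inliers.sum() < 4:
        raise PoseEstimationError("RANSAC found no 4-point consensus")

    R0, t0 = _pose_from_4(pts3[best_inliers], px[best_inliers], cam)
    R, t, res = _refine_pose(R0, t0, pts3[best_inliers], px[best_inliers], cam)
    # one re-classification pass with the refined pose
    err = np.linalg.norm(project_points(pts3 @ R.T + t, cam) - px, axis=1)
    final_in = err < inlier_px
    if final_in.sum() >= 4 and final_in.sum() > best_inliers.sum():
        R, t, _ = _refine_pose(R, t, pts3[final_in], px[final_in], cam)
        best_inliers = final_in
    return MarkerPose(R_m=R, t_m=t, n_inliers=int(best_inliers.sum()))


def square_marker_corners(side_mm: float) -> np.ndarray:
    """Corner layout of a square planar marker centred on its own origin."""
    h = side_mm / 2.0
    return np.array([[-h, -h, 0], [h, -h, 0], [h, h, 0], [-h, h, 0]], dtype=float)


# --- pivot calibration ------------------------------------------------------

def pivot_calibrate(poses: list[MarkerPose]) -> tuple[ProbeModel, Point3D]:
    """Solve ``R_i @ t_tip + t_i = p`` for the tip offset and the pivot point.

    Stacks one rigid constraint per pose into a linear system in the six
    unknowns ``(t_tip, p)`` and solves by least squares.  ``rms_residual``
    is the RMS of the per-pose constraint violations in millimetres.
    """
    if len(poses) < 3:
        raise UnderdeterminedError(f"need >= 3 poses, got {len(poses)}")
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, pose in enumerate(poses):
        A[3 * i:3 * i + 3, :3] = pose.R_m
        A[3 * i:3 * i + 3, 3:] = -np.eye(3)
        b[3 * i:3 * i + 3] = -pose.t_m

    s = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(s > s[0] * 1e-9))
    if rank < 5:
        raise UnderdeterminedError(
            "rotation set has no diversity (all poses share the same "
            f"orientation?); system rank {rank} < 5")
    if rank < 6 or s[0] / s[-1] > 1e6:
        warnings.warn(
            f"pivot rotations are nearly single-axis (condition "
            f"{s[0] / max(s[-1], 1e-300):.2e}); one tip component is weakly "
            "constrained", PivotConditioningWarning)

    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    t_tip, p = x[:3], x[3:]
    resid = A @ x - b
    rms = float(np.sqrt(np.mean(np.sum(resid.reshape(-1, 3) ** 2, axis=1))))
    probe = ProbeModel(R_probe=np.eye(3), T_probe=t_tip, rms_residual=rms)
    return probe, Point3D.from_array(p, "left")


def compute_probe_tip(pose: MarkerPose, probe: ProbeModel) -> Point3D:
    """Tip position in the left-camera frame from a marker pose.

    The tip sits at ``R_probe @ 0 + T_probe`` in the marker frame (a point
    target carries no orientation, so R_probe is the identity); the marker
    pose maps it into the camera: ``tip = R_m @ T_probe + t_m``.
    """
    tip_marker = probe.R_probe @ np.zeros(3) + probe.T_probe
    return Point3D.from_array(pose.R_m @ tip_marker + pose.t_m, "left")


def project_biopsy_site(tip: Point3D, rig: StereoRig,
                        image_shape: tuple[int, int] | None = None
                        ) -> tuple[Pixel, bool]:
    """Project a left-frame tip into the hyperspectral image.

    Returns the pixel and an in-view flag (always True when no image shape
    is given).  Out-of-bounds pixels are flagged, never clamped.
    """
    p_right = transform_left_to_right(tip, rig)
    pixel = project_to_image(p_right, rig.right)
    in_view = True
    if image_shape is not None:
        h, w = image_shape
        in_view = (-0.5 <= pixel.u < w - 0.5) and (-0.5 <= pixel.v < h - 0.5)
    return pixel, in_view


def probe_tip_error_protocol(touch_events: list[tuple[MarkerPose, Pixel]],
                             probe: ProbeModel, rig: StereoRig
                             ) -> tuple[float, float]:
    """Probe-tip error: distance between each projected tip and the known
    reference-marker centre on the HSI image; returns mean and sample sd (px)."""
    if not touch_events:
        raise ValueError("need at least one touch event")
    dists = []
    for pose, known_px in touch_events:
        tip = compute_probe_tip(pose, probe)
        pred, _ = project_biopsy_site(tip, rig)
        dists.append(np.hypot(pred.u - known_px.u, pred.v - known_px.v))
    dists = np.asarray(dists)
    sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    return float(np.mean(dists)), sd


def pixel_error_to_mm(err_px: float, pixel_size_mm: float) -> float:
    """Convert a pixel-domain error to millimetres on the specimen.

    The camera footprint must be given explicitly (0.12 mm/px for the RGB
    camera, 0.31 mm/px for the hyperspectral camera at 30 cm working
    distance).  Report at two decimals; full precision is the return value.
    """
    if err_px < 0:
        raise ValueError("pixel error must be non-negative")
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    return err_px * pixel_size_mm


# --- file formats -----------------------------------------------------------

def save_poses(path: str | Path, poses: list[MarkerPose]) -> None:
    doc = [{"event_id": i, "R": p.R_m.ravel().tolist(), "t": p.t_m.tolist()}
           for i, p in enumerate(poses)]
    Path(path).write_text(json.dumps(doc, indent=1))


def load_poses(path: str | Path) -> list[MarkerPose]:
    doc = json.loads(Path(path).read_text())
    return [MarkerPose(R_m=np.array(e["R"], dtype=float).reshape(3, 3),
                       t_m=np.array(e["t"], dtype=float)) for e in doc]


def save_probe(path: str | Path, probe: ProbeModel) -> None:
    Path(path).write_text(yaml.safe_dump({
        "R_probe": probe.R_probe.tolist(),
        "T_probe_mm": probe.T_probe.tolist(),
        "rms_residual_mm": float(probe.rms_residual),
    }, sort_keys=False))


def load_probe(path: str | Path) -> ProbeModel:
    doc = yaml.safe_load(Path(path).read_text())
    return ProbeModel(R_probe=np.array(doc["R_probe"]),
                      T_probe=np.array(doc["T_probe_mm"]),
                      rms_residual=float(doc["rms_residual_mm"]))


def save_sites_csv(path: str | Path, sites: list[BiopsySite]) -> None:
    import pandas as pd
    rows = [{
        "specimen_id": s.specimen_id, "site_id": s.site_id,
        "x": s.tip_3d.x, "y": s.tip_3d.y, "z": s.tip_3d.z,
        "u_hsi": s.hsi_pixel.u, "v_hsi": s.hsi_pixel.v,
        "label": s.pcle_label, "confidence": s.pcle_confidence,
        "in_view": s.in_view,
    } for s in sites]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sites_csv(path: str | Path) -> list[BiopsySite]:
    import pandas as pd
    df = pd.read_csv(path)
    return [BiopsySite(
        tip_3d=Point3D(r.x, r.y, r.z, "left"),
        hsi_pixel=Pixel(r.u_hsi, r.v_hsi),
        pcle_label=str(r.label), pcle_confidence=float(r.confidence),
        specimen_id=r.specimen_id, site_id=int(r.site_id),
        in_view=bool(r.in_view)) for r in df.itertuples()]
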
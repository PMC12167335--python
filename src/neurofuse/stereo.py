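"""Stereo geometry between the RGB (left) and hyperspectral (right) cameras.

The surgical camera emits a single side-by-side composite frame that is
split down the middle into the left/right views.  Stereo calibration from
checkerboard corner detections recovers each camera's intrinsics and the
rigid transform (R, T) linking the two; a point known in the left frame is
transferred with ``P_right = R @ P_left + T`` and projected onto the
hyperspectral image plane with the pinhole model.

Calibration is a two-stage estimator: closed-form initialisation from
per-view plane homographies (Zhang's method), followed by a joint
nonlinear refinement of intrinsics, per-view board poses and the relative
pose, minimising corner reprojection error in both cameras.

Conventions: pixel (0, 0) is the centre of the top-left pixel; camera
frames are right-handed with x right, y down, z forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

FRAMES = ("left", "right")


class BehindCamera(ValueError):
    """Projection requested for a point at or behind the image plane."""


class FrameError(ValueError):
    """A 3-D point carried the wrong camera-frame tag."""


class CalibrationDegenerateWarning(UserWarning):
    """Calibration geometry is ill-conditioned (e.g. coplanar board motion)."""


# --- domain types ---------------------------------------------------------

@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics with a 5-coefficient radial-tangential distortion."""

    K: np.ndarray                          # 3x3, fx fy cx cy in pixels
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.K.shape != (3, 3):
            raise ValueError("K must be 3x3")
        if self.K[0, 0] <= 0 or self.K[1, 1] <= 0:
            raise ValueError("focal lengths must be positive")
        if abs(self.K[2, 2] - 1.0) > 1e-12:
            raise ValueError("K[2,2] must be 1")
        if self.distortion.shape != (5,):
            raise ValueError("distortion must have 5 coefficients (k1 k2 p1 p2 k3)")

    @property
    def fx(self) -> float: return float(self.K[0, 0])
    @property
    def fy(self) -> float: return float(self.K[1, 1])
    @property
    def cx(self) -> float: return float(self.K[0, 2])
    @property
    def cy(self) -> float: return float(self.K[1, 2])


@dataclass
class StereoRig:
    """Left/right intrinsics plus the rotation/translation linking them (mm)."""

    left: CameraIntrinsics
    right: CameraIntrinsics
    R: np.ndarray
    T: np.ndarray
    rms_px: float | None = None           # calibration corner reprojection RMS

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det +1)")


@dataclass
class Point3D:
    """A 3-D point in millimetres, tagged with its camera frame."""

    x: float
    y: float
    z: float
    frame: str = "left"

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise FrameError(f"frame must be one of {FRAMES}, got {self.frame!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray, frame: str) -> "Point3D":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)


@dataclass
class Pixel:
    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


# --- elementary operations ------------------------------------------------

def split_stereo_composite(composite: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a side-by-side stereo composite into (left, right) half-frames."""
    composite = np.asarray(composite)
    if composite.ndim not in (2, 3):
        raise ValueError("composite must be a 2-D or 3-D image array")
    w = composite.shape[1]
    if w % 2 != 0:
        raise ValueError(f"composite width {w} is odd; cannot split down the middle")
    half = w // 2
    return composite[:, :half].copy(), composite[:, half:].copy()


def _distort(x: np.ndarray, y: np.ndarray, d: np.ndarray):
    k1, k2, p1, p2, k3 = d
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return xd, yd


def project_points(pts: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Vectorised pinhole projection of an (N, 3) array; returns (N, 2) pixels."""
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCamera("point(s) at or behind the camera (z <= 0)")
    x = pts[:, 0] / z
    y = pts[:, 1] / z
    if np.any(cam.distortion):
        x, y = _distort(x, y, cam.distortion)
    u = cam.fx * x + cam.cx
    v = cam.fy * y + cam.cy
    return np.column_stack([u, v])


def project_to_image(p: Point3D, cam: CameraIntrinsics) -> Pixel:
    """Project a 3-D camera-frame point onto the image plane (perspective
    division then intrinsics, distortion applied when coefficients are set)."""
    uv = project_points(p.as_array()[None, :], cam)[0]
    return Pixel(float(uv[0]), float(uv[1]))


def transform_left_to_right(p: Point3D, rig: StereoRig) -> Point3D:
    """Map a left-camera point into the right (hyperspectral) camera frame."""
    if p.frame != "left":
        raise FrameError(f"expected a left-frame point, got {p.frame!r}")
    return Point3D.from_array(rig.R @ p.as_array() + rig.T, "right")


def transform_right_to_left(p: Point3D, rig: StereoRig) -> Point3D:
    if p.frame != "right":
        raise FrameError(f"expected a right-frame point, got {p.frame!r}")
    return Point3D.from_array(rig.R.T @ (p.as_array() - rig.T), "left")


def reprojection_error(pred: list[Pixel] | np.ndarray,
                       truth: list[Pixel] | np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation of per-pair pixel distances."""
    pred = np.asarray([p.as_array() if isinstance(p, Pixel) else p for p in pred],
                      dtype=float).reshape(-1, 2)
    truth = np.asarray([p.as_array() if isinstance(p, Pixel) else p for p in truth],
                       dtype=float).reshape(-1, 2)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal lengths")
    if pred.shape[0] == 0:
        raise ValueError("need at least one pixel pair")
    d = np.linalg.norm(pred - truth, axis=1)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(np.mean(d)), sd


# --- checkerboard geometry ------------------------------------------------

@dataclass
class BoardSpec:
    """Inner-corner grid of a planar checkerboard: rows x cols corners,
    square edge in millimetres."""

    rows: int
    cols: int
    square_mm: float

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2 or self.square_mm <= 0:
            raise ValueError("board needs >= 2x2 corners and a positive square size")

    def object_points(self) -> np.ndarray:
        """Corner coordinates in the board plane (z = 0), row-major."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        pts = np.zeros((self.rows * self.cols, 3))
        pts[:, 0] = jj.ravel() * self.square_mm
        pts[:, 1] = ii.ravel() * self.square_mm
        return pts

    @classmethod
    def parse(cls, text: str) -> "BoardSpec":
        """Parse a '9x6x10' style rows x cols x square_mm string."""
        parts = text.lower().split("x")
        if len(parts) != 3:
            raise ValueError("board spec must look like ROWSxCOLSxSQUARE_MM")
        return cls(int(parts[0]), int(parts[1]), float(parts[2]))


# --- Zhang initialisation -------------------------------------------------

def _homography_dlt(obj_xy: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Plane-to-image homography with Hartley normalisation."""
    def normalise(pts):
        c = pts.mean(axis=0)
        s = np.sqrt(2) / np.mean(np.linalg.norm(pts - c, axis=1))
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return ph, T

    src, Ts = normalise(obj_xy)
    dst, Td = normalise(img)
    n = len(obj_xy)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = src
    A[0::2, 6:9] = -dst[:, 0:1] * src
    A[1::2, 3:6] = src
    A[1::2, 6:9] = -dst[:, 1:2] * src
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise np.linalg.LinAlgError("degenerate homography scale")
    return H / H[2, 2]


def _v_ij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array([
        H[0, i] * H[0, j],
        H[0, i] * H[1, j] + H[1, i] * H[0, j],
        H[1, i] * H[1, j],
        H[2, i] * H[0, j] + H[0, i] * H[2, j],
        H[2, i] * H[1, j] + H[1, i] * H[2, j],
        H[2, i] * H[2, j],
    ])


def _focal_from_homographies(Hs: list[np.ndarray], cx: float, cy: float) -> float:
    """Median focal estimate with a fixed principal point (robust fallback
    for near-degenerate board motion, e.g. telephoto narrow-FOV optics)."""
    f2s = []
    for H in Hs:
        a1 = np.array([H[0, 0] - cx * H[2, 0], H[1, 0] - cy * H[2, 0]])
        a2 = np.array([H[0, 1] - cx * H[2, 1], H[1, 1] - cy * H[2, 1]])
        b1, b2 = H[2, 0], H[2, 1]
        if abs(b1 * b2) > 1e-12:
            f2 = -(a1 @ a2) / (b1 * b2)
            if f2 > 0:
                f2s.append(f2)
        if abs(b2 ** 2 - b1 ** 2) > 1e-12:
            f2 = (a1 @ a1 - a2 @ a2) / (b2 ** 2 - b1 ** 2)
            if f2 > 0:
                f2s.append(f2)
    if not f2s:
        raise np.linalg.LinAlgError("no usable focal constraint")
    return float(np.sqrt(np.median(f2s)))


def _intrinsics_from_homographies(Hs: list[np.ndarray],
                                  corner_centroid: np.ndarray) -> np.ndarray:
    """Closed-form K (zero skew enforced) from >= 3 plane homographies.

    Solves Zhang's absolute-conic system; when the board motion leaves it
    ill-conditioned, falls back to a focal-only estimate anchored at the
    observed corner centroid.  Either way the result is only an initial
    value for the joint bundle refinement.
    """
    V = []
    for H in Hs:
        V.append(_v_ij(H, 0, 1))
        V.append(_v_ij(H, 0, 0) - _v_ij(H, 1, 1))
    # zero-skew constraint: B12 = 0
    V.append([0, 1, 0, 0, 0, 0])
    V = np.asarray(V)
    _, _, vt = np.linalg.svd(V)
    b = vt[-1]
    B = np.array([[b[0], b[1], b[2]],
                  [b[1], b[3], b[4]],
                  [b[2], b[4], b[5]]])
    if B[0, 0] < 0:
        B = -B
    try:
        L = np.linalg.cholesky(B)          # B = K^-T K^-1 (up to scale)
        K = np.linalg.inv(L.T)
        K = K / K[2, 2]
        if not np.all(np.isfinite(K)) or K[0, 0] <= 0 or K[1, 1] <= 0:
            raise np.linalg.LinAlgError("invalid intrinsics")
        K[0, 1] = 0.0                      # enforce zero skew exactly
        return K
    except np.linalg.LinAlgError:
        cx, cy = corner_centroid
        f = _focal_from_homographies(Hs, cx, cy)
        return np.array([[f, 0, cx], [0, f, cy], [0, 0, 1]])


def _pose_from_homography(H: np.ndarray, K: np.ndarray):
    if not np.all(np.isfinite(H)):
        raise np.linalg.LinAlgError("degenerate homography")
    M = np.linalg.inv(K) @ H
    lam = 1.0 / np.linalg.norm(M[:, 0])
    if M[2, 2] * lam < 0:       # board must sit in front of the camera
        lam = -lam
    r1 = lam * M[:, 0]
    r2 = lam * M[:, 1]
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1, 1, -1]) @ Vt
    t = lam * M[:, 2]
    return R, t


def _mean_rotation(Rs: list[np.ndarray]) -> np.ndarray:
    quats = np.array([Rotation.from_matrix(R).as_quat() for R in Rs])
    # align hemispheres, then eigenvector mean
    quats[quats @ quats[0] < 0] *= -1
    _, vecs = np.linalg.eigh(quats.T @ quats)
    return Rotation.from_quat(vecs[:, -1]).as_matrix()


def rotation_angle_between(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic (axis-angle) distance between two rotations, radians."""
    return float(np.linalg.norm(Rotation.from_matrix(Ra.T @ Rb).as_rotvec()))


# --- joint stereo calibration --------------------------------------------

def calibrate_stereo(left_views: list[np.ndarray], right_views: list[np.ndarray],
                     board: BoardSpec) -> tuple[StereoRig, float]:
    """Calibrate the two-camera rig from paired checkerboard corner sets.

    Each view is an (n_corners, 2) pixel array ordered row-major to match
    :meth:`BoardSpec.object_points`.  Returns the rig and the pooled corner
    reprojection RMS (pixels, over both cameras).
    """
    if len(left_views) != len(right_views):
        raise ValueError("left and right view lists must have equal length")
    n_views = len(left_views)
    if n_views < 3:
        raise ValueError(f"need >= 3 views for calibration, got {n_views}")
    obj = board.object_points()
    n_pts = obj.shape[0]
    left_views = [np.asarray(v, dtype=float).reshape(n_pts, 2) for v in left_views]
    right_views = [np.asarray(v, dtype=float).reshape(n_pts, 2) for v in right_views]

    # stage 1: Zhang closed form per camera
    Hs_l = [_homography_dlt(obj[:, :2], v) for v in left_views]
    Hs_r = [_homography_dlt(obj[:, :2], v) for v in right_views]
    K_l = _intrinsics_from_homographies(Hs_l, np.mean(left_views, axis=(0, 1)))
    K_r = _intrinsics_from_homographies(Hs_r, np.mean(right_views, axis=(0, 1)))
    poses_l = [_pose_from_homography(H, K_l) for H in Hs_l]
    poses_r = [_pose_from_homography(H, K_r) for H in Hs_r]

    # conditioning diagnostic: board orientations must span rotation space
    rvecs = np.array([Rotation.from_matrix(R).as_rotvec() for R, _ in poses_l])
    sv = np.linalg.svd(rvecs - rvecs.mean(axis=0), compute_uv=False)
    cond = sv[0] / max(sv[1], 1e-300) if len(sv) > 1 else np.inf
    if sv[1] < 1e-3 * max(sv[0], 1.0):
        warnings.warn(
            f"checkerboard motion is nearly coplanar (orientation spread "
            f"condition {cond:.2e}); calibration may be ill-conditioned",
            CalibrationDegenerateWarning)

    rel_Rs = [Rr @ Rl.T for (Rl, _), (Rr, _) in zip(poses_l, poses_r)]
    rel_ts = [tr - Rrel @ tl
              for Rrel, (Rl, tl), (Rr, tr) in zip(rel_Rs, poses_l, poses_r)]
    R0 = _mean_rotation(rel_Rs)
    T0 = np.mean(rel_ts, axis=0)

    # stage 2: joint bundle refinement
    x0 = np.concatenate([
        [K_l[0, 0], K_l[1, 1], K_l[0, 2], K_l[1, 2]],
        [K_r[0, 0], K_r[1, 1], K_r[0, 2], K_r[1, 2]],
        Rotation.from_matrix(R0).as_rotvec(), T0,
        np.concatenate([np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
                        for R, t in poses_l]),
    ])
    obs = np.concatenate([np.concatenate([l.ravel(), r.ravel()])
                          for l, r in zip(left_views, right_views)])

    def unpack(x):
        kl = CameraIntrinsics(np.array([[x[0], 0, x[2]], [0, x[1], x[3]], [0, 0, 1]]))
        kr = CameraIntrinsics(np.array([[x[4], 0, x[6]], [0, x[5], x[7]], [0, 0, 1]]))
        Rrel = Rotation.from_rotvec(x[8:11]).as_matrix()
        Trel = x[11:14]
        poses = []
        for i in range(n_views):
            s = 14 + 6 * i
            poses.append((Rotation.from_rotvec(x[s:s + 3]).as_matrix(), x[s + 3:s + 6]))
        return kl, kr, Rrel, Trel, poses

    def _project_flat(pts, fx, fy, cx, cy):
        z = np.maximum(pts[..., 2], 1e-9)   # keep finite during line search
        return np.stack([fx * pts[..., 0] / z + cx,
                         fy * pts[..., 1] / z + cy], axis=-1)

    def residuals(x):
        Rrel = Rotation.from_rotvec(x[8:11]).as_matrix()
        Trel = x[11:14]
        pv = x[14:].reshape(n_views, 6)
        Rl = Rotation.from_rotvec(pv[:, :3]).as_matrix()    # (V, 3, 3)
        pl = np.einsum("vij,pj->vpi", Rl, obj) + pv[:, None, 3:]
        pr = pl @ Rrel.T + Trel
        uv_l = _project_flat(pl, x[0], x[1], x[2], x[3])
        uv_r = _project_flat(pr, x[4], x[5], x[6], x[7])
        out = np.concatenate([uv_l.reshape(n_views, -1),
                              uv_r.reshape(n_views, -1)], axis=1)
        return out.ravel() - obs

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=400)
    kl, kr, Rrel, Trel, _ = unpack(sol.x)
    per_corner = sol.fun.reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(per_corner ** 2, axis=1))))
    rig = StereoRig(left=kl, right=kr, R=Rrel, T=Trel, rms_px=rms)
    return rig, rms


# --- file formats ---------------------------------------------------------

def save_rig(path: str | Path, rig: StereoRig, board: BoardSpec | None = None) -> None:
    """Write the rig to YAML; round-trips bit-exactly via full-precision reprs."""
    doc = {
        "K_left": rig.left.K.tolist(),
        "K_right": rig.right.K.tolist(),
        "distortion_left": rig.left.distortion.tolist(),
        "distortion_right": rig.right.distortion.tolist(),
        "R": rig.R.tolist(),
        "T_mm": rig.T.tolist(),
        "rms_px": None if rig.rms_px is None else float(rig.rms_px),
    }
    if board is not None:
        doc["board"] = {"rows": board.rows, "cols": board.cols,
                        "square_mm": board.square_mm}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_rig(path: str | Path) -> StereoRig:
    doc = yaml.safe_load(Path(path).read_text())
    return StereoRig(
        left=CameraIntrinsics(np.array(doc["K_left"]),
                              np.array(doc.get("distortion_left", np.zeros(5)))),
        right=CameraIntrinsics(np.array(doc["K_right"]),
                               np.array(doc.get("distortion_right", np.zeros(5)))),
        R=np.array(doc["R"]), T=np.array(doc["T_mm"]),
        rms_px=doc.get("rms_px"))


def load_corner_csv(path: str | Path) -> dict[int, np.ndarray]:
    """Read corner sets from CSV (view_id, corner_id, u, v[, camera])."""
    import pandas as pd
    df = pd.read_csv(path)
    views = {}
    for vid, grp in df.groupby("view_id"):
        grp = grp.sort_values("corner_id")
        views[int(vid)] = grp[["u", "v"]].to_numpy(dtype=float)
    return views
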
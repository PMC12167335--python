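"""Synthetic multimodal phantom generator.

Emulates an ex vivo brain-phantom study: five specimens imaged by a
275 x 290-pixel, 51-band (450-850 nm) hyperspectral camera and a stereo RGB
camera, each specimen carrying one injected fluorescent "tumor" blob
(exposed size 5-17.6 mm) surrounded by healthy tissue on a dark background,
with 15-20 tracked optical-biopsy sites around the tumor margin.

Everything is generated from one root seed through per-purpose child
streams (``numpy`` ``spawn_key`` splitting), so a dataset is byte-identical
across runs.  The white/dark reference cubes are constructed so radiometric
calibration recovers the designed reflectance to numerical precision, and
biopsy-site geometry closes exactly: projecting the stored 3-D tip through
the stored rig reproduces the stored HSI pixel.

The generator also plants configurable "satellite" blobs whose spectra look
like tumor but whose ground truth is healthy — the over-prediction pattern
that motivates connected-component filtering in the fusion stage.

Deliberate simplifications: spectra are i.i.d. around smooth class means
(no spatial correlation, no illumination drift), textures are parametric
blob/speckle fields rather than cellular imagery, and specimen anatomy is a
smooth ellipse.  Results on this phantom demonstrate algorithmic
correctness, not clinical performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from scipy.spatial.transform import Rotation

from .calibration import RawCube, ReflectanceCube
from .classify import LabeledPCLEImage
from .fusion import BG, HEALTHY, TUMOR
from .probe import BiopsySite, MarkerPose, ProbeModel
from .stereo import BoardSpec, CameraIntrinsics, Pixel, Point3D, StereoRig, \
    project_points
from .probe import compute_probe_tip, project_biopsy_site


# --- configuration ----------------------------------------------------------

def default_rig() -> StereoRig:
    """A plausible microscope rig: RGB half-frame on the left (0.12 mm/px at
    30 cm -> f = 2500 px), hyperspectral on the right (0.31 mm/px -> ~968 px),
    a small baseline and a slight convergence angle."""
    left = CameraIntrinsics(np.array([[2500.0, 0, 479.5],
                                      [0, 2500.0, 539.5],
                                      [0, 0, 1]]))
    right = CameraIntrinsics(np.array([[968.0, 0, 144.5],
                                       [0, 968.0, 137.0],
                                       [0, 0, 1]]))
    R = Rotation.from_rotvec([0.0, np.deg2rad(2.0), 0.0]).as_matrix()
    T = np.array([25.0, 2.0, 5.0])
    return StereoRig(left=left, right=right, R=R, T=T)


def default_probe() -> ProbeModel:
    """Marker-to-tip offset of a hand-held probe (~120 mm shaft)."""
    return ProbeModel(R_probe=np.eye(3), T_probe=np.array([5.0, -3.0, 120.0]))


#: Per-class reflectance means: sums of Gaussians over wavelength.  Each row
#: of deviations is scaled by ``class_separation`` so separability can be
#: collapsed to chance in controls.
_BASE_CURVE = [(0.25, 550.0, 80.0), (0.15, 700.0, 90.0)]
_CLASS_DEVIATIONS = {
    BG: [(-0.15, 600.0, 150.0)],                       # dark drape/table
    HEALTHY: [(0.20, 560.0, 40.0), (0.10, 640.0, 50.0)],
    TUMOR: [(0.25, 520.0, 35.0), (-0.10, 680.0, 60.0)],
}


def class_mean_spectra(band_centers_nm: np.ndarray,
                       class_separation: float = 1.0) -> np.ndarray:
    """(3, bands) smooth mean reflectance curves for BG/healthy/tumor."""
    wl = np.asarray(band_centers_nm, dtype=float)
    base = sum(a * np.exp(-0.5 * ((wl - mu) / s) ** 2) for a, mu, s in _BASE_CURVE)
    out = np.zeros((3, wl.size))
    for cls, devs in _CLASS_DEVIATIONS.items():
        dev = sum(a * np.exp(-0.5 * ((wl - mu) / s) ** 2) for a, mu, s in devs)
        out[cls] = np.clip(base + class_separation * dev, 0.02, 0.95)
    return out


@dataclass
class PhantomConfig:
    n_specimens: int = 5
    image_shape: tuple[int, int] = (275, 290)       # HSI rows x cols
    n_bands: int = 51
    band_range_nm: tuple[float, float] = (450.0, 850.0)
    noise_sd: float = 0.02                          # reflectance noise
    class_separation: float = 1.0                   # 0 collapses classes
    tumor_size_mm: tuple[float, float] = (5.0, 17.6)
    pixel_size_mm: float = 0.31
    n_biopsy_sites: tuple[int, int] = (15, 20)
    satellite_fp_blobs: int = 2
    n_spectra_per_specimen: int = 4000
    spectra_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    pcle_image_size: int = 64
    n_pcle_healthy: int = 24
    n_pcle_core: int = 24
    dark_level_dn: float = 100.0
    white_gain_dn: float = 3000.0
    working_distance_mm: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1 or self.n_bands < 2:
            raise ValueError("need >= 1 specimen and >= 2 bands")
        if self.tumor_size_mm[0] >= self.tumor_size_mm[1]:
            raise ValueError("tumor_size_mm range is degenerate")
        if self.n_biopsy_sites[0] > self.n_biopsy_sites[1] or self.n_biopsy_sites[0] < 1:
            raise ValueError("n_biopsy_sites range invalid")
        if self.noise_sd < 0 or self.class_separation < 0:
            raise ValueError("noise and separation must be >= 0")

    @property
    def band_centers_nm(self) -> np.ndarray:
        return np.linspace(*self.band_range_nm, self.n_bands)


@dataclass
class Specimen:
    specimen_id: int
    raw: RawCube
    white: RawCube
    dark: RawCube
    designed_reflectance: np.ndarray     # rows x cols x bands, ground truth
    gt_labels: np.ndarray                # rows x cols in {BG, HEALTHY, TUMOR}
    spectral_class_map: np.ndarray       # gt + satellite blobs flipped to tumor
    spectra: tuple[np.ndarray, np.ndarray]   # (X: N x bands, y: N codes), raw-band
    pcle_images: list[LabeledPCLEImage]  # healthy + core (training pool)
    sites: list[BiopsySite]              # margin sampling events
    site_images: list[LabeledPCLEImage]  # one margin scan per site
    site_poses: list[MarkerPose]         # true marker pose per site


@dataclass
class PhantomDataset:
    config: PhantomConfig
    rig: StereoRig
    probe: ProbeModel
    specimens: list[Specimen] = field(default_factory=list)


def _child(seed: int, *key: int) -> np.random.Generator:
    """Independent child stream: root seed plus a structural spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _smooth_noise(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    return f / (np.abs(f).max() + 1e-12)


def _make_label_map(cfg: PhantomConfig, rng) -> tuple[np.ndarray, np.ndarray, float]:
    """Ground-truth labels, spectral-class map (with satellites), tumor radius px."""
    h, w = cfg.image_shape
    yy, xx = np.mgrid[:h, :w]
    cy, cx = h / 2 + rng.uniform(-8, 8), w / 2 + rng.uniform(-8, 8)
    # specimen body: wobbly ellipse covering roughly half the frame
    ay, ax = h * rng.uniform(0.30, 0.36), w * rng.uniform(0.30, 0.36)
    body_field = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    body = body_field + 0.25 * _smooth_noise(rng, (h, w), 18) < 1.0

    labels = np.full((h, w), BG, dtype=np.int64)
    labels[body] = HEALTHY

    # tumor blob: smooth bump inside the body, size drawn in millimetres
    size_mm = rng.uniform(*cfg.tumor_size_mm)
    r_px = size_mm / 2.0 / cfg.pixel_size_mm
    tcy = cy + rng.uniform(-0.25, 0.25) * ay
    tcx = cx + rng.uniform(-0.25, 0.25) * ax
    d2 = (yy - tcy) ** 2 + (xx - tcx) ** 2
    bump = np.exp(-0.5 * d2 / (r_px / 1.18) ** 2) * \
        (1.0 + 0.25 * _smooth_noise(rng, (h, w), 6))
    tumor = (bump > 0.5) & body
    labels[tumor] = TUMOR

    # satellite false positives: healthy ground truth, tumor-like spectra
    spectral = labels.copy()
    healthy_far = (labels == HEALTHY) & (d2 > (3.0 * r_px) ** 2)
    cand = np.argwhere(healthy_far)
    for _ in range(cfg.satellite_fp_blobs):
        if len(cand) == 0:
            break
        sy, sx = cand[rng.integers(len(cand))]
        sr = rng.uniform(2.0, 4.5)
        blob = ((yy - sy) ** 2 + (xx - sx) ** 2 <= sr ** 2) & (labels == HEALTHY)
        spectral[blob] = TUMOR
    return labels, spectral, r_px


def render_pcle_textures(class_name: str, n_images: int, *, size: int = 64,
                         seed: int = 0, mixing_fraction: float = 0.5,
                         rng: np.random.Generator | None = None
                         ) -> list[np.ndarray]:
    """Parametric probe textures on a 0-255 intensity scale.

    Fluorescent (tumor) scans are bright blob fields on a dark ground;
    healthy scans are low-intensity speckle; margin scans blend the two
    across a smooth boundary with the given mixing fraction.
    """
    if class_name not in ("healthy", "tumor", "margin"):
        raise ValueError("class_name must be healthy/tumor/margin")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        if class_name == "margin":
            t = _tumor_texture(rng, size)
            hth = _healthy_texture(rng, size)
            edge = gaussian_filter(rng.standard_normal((size, size)), size / 4)
            thresh = np.quantile(edge, 1.0 - mixing_fraction)
            img = np.where(edge > thresh, t, hth)
        elif class_name == "tumor":
            img = _tumor_texture(rng, size)
        else:
            img = _healthy_texture(rng, size)
        out.append(np.clip(img, 0, 255))
    return out


def _tumor_texture(rng, size):
    yy, xx = np.mgrid[:size, :size]
    img = np.full((size, size), 12.0)
    for _ in range(rng.integers(6, 13)):
        by, bx = rng.uniform(0, size, 2)
        s = rng.uniform(2.5, 7.0)
        img += rng.uniform(120, 220) * np.exp(
            -0.5 * ((yy - by) ** 2 + (xx - bx) ** 2) / s ** 2)
    img += rng.normal(0, 4, (size, size))
    return img


def _healthy_texture(rng, size):
    speckle = gaussian_filter(rng.standard_normal((size, size)), 1.0)
    img = 18.0 + 10.0 * np.abs(speckle) + rng.normal(0, 3, (size, size))
    return img


def _generate_specimen(cfg: PhantomConfig, rig: StereoRig, probe: ProbeModel,
                       spec_id: int, seed: int,
                       include_cubes: bool = True) -> Specimen:
    wl = cfg.band_centers_nm
    means = class_mean_spectra(wl, cfg.class_separation)
    h, w = cfg.image_shape

    rng_geom = _child(seed, spec_id, 0)
    rng_cube = _child(seed, spec_id, 1)
    rng_ref = _child(seed, spec_id, 2)
    rng_pcle = _child(seed, spec_id, 3)
    rng_sites = _child(seed, spec_id, 4)
    rng_pool = _child(seed, spec_id, 5)

    gt, spectral_map, r_px = _make_label_map(cfg, rng_geom)

    if include_cubes:
        designed = means[spectral_map] + rng_cube.normal(0, cfg.noise_sd,
                                                         (h, w, wl.size))
        designed = np.clip(designed, 0.0, 1.2)

        # reference cubes: spatially varying but strictly positive denominator
        dark = cfg.dark_level_dn * \
            (1.0 + 0.05 * _smooth_noise(rng_ref, (h, w), 30))[..., None] \
            * np.ones(wl.size)
        gain = cfg.white_gain_dn * \
            (1.0 + 0.10 * _smooth_noise(rng_ref, (h, w), 40))[..., None] \
            * (0.8 + 0.4 * np.linspace(0, 1, wl.size))
        white = dark + gain
        raw = dark + designed * gain
    else:   # label maps, spectra pools and sites only (geometry unaffected)
        designed = np.zeros((h, w, 0))
        raw = white = dark = None

    # labelled spectrum pool, drawn i.i.d. from the class models
    n = cfg.n_spectra_per_specimen
    counts = np.round(np.asarray(cfg.spectra_proportions) * n).astype(int)
    Xs, ys = [], []
    for cls, cnt in zip((BG, HEALTHY, TUMOR), counts):
        Xs.append(means[cls] + rng_pool.normal(0, cfg.noise_sd, (cnt, wl.size)))
        ys.append(np.full(cnt, cls))
    X = np.concatenate(Xs)
    y = np.concatenate(ys)

    # training-pool probe scans (healthy regions and tumor core)
    pcle = [LabeledPCLEImage(im, "healthy", "healthy", spec_id)
            for im in render_pcle_textures("healthy", cfg.n_pcle_healthy,
                                           size=cfg.pcle_image_size, rng=rng_pcle)]
    pcle += [LabeledPCLEImage(im, "tumor", "core", spec_id)
             for im in render_pcle_textures("tumor", cfg.n_pcle_core,
                                            size=cfg.pcle_image_size, rng=rng_pcle)]

    # margin biopsy sites: pixels in a band around the tumor boundary
    tumor_mask = gt == TUMOR
    band = binary_dilation(tumor_mask, iterations=4) & \
        ~binary_erosion(tumor_mask, iterations=3)
    cand = np.argwhere(band)
    n_sites = int(rng_sites.integers(cfg.n_biopsy_sites[0],
                                     cfg.n_biopsy_sites[1] + 1))
    picks = cand[rng_sites.choice(len(cand), size=min(n_sites, len(cand)),
                                  replace=False)]
    # guarantee at least one site on true tumor tissue
    if not any(tumor_mask[py, px] for py, px in picks) and tumor_mask.any():
        inside = np.argwhere(tumor_mask)
        picks[0] = inside[rng_sites.integers(len(inside))]

    sites, site_images, site_poses = [], [], []
    Kinv = np.linalg.inv(rig.right.K)
    for i, (py, px) in enumerate(picks):
        depth = cfg.working_distance_mm * rng_sites.uniform(0.97, 1.03)
        p_right = depth * (Kinv @ np.array([float(px), float(py), 1.0]))
        tip = Point3D.from_array(rig.R.T @ (p_right - rig.T), "left")
        R_m = Rotation.random(random_state=rng_sites).as_matrix()
        t_m = tip.as_array() - R_m @ probe.T_probe
        pose = MarkerPose(R_m=R_m, t_m=t_m)
        # store the tip as reproduced by the pose chain so the stored pixel,
        # tip and pose are mutually consistent to the last bit
        tip = compute_probe_tip(pose, probe)
        pixel, in_view = project_biopsy_site(tip, rig,
                                             image_shape=cfg.image_shape)
        true_cls = "tumor" if tumor_mask[py, px] else "healthy"
        sites.append(BiopsySite(tip_3d=tip, hsi_pixel=pixel, pcle_label=true_cls,
                                pcle_confidence=1.0, specimen_id=spec_id,
                                site_id=i, in_view=in_view))
        site_poses.append(pose)
        tex = render_pcle_textures(true_cls, 1, size=cfg.pcle_image_size,
                                   rng=rng_sites)[0]
        site_images.append(LabeledPCLEImage(tex, true_cls, "margin", spec_id))

    if include_cubes:
        cubes = (RawCube(raw, wl), RawCube(white, wl), RawCube(dark, wl))
    else:
        cubes = (None, None, None)
    return Specimen(
        specimen_id=spec_id,
        raw=cubes[0], white=cubes[1], dark=cubes[2],
        designed_reflectance=designed, gt_labels=gt,
        spectral_class_map=spectral_map, spectra=(X, y),
        pcle_images=pcle, sites=sites, site_images=site_images,
        site_poses=site_poses)


def generate_phantom(cfg: PhantomConfig | None = None,
                     include_cubes: bool = True) -> PhantomDataset:
    """Generate the full multi-specimen dataset; deterministic per seed.

    ``include_cubes=False`` skips the raw/white/dark cube synthesis (the
    bulk of the data) while producing identical label maps, spectrum pools,
    probe textures and biopsy-site geometry — each content type draws from
    its own child random stream.
    """
    cfg = cfg or PhantomConfig()
    rig = default_rig()
    probe = default_probe()
    specimens = [_generate_specimen(cfg, rig, probe, k, cfg.seed, include_cubes)
                 for k in range(cfg.n_specimens)]
    return PhantomDataset(config=cfg, rig=rig, probe=probe, specimens=specimens)


# --- geometric fixtures -----------------------------------------------------

def render_checkerboard_views(rig: StereoRig, board: BoardSpec, n_views: int,
                              noise_sd_px: float = 0.0, seed: int = 0,
                              image_shape_left: tuple[int, int] = (1080, 960),
                              image_shape_right: tuple[int, int] = (275, 290),
                              max_retries: int = 2000
                              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact pinhole projections of checkerboard poses visible in both
    cameras, plus optional Gaussian corner noise."""
    rng = np.random.default_rng(seed)
    obj = board.object_points()
    centre = obj.mean(axis=0)
    left_views, right_views = [], []
    tries = 0
    while len(left_views) < n_views:
        tries += 1
        if tries > max_retries:
            raise RuntimeError("could not sample a visible checkerboard pose")
        Rb = Rotation.from_rotvec(rng.normal(0, 0.18, 3)).as_matrix()
        # aim the board centre at the right (narrow-FOV) camera's optical
        # axis, where the two frusta overlap, with a little jitter
        depth = rng.uniform(300, 430)
        axis_pt_right = np.array([0.0, 0.0, depth])
        target = rig.R.T @ (axis_pt_right - rig.T) + rng.uniform(-12, 12, 3)
        tb = target - Rb @ centre
        pts_l = obj @ Rb.T + tb
        if np.any(pts_l[:, 2] <= 1.0):
            continue
        pts_r = pts_l @ rig.R.T + rig.T
        if np.any(pts_r[:, 2] <= 1.0):
            continue
        uv_l = project_points(pts_l, rig.left)
        uv_r = project_points(pts_r, rig.right)
        hl, wl_ = image_shape_left
        hr, wr = image_shape_right
        if not (np.all((uv_l[:, 0] > 2) & (uv_l[:, 0] < wl_ - 3)
                       & (uv_l[:, 1] > 2) & (uv_l[:, 1] < hl - 3))
                and np.all((uv_r[:, 0] > 2) & (uv_r[:, 0] < wr - 3)
                           & (uv_r[:, 1] > 2) & (uv_r[:, 1] < hr - 3))):
            continue
        if noise_sd_px > 0:
            uv_l = uv_l + rng.normal(0, noise_sd_px, uv_l.shape)
            uv_r = uv_r + rng.normal(0, noise_sd_px, uv_r.shape)
        left_views.append(uv_l)
        right_views.append(uv_r)
    return left_views, right_views


def simulate_pivot_sequence(probe: ProbeModel, n_poses: int,
                            noise_sd_mm: float = 0.0, seed: int = 0,
                            pivot_point: np.ndarray | None = None,
                            single_axis: bool = False) -> list[MarkerPose]:
    """Marker poses of a probe rotating about its stationary tip.

    Noiseless sequences satisfy ``R_i @ T_probe + t_i = p`` exactly;
    ``single_axis`` restricts rotation to one axis (a designed degeneracy
    for conditioning tests).
    """
    if n_poses < 3:
        raise ValueError("need >= 3 poses")
    rng = np.random.default_rng(seed)
    p = np.array([0.0, 0.0, 300.0]) if pivot_point is None else \
        np.asarray(pivot_point, dtype=float)
    poses = []
    for _ in range(n_poses):
        if single_axis:
            R = Rotation.from_rotvec([0, 0, rng.uniform(0, 2 * np.pi)]).as_matrix()
        else:
            R = Rotation.random(random_state=rng).as_matrix()
        t = p - R @ probe.T_probe
        if noise_sd_mm > 0:
            t = t + rng.normal(0, noise_sd_mm, 3)
        poses.append(MarkerPose(R_m=R, t_m=t))
    return poses


# --- dataset directory layout ----------------------------------------------

_PALETTE = [0, 0, 0, 0, 255, 0, 255, 0, 0]   # black / green / red


def write_dataset(dataset: PhantomDataset, out_dir: str | Path) -> None:
    """Write the directory layout consumed by the training CLI:
    ``specimen_<k>/{hsi.hdr, hsi.raw, white.hdr, dark.hdr, annotation.png,
    pcle/<region>_<i>.png, sites.csv}`` plus a manifest."""
    from PIL import Image
    from . import envi
    from .probe import save_sites_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in dataset.specimens:
        d = out / f"specimen_{sp.specimen_id}"
        (d / "pcle").mkdir(parents=True, exist_ok=True)
        envi.write_envi(d / "hsi.hdr", sp.raw.data, sp.raw.band_centers_nm)
        envi.write_envi(d / "white.hdr", sp.white.data, sp.white.band_centers_nm)
        envi.write_envi(d / "dark.hdr", sp.dark.data, sp.dark.band_centers_nm)
        img = Image.fromarray(sp.gt_labels.astype(np.uint8), mode="P")
        img.putpalette(_PALETTE)
        img.save(d / "annotation.png")
        counters: dict[str, int] = {}
        for im in sp.pcle_images + sp.site_images:
            i = counters.get(im.region, 0)
            counters[im.region] = i + 1
            Image.fromarray(np.clip(im.image, 0, 255).astype(np.uint8)).save(
                d / "pcle" / f"{im.region}_{i}.png")
        save_sites_csv(d / "sites.csv", sp.sites)
    manifest = {
        "n_specimens": dataset.config.n_specimens,
        "seed": dataset.config.seed,
        "image_shape": list(dataset.config.image_shape),
        "n_bands": dataset.config.n_bands,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
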
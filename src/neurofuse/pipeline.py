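"""End-to-end orchestration: calibrate, train, classify, project, fuse, score.

One run reproduces the four-variant comparison — HSI alone, pCLE alone,
HSI with largest-component filtering (HSI LCC), and the fused HSI+pCLE —
under leave-one-specimen-out cross-validation, on a synthetic phantom
dataset or any dataset exposing the same in-memory structure.

The probe-only variant is scored as the rasterised tumor-labelled biopsy
sites (disc radius from :class:`~neurofuse.fusion.FusionConfig`) against
the ground-truth tumor mask; since the probe samples discrete points it is
scored for the tumor class only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .calibration import restrict_bands, white_dark_calibrate
from .classify import (ClassifierSpec, classify_cube, classify_pcle,
                       make_loso_folds, train_pcle_classifier,
                       train_spectral_classifier, undersample_indices)
from .fusion import (TUMOR, FusionConfig, hsi_lcc_baseline, logical_or_fusion,
                     pcle_informed_lcc, rasterize_sites)
from .metrics import (aggregate_fold_reports, classification_report,
                      crossfold_aggregate, dice, recall, segmentation_report)
from .phantom import (PhantomDataset, render_checkerboard_views,
                      simulate_pivot_sequence)
from .probe import (BiopsySite, compute_probe_tip, pivot_calibrate,
                    project_biopsy_site)
from .stereo import BoardSpec, calibrate_stereo

logger = logging.getLogger(__name__)

VARIANTS = ("HSI", "pCLE", "HSI_LCC", "HSI+pCLE")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    spectral_family: str = "mlp"
    pcle_family: str = "cnn_small"
    cutoff_nm: float = 770.0
    fusion: FusionConfig = field(default_factory=FusionConfig)
    calibrate_geometry: bool = True      # recover rig/probe from rendered data
    n_checkerboard_views: int = 30
    board: tuple[int, int, float] = (6, 9, 10.0)
    corner_noise_px: float = 0.1
    n_pivot_poses: int = 20
    pivot_noise_mm: float = 0.05
    seed: int = 0


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:   # noqa: BLE001 - re-tagged with stage
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("geometry_calibration")
def _estimate_geometry(dataset: PhantomDataset, cfg: RunConfig):
    if not cfg.calibrate_geometry:
        return dataset.rig, dataset.probe, {}
    board = BoardSpec(*cfg.board)
    # board views are bounded by the full sensor extents implied by the rig
    # intrinsics, regardless of any cropped dataset frame
    lv, rv = render_checkerboard_views(
        dataset.rig, board, cfg.n_checkerboard_views,
        noise_sd_px=cfg.corner_noise_px, seed=cfg.seed)
    rig, rms = calibrate_stereo(lv, rv, board)
    poses = simulate_pivot_sequence(dataset.probe, cfg.n_pivot_poses,
                                    noise_sd_mm=cfg.pivot_noise_mm,
                                    seed=cfg.seed + 1)
    probe, _pivot = pivot_calibrate(poses)
    diag = {"stereo_rms_px": rms, "pivot_rms_mm": probe.rms_residual}
    return rig, probe, diag


@_stage("site_projection")
def _project_sites(specimen, rig, probe, image_shape) -> list[BiopsySite]:
    """Recompute each site's HSI pixel through the estimated rig/probe chain."""
    out = []
    for site, pose in zip(specimen.sites, specimen.site_poses):
        tip = compute_probe_tip(pose, probe)
        pixel, in_view = project_biopsy_site(tip, rig, image_shape=image_shape)
        out.append(BiopsySite(tip_3d=tip, hsi_pixel=pixel,
                              pcle_label=site.pcle_label,
                              pcle_confidence=site.pcle_confidence,
                              specimen_id=site.specimen_id,
                              site_id=site.site_id, in_view=in_view))
    return out


@_stage("hsi_calibration")
def _calibrated_cube(specimen, cutoff_nm, pixel_size_mm):
    cube = white_dark_calibrate(specimen.raw, specimen.white, specimen.dark,
                                pixel_size_mm=pixel_size_mm)
    return restrict_bands(cube, cutoff_nm)


def run_pipeline(dataset: PhantomDataset, cfg: RunConfig | None = None) -> dict:
    """Run LOSO training/evaluation and return the four-variant comparison.

    The returned dict has per-variant aggregated reports (``reports``), the
    raw per-fold values (``folds``), probe-frame classification scores
    (``pcle_classification``), geometry diagnostics, and a manifest.
    """
    cfg = cfg or RunConfig()
    rig, probe, geo_diag = _estimate_geometry(dataset, cfg)
    band_keep = dataset.config.band_centers_nm < cfg.cutoff_nm

    ids = [sp.specimen_id for sp in dataset.specimens]
    by_id = {sp.specimen_id: sp for sp in dataset.specimens}
    folds = make_loso_folds(ids)

    fold_reports = {v: [] for v in VARIANTS}
    pcle_cls_scores = []
    for k, (train_ids, test_id) in enumerate(folds):
        fold_seed = cfg.seed * 1009 + k   # distinct per fold, < 2**31 for small seeds

        # -- spectral model ------------------------------------------------
        try:
            X = np.concatenate([by_id[i].spectra[0] for i in train_ids])[:, band_keep]
            y = np.concatenate([by_id[i].spectra[1] for i in train_ids])
            keep = undersample_indices(y, seed=fold_seed)
            spec = ClassifierSpec(family=cfg.spectral_family, seed=fold_seed)
            model = train_spectral_classifier(X[keep], y[keep], spec)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("spectral_training", exc) from exc

        test_sp = by_id[test_id]
        cube = _calibrated_cube(test_sp, cfg.cutoff_nm,
                                dataset.config.pixel_size_mm)
        try:
            seg = classify_cube(cube, model)
        except Exception as exc:
            raise StageError("spectral_inference", exc) from exc

        # -- probe model ---------------------------------------------------
        try:
            train_imgs = [im for i in train_ids for im in by_id[i].pcle_images]
            pcle_spec = ClassifierSpec(family=cfg.pcle_family, seed=fold_seed)
            pcle_model = train_pcle_classifier(train_imgs, pcle_spec)
            pred_labels, pred_proba = classify_pcle(test_sp.site_images, pcle_model)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("pcle_training", exc) from exc
        true_labels = [im.label for im in test_sp.site_images]
        acc, f1 = classification_report(pred_labels, true_labels)
        pcle_cls_scores.append({"accuracy": acc, "macro_f1": f1})

        # -- site projection with predicted tissue calls --------------------
        if not test_sp.sites:
            raise StageError("fusion", ValueError(
                f"specimen {test_id} has no biopsy sites"))
        sites = _project_sites(test_sp, rig, probe, dataset.config.image_shape)
        for s, lab, pr in zip(sites, pred_labels, pred_proba):
            s.pcle_label = lab
            s.pcle_confidence = float(pr.max())

        # -- fusion variants -------------------------------------------------
        try:
            gt = test_sp.gt_labels
            fold_reports["HSI"].append(segmentation_report(seg.labels, gt))
            lcc = hsi_lcc_baseline(seg.tumor_mask, seg.confidence, cfg.fusion)
            fold_reports["HSI_LCC"].append(segmentation_report(lcc.labels, gt))
            or_mask = logical_or_fusion(seg.tumor_mask, sites, cfg.fusion)
            fused = pcle_informed_lcc(or_mask, sites, seg.confidence, cfg.fusion,
                                      hsi_tumor_mask=seg.tumor_mask)
            fold_reports["HSI+pCLE"].append(segmentation_report(fused.labels, gt))
            pcle_mask = rasterize_sites(gt.shape, sites,
                                        cfg.fusion.site_radius_px)
            gt_tumor = gt == TUMOR
            fold_reports["pCLE"].append({
                "tumor": {"dice": dice(pcle_mask, gt_tumor),
                          "recall": recall(pcle_mask, gt_tumor)}})
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fusion", exc) from exc
        logger.info("fold %d (test specimen %s) done", k, test_id)

    reports = {v: aggregate_fold_reports(fold_reports[v])
               for v in ("HSI", "HSI_LCC", "HSI+pCLE")}
    # probe-only: tumor class only (the probe cannot score BG/healthy pixels)
    pcle_dice = [fr["tumor"]["dice"] for fr in fold_reports["pCLE"]]
    pcle_recall = [fr["tumor"]["recall"] for fr in fold_reports["pCLE"]]
    reports["pCLE"] = {
        "tumor.dice": crossfold_aggregate(pcle_dice),
        "tumor.recall": crossfold_aggregate(pcle_recall),
    }
    acc_m, acc_sd = crossfold_aggregate([s["accuracy"] for s in pcle_cls_scores])
    f1_m, f1_sd = crossfold_aggregate([s["macro_f1"] for s in pcle_cls_scores])

    return {
        "reports": reports,
        "folds": fold_reports,
        "pcle_classification": {"accuracy": (acc_m, acc_sd),
                                "macro_f1": (f1_m, f1_sd)},
        "geometry": geo_diag,
        "manifest": {
            "seed": cfg.seed,
            "spectral_family": cfg.spectral_family,
            "pcle_family": cfg.pcle_family,
            "cutoff_nm": cfg.cutoff_nm,
            "n_specimens": dataset.config.n_specimens,
            "image_shape": list(dataset.config.image_shape),
            "fusion": asdict(cfg.fusion),
        },
    }


def summarize(result: dict) -> dict:
    """Flatten a pipeline result into plain JSON-serialisable numbers."""
    out = {"manifest": result["manifest"], "geometry": result["geometry"]}
    for variant in ("HSI", "HSI_LCC", "HSI+pCLE"):
        rep = result["reports"][variant]
        out[variant] = {key: {"mean": m, "sd": s}
                        for key, (m, s) in rep.mean_sd.items()}
    out["pCLE"] = {key: {"mean": m, "sd": s}
                   for key, (m, s) in result["reports"]["pCLE"].items()}
    acc, f1 = (result["pcle_classification"]["accuracy"],
               result["pcle_classification"]["macro_f1"])
    out["pcle_classification"] = {
        "accuracy": {"mean": acc[0], "sd": acc[1]},
        "macro_f1": {"mean": f1[0], "sd": f1[1]},
    }
    return out


def write_report(result: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(summarize(result), indent=1))
    return path
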
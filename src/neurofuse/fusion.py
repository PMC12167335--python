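"""Multimodal tumor-mask fusion.

The hyperspectral segmentation covers the whole field of view but tends to
over-predict tumor; the endomicroscopy probe samples only discrete sites but
identifies tumor tissue reliably.  Fusion combines them in three steps:

1. logical OR of the HSI tumor mask with the rasterised tumor-labelled
   biopsy sites;
2. among the connected components of the OR mask, keep only the largest one
   that contains at least one tumor-labelled site;
3. every discarded tumor pixel is re-labelled to its runner-up class (the
   next highest of the BG/healthy confidences from the spectral model),
   never filled spatially.

An HSI-only variant keeps the largest component unconditionally (the
"HSI LCC" baseline).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

# label codes shared across the pipeline
BG, HEALTHY, TUMOR = 0, 1, 2

# provenance codes
PROV_NONE, PROV_HSI, PROV_PCLE, PROV_REPLACED = 0, 1, 2, 3
PROV_NAMES = {PROV_NONE: "none", PROV_HSI: "hsi",
              PROV_PCLE: "pcle", PROV_REPLACED: "replaced"}


@dataclass
class FusionConfig:
    connectivity: int = 8            # 4 or 8-connected components
    site_radius_px: int = 0          # disc radius when rasterising a site
    fallback: str = "hsi_lcc"        # {"hsi_lcc", "keep_all"} when no site hits
    keep_all_qualifying: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.site_radius_px < 0:
            raise ValueError("site_radius_px must be >= 0")
        if self.fallback not in ("hsi_lcc", "keep_all"):
            raise ValueError("fallback must be 'hsi_lcc' or 'keep_all'")


@dataclass
class FusedSegmentation:
    labels: np.ndarray                       # 2-D {BG, HEALTHY, TUMOR}
    provenance: np.ndarray                   # 2-D provenance codes
    kept_components: list = field(default_factory=list)


def rasterize_sites(shape: tuple[int, int], sites, radius_px: int = 0,
                    label: str = "tumor") -> np.ndarray:
    """Binary map of the sites with the given label, as discs of ``radius_px``.

    Sites flagged out of view or falling outside ``shape`` are skipped with a
    log message.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for s in sites:
        if s.pcle_label != label:
            continue
        u, v = int(round(s.hsi_pixel.u)), int(round(s.hsi_pixel.v))
        if not s.in_view or not (0 <= u < w and 0 <= v < h):
            logger.info("skipping out-of-view site %s/%s at (%.1f, %.1f)",
                        s.specimen_id, s.site_id, s.hsi_pixel.u, s.hsi_pixel.v)
            continue
        if radius_px == 0:
            mask[v, u] = True
        else:
            mask |= (yy - v) ** 2 + (xx - u) ** 2 <= radius_px ** 2
    return mask


def logical_or_fusion(hsi_tumor_mask: np.ndarray, sites,
                      cfg: FusionConfig | None = None) -> np.ndarray:
    """Union of the HSI tumor mask with rasterised tumor-labelled sites.

    Healthy-labelled sites contribute nothing: only tumor observations from
    the probe are routed into the combined mask.
    """
    cfg = cfg or FusionConfig()
    hsi_tumor_mask = np.asarray(hsi_tumor_mask, dtype=bool)
    site_mask = rasterize_sites(hsi_tumor_mask.shape, sites, cfg.site_radius_px)
    return hsi_tumor_mask | site_mask


def _check_confidences(hsi_conf: np.ndarray, shape) -> np.ndarray:
    hsi_conf = np.asarray(hsi_conf, dtype=float)
    if hsi_conf.shape != (3, *shape):
        raise ValueError("hsi_conf must be (3, rows, cols)")
    sums = hsi_conf.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("confidence maps must sum to 1 per pixel")
    return hsi_conf


def _runner_up_labels(hsi_conf: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the BG/healthy confidences (tumor excluded)."""
    return np.where(hsi_conf[HEALTHY] > hsi_conf[BG], HEALTHY, BG)


def _base_labels(hsi_conf: np.ndarray) -> np.ndarray:
    return np.argmax(hsi_conf, axis=0)


def _assemble(tumor_keep: np.ndarray, hsi_tumor_mask: np.ndarray,
              or_mask: np.ndarray, hsi_conf: np.ndarray,
              kept_ids: list) -> FusedSegmentation:
    labels = _base_labels(hsi_conf)
    prov = np.full(labels.shape, PROV_NONE, dtype=np.uint8)
    runner_up = _runner_up_labels(hsi_conf)

    # pixels the pipeline touched: anything in the OR mask or argmax-tumor
    touched = or_mask | (labels == TUMOR)
    replaced = touched & ~tumor_keep
    labels[replaced] = runner_up[replaced]
    prov[replaced] = PROV_REPLACED

    labels[tumor_keep] = TUMOR
    prov[tumor_keep & hsi_tumor_mask] = PROV_HSI
    prov[tumor_keep & ~hsi_tumor_mask] = PROV_PCLE
    return FusedSegmentation(labels=labels, provenance=prov,
                             kept_components=kept_ids)


def hsi_lcc_baseline(hsi_tumor_mask: np.ndarray, hsi_conf: np.ndarray,
                     cfg: FusionConfig | None = None) -> FusedSegmentation:
    """Keep only the largest connected tumor component, ignoring the probe.

    Ties by pixel count are broken by the smallest top-left (row-major)
    pixel index; every removed pixel takes its runner-up class.
    """
    cfg = cfg or FusionConfig()
    hsi_tumor_mask = np.asarray(hsi_tumor_mask, dtype=bool)
    hsi_conf = _check_confidences(hsi_conf, hsi_tumor_mask.shape)
    comps = cc_label(hsi_tumor_mask, connectivity=cfg.connectivity // 4)
    n_comp = comps.max()
    if n_comp == 0:
        warnings.warn("empty tumor mask; nothing to filter", UserWarning)
        return _assemble(np.zeros_like(hsi_tumor_mask), hsi_tumor_mask,
                         hsi_tumor_mask, hsi_conf, [])
    sizes = np.bincount(comps.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:   # tie-break on first row-major occurrence
        flat = comps.ravel()
        first = {cid: np.flatnonzero(flat == cid)[0] for cid in best}
        keep_id = min(best, key=lambda cid: first[cid])
    else:
        keep_id = int(best[0])
    keep = comps == keep_id
    return _assemble(keep, hsi_tumor_mask, hsi_tumor_mask, hsi_conf, [int(keep_id)])


def pcle_informed_lcc(or_mask: np.ndarray, sites, hsi_conf: np.ndarray,
                      cfg: FusionConfig | None = None,
                      hsi_tumor_mask: np.ndarray | None = None
                      ) -> FusedSegmentation:
    """Keep the largest OR-mask component containing a tumor-labelled site.

    All other tumor pixels are re-labelled to their runner-up class and
    tagged ``replaced``.  With no qualifying component the configured
    fallback applies (default: degrade to the HSI-LCC baseline).
    ``hsi_tumor_mask`` distinguishes HSI-origin from probe-origin pixels in
    the provenance map; when omitted the whole OR mask is attributed to HSI.
    """
    cfg = cfg or FusionConfig()
    or_mask = np.asarray(or_mask, dtype=bool)
    hsi_conf = _check_confidences(hsi_conf, or_mask.shape)
    if hsi_tumor_mask is None:
        hsi_tumor_mask = or_mask
    else:
        hsi_tumor_mask = np.asarray(hsi_tumor_mask, dtype=bool)

    if not or_mask.any():
        warnings.warn("empty OR mask; result contains no tumor", UserWarning)
        return _assemble(np.zeros_like(or_mask), hsi_tumor_mask, or_mask,
                         hsi_conf, [])

    site_mask = rasterize_sites(or_mask.shape, sites, cfg.site_radius_px)
    comps = cc_label(or_mask, connectivity=cfg.connectivity // 4)
    qualifying = np.unique(comps[site_mask & (comps > 0)])
    if len(qualifying) == 0:
        logger.warning("no component contains a tumor site; falling back to %s",
                       cfg.fallback)
        if cfg.fallback == "hsi_lcc":
            return hsi_lcc_baseline(hsi_tumor_mask, hsi_conf, cfg)
        return _assemble(or_mask, hsi_tumor_mask, or_mask, hsi_conf,
                         [int(c) for c in np.unique(comps[comps > 0])])

    if cfg.keep_all_qualifying:
        kept_ids = [int(c) for c in qualifying]
    else:
        sizes = np.bincount(comps.ravel())
        kept_ids = [int(max(qualifying, key=lambda cid: sizes[cid]))]
    keep = np.isin(comps, kept_ids)
    return _assemble(keep, hsi_tumor_mask, or_mask, hsi_conf, kept_ids)
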
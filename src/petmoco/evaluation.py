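"""Evaluation of parametric maps: myocardium masking, ROI statistics over
noise realizations, bias and standard-deviation-reduction metrics, the
image-derived input function, and line profiles.

Conventions follow the study design: for each ROI the K1 map is averaged
per noise realization, then the mean and the (N-1)-normalized standard
deviation are taken across realizations; bias of a method M against the
static reference is (mean_M - mean_ST)/mean_ST, "true bias" is relative to
the generating K1, and the noise reduction of MC relative to GA is
|sigma_MC - sigma_GA| / sigma_GA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LABELS, Phantom

__all__ = ["RoiSpec", "RoiStats", "myocardium_mask", "roi_stats",
           "bias_metric", "truth_bias", "sd_reduction", "image_derived_if",
           "line_profile", "default_rois", "blood_pool_roi"]

MYO_ROI_VOLUME_ML = 0.18


@dataclass
class RoiSpec:
    """A small pixel region of interest.

    ``pixels`` is an (n, 2) array of (row, col) indices; myocardial ROIs
    target a nominal 0.18-mL volume (pixel count x pixel volume within 15%)
    and sit at least one eroded pixel away from the myocardium edge.
    """

    pixels: np.ndarray
    label: str
    pixel_volume_ml: float

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError(f"ROI {self.label}: empty pixel set")

    @property
    def volume_ml(self) -> float:
        return self.pixels.shape[0] * self.pixel_volume_ml

    def mean_of(self, image: np.ndarray) -> float:
        return float(image[self.pixels[:, 0], self.pixels[:, 1]].mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class RoiStats:
    """Across-realization ROI summary of a parameter map."""

    label: str
    per_realization: np.ndarray  # ROI mean per noise realization
    mean: float
    sd: float
    n_realizations: int


def myocardium_mask(last_frame_image: np.ndarray,
                    threshold_fraction: float = 0.5) -> np.ndarray:
    """Threshold the late static image and keep the largest component."""
    img = np.asarray(last_frame_image)
    if np.any(img < 0):
        img = np.clip(img, 0, None)
    mask = img >= threshold_fraction * img.max()
    if not mask.any():
        raise ValueError(f"threshold fraction {threshold_fraction} leaves an empty mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def roi_stats(k1_maps: np.ndarray, roi: RoiSpec) -> RoiStats:
    """Mean and sample SD of the ROI-mean K1 across noise realizations."""
    maps = np.asarray(k1_maps)
    if maps.ndim == 2:
        maps = maps[None]
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 realizations for a standard deviation")
    per = np.array([roi.mean_of(m) for m in maps])
    return RoiStats(roi.label, per, float(per.mean()), float(per.std(ddof=1)), n)


def bias_metric(method_mean: float, st_mean: float) -> float:
    """Fractional bias of a method against the static reference."""
    if st_mean == 0:
        raise ValueError("static reference mean is zero; bias undefined")
    return (method_mean - st_mean) / st_mean


def truth_bias(method_mean: float, true_k1: float) -> float:
    """Fractional bias against the generating (ground-truth) K1."""
    if true_k1 == 0:
        raise ValueError("true K1 is zero; bias undefined")
    return (method_mean - true_k1) / true_k1


def sd_reduction(sd_mc: float, sd_ga: float) -> float:
    """Fractional SD reduction of MC relative to GA: |sd_MC - sd_GA| / sd_GA."""
    if sd_ga <= 0:
        raise ValueError("GA standard deviation must be positive")
    return abs(sd_mc - sd_ga) / sd_ga


def image_derived_if(dynamic_series: np.ndarray, blood_roi: RoiSpec,
                     label_map: np.ndarray | None = None) -> np.ndarray:
    """Per-frame mean concentration in a blood-pool ROI.

    When a label map is supplied the ROI is validated: every pixel must lie
    in the LV blood pool and no pixel may touch the myocardium or defect
    (8-neighbourhood), keeping the spillover contamination out.
    """
    series = np.asarray(dynamic_series)
    if label_map is not None:
        labels = label_map[blood_roi.pixels[:, 0], blood_roi.pixels[:, 1]]
        if np.any(labels != LABELS["lv_blood"]):
            raise ValueError("blood ROI leaves the LV blood pool")
        wall = np.isin(label_map, [LABELS["myocardium"], LABELS["defect"]])
        near_wall = ndimage.binary_dilation(wall, structure=np.ones((3, 3)))
        if np.any(near_wall[blood_roi.pixels[:, 0], blood_roi.pixels[:, 1]]):
            raise ValueError("blood ROI touches the myocardium; move it inward")
    return np.array([blood_roi.mean_of(frame) for frame in series])


def line_profile(image: np.ndarray, start: tuple[float, float],
                 end: tuple[float, float]) -> np.ndarray:
    """Bilinear samples along a segment at 1-pixel spacing (endpoints included)."""
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    for p in (p0, p1):
        if np.any(p < 0) or p[0] > image.shape[0] - 1 or p[1] > image.shape[1] - 1:
            raise ValueError("profile endpoints must lie inside the image grid")
    n = int(np.ceil(np.linalg.norm(p1 - p0))) + 1
    rr = np.linspace(p0[0], p1[0], n)
    cc = np.linspace(p0[1], p1[1], n)
    return ndimage.map_coordinates(np.asarray(image, dtype=float), [rr, cc], order=1)


def _eroded_wall(phantom: Phantom) -> np.ndarray:
    wall = np.isin(phantom.label_map, [LABELS["myocardium"], LABELS["defect"]])
    return ndimage.binary_erosion(wall, structure=np.ones((3, 3)))


def _nearest_pixels(candidates: np.ndarray, anchor: np.ndarray, k: int) -> np.ndarray:
    d = np.linalg.norm(candidates - anchor, axis=1)
    return candidates[np.argsort(d)[:k]]


def default_rois(phantom: Phantom, n_pixels: int | None = None) -> dict[str, RoiSpec]:
    """Four nominal-0.18-mL myocardial ROIs away from the wall edges.

    ROI1 septal, ROI2 anterior, ROI3 at the defect centre, ROI4
    inferior-lateral; each takes the ``n_pixels`` eroded-wall pixels nearest
    to its mid-wall anchor (defect pixels for ROI3).
    """
    px_vol = phantom.pixel_size**2 * phantom.slice_thickness / 1000.0  # mL
    k = n_pixels or max(1, round(MYO_ROI_VOLUME_ML / px_vol))
    cfg = phantom.config
    r_mid = 0.5 * (cfg.lv_inner_radius + cfg.lv_outer_radius) / phantom.pixel_size
    cy, cx = phantom.lv_center
    eroded = np.argwhere(_eroded_wall(phantom))
    defect = np.argwhere(phantom.label_map == LABELS["defect"])

    def anchor(angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return np.array([cy - r_mid * np.sin(th), cx + r_mid * np.cos(th)])

    rois: dict[str, RoiSpec] = {}
    angles = {"ROI1": 180.0, "ROI2": 90.0, "ROI4": -60.0}
    for name in ("ROI1", "ROI2"):
        rois[name] = RoiSpec(_nearest_pixels(eroded, anchor(angles[name]), k), name, px_vol)
    # the defect ROI centres on the defect label; when the defect occupies
    # fewer pixels than the nominal volume, adjacent wall pixels complete it
    if defect.size:
        centroid = defect.mean(axis=0)
        pool = np.concatenate([defect, eroded]) if defect.shape[0] < k else defect
    else:
        centroid = anchor(cfg.defect_angle_deg)
        pool = eroded
    seen = set()
    uniq = np.array([p for p in map(tuple, pool) if not (p in seen or seen.add(p))])
    rois["ROI3"] = RoiSpec(_nearest_pixels(uniq, centroid, k), "ROI3", px_vol)
    rois["ROI4"] = RoiSpec(_nearest_pixels(eroded, anchor(angles["ROI4"]), k), "ROI4", px_vol)
    return rois


def blood_pool_roi(phantom: Phantom, n_pixels: int = 4) -> RoiSpec:
    """Small LV blood-pool ROI kept away from the myocardium."""
    px_vol = phantom.pixel_size**2 * phantom.slice_thickness / 1000.0
    lv = phantom.label_map == LABELS["lv_blood"]
    wall = np.isin(phantom.label_map, [LABELS["myocardium"], LABELS["defect"]])
    near_wall = ndimage.binary_dilation(wall, structure=np.ones((3, 3)), iterations=2)
    candidates = np.argwhere(lv & ~near_wall)
    if candidates.shape[0] < n_pixels:
        raise ValueError("LV blood pool too small for an edge-free ROI")
    center = np.array(phantom.lv_center)
    return RoiSpec(_nearest_pixels(candidates, center, n_pixels), "blood-pool", px_vol)
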
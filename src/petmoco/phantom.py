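"""Synthetic 2D thorax phantom with cardiac/respiratory motion.

A single coronal plane holds a left-ventricular myocardial ring with LV and
RV blood pools, lungs, liver and a soft-tissue body ellipse.  A
non-transmural perfusion defect (about 4 mm across the wall thickness and
about 12 mm along the wall) is embedded in the mid-anterolateral myocardium.
Each tissue carries one-tissue-compartment kinetic parameters (K1, k2),
a 511-keV linear attenuation coefficient, and proton-density/T1/T2 values
for the MR signal simulation.

Ground-truth motion is an analytic, invertible deformation per motion
phase: a smooth radial contraction about the LV centre (cardiac) plus an
in-plane superior-inferior translation of the torso (respiratory), each
modulated by a raised-cosine cyclic weight that vanishes at the reference
phase (end-diastole / end-exhalation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "TissueProperties",
    "Phantom",
    "MotionPhaseSpec",
    "PhantomConfig",
    "LABELS",
    "default_tissue_table",
    "build_phantom",
    "true_deformation",
    "deform_maps",
    "jacobian_determinant",
]

#: tissue label ids used throughout the package
LABELS = {
    "air": 0,
    "soft_tissue": 1,
    "lung": 2,
    "liver": 3,
    "myocardium": 4,
    "defect": 5,
    "lv_blood": 6,
    "rv_blood": 7,
}


@dataclass(frozen=True)
class TissueProperties:
    """Per-tissue physical properties.

    K1 is the uptake rate (mL·min⁻¹·mL⁻¹), k2 the washout rate (min⁻¹),
    mu the 511-keV linear attenuation coefficient (mm⁻¹), pd the proton
    density as a fraction of water, t1/t2 the relaxation times (ms).
    Blood-pool tissues carry the arterial input function directly instead
    of a compartment TAC (``blood_pool=True``).
    """

    tissue_label: int
    name: str
    K1: float
    k2: float
    mu: float
    pd: float
    t1: float
    t2: float
    blood_pool: bool = False

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.mu < 0:
            raise ValueError(f"{self.name}: K1, k2 and mu must be non-negative")
        if self.pd < 0 or self.pd > 1.2:
            raise ValueError(f"{self.name}: pd must lie in [0, 1.2]")
        if self.pd > 0 and not (self.t1 > self.t2 > 0):
            raise ValueError(f"{self.name}: need t1 > t2 > 0 for proton-bearing tissue")


def default_tissue_table() -> dict[int, TissueProperties]:
    """Default tissue assignments.

    Healthy myocardium (K1=0.80, k2=0.17; PD/T1/T2 = 0.67/830/62) and the
    defect (K1=0.36, k2=0.21; 0.77/1080/82) follow published 13N-ammonia
    and 3-T relaxometry values.  The remaining tissues use water-like
    attenuation (0.0096 mm⁻¹, lungs at ~0.3x) and plausible 3-T MR values;
    all entries are overridable through ``PhantomConfig``.
    """
    t = [
        TissueProperties(0, "air", 0.0, 0.0, 0.0, 0.0, 1.0, 0.5),
        TissueProperties(1, "soft_tissue", 0.05, 0.10, 0.0096, 0.70, 1200.0, 40.0),
        TissueProperties(2, "lung", 0.10, 0.25, 0.0029, 0.20, 1200.0, 30.0),
        TissueProperties(3, "liver", 0.45, 0.35, 0.0096, 0.70, 810.0, 42.0),
        TissueProperties(4, "myocardium", 0.80, 0.17, 0.0096, 0.67, 830.0, 62.0),
        TissueProperties(5, "defect", 0.36, 0.21, 0.0096, 0.77, 1080.0, 82.0),
        TissueProperties(6, "lv_blood", 0.0, 0.0, 0.0096, 0.90, 1932.0, 275.0, True),
        TissueProperties(7, "rv_blood", 0.0, 0.0, 0.0096, 0.90, 1932.0, 275.0, True),
    ]
    return {p.tissue_label: p for p in t}


@dataclass
class PhantomConfig:
    """Geometry of the synthetic thorax (all lengths in mm)."""

    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 3.0
    slice_thickness: float = 3.0
    body_semi_axes: tuple[float, float] = (165.0, 120.0)  # (rows=SI, cols=LR)
    heart_center_offset: tuple[float, float] = (-15.0, -12.0)  # from grid centre
    lv_inner_radius: float = 12.0
    lv_outer_radius: float = 24.0
    defect_thickness: float = 4.0  # across the wall
    defect_arc_length: float = 12.0  # along the wall
    defect_angle_deg: float = 45.0  # mid-anterolateral (up-left of LV centre)
    rv_center_offset: tuple[float, float] = (0.0, -38.0)  # from LV centre
    rv_radius: float = 11.0
    lung_semi_axes: tuple[float, float] = (75.0, 38.0)
    lung_center_offsets: tuple[tuple[float, float], ...] = ((-35.0, -62.0), (-35.0, 62.0))
    liver_center_offset: tuple[float, float] = (58.0, -45.0)
    liver_semi_axes: tuple[float, float] = (42.0, 62.0)
    properties: dict[int, TissueProperties] = field(default_factory=default_tissue_table)


@dataclass
class Phantom:
    """Reference-phase label map plus tissue property table."""

    grid_shape: tuple[int, int]
    pixel_size: float
    slice_thickness: float
    label_map: np.ndarray
    properties: dict[int, TissueProperties]
    lv_center: tuple[float, float]  # pixel coordinates (row, col)
    config: PhantomConfig | None = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_map).tolist())
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels without property rows: {sorted(missing)}")

    def property_map(self, attr: str) -> np.ndarray:
        """Pixel map of one property (``K1 | k2 | mu | pd | t1 | t2``)."""
        lut = np.zeros(max(self.properties) + 1, dtype=float)
        for lab, p in self.properties.items():
            lut[lab] = getattr(p, attr)
        return lut[self.label_map]

    def label_mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]


@dataclass(frozen=True)
class MotionPhaseSpec:
    """Cardiac x respiratory motion-phase grid.

    ``cardiac_amplitude`` is the peak radial contraction fraction (unitless),
    ``resp_amplitude`` the peak superior-inferior translation in mm.  Phase
    (0, 0) is the reference (end-diastole / end-exhalation) and carries zero
    deformation.
    """

    n_cardiac: int = 5
    n_resp: int = 5
    cardiac_amplitude: float = 0.10
    resp_amplitude: float = 10.0
    reference_phase: tuple[int, int] = (0, 0)

    @property
    def total_phases(self) -> int:
        return self.n_cardiac * self.n_resp

    def phases(self) -> Iterator[tuple[int, int]]:
        for c in range(self.n_cardiac):
            for r in range(self.n_resp):
                yield (c, r)

    def cardiac_weight(self, c: int) -> float:
        if not 0 <= c < self.n_cardiac:
            raise ValueError(f"cardiac phase {c} outside [0, {self.n_cardiac})")
        if self.n_cardiac == 1:
            return 0.0
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * c / self.n_cardiac))

    def resp_weight(self, r: int) -> float:
        if not 0 <= r < self.n_resp:
            raise ValueError(f"resp phase {r} outside [0, {self.n_resp})")
        if self.n_resp == 1:
            return 0.0
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * r / self.n_resp))

    @staticmethod
    def cm(n_cardiac: int = 10, cardiac_amplitude: float = 0.10) -> "MotionPhaseSpec":
        """Cardiac-motion-only study (10 cardiac x 1 respiratory phases)."""
        return MotionPhaseSpec(n_cardiac=n_cardiac, n_resp=1,
                               cardiac_amplitude=cardiac_amplitude, resp_amplitude=0.0)

    @staticmethod
    def crm(n_cardiac: int = 5, n_resp: int = 5,
            cardiac_amplitude: float = 0.10, resp_amplitude: float = 10.0) -> "MotionPhaseSpec":
        """Combined cardiac+respiratory study (5 x 5 = 25 phases)."""
        return MotionPhaseSpec(n_cardiac=n_cardiac, n_resp=n_resp,
                               cardiac_amplitude=cardiac_amplitude,
                               resp_amplitude=resp_amplitude)

    @staticmethod
    def static() -> "MotionPhaseSpec":
        """Degenerate single-phase (motionless) spec."""
        return MotionPhaseSpec(n_cardiac=1, n_resp=1,
                               cardiac_amplitude=0.0, resp_amplitude=0.0)


def _pixel_grid(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (y, x) coordinates of pixel centres, origin at grid centre."""
    rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * pixel_size
    cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * pixel_size
    return np.meshgrid(rows, cols, indexing="ij")


def build_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Paint the reference-phase label map from the configured geometry.

    Raises ``ValueError`` naming the violated dimension when the defect does
    not fit inside the myocardial wall.
    """
    cfg = config or PhantomConfig()
    if cfg.pixel_size <= 0 or min(cfg.grid_shape) <= 0:
        raise ValueError("grid_shape and pixel_size must be positive")
    wall = cfg.lv_outer_radius - cfg.lv_inner_radius
    if cfg.defect_thickness > wall:
        raise ValueError(
            f"defect_thickness {cfg.defect_thickness} mm exceeds wall thickness {wall} mm")

    yy, xx = _pixel_grid(cfg.grid_shape, cfg.pixel_size)
    lab = np.zeros(cfg.grid_shape, dtype=np.int32)

    def ellipse(cy, cx, ay, ax_):
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0

    # body
    lab[ellipse(0.0, 0.0, *cfg.body_semi_axes)] = LABELS["soft_tissue"]
    # lungs
    for off in cfg.lung_center_offsets:
        lab[ellipse(off[0], off[1], *cfg.lung_semi_axes)] = LABELS["lung"]
    # liver
    lo = cfg.liver_center_offset
    lab[ellipse(lo[0], lo[1], *cfg.liver_semi_axes)] = LABELS["liver"]

    # heart
    hy, hx = cfg.heart_center_offset
    r = np.hypot(yy - hy, xx - hx)
    theta = np.arctan2(-(yy - hy), xx - hx)  # CCW angle, 0 = +x (patient-left)
    lab[r <= cfg.lv_outer_radius] = LABELS["myocardium"]
    lab[r <= cfg.lv_inner_radius] = LABELS["lv_blood"]
    # RV blood pool, clipped so it never eats the LV wall
    ry, rx = cfg.rv_center_offset
    rv = np.hypot(yy - (hy + ry), xx - (hx + rx)) <= cfg.rv_radius
    lab[rv & (r > cfg.lv_outer_radius)] = LABELS["rv_blood"]

    # non-transmural defect: radial band centred mid-wall, arc along the wall
    if cfg.defect_arc_length > 0 and cfg.defect_thickness > 0:
        r_mid = 0.5 * (cfg.lv_inner_radius + cfg.lv_outer_radius)
        r_lo = r_mid - cfg.defect_thickness / 2.0
        r_hi = r_mid + cfg.defect_thickness / 2.0
        if r_lo < cfg.lv_inner_radius or r_hi > cfg.lv_outer_radius:
            raise ValueError("defect_thickness does not fit inside the myocardial wall")
        half_arc = 0.5 * cfg.defect_arc_length / r_mid  # radians
        th0 = np.deg2rad(cfg.defect_angle_deg)
        dth = np.angle(np.exp(1j * (theta - th0)))
        dmask = (r >= r_lo) & (r <= r_hi) & (np.abs(dth) <= half_arc)
        dmask &= lab == LABELS["myocardium"]
        lab[dmask] = LABELS["defect"]

    center_px = (
        (cfg.grid_shape[0] - 1) / 2.0 + hy / cfg.pixel_size,
        (cfg.grid_shape[1] - 1) / 2.0 + hx / cfg.pixel_size,
    )
    props = {k: v for k, v in cfg.properties.items() if k in np.unique(lab)}
    return Phantom(cfg.grid_shape, cfg.pixel_size, cfg.slice_thickness,
                   lab, props, center_px, cfg)


def true_deformation(phantom: Phantom, spec: MotionPhaseSpec,
                     phase: tuple[int, int]) -> np.ndarray:
    """Ground-truth pull-back displacement field for one motion phase.

    Returns an array ``u`` of shape ``(2,) + grid_shape`` in mm such that the
    phase image is ``reference(x + u(x))``: sampling the reference map at
    ``x + u(x)`` contracts the heart toward the LV centre (cardiac) and
    translates the torso along the superior-inferior axis (respiratory).
    The reference phase yields an identically zero field.

    Raises ``ValueError`` for phases outside the grid or amplitudes that
    make the map non-invertible (non-positive Jacobian determinant).
    """
    c, rph = phase
    wc = spec.cardiac_amplitude * spec.cardiac_weight(c)
    wr = spec.resp_amplitude * spec.resp_weight(rph)

    shape = phantom.grid_shape
    ps = phantom.pixel_size
    yy, xx = _pixel_grid(shape, ps)
    cy = (phantom.lv_center[0] - (shape[0] - 1) / 2.0) * ps
    cx = (phantom.lv_center[1] - (shape[1] - 1) / 2.0) * ps

    u = np.zeros((2,) + shape)
    if wc != 0.0:
        dy, dx = yy - cy, xx - cx
        r2 = dy * dy + dx * dx
        rho = 40.0  # mm, spatial extent of the cardiac contraction
        g = np.exp(-r2 / (2.0 * rho * rho))
        # sample outward -> image contracts; inner wall moves more than outer
        u[0] += wc * g * dy
        u[1] += wc * g * dx
    # respiratory: rigid SI translation of the whole torso
    u[0] += wr

    if wc != 0.0:
        jmin = jacobian_determinant(u, ps).min()
        if jmin <= 0:
            raise ValueError(f"deformation not invertible (min Jacobian {jmin:.3g})")
    return u


def jacobian_determinant(u: np.ndarray, pixel_size: float) -> np.ndarray:
    """Finite-difference Jacobian determinant of x -> x + u(x)."""
    duy_dy, duy_dx = np.gradient(u[0], pixel_size)
    dux_dy, dux_dx = np.gradient(u[1], pixel_size)
    return (1.0 + duy_dy) * (1.0 + dux_dx) - duy_dx * dux_dy


_CONTINUOUS = {"activity", "mu", "pd", "t1", "t2"}


def deform_maps(phantom: Phantom, u: np.ndarray, map_kind: str,
                activity_values: dict[int, float] | None = None) -> np.ndarray:
    """Resample one property map through a displacement field (pull-back).

    ``map_kind`` selects ``mu``/``pd``/``t1``/``t2`` from the property table,
    ``label`` for the nearest-neighbour-warped label map, or ``activity``
    with per-label concentrations supplied via ``activity_values``.
    Out-of-grid samples take the background (air) value.
    """
    if map_kind == "label":
        base = phantom.label_map.astype(float)
        order, cval = 0, 0.0
    elif map_kind == "activity":
        if activity_values is None:
            raise ValueError("activity warp needs per-label activity_values")
        lut = np.zeros(max(phantom.properties) + 1)
        for lab, v in activity_values.items():
            lut[lab] = v
        base = lut[phantom.label_map]
        order, cval = 1, 0.0
    elif map_kind in _CONTINUOUS:
        base = phantom.property_map(map_kind)
        order, cval = 1, 0.0
    else:
        raise ValueError(f"unknown map_kind {map_kind!r}")

    out = warp_map(base, u, phantom.pixel_size, order=order, cval=cval)
    if map_kind == "label":
        out = out.round().astype(phantom.label_map.dtype)
    return out


def warp_map(image: np.ndarray, u: np.ndarray, pixel_size: float,
             order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Pull-back resampling: ``out(x) = image(x + u(x))`` with u in mm."""
    if u[0].shape != image.shape:
        raise ValueError("field grid does not match image grid")
    rr, cc = np.meshgrid(np.arange(image.shape[0], dtype=float),
                         np.arange(image.shape[1], dtype=float), indexing="ij")
    coords = np.stack([rr + u[0] / pixel_size, cc + u[1] / pixel_size])
    return map_coordinates(image, coords, order=order, mode="constant", cval=cval)
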
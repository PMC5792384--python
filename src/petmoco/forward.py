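"""PET forward model: mean sinogram = A G P x.

P blurs the activity image with a Gaussian point-spread function in image
space (default FWHM 4.5 mm), G forward-projects with exact Siddon
ray-tracing over a 2D parallel-beam geometry, and the diagonal A applies
per-bin attenuation factors exp(-line integral of mu).  Mean counts are
scaled so that the noise-free total in the last (4-min) frame is 50,000
for the simulated 3-mm slice; Poisson realizations are drawn bin-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.ndimage import gaussian_filter

from .kinetics import FrameSchedule

__all__ = [
    "ProjectionGeometry",
    "SystemOperators",
    "siddon_ray",
    "build_system_matrix",
    "apply_psf",
    "attenuation_factors",
    "forward_project",
    "calibrate_scale",
    "phase_weight",
    "add_poisson_noise",
    "realization_rng",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ProjectionGeometry:
    """2D parallel-beam sampling: angles over [0, pi), signed radial bins."""

    n_angles: int = 180
    n_radial: int = 128
    radial_bin_size: float = 3.0  # mm

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_offsets(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_bin_size

    @property
    def n_bins(self) -> int:
        return self.n_angles * self.n_radial

    def covers_radius(self, radius_mm: float) -> bool:
        """True when every ray within ``radius_mm`` of centre is sampled."""
        return self.radial_offsets[-1] >= radius_mm


@njit(cache=True)
def _siddon_kernel(n_rows, n_cols, ps, cos_t, sin_t, t, out_idx, out_len):
    """Exact Siddon traversal of the ray {x cos + y sin = t} through the grid.

    Grid is centred at the origin; x runs along columns, y along rows.
    Returns the number of crossed pixels; fills pixel flat-indices and
    intersection lengths (mm).
    """
    half_w = n_cols * ps / 2.0
    half_h = n_rows * ps / 2.0
    # ray: p(s) = (t*cos - s*sin, t*sin + s*cos)
    px, py = t * cos_t, t * sin_t
    dx, dy = -sin_t, cos_t

    s_min = -1.0e30
    s_max = 1.0e30
    if abs(dx) > 1e-12:
        s1 = (-half_w - px) / dx
        s2 = (half_w - px) / dx
        lo = min(s1, s2); hi = max(s1, s2)
        if lo > s_min: s_min = lo
        if hi < s_max: s_max = hi
    elif px <= -half_w or px >= half_w:
        return 0
    if abs(dy) > 1e-12:
        s1 = (-half_h - py) / dy
        s2 = (half_h - py) / dy
        lo = min(s1, s2); hi = max(s1, s2)
        if lo > s_min: s_min = lo
        if hi < s_max: s_max = hi
    elif py <= -half_h or py >= half_h:
        return 0
    if s_min >= s_max:
        return 0

    # merge all pixel-boundary crossings inside [s_min, s_max]; the midpoint
    # of each interval identifies the crossed pixel unambiguously
    eps = 1e-9
    svals = np.empty(n_rows + n_cols + 4, dtype=np.float64)
    m = 0
    svals[m] = s_min; m += 1
    if abs(dx) > 1e-12:
        for k in range(n_cols + 1):
            s = (-half_w + k * ps - px) / dx
            if s_min + eps < s < s_max - eps:
                svals[m] = s; m += 1
    if abs(dy) > 1e-12:
        for k in range(n_rows + 1):
            s = (-half_h + k * ps - py) / dy
            if s_min + eps < s < s_max - eps:
                svals[m] = s; m += 1
    svals[m] = s_max; m += 1
    sv = np.sort(svals[:m])

    n = 0
    for i in range(m - 1):
        ds = sv[i + 1] - sv[i]
        if ds <= eps:
            continue
        smid = 0.5 * (sv[i] + sv[i + 1])
        col = int(np.floor((px + dx * smid + half_w) / ps))
        row = int(np.floor((py + dy * smid + half_h) / ps))
        if 0 <= col < n_cols and 0 <= row < n_rows:
            out_idx[n] = row * n_cols + col
            out_len[n] = ds
            n += 1
    return n


def siddon_ray(grid_shape: tuple[int, int], pixel_size: float,
               angle: float, radial_offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixels crossed by one ray and their exact intersection lengths (mm).

    The ray is the line ``x cos(angle) + y sin(angle) = radial_offset`` in
    the grid's centred physical frame.  Lengths sum to the chord length of
    the ray through the grid bounding box; a ray missing the grid returns
    empty arrays.
    """
    n_rows, n_cols = grid_shape
    cap = n_rows + n_cols + 4
    idx = np.empty(cap, dtype=np.int64)
    ln = np.empty(cap, dtype=np.float64)
    n = _siddon_kernel(n_rows, n_cols, float(pixel_size),
                       float(np.cos(angle)), float(np.sin(angle)),
                       float(radial_offset), idx, ln)
    return idx[:n].copy(), ln[:n].copy()


@njit(cache=True)
def _build_matrix_kernel(n_rows, n_cols, ps, cos_a, sin_a, offsets,
                         indptr, indices, data):
    cap = n_rows + n_cols + 4
    idx = np.empty(cap, dtype=np.int64)
    ln = np.empty(cap, dtype=np.float64)
    pos = 0
    ray = 0
    for a in range(cos_a.shape[0]):
        for j in range(offsets.shape[0]):
            n = _siddon_kernel(n_rows, n_cols, ps, cos_a[a], sin_a[a],
                               offsets[j], idx, ln)
            for k in range(n):
                indices[pos] = idx[k]
                data[pos] = ln[k]
                pos += 1
            ray += 1
            indptr[ray] = pos
    return pos


def build_system_matrix(geometry: ProjectionGeometry, grid_shape: tuple[int, int],
                        pixel_size: float) -> sp.csr_matrix:
    """Sparse Siddon projector G of shape (n_bins, n_pixels); entries in mm."""
    n_rows, n_cols = grid_shape
    angles = geometry.angles
    offsets = geometry.radial_offsets
    n_rays = geometry.n_bins
    cap = n_rays * (n_rows + n_cols + 4)
    indptr = np.zeros(n_rays + 1, dtype=np.int64)
    indices = np.empty(cap, dtype=np.int64)
    data = np.empty(cap, dtype=np.float64)
    nnz = _build_matrix_kernel(n_rows, n_cols, float(pixel_size),
                               np.cos(angles), np.sin(angles), offsets,
                               indptr, indices, data)
    return sp.csr_matrix((data[:nnz], indices[:nnz], indptr),
                         shape=(n_rays, n_rows * n_cols))


def apply_psf(image: np.ndarray, fwhm_mm: float, pixel_size: float) -> np.ndarray:
    """Image-space Gaussian PSF; ``fwhm_mm=0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("PSF FWHM must be non-negative")
    if fwhm_mm == 0:
        return image.copy()
    sigma_px = fwhm_mm / FWHM_TO_SIGMA / pixel_size
    return gaussian_filter(image, sigma_px, mode="constant")


@dataclass
class SystemOperators:
    """Bundled P (PSF), G (Siddon projector) and A (attenuation factors)."""

    geometry: ProjectionGeometry
    grid_shape: tuple[int, int]
    pixel_size: float
    psf_fwhm_mm: float = 4.5
    mu_map: np.ndarray | None = None
    _G: sp.csr_matrix | None = field(default=None, repr=False)
    _A: np.ndarray | None = field(default=None, repr=False)

    @property
    def G(self) -> sp.csr_matrix:
        if self._G is None:
            self._G = build_system_matrix(self.geometry, self.grid_shape, self.pixel_size)
        return self._G

    @property
    def A(self) -> np.ndarray:
        if self._A is None:
            if self.mu_map is None:
                self._A = np.ones(self.geometry.n_bins)
            else:
                self._A = attenuation_factors(self.mu_map, self.geometry,
                                              self.pixel_size, _G=self.G)
        return self._A

    def with_mu(self, mu_map: np.ndarray | None) -> "SystemOperators":
        """Same geometry/PSF with a different attenuation map (G shared)."""
        return SystemOperators(self.geometry, self.grid_shape, self.pixel_size,
                               self.psf_fwhm_mm, mu_map, _G=self.G)


def attenuation_factors(mu_map: np.ndarray, geometry: ProjectionGeometry,
                        pixel_size: float, _G: sp.csr_matrix | None = None) -> np.ndarray:
    """Per-bin attenuation factors exp(-sum mu * length), Siddon traversal."""
    if np.any(mu_map < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    G = _G if _G is not None else build_system_matrix(geometry, mu_map.shape, pixel_size)
    return np.exp(-(G @ mu_map.ravel()))


def forward_project(activity_image: np.ndarray, operators: SystemOperators) -> np.ndarray:
    """Noise-free unscaled projection A G P x, shape (n_angles, n_radial)."""
    if activity_image.shape != operators.grid_shape:
        raise ValueError("activity image does not match the projector grid")
    blurred = apply_psf(activity_image, operators.psf_fwhm_mm, operators.pixel_size)
    y = operators.A * (operators.G @ blurred.ravel())
    return y.reshape(operators.geometry.n_angles, operators.geometry.n_radial)


def phase_weight(total_phases: int) -> float:
    """Fraction of a frame's events collected in each motion phase.

    Cycles are short relative to frame durations, so every phase receives
    an equal 1/total_phases share of the frame duration.
    """
    if total_phases < 1:
        raise ValueError("total_phases must be >= 1")
    return 1.0 / total_phases


def calibrate_scale(noise_free_sinograms: np.ndarray, schedule: FrameSchedule,
                    target_counts: float = 50_000.0) -> float:
    """Scale factor making the last-frame noise-free total equal ``target_counts``.

    ``noise_free_sinograms`` has shape (n_frames, n_phases, ...) of unscaled
    mean counts; the factor applies uniformly to every frame and phase.
    """
    last = np.asarray(noise_free_sinograms)[schedule.n_frames - 1]
    total = float(last.sum())
    if total <= 0:
        raise ValueError("cannot calibrate: last frame has zero total counts")
    return target_counts / total


def realization_rng(master_seed: int, realization: int) -> np.random.Generator:
    """Independent, reproducible stream for one noise realization."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(realization)]))


def add_poisson_noise(mean_sinogram: np.ndarray,
                      rng: np.random.Generator | int) -> np.ndarray:
    """Bin-wise Poisson draw around a non-negative mean sinogram."""
    mean = np.asarray(mean_sinogram)
    if np.any(mean < 0):
        raise ValueError("mean counts must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.poisson(mean)
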
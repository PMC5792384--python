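"""Attenuation-corrected filtered back-projection for 2D parallel-beam data.

Sinograms are precorrected bin-wise by the chosen attenuation factors,
ramp-filtered (band-limited Ram-Lak kernel with a Hann apodization
window by default) and back-projected with linear interpolation onto the phantom
grid through a precomputed sparse operator, so that stacks of sinograms
reconstruct in one sparse mat-mat product.

The discrete filter follows the standard band-limited ramp impulse
response h[0] = 1/(4 tau^2), h[n] = -1/(pi n tau)^2 for odd n (tau = radial
bin size), which makes the reconstruction quantitative: a projected
uniform disk comes back at its true concentration to within a few percent.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .forward import ProjectionGeometry

__all__ = ["precorrect", "ramp_filter", "filter_sinogram",
           "build_backprojector", "fbp", "fbp_stack"]


def precorrect(sinogram: np.ndarray, attenuation: np.ndarray) -> np.ndarray:
    """Bin-wise division of a sinogram by its attenuation factors."""
    att = np.asarray(attenuation).reshape(sinogram.shape[-2:])
    if np.any(att <= 0):
        raise ValueError("attenuation factors must be positive")
    return np.asarray(sinogram, dtype=float) / att


@lru_cache(maxsize=8)
def _ramp_response(n_radial: int, bin_size: float, window: str) -> np.ndarray:
    """Frequency response (rfft, zero-padded) of the windowed ramp filter."""
    pad = 1 << int(np.ceil(np.log2(2 * n_radial)))
    n = np.arange(-n_radial + 1, n_radial)
    h = np.zeros_like(n, dtype=float)
    h[n == 0] = 1.0 / (4.0 * bin_size**2)
    odd = n % 2 == 1
    h[odd] = -1.0 / (np.pi * n[odd] * bin_size) ** 2
    kernel = np.zeros(pad)
    kernel[: n.size] = h
    kernel = np.roll(kernel, -(n_radial - 1))
    H = np.real(np.fft.rfft(kernel))
    freq = np.fft.rfftfreq(pad, d=bin_size)
    nyq = 0.5 / bin_size
    if window == "ramp":
        w = np.ones_like(freq)
    elif window == "cosine":
        w = np.cos(np.pi * freq / (2.0 * nyq))
    elif window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * freq / nyq))
    else:
        raise ValueError(f"unknown filter window {window!r}")
    return H * w


def ramp_filter(n_radial: int, bin_size: float, window: str = "hann") -> np.ndarray:
    """Windowed ramp-filter frequency response on the padded rfft grid."""
    return _ramp_response(n_radial, float(bin_size), window)


def filter_sinogram(sinogram: np.ndarray, bin_size: float,
                    window: str = "hann") -> np.ndarray:
    """Apply the windowed ramp filter along the radial (last) axis."""
    s = np.asarray(sinogram, dtype=float)
    n_radial = s.shape[-1]
    H = _ramp_response(n_radial, float(bin_size), window)
    pad = 2 * (H.size - 1)
    spad = np.fft.rfft(s, n=pad, axis=-1)
    out = np.fft.irfft(spad * H, n=pad, axis=-1)[..., :n_radial]
    return out * bin_size  # discrete convolution -> integral


@lru_cache(maxsize=8)
def _backprojector_cached(n_angles: int, n_radial: int, bin_size: float,
                          n_rows: int, n_cols: int, pixel_size: float) -> sp.csr_matrix:
    geom = ProjectionGeometry(n_angles, n_radial, bin_size)
    rows_phys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * pixel_size
    cols_phys = (np.arange(n_cols) - (n_cols - 1) / 2.0) * pixel_size
    yy, xx = np.meshgrid(rows_phys, cols_phys, indexing="ij")
    npix = n_rows * n_cols
    t0 = geom.radial_offsets[0]

    rows_idx, cols_idx, vals = [], [], []
    pix = np.arange(npix)
    for k, ang in enumerate(geom.angles):
        t = xx * np.cos(ang) + yy * np.sin(ang)
        b = (t.ravel() - t0) / bin_size
        i0 = np.floor(b).astype(np.int64)
        frac = b - i0
        for off, w in ((0, 1.0 - frac), (1, frac)):
            i = i0 + off
            ok = (i >= 0) & (i < n_radial) & (w > 0)
            rows_idx.append(pix[ok])
            cols_idx.append(k * n_radial + i[ok])
            vals.append(w[ok])
    B = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(npix, n_angles * n_radial),
    )
    return B * (np.pi / n_angles)


def build_backprojector(geometry: ProjectionGeometry, grid_shape: tuple[int, int],
                        pixel_size: float) -> sp.csr_matrix:
    """Sparse back-projection operator (n_pixels x n_bins), angle weight folded in."""
    return _backprojector_cached(geometry.n_angles, geometry.n_radial,
                                 float(geometry.radial_bin_size),
                                 grid_shape[0], grid_shape[1], float(pixel_size))


def fbp(sinogram: np.ndarray, geometry: ProjectionGeometry,
        grid_shape: tuple[int, int], pixel_size: float,
        window: str = "hann") -> np.ndarray:
    """Filtered back-projection of one (n_angles, n_radial) sinogram."""
    if sinogram.shape != (geometry.n_angles, geometry.n_radial):
        raise ValueError(f"sinogram shape {sinogram.shape} does not match geometry "
                         f"({geometry.n_angles}, {geometry.n_radial})")
    return fbp_stack(sinogram[None], geometry, grid_shape, pixel_size, window)[0]


def fbp_stack(sinograms: np.ndarray, geometry: ProjectionGeometry,
              grid_shape: tuple[int, int], pixel_size: float,
              window: str = "hann") -> np.ndarray:
    """FBP of a stack (..., n_angles, n_radial) in one sparse product."""
    s = np.asarray(sinograms, dtype=float)
    lead = s.shape[:-2]
    if s.shape[-2:] != (geometry.n_angles, geometry.n_radial):
        raise ValueError("sinogram stack does not match geometry")
    filt = filter_sinogram(s, geometry.radial_bin_size, window)
    B = build_backprojector(geometry, grid_shape, pixel_size)
    flat = filt.reshape(-1, geometry.n_bins).T  # (n_bins, n_sinos)
    imgs = (B @ flat).T
    return imgs.reshape(lead + grid_shape)
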
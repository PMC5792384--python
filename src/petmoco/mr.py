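"""Spoiled gradient-echo MR image simulation per motion phase.

Each phase's proton-density/T1/T2 maps are warped through the ground-truth
deformation and converted to a steady-state spoiled-GRE magnitude signal

    S = PD * sin(a) * (1 - E1) / (1 - cos(a) E1) * exp(-TE/T2),  E1 = exp(-TR/T1),

with the sequence defaults TR = 9.56 ms, TE = 2.4 ms, FA = 46 deg.  MR
thermal noise is deliberately absent; magnitude images are normalized to a
study-wide maximum so registration sees consistent intensities across
phases.  T2 (not T2*) governs the echo decay since no off-resonance model
is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import MotionPhaseSpec, Phantom, deform_maps, true_deformation

__all__ = ["GreParams", "gre_signal", "simulate_phase_image", "simulate_all_phases"]


@dataclass(frozen=True)
class GreParams:
    """Spoiled-GRE sequence parameters (ms, degrees)."""

    tr: float = 9.56
    te: float = 2.4
    flip_angle: float = 46.0

    def __post_init__(self) -> None:
        if not 0 < self.te < self.tr:
            raise ValueError("need 0 < TE < TR")
        if not 0 < self.flip_angle < 180:
            raise ValueError("flip angle must lie in (0, 180) degrees")


def gre_signal(pd, t1, t2, params: GreParams = GreParams()) -> np.ndarray:
    """Steady-state spoiled-GRE signal; background (pd = 0) maps to 0."""
    pd = np.asarray(pd, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any((pd > 0) & ((t1 <= 0) | (t2 <= 0))):
        raise ValueError("proton-bearing tissue needs positive T1 and T2")
    alpha = np.deg2rad(params.flip_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(t1 > 0, np.exp(-params.tr / np.maximum(t1, 1e-12)), 0.0)
        decay = np.where(t2 > 0, np.exp(-params.te / np.maximum(t2, 1e-12)), 0.0)
    s = pd * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1) * decay
    return np.where(pd > 0, s, 0.0)


def simulate_phase_image(phantom: Phantom, spec: MotionPhaseSpec,
                         phase: tuple[int, int], params: GreParams = GreParams(),
                         kspace_roundtrip: bool = False) -> np.ndarray:
    """MR magnitude image for one motion phase (unnormalized).

    Warps the PD/T1/T2 maps to the phase, evaluates the GRE signal, and
    optionally passes the image through a fully sampled discrete Fourier
    transform round trip (encode then reconstruct, magnitude output).
    """
    u = true_deformation(phantom, spec, phase)
    pd = deform_maps(phantom, u, "pd")
    t1 = deform_maps(phantom, u, "t1")
    t2 = deform_maps(phantom, u, "t2")
    # interpolation can blend background (t=0) with tissue; keep decay finite
    img = gre_signal(pd, np.maximum(t1, 1e-6), np.maximum(t2, 1e-6), params)
    if kspace_roundtrip:
        img = np.abs(np.fft.ifft2(np.fft.fft2(img)))
    return img


def simulate_all_phases(phantom: Phantom, spec: MotionPhaseSpec,
                        params: GreParams = GreParams(),
                        kspace_roundtrip: bool = True) -> dict[tuple[int, int], np.ndarray]:
    """MR images for every motion phase, normalized to a study-wide max of 1."""
    images = {ph: simulate_phase_image(phantom, spec, ph, params, kspace_roundtrip)
              for ph in spec.phases()}
    peak = max(float(im.max()) for im in images.values())
    if peak <= 0:
        raise ValueError("all-zero MR study; check phantom proton densities")
    return {ph: im / peak for ph, im in images.items()}
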
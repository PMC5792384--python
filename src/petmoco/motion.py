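"""Motion estimation and correction.

Motion fields between MR phase images are estimated with multi-resolution
Demons registration (intensity-driven diffusion registration, SimpleITK
backend).  Fields warp images by pull-back: a ``to_reference`` field
resamples a phase image into the reference anatomy.  Both directions are
obtained by registering twice (phase->reference and reference->phase)
rather than by numerical field inversion.

``assemble_study`` builds the four dynamic series compared throughout the
package: ST (motionless reference), GA (reference-phase gate only), NMC
(phases summed without warping) and MC (phases warped to the reference
before summation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .phantom import MotionPhaseSpec, warp_map

__all__ = ["MotionField", "DemonsSettings", "demons_register",
           "estimate_all_fields", "warp_image", "warp_attenuation_map",
           "invert_field", "assemble_study"]


@dataclass
class MotionField:
    """Dense 2D displacement field in mm, shape (2, rows, cols), (dy, dx).

    ``direction`` is ``to_reference`` (warps a phase image into the
    reference frame by pull-back) or ``from_reference``.
    """

    displacement: np.ndarray
    pixel_size: float
    direction: str = "to_reference"
    source_phase: tuple[int, int] | None = None
    target_phase: tuple[int, int] | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, rows, cols)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        if self.direction not in ("to_reference", "from_reference"):
            raise ValueError(f"unknown field direction {self.direction!r}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.displacement[0], self.displacement[1])

    @staticmethod
    def zero(grid_shape: tuple[int, int], pixel_size: float,
             direction: str = "to_reference") -> "MotionField":
        return MotionField(np.zeros((2,) + tuple(grid_shape)), pixel_size, direction)


@dataclass
class DemonsSettings:
    """Multi-resolution Thirion-demons settings.

    ``iterations`` are per pyramid level, coarsest first; ``shrink_factors``
    are the corresponding downsampling factors; the displacement field is
    smoothed with a Gaussian of ``smoothing_sigma`` pixels after each
    update (diffusion-like regularization).
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (100, 50, 25)
    smoothing_sigma: float = 1.5
    intensity_difference_threshold: float = 0.001

    def __post_init__(self) -> None:
        if len(self.shrink_factors) != len(self.iterations):
            raise ValueError("shrink_factors and iterations must pair up")


def _to_sitk(image: np.ndarray, pixel_size: float) -> sitk.Image:
    im = sitk.GetImageFromArray(np.ascontiguousarray(image, dtype=np.float64))
    im.SetSpacing((pixel_size, pixel_size))
    return im


def demons_register(fixed: np.ndarray, moving: np.ndarray, pixel_size: float,
                    settings: DemonsSettings | None = None) -> MotionField:
    """Estimate the field u with moving(x + u(x)) ~ fixed(x).

    Multi-resolution Demons: the field from each coarse level initializes
    the next finer level.  Raises ``ValueError`` for constant images (no
    intensity gradient to drive the update).
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a grid")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        raise ValueError("cannot register constant images")
    st = settings or DemonsSettings()

    fixed_i = _to_sitk(fixed, pixel_size)
    moving_i = _to_sitk(moving, pixel_size)
    disp: sitk.Image | None = None
    for shrink, iters in zip(st.shrink_factors, st.iterations):
        if shrink > 1:
            f = sitk.SmoothingRecursiveGaussian(fixed_i, shrink * pixel_size / 2.0)
            m = sitk.SmoothingRecursiveGaussian(moving_i, shrink * pixel_size / 2.0)
            f = sitk.Shrink(f, [shrink, shrink])
            m = sitk.Shrink(m, [shrink, shrink])
        else:
            f, m = fixed_i, moving_i
        filt = sitk.DemonsRegistrationFilter()
        filt.SetNumberOfIterations(iters)
        filt.SmoothDisplacementFieldOn()
        filt.SetStandardDeviations(st.smoothing_sigma * shrink * pixel_size)
        filt.SetIntensityDifferenceThreshold(st.intensity_difference_threshold)
        if disp is None:
            disp = filt.Execute(f, m)
        else:
            init = sitk.Resample(disp, f, sitk.Transform(), sitk.sitkLinear,
                                 0.0, disp.GetPixelID())
            disp = filt.Execute(f, m, init)
    # upsample the final field to the full grid if the last level was coarse
    if disp.GetSize() != fixed_i.GetSize():
        disp = sitk.Resample(disp, fixed_i, sitk.Transform(), sitk.sitkLinear,
                             0.0, disp.GetPixelID())
    arr = sitk.GetArrayFromImage(disp)  # (rows, cols, (dx, dy)) in mm
    u = np.stack([arr[..., 1], arr[..., 0]])
    warped = warp_map(moving, u, pixel_size)
    nf, nw = fixed - fixed.mean(), warped - warped.mean()
    denom = np.linalg.norm(nf) * np.linalg.norm(nw)
    ncc = float((nf * nw).sum() / denom) if denom > 0 else 0.0
    return MotionField(u, pixel_size, similarity=ncc)


def estimate_all_fields(mr_phase_images: dict[tuple[int, int], np.ndarray],
                        reference_phase: tuple[int, int], pixel_size: float,
                        settings: DemonsSettings | None = None,
                        ) -> dict[tuple[int, int], tuple[MotionField, MotionField]]:
    """Register every phase to the reference and back.

    Returns ``{phase: (to_reference, from_reference)}``; the reference phase
    maps to exact zero fields.  Registration failures propagate tagged with
    the offending phase.
    """
    if reference_phase not in mr_phase_images:
        raise ValueError(f"reference phase {reference_phase} missing from MR images")
    ref = mr_phase_images[reference_phase]
    out: dict[tuple[int, int], tuple[MotionField, MotionField]] = {}
    for ph, img in mr_phase_images.items():
        if ph == reference_phase:
            z = MotionField.zero(ref.shape, pixel_size)
            out[ph] = (z, MotionField.zero(ref.shape, pixel_size, "from_reference"))
            continue
        try:
            to_ref = demons_register(ref, img, pixel_size, settings)
            from_ref = demons_register(img, ref, pixel_size, settings)
        except Exception as exc:  # annotate with the phase id
            raise RuntimeError(f"registration failed for phase {ph}: {exc}") from exc
        to_ref.source_phase, to_ref.target_phase = ph, reference_phase
        from_ref.direction = "from_reference"
        from_ref.source_phase, from_ref.target_phase = reference_phase, ph
        out[ph] = (to_ref, from_ref)
    return out


def warp_image(image: np.ndarray, field: MotionField,
               interpolation: str = "linear") -> np.ndarray:
    """Pull-back resampling of an image through a motion field."""
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return warp_map(image, field.displacement, field.pixel_size, order=order)


def warp_attenuation_map(reference_mu: np.ndarray, field: MotionField) -> np.ndarray:
    """Transform the reference mu map to a motion phase (MC attenuation).

    Requires a ``from_reference`` field: the phase-frame map samples the
    reference map by pull-back.
    """
    if field.direction != "from_reference":
        raise ValueError("warp_attenuation_map needs a from_reference field")
    return warp_image(reference_mu, field)


def invert_field(field: MotionField, n_iter: int = 30) -> MotionField:
    """Fixed-point inverse of a displacement field (v with v(x)+u(x+v)=0)."""
    u = field.displacement
    v = -u.copy()
    for _ in range(n_iter):
        v = -np.stack([warp_map(u[0], v, field.pixel_size),
                       warp_map(u[1], v, field.pixel_size)])
    direction = ("from_reference" if field.direction == "to_reference"
                 else "to_reference")
    return MotionField(v, field.pixel_size, direction,
                       field.target_phase, field.source_phase)


def assemble_study(per_phase_frames: dict[tuple[int, int], np.ndarray],
                   fields: dict[tuple[int, int], tuple[MotionField, MotionField]] | None,
                   mode: str, phase_spec: MotionPhaseSpec,
                   st_frames: np.ndarray | None = None) -> np.ndarray:
    """Combine per-phase per-frame reconstructions into one dynamic series.

    ``per_phase_frames[phase]`` is an (n_frames, rows, cols) stack in
    phase-weighted concentration units (each phase carries 1/total_phases
    of the frame's events).  Modes: ``ST`` returns the supplied motionless
    reference series; ``GA`` rescales the reference-phase stack by the
    gated count fraction; ``NMC`` sums phases unwarped; ``MC`` warps each
    phase to the reference through its ``to_reference`` field, then sums.
    """
    mode = mode.upper()
    if mode not in ("ST", "GA", "NMC", "MC"):
        raise ValueError(f"unknown study mode {mode!r}")
    if mode == "ST":
        if st_frames is None:
            raise ValueError("ST assembly needs the motionless reference series")
        return np.asarray(st_frames)

    ref = phase_spec.reference_phase
    missing = [ph for ph in phase_spec.phases() if ph not in per_phase_frames]
    if mode == "GA":
        if ref not in per_phase_frames:
            raise ValueError(f"GA assembly: missing reference phase {ref}")
        return np.asarray(per_phase_frames[ref]) * phase_spec.total_phases
    if missing:
        raise ValueError(f"{mode} assembly: missing phases {missing}")

    if mode == "NMC":
        return np.sum([per_phase_frames[ph] for ph in phase_spec.phases()], axis=0)
    if mode == "MC":
        if fields is None:
            raise ValueError("MC assembly needs motion fields")
        total = np.zeros_like(np.asarray(per_phase_frames[ref], dtype=float))
        for ph in phase_spec.phases():
            stack = np.asarray(per_phase_frames[ph], dtype=float)
            to_ref = fields[ph][0]
            if np.any(to_ref.displacement):
                stack = np.stack([warp_image(fr, to_ref) for fr in stack])
            total += stack
        return total
    raise AssertionError("unreachable")
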
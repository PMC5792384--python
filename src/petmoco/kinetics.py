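"""Tracer kinetics: input function, one-tissue-compartment TACs, spillover
measurement model, and voxelwise unweighted least-squares fitting.

Time is handled in minutes inside the kinetic equations and in seconds in
frame schedules; activity concentration is in arbitrary kBq/mL-like units.
The tissue curve follows the one-tissue compartment model

    Ct(t) = K1 * Cp(t) (x) exp(-k2 t),

and a measured myocardial frame value mixes ventricular blood-pool
spillover with the frame-averaged tissue curve:

    C_PET(t_m) = f_LV C_LV(t_m) + f_RV C_RV(t_m)
                 + (1 - f_LV - f_RV) * (1/dt_m) \\int_{t_m} Ct(tau) dtau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

__all__ = [
    "InputFunction",
    "FrameSchedule",
    "KineticParams",
    "FitResult",
    "eval_input_function",
    "tissue_tac",
    "frame_average",
    "measurement_model",
    "fit_voxel",
    "fit_voxels",
]

SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class InputFunction:
    """Parametric arterial input function Cp(t), t in minutes.

    Models: ``feng`` — Cp(t) = (A1 t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t}
    + A3 e^{-l3 t} with params (A1, A2, A3, l1, l2, l3); ``biexponential``
    — Cp(t) = A t e^{-a t} with params (A, a); ``tabulated`` — linear
    interpolation of (times, values) samples.  Parametric models satisfy
    Cp(0) = 0 and stay non-negative for the defaults used here.
    """

    model: str = "feng"
    params: tuple[float, ...] = (4000.0, 20.0, 21.0, 2.0, 0.12, 0.01)
    table: tuple[Sequence[float], Sequence[float]] | None = None

    def __call__(self, t):
        return eval_input_function(self, t)


def eval_input_function(aif: InputFunction, t) -> np.ndarray:
    """Evaluate Cp at times ``t`` (minutes, scalar or array); t must be >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("input function is defined for t >= 0 only")
    if aif.model == "feng":
        a1, a2, a3, l1, l2, l3 = aif.params
        cp = (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)
        return np.clip(cp, 0.0, None)
    if aif.model == "biexponential":
        a, lam = aif.params
        return a * t * np.exp(-lam * t)
    if aif.model == "tabulated":
        tt, vv = aif.table
        return np.interp(t, tt, vv, left=0.0, right=float(vv[-1]))
    raise ValueError(f"unknown input-function model {aif.model!r}")


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic framing; starts/durations in seconds.

    The default is the 17-frame protocol 8x5 s, 4x10 s, 2x20 s, 1x40 s,
    1x2 min, 1x4 min (520 s total).
    """

    frame_durations: tuple[float, ...] = (5.0,) * 8 + (10.0,) * 4 + (20.0,) * 2 + (40.0, 120.0, 240.0)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.frame_durations):
            raise ValueError("frame durations must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frame_durations)

    @property
    def frame_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.frame_durations)[:-1]])

    @property
    def frame_ends(self) -> np.ndarray:
        return np.cumsum(self.frame_durations)

    @property
    def total_seconds(self) -> float:
        return float(np.sum(self.frame_durations))

    @property
    def midpoints_min(self) -> np.ndarray:
        return (self.frame_starts + np.asarray(self.frame_durations) / 2.0) / SEC_PER_MIN


@dataclass(frozen=True)
class KineticParams:
    """One-tissue-compartment parameters plus LV/RV spillover fractions.

    Physical (generating) parameters are non-negative with
    f_lv + f_rv <= 1; ``require_physical`` enforces that and is called by
    the forward-model operations.  Fitted estimates are allowed to be
    negative: at low counts the unweighted least-squares estimator spreads
    symmetrically around the truth, and clipping it at zero would bias
    every ROI average upward.
    """

    K1: float
    k2: float
    f_lv: float = 0.0
    f_rv: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.K1, self.k2, self.f_lv, self.f_rv)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("kinetic parameters must be finite")

    def require_physical(self) -> "KineticParams":
        if min(self.K1, self.k2, self.f_lv, self.f_rv) < 0:
            raise ValueError("kinetic parameters must be non-negative")
        if self.f_lv + self.f_rv > 1.0 + 1e-12:
            raise ValueError("spillover fractions must satisfy f_lv + f_rv <= 1")
        return self


def _fine_grid(total_seconds: float, fine_dt: float) -> np.ndarray:
    """Fine time grid in minutes covering [0, total_seconds]."""
    n = int(round(total_seconds / fine_dt))
    return np.arange(n + 1) * (fine_dt / SEC_PER_MIN)


def tissue_tac(params: KineticParams, aif: InputFunction,
               total_seconds: float = 520.0, fine_dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """One-tissue-compartment TAC on a fine grid via trapezoid convolution.

    Uses the exponential-kernel identity
    ``Ct(t) = K1 e^{-k2 t} \\int_0^t Cp(s) e^{k2 s} ds`` with trapezoid
    quadrature, which equals the trapezoid discretisation of the
    convolution integral.  Returns ``(t_min, Ct)``.
    """
    if fine_dt > 1.0:
        raise ValueError("fine_dt must be <= 1 s")
    params.require_physical()
    t = _fine_grid(total_seconds, fine_dt)
    cp = eval_input_function(aif, t)
    ct = params.K1 * _conv_exp(cp, t, params.k2)
    return t, ct


def _conv_exp(cp: np.ndarray, t_min: np.ndarray, k2: float) -> np.ndarray:
    """(Cp (x) exp(-k2 t)) on grid t_min, trapezoid rule, k2 in 1/min."""
    # exp(k2*t) stays within float64 range for k2 <= ~60 over a 10-min study
    g = cp * np.exp(k2 * t_min)
    integral = cumulative_trapezoid(g, t_min, initial=0.0)
    return np.exp(-k2 * t_min) * integral


def frame_average(t_min: np.ndarray, tac: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Per-frame time average of a fine-grid TAC (trapezoid quadrature)."""
    if schedule.total_seconds / SEC_PER_MIN > t_min[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the fine time grid")
    cum = cumulative_trapezoid(tac, t_min, initial=0.0)
    starts = schedule.frame_starts / SEC_PER_MIN
    ends = schedule.frame_ends / SEC_PER_MIN
    c0 = np.interp(starts, t_min, cum)
    c1 = np.interp(ends, t_min, cum)
    return (c1 - c0) / (ends - starts)


def measurement_model(params: KineticParams, aif: InputFunction,
                      lv_tac: np.ndarray, rv_tac: np.ndarray,
                      schedule: FrameSchedule, fine_dt: float = 0.1) -> np.ndarray:
    """Framed myocardial measurement: spillover-mixed, frame-averaged TAC."""
    params.require_physical()
    t, ct = tissue_tac(params, aif, schedule.total_seconds, fine_dt)
    framed = frame_average(t, ct, schedule)
    return (params.f_lv * np.asarray(lv_tac) + params.f_rv * np.asarray(rv_tac)
            + (1.0 - params.f_lv - params.f_rv) * framed)


@dataclass
class FitResult:
    params: KineticParams
    residual_norm: float
    converged: bool
    n_evaluations: int = 0


DEFAULT_INIT = KineticParams(0.5, 0.2, 0.1, 0.05)
DEFAULT_BOUNDS = ((-5.0, 5.0), (0.0, 2.0), (-2.0, 2.0), (-2.0, 2.0))


class _ModelCache:
    """Shared precomputation for repeated fits against one (aif, schedule)."""

    def __init__(self, aif: InputFunction, schedule: FrameSchedule, fine_dt: float):
        self.schedule = schedule
        self.t = _fine_grid(schedule.total_seconds, fine_dt)
        self.cp = eval_input_function(aif, self.t)
        self.starts = schedule.frame_starts / SEC_PER_MIN
        self.ends = schedule.frame_ends / SEC_PER_MIN
        self.widths = self.ends - self.starts

    def basis_grid(self, k2_max: float, n: int = 40) -> tuple[np.ndarray, np.ndarray]:
        """Unit-K1 framed tissue curves on a k2 grid (for profiled init)."""
        key = (round(k2_max, 6), n)
        cache = getattr(self, "_basis", None)
        if cache is None:
            cache = self._basis = {}
        if key not in cache:
            k2s = np.linspace(1e-3, k2_max, n)
            cache[key] = (k2s, np.stack([self.framed_unit_tissue(k) for k in k2s]))
        return cache[key]

    def framed_unit_tissue(self, k2: float) -> np.ndarray:
        """Frame-averaged tissue curve for K1 = 1 at washout k2."""
        ct = _conv_exp(self.cp, self.t, k2)
        cum = cumulative_trapezoid(ct, self.t, initial=0.0)
        c0 = np.interp(self.starts, self.t, cum)
        c1 = np.interp(self.ends, self.t, cum)
        return (c1 - c0) / self.widths


def _residual_fn(cache: _ModelCache, lv: np.ndarray, rv: np.ndarray,
                 target: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    def resid(theta: np.ndarray) -> np.ndarray:
        k1, k2, flv, frv = theta
        model = flv * lv + frv * rv + (1.0 - flv - frv) * k1 * cache.framed_unit_tissue(k2)
        r = model - target
        # soft constraint keeping f_lv + f_rv inside the simplex
        excess = max(0.0, flv + frv - 1.0)
        return np.append(r, 1e3 * np.max(np.abs(target)) * excess)
    return resid


def _profile_init(cache: _ModelCache, lv: np.ndarray, rv: np.ndarray,
                  target: np.ndarray, bounds) -> KineticParams:
    """Near-global starting point by profiling over k2.

    For fixed k2 the model is linear in (f_lv, f_rv, (1-f_lv-f_rv)*K1), so
    an ordinary least-squares solve on a k2 grid locates the global basin
    of the unweighted cost; the bounded nonlinear polish then refines it.
    """
    k2s, basis = cache.basis_grid(bounds[1][1])
    best_cost, best = np.inf, None
    for k2, b in zip(k2s, basis):
        A = np.stack([lv, rv, b], axis=1)
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        r = A @ coef - target
        cost = float(r @ r)
        if cost < best_cost:
            best_cost, best = cost, (k2, coef)
    k2, (flv, frv, k1p) = best
    fb = flv + frv
    if fb > 0.95:
        flv, frv = 0.95 * flv / fb, 0.95 * frv / fb
        fb = 0.95
    k1 = k1p / (1.0 - fb)

    def interior(v, lo, hi):  # strict interior start for the trf polish
        eps = 1e-4 * (hi - lo)
        return float(np.clip(v, lo + eps, hi - eps))

    return KineticParams(interior(k1, *bounds[0]), interior(k2, *bounds[1]),
                         interior(flv, *bounds[2]), interior(frv, *bounds[3]))


def fit_voxel(tac_measured: np.ndarray, aif: InputFunction,
              lv_tac: np.ndarray, rv_tac: np.ndarray, schedule: FrameSchedule,
              init: KineticParams | None = None,
              bounds=DEFAULT_BOUNDS, fine_dt: float = 0.1,
              fit_spillover: bool = True,
              _cache: "_ModelCache | None" = None) -> FitResult:
    """Unweighted least-squares fit of (K1, k2, f_lv, f_rv) to a framed TAC.

    With ``init=None`` the start point comes from a profiled grid search
    over k2 (globally robust); passing explicit ``init`` skips it.
    Non-convergence is reported through ``FitResult.converged`` rather than
    an exception; an all-zero measured TAC short-circuits to K1 = 0 with the
    convergence flag lowered.  ``fit_spillover=False`` pins both spillover
    fractions at their initial values (used for spillover-free round trips).
    """
    target = np.asarray(tac_measured, dtype=float)
    if schedule.n_frames < 5:
        raise ValueError("need at least 5 frames to fit 4 parameters")
    if not np.any(target):
        return FitResult(KineticParams(0.0, DEFAULT_INIT.k2, 0.0, 0.0), 0.0, False)

    cache = _cache or _ModelCache(aif, schedule, fine_dt)
    lv = np.asarray(lv_tac, dtype=float)
    rv = np.asarray(rv_tac, dtype=float)

    if init is None:
        init = (_profile_init(cache, lv, rv, target, bounds)
                if fit_spillover else DEFAULT_INIT)

    if fit_spillover:
        x0 = np.array([init.K1, init.k2, init.f_lv, init.f_rv])
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        fun = _residual_fn(cache, lv, rv, target)
    else:
        flv0, frv0 = init.f_lv, init.f_rv
        x0 = np.array([init.K1, init.k2])
        lo = np.array([bounds[0][0], bounds[1][0]])
        hi = np.array([bounds[0][1], bounds[1][1]])
        full = _residual_fn(cache, lv, rv, target)
        fun = lambda th: full(np.array([th[0], th[1], flv0, frv0]))  # noqa: E731

    sol = least_squares(fun, x0, bounds=(lo, hi), method="trf",
                        ftol=1e-8, xtol=1e-10, gtol=1e-10)
    if fit_spillover:
        k1, k2, flv, frv = sol.x
    else:
        k1, k2 = sol.x
        flv, frv = init.f_lv, init.f_rv
    tot = flv + frv
    if tot > 1.0 > 0.0 < min(flv, frv):  # project penalty overshoot back
        flv, frv = flv / tot, frv / tot
    params = KineticParams(float(k1), float(k2), float(flv), float(frv))
    return FitResult(params, float(np.linalg.norm(sol.fun[: schedule.n_frames])),
                     bool(sol.success), int(sol.nfev))


def fit_voxels(tac_stack: np.ndarray, aif: InputFunction,
               lv_tac: np.ndarray, rv_tac: np.ndarray, schedule: FrameSchedule,
               init: KineticParams | None = None,
               bounds=DEFAULT_BOUNDS, fine_dt: float = 0.1) -> list[FitResult]:
    """Fit many voxels (rows of ``tac_stack``) sharing one AIF/schedule."""
    cache = _ModelCache(aif, schedule, fine_dt)
    return [fit_voxel(row, aif, lv_tac, rv_tac, schedule, init=init,
                      bounds=bounds, fine_dt=fine_dt, _cache=cache)
            for row in np.atleast_2d(tac_stack)]
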
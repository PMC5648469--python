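"""One-compartment kinetic modelling of dynamic 13N-ammonia PET.

The deGrado model describes the early (0-4 min) myocardial kinetics of
13N-NH3 with a single tissue compartment,

    dCt/dt = K1 * Ca(t) - k2 * Ct(t),   Ct(0) = 0,

where ``Ca`` is the arterial (blood-pool) activity.  The measured signal
includes a fractional blood volume / spillover term,

    Cmeas(t) = (1 - Vb) * Ct(t) + Vb * Ca(t).

Myocardial blood flow follows from K1 through the extraction fraction:
constant E (about 0.90 for 13N-NH3) or a Renkin-Crone flow dependence
``E(F) = 1 - a * exp(-b / F)``.  Activities are assumed decay-corrected, as
produced by standard reconstruction.  Rates: K1 in ml/min/g, k2 in 1/min;
the time axis is in seconds and the min->s conversion happens inside the
model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, least_squares

__all__ = [
    "DeGradoParams",
    "ExtractionModel",
    "TAC",
    "DeGradoFit",
    "degrado_forward",
    "frame_average",
    "degrado_fit",
    "k1_to_flow",
    "DEGRADO_BOUNDS",
]

SEC_PER_MIN = 60.0

DEGRADO_BOUNDS = {"K1": (0.0, 8.0), "k2": (0.0, 2.0), "Vb": (0.0, 0.6)}


@dataclass(frozen=True)
class DeGradoParams:
    """K1: uptake (ml/min/g); k2: washout (1/min); Vb: blood fraction [0,1)."""

    K1: float
    k2: float = 0.3
    Vb: float = 0.3

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError(f"K1 must be >= 0, got {self.K1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if not 0 <= self.Vb < 1:
            raise ValueError(f"Vb must be in [0, 1), got {self.Vb}")


@dataclass(frozen=True)
class ExtractionModel:
    """Tracer extraction: constant E, or Renkin-Crone E(F) = 1 - a*exp(-b/F)."""

    mode: str = "constant"
    E_const: float = 0.90
    a: float = 0.607
    b: float = 1.25

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "renkin_crone"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")
        if self.mode == "constant" and not 0 < self.E_const <= 1:
            raise ValueError("E_const must be in (0, 1]")
        if self.mode == "renkin_crone" and not 0 <= self.a < 1:
            raise ValueError("Renkin-Crone 'a' must be in [0, 1) so E > 0")

    def extraction(self, flow):
        if self.mode == "constant":
            return np.full_like(np.asarray(flow, float), self.E_const)
        return 1.0 - self.a * np.exp(-self.b / np.asarray(flow, float))


@dataclass(frozen=True)
class TAC:
    """Frame-averaged, decay-corrected time-activity curve for one segment."""

    frame_start: np.ndarray
    frame_duration: np.ndarray
    activity: np.ndarray
    segment_id: int | str = 0

    def __post_init__(self) -> None:
        n = len(self.frame_start)
        if len(self.frame_duration) != n or len(self.activity) != n:
            raise ValueError("frame_start, frame_duration, activity must align")
        if np.any(np.asarray(self.frame_duration) <= 0):
            raise ValueError("frame durations must be > 0")

    @property
    def frame_mid(self) -> np.ndarray:
        return np.asarray(self.frame_start) + 0.5 * np.asarray(self.frame_duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment": self.segment_id,
            "frame_start_s": self.frame_start,
            "frame_duration_s": self.frame_duration,
            "activity_kBq_per_mL": self.activity,
        })


def _blood_arrays(blood):
    from .phantom import AIFCurve

    if isinstance(blood, AIFCurve):
        return np.asarray(blood.times, float), np.asarray(blood.values, float)
    t, v = blood
    return np.asarray(t, float), np.asarray(v, float)


def degrado_forward(params: DeGradoParams, blood, times) -> np.ndarray:
    """Continuous model activity (1-Vb)*Ct + Vb*Ca at ``times`` (seconds).

    ``Ct`` is the exponential convolution ``K1 * int Ca(tau) e^{-k2 (t-tau)}``
    evaluated by trapezoidal quadrature of ``e^{k2 tau} Ca(tau)`` on the
    blood curve's own sampling, so accuracy follows the blood-curve grid.
    """
    bt, bc = _blood_arrays(blood)
    if np.any(bc < -1e-12):
        raise ValueError("blood curve must be non-negative")
    times = np.asarray(times, float)
    k1_s = params.K1 / SEC_PER_MIN
    k2_s = params.k2 / SEC_PER_MIN
    # integral on the blood grid, then interpolated to the requested times
    growth = np.exp(k2_s * (bt - bt[-1]))   # shifted to avoid overflow
    integ = cumulative_trapezoid(growth * bc, bt, initial=0.0)
    ct_grid = k1_s * np.exp(-k2_s * (bt - bt[-1])) * integ
    ct = np.interp(times, bt, ct_grid)
    ca = np.interp(times, bt, bc)
    return (1.0 - params.Vb) * ct + params.Vb * ca


def frame_average(curve_times, curve_values, schedule) -> np.ndarray:
    """Average a continuous curve over each frame of a schedule.

    Exact for the piecewise-linear interpolant of the curve (cumulative
    trapezoid evaluated at the frame edges).  ``schedule`` is a
    :class:`~duoflow.phantom.FrameSchedule`.
    """
    t = np.asarray(curve_times, float)
    v = np.asarray(curve_values, float)
    starts = np.asarray(schedule.frame_start, float)
    ends = starts + np.asarray(schedule.frame_duration, float)
    if starts[0] < t[0] - 1e-9 or ends[-1] > t[-1] + 1e-9:
        raise ValueError("frame schedule extends past the curve support")
    cum = cumulative_trapezoid(v, t, initial=0.0)
    c_start = np.interp(starts, t, cum)
    c_end = np.interp(ends, t, cum)
    return (c_end - c_start) / (ends - starts)


@dataclass
class DeGradoFit:
    params: DeGradoParams
    rss: float
    converged: bool
    at_bounds: dict = field(default_factory=dict)
    n_frames_used: int = 0


def degrado_fit(tac: TAC, blood, fit_window_s: float = 240.0,
                bounds: dict | None = None) -> DeGradoFit:
    """Weighted NLLS fit of the one-compartment model to a frame-averaged TAC.

    Only frames starting inside the fit window (default: the first 4 min)
    are used; residuals are weighted by sqrt(frame duration) so squared
    weights are proportional to frame duration.
    """
    from .phantom import FrameSchedule

    bounds = bounds or DEGRADO_BOUNDS
    bt, bc = _blood_arrays(blood)
    use = np.asarray(tac.frame_start, float) < fit_window_s
    starts = np.asarray(tac.frame_start, float)[use]
    durs = np.asarray(tac.frame_duration, float)[use]
    obs = np.asarray(tac.activity, float)[use]
    if use.sum() < 6:
        raise ValueError("need at least 6 frames inside the fit window")
    sched = FrameSchedule(frame_start=starts, frame_duration=durs)
    w = np.sqrt(durs)

    def residuals(theta):
        p = DeGradoParams(K1=theta[0], k2=theta[1], Vb=theta[2])
        model = frame_average(bt, degrado_forward(p, (bt, bc), bt), sched)
        return w * (model - obs)

    # Patlak-like early-slope initialization for K1
    cum_ca = cumulative_trapezoid(bc, bt, initial=0.0) / SEC_PER_MIN  # min-scaled
    mids = starts + 0.5 * durs
    x = np.interp(mids[:6], bt, cum_ca)
    y = obs[:6]
    k1_0 = float(np.sum(x * y) / np.sum(x * x)) if np.sum(x * x) > 0 else 1.0
    k1_0 = float(np.clip(k1_0, bounds["K1"][0] + 1e-6, bounds["K1"][1]))

    lb = np.array([bounds[p][0] for p in ("K1", "k2", "Vb")])
    ub = np.array([bounds[p][1] for p in ("K1", "k2", "Vb")])
    x0 = np.clip(np.array([k1_0, 0.2, 0.3]), lb, ub)
    sol = least_squares(residuals, x0, bounds=(lb, ub),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    params = DeGradoParams(K1=float(sol.x[0]), k2=float(sol.x[1]), Vb=float(sol.x[2]))
    tol = 1e-8
    names = ("K1", "k2", "Vb")
    at_bounds = {
        p: bool(sol.x[i] - lb[i] < tol or ub[i] - sol.x[i] < tol)
        for i, p in enumerate(names)
    }
    return DeGradoFit(params=params, rss=float(np.sum(sol.fun ** 2)),
                      converged=bool(sol.success), at_bounds=at_bounds,
                      n_frames_used=int(use.sum()))


def k1_to_flow(K1, extraction: ExtractionModel | None = None):
    """Myocardial blood flow (ml/min/g) from the uptake rate K1.

    Constant mode divides by E; Renkin-Crone mode solves
    ``K1 = F * (1 - a*exp(-b/F))`` for F by bracketed root finding.
    """
    extraction = extraction or ExtractionModel()
    k1_arr = np.atleast_1d(np.asarray(K1, float))
    if np.any(k1_arr < 0):
        raise ValueError("K1 must be >= 0")
    if extraction.mode == "constant":
        flow = k1_arr / extraction.E_const
    else:
        a, b = extraction.a, extraction.b
        flow = np.empty_like(k1_arr)
        for i, k1 in enumerate(k1_arr):
            if k1 == 0:
                flow[i] = 0.0
                continue
            f = lambda m: m * (1.0 - a * np.exp(-b / m)) - k1
            hi = max(2.0 * k1 / (1.0 - a), 1.0)
            while f(hi) < 0:
                hi *= 2.0
                if hi > 1e6:
                    raise ValueError("no Renkin-Crone root in bracket")
            flow[i] = brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12)
    return float(flow[0]) if np.isscalar(K1) or np.ndim(K1) == 0 else flow
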
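"""Two-tissue compartment model: forward simulation, nonlinear fitting,
VT and %COV, and the %COV quality-control filter.

Model
-----
Free/non-specific tissue concentration C1 and specifically bound C2
obey, driven by parent plasma cp(t):

    dC1/dt = K1 cp - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2,      C1(0) = C2(0) = 0

Measured activity adds the vascular signal:

    C_model(t) = (1 - vb) (C1 + C2) + vb * C_whole_blood(t)

The total distribution volume is VT = K1/k2 (1 + k3/k4) (K1/k2 when
k3 = 0).  The forward solution is evaluated exactly for piecewise-
linear cp via recursive exponential convolution, then duration-averaged
over each acquisition frame; an adaptive-ODE route is kept as a
cross-check.

Fit quality is summarized as %COV = 100 * SE(VT)/VT with SE propagated
from the least-squares parameter covariance by the delta method; fits
with %COV above a threshold (20 by default) are excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, interpolate, optimize, signal

from .errors import NumericalError, ScheduleError, ValidationError
from .input_function import PlasmaInputFunction
from .tac_io import FrameSchedule, TimeActivityCurve

__all__ = [
    "TwoTissueParams",
    "KineticFit",
    "compute_vt",
    "simulate_2tcm",
    "fit_2tcm",
    "qc_filter",
]


@dataclass
class TwoTissueParams:
    """Rate constants of the reversible 2-TCM.

    K1 [mL/cm^3/min] and k2 [1/min] are influx/efflux across the
    blood-brain barrier; k3/k4 [1/min] exchange with the specific
    binding compartment; vb is the fractional blood volume.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.05

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValidationError("K1 and k2 must be non-negative")
        if self.K1 > 0 and self.k2 <= 0:
            raise ValidationError("k2 must be positive when K1 > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ValidationError("k3 and k4 must be non-negative")
        if not (0.0 <= self.vb <= 1.0):
            raise ValidationError("vb must lie in [0, 1]")


def compute_vt(params: TwoTissueParams) -> float:
    """Total distribution volume VT = K1/k2 (1 + k3/k4).

    Reduces to K1/k2 when k3 = 0 (no specific binding) regardless of
    k4.  Irreversible binding (k3 > 0, k4 = 0) has no finite VT.
    """
    if params.k2 == 0:
        raise ValidationError("VT undefined for k2 = 0")
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 == 0:
        raise ValidationError("VT undefined for irreversible binding (k3 > 0, k4 = 0)")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


# ---------------------------------------------------------------------------
# forward model


def _expconv(cp: np.ndarray, dt: float, theta: float) -> np.ndarray:
    """y(t) = int_0^t cp(s) exp(-theta (t-s)) ds, exact for piecewise-
    linear cp on a uniform grid (recursive update via lfilter)."""
    x = theta * dt
    if x < 1e-6:
        # series limits: A -> dt, B -> dt/2 (trapezoid)
        A = dt * (1.0 - x / 2.0 + x * x / 6.0)
        B = dt * (0.5 - x / 3.0 + x * x / 8.0)
        E = np.exp(-x)
    else:
        E = np.exp(-x)
        A = (1.0 - E) / theta
        B = A - (1.0 - E * (1.0 + x)) / (theta * theta * dt)
    y = signal.lfilter([B, A - B], [1.0, -E], cp)
    if cp[0] != 0.0:  # enforce y(0) = 0 exactly
        n = cp.size
        y -= B * cp[0] * E ** np.arange(n)
    return y


def _tissue_impulse_coefficients(p: TwoTissueParams) -> list[tuple[float, float]]:
    """(amplitude, rate) pairs of the tissue impulse response
    h(t) = sum_i phi_i exp(-theta_i t), with C1+C2 = cp * h."""
    if p.k3 == 0.0 and p.k4 == 0.0:
        return [(p.K1, p.k2)]
    s = p.k2 + p.k3 + p.k4
    disc = s * s - 4.0 * p.k2 * p.k4
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    th1 = 0.5 * (s - root)
    th2 = 0.5 * (s + root)
    if root < 1e-12:  # defective (equal-root) case: nudge apart
        th1 *= 1.0 - 1e-9
        th2 *= 1.0 + 1e-9
        root = th2 - th1
    phi1 = p.K1 * (p.k3 + p.k4 - th1) / root
    phi2 = p.K1 * (th2 - p.k3 - p.k4) / root
    return [(phi1, th1), (phi2, th2)]


def _continuous_model(p: TwoTissueParams, input_fn: PlasmaInputFunction) -> np.ndarray:
    """Model activity on the input-function grid."""
    tissue = np.zeros_like(input_fn.cp)
    if p.K1 > 0:
        dt = input_fn.dt
        for phi, theta in _tissue_impulse_coefficients(p):
            tissue += phi * _expconv(input_fn.cp, dt, theta)
    return (1.0 - p.vb) * tissue + p.vb * input_fn.whole_blood


def _frame_average(time: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Duration-average of a continuous curve over each frame (trapezoid)."""
    cumint = integrate.cumulative_trapezoid(curve, time, initial=0.0)
    I_start = np.interp(schedule.frame_start, time, cumint)
    I_end = np.interp(schedule.frame_end, time, cumint)
    return (I_end - I_start) / schedule.durations


def simulate_2tcm(
    params: TwoTissueParams,
    input_fn: PlasmaInputFunction,
    schedule: FrameSchedule,
    label: str = "",
    method: str = "analytic",
) -> TimeActivityCurve:
    """Forward-simulate the framed TAC for the given rate constants.

    ``method="analytic"`` (default) uses exact exponential convolution
    on the input grid; ``method="ode"`` integrates the state equations
    with an adaptive solver and exists as an independent cross-check.
    """
    if schedule.scan_end > input_fn.time[-1] + 1e-9:
        raise ScheduleError("frame schedule extends beyond the input-function support")
    if method == "analytic":
        model = _continuous_model(params, input_fn)
        time = input_fn.time
    elif method == "ode":
        time, model = _ode_model(params, input_fn)
    else:
        raise ValidationError(f"unknown simulation method {method!r}")
    frames = _frame_average(time, model, schedule)
    return TimeActivityCurve(schedule, np.clip(frames, 0.0, None), label=label)


def _ode_model(p: TwoTissueParams, input_fn: PlasmaInputFunction):
    cp = interpolate.interp1d(input_fn.time, input_fn.cp, assume_sorted=True)

    def rhs(t, y):
        c1, c2 = y
        return [
            p.K1 * float(cp(t)) - (p.k2 + p.k3) * c1 + p.k4 * c2,
            p.k3 * c1 - p.k4 * c2,
        ]

    sol = integrate.solve_ivp(
        rhs,
        (0.0, float(input_fn.time[-1])),
        [0.0, 0.0],
        t_eval=input_fn.time,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        max_step=0.25,
    )
    tissue = sol.y[0] + sol.y[1]
    return input_fn.time, (1.0 - p.vb) * tissue + p.vb * input_fn.whole_blood


# ---------------------------------------------------------------------------
# fitting


@dataclass
class KineticFit:
    """Result of a 2-TCM weighted nonlinear least-squares fit."""

    params: TwoTissueParams
    covariance: np.ndarray
    vt: float
    vt_se: float
    pct_cov: float
    param_pct_cov: dict
    residual_rss: float
    converged: bool


#: deterministic multi-start points (K1, k2, k3, k4) spanning slow and
#: fast kinetics; 2-TCM objective surfaces are multimodal.
DEFAULT_STARTS: tuple[tuple[float, float, float, float], ...] = (
    (0.15, 0.10, 0.05, 0.03),
    (0.05, 0.03, 0.02, 0.01),
    (0.50, 0.30, 0.10, 0.05),
)

DEFAULT_BOUNDS = ([1e-6, 1e-6, 1e-6, 1e-6], [2.0, 1.0, 1.0, 1.0])


def _vt_gradient(K1, k2, k3, k4) -> np.ndarray:
    vt = K1 / k2 * (1.0 + k3 / k4)
    return np.array(
        [
            (1.0 + k3 / k4) / k2,
            -vt / k2,
            K1 / (k2 * k4),
            -K1 * k3 / (k2 * k4 * k4),
        ]
    )


def fit_2tcm(
    tac: TimeActivityCurve,
    input_fn: PlasmaInputFunction,
    vb: float = 0.05,
    weights: str | np.ndarray = "uniform",
    starts=DEFAULT_STARTS,
    bounds=DEFAULT_BOUNDS,
    max_nfev: int = 400,
) -> KineticFit:
    """Fit (K1, k2, k3, k4) with vb held fixed (5% vascular signal by
    default); VT and its standard error follow by the delta method.

    Weighting is uniform by default; pass ``weights="duration"`` for
    frame-duration weights or an explicit per-frame array.
    """
    y = tac.activity
    if y.size < 8:
        raise ValidationError("need >= 8 frames for a 4-parameter fit")
    if isinstance(weights, str):
        if weights == "uniform":
            w = np.ones_like(y)
        elif weights == "duration":
            w = np.sqrt(tac.schedule.durations / tac.schedule.durations.max())
        else:
            raise ValidationError(f"unknown weighting scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)

    schedule = tac.schedule

    def resid(x):
        p = TwoTissueParams(x[0], x[1], x[2], x[3], vb)
        model = _frame_average(input_fn.time, _continuous_model(p, input_fn), schedule)
        return w * (model - y)

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                resid, x0, bounds=bounds, method="trf", x_scale="jac", max_nfev=max_nfev
            )
        except Exception:  # pragma: no cover - optimizer failures
            continue
        if best is None:
            best = res
        elif res.cost < best.cost * (1.0 - 1e-10):
            best = res
        elif abs(res.cost - best.cost) <= 1e-10 * max(best.cost, 1e-300):
            if res.x[0] < best.x[0]:  # tie-break: lowest K1
                best = res
    if best is None:
        raise NumericalError("2-TCM fit failed from every start point")

    K1, k2, k3, k4 = best.x
    params = TwoTissueParams(float(K1), float(k2), float(k3), float(k4), vb)
    converged = bool(best.status > 0)
    rss = float(2.0 * best.cost)
    n, npar = y.size, 4

    J = best.jac
    JTJ = J.T @ J
    sigma2 = rss / max(n - npar, 1)
    try:
        cov = sigma2 * np.linalg.inv(JTJ)
        singular = not np.all(np.isfinite(cov))
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JTJ)
        singular = True

    vt = compute_vt(params)
    grad = _vt_gradient(K1, k2, k3, k4)
    var_vt = float(grad @ cov @ grad)
    if singular or var_vt < 0 or not np.isfinite(var_vt):
        warnings.warn("singular parameter covariance: %COV set to +inf", RuntimeWarning)
        vt_se, pct = np.inf, np.inf
    else:
        vt_se = float(np.sqrt(var_vt))
        pct = 100.0 * vt_se / vt if vt > 0 else np.inf

    names = ("K1", "k2", "k3", "k4")
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    param_pct = {
        nm: (100.0 * float(se) / abs(val) if abs(val) > 0 else np.inf)
        for nm, se, val in zip(names, diag, best.x)
    }
    return KineticFit(
        params=params,
        covariance=cov,
        vt=float(vt),
        vt_se=vt_se,
        pct_cov=float(pct),
        param_pct_cov=param_pct,
        residual_rss=rss,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    fits: pd.DataFrame, threshold: float = 20.0, per_parameter: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Retain rows whose %COV is at or below the threshold (inclusive).

    ``fits`` needs columns subject_id, roi, pct_cov (plus per-parameter
    pct_cov_* columns if ``per_parameter``).  Returns the filtered frame
    and the per-ROI retained count (the effective sample size).
    """
    if threshold <= 0:
        raise ValidationError("%COV threshold must be positive")
    if len(fits) == 0:
        return fits.copy(), pd.Series(dtype=int, name="n_retained")
    keep = fits["pct_cov"] <= threshold
    if per_parameter:
        for col in fits.columns:
            if col.startswith("pct_cov_"):
                keep &= fits[col] <= threshold
    kept = fits[keep].copy()
    n_roi = kept.groupby("roi", observed=True).size().rename("n_retained")
    return kept, n_roi
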
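"""Arterial plasma input function construction.

The kinetic model is driven by the concentration of *parent* (un-
metabolized) radioligand in arterial plasma.  Building it from raw
blood data takes four corrections, each with its own small model:

1. **Dispersion** — the continuous withdrawal line smears the true
   blood curve; the smearing is a convolution with a monoexponential
   kernel of time constant tau (16 s for this sampler) and is undone by
   iterative deconvolution.
2. **Merging** — the dispersion-corrected sampler curve covers the
   first ~22.5 min; timed manual samples cover the rest, with a fitted
   exponential tail for extrapolation.
3. **Blood-to-plasma ratio** — a bi-exponential r(t) fitted to manual
   blood/plasma pairs converts whole blood to total plasma activity.
4. **Parent fraction** — a Hill function fp(t) = 1 - a t^b/(c + t^b)
   fitted to the measured fraction of unmetabolized ligand strips the
   radiometabolite signal, leaving cp(t) = blood(t)/r(t) * fp(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import ModelError, NumericalError, ValidationError

__all__ = [
    "BloodCurve",
    "BloodPlasmaRatioModel",
    "ParentFractionModel",
    "DispersionModel",
    "PlasmaInputFunction",
    "dispersion_convolve",
    "dispersion_correct",
    "merge_blood_samples",
    "fit_blood_to_plasma",
    "fit_hill_parent_fraction",
    "build_plasma_input",
    "construct_input_function",
    "default_dense_grid",
]

#: 1 s spacing resolves the bolus peak; 125 min covers the scan.
DEFAULT_GRID_END_MIN = 125.0
DEFAULT_GRID_STEP_MIN = 1.0 / 60.0


def default_dense_grid(
    end_min: float = DEFAULT_GRID_END_MIN, step_min: float = DEFAULT_GRID_STEP_MIN
) -> np.ndarray:
    n = int(round(end_min / step_min))
    return np.linspace(0.0, end_min, n + 1)


@dataclass
class BloodCurve:
    """Whole-blood activity (kBq/mL) versus time (minutes)."""

    time: np.ndarray
    activity: np.ndarray
    source: str = "auto"  # auto | manual | merged

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        self.time, self.activity = t, a
        if t.ndim != 1 or t.shape != a.shape or t.size == 0:
            raise ValidationError("time and activity must be equal-length 1-D sequences")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("blood sample times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValidationError("blood activity must be finite")

    @property
    def is_uniform(self) -> bool:
        dt = np.diff(self.time)
        return bool(dt.size == 0 or np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12))


@dataclass
class BloodPlasmaRatioModel:
    """Bi-exponential blood-to-plasma activity ratio r(t).

    plasma(t) = blood(t) / r(t) under the blood-to-plasma convention
    (set ``inverse=True`` if the ratios were measured as plasma/blood).
    """

    a1: float
    lambda1: float  # 1/min
    a2: float
    lambda2: float  # 1/min
    inverse: bool = False

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("decay rates must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = self.a1 * np.exp(-self.lambda1 * t) + self.a2 * np.exp(-self.lambda2 * t)
        return 1.0 / r if self.inverse else r


@dataclass
class ParentFractionModel:
    """Hill model of the unmetabolized (parent) fraction.

    fp(t) = 1 - a * t**b / (c + t**b); fp(0) = 1, monotone non-increasing,
    asymptote 1 - a.  Units: a unitless in [0, 1], b unitless > 0,
    c in min**b > 0.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValidationError("Hill amplitude a must lie in [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise ValidationError("Hill exponent b and half-saturation c must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore"):
            tb = np.where(t > 0, np.power(np.clip(t, 0, None), self.b), 0.0)
        return 1.0 - self.a * tb / (self.c + tb)


@dataclass
class DispersionModel:
    """Monoexponential line-dispersion kernel and deconvolution settings."""

    tau_s: float = 16.0
    n_iter: int = 50
    smoothing_fwhm_s: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValidationError("dispersion time constant tau must be >= 0")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")


@dataclass
class PlasmaInputFunction:
    """Metabolite- and dispersion-corrected parent plasma activity.

    Evaluated on a dense, uniform time grid starting at 0.  ``cp`` is
    the model-driving concentration; ``whole_blood`` on the same grid
    feeds the vascular term of the tissue model.
    """

    time: np.ndarray
    cp: np.ndarray
    whole_blood: np.ndarray
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        self.time = t
        self.cp = np.asarray(self.cp, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValidationError("input-function grid must increase strictly from 0")
        if self.cp.shape != t.shape or self.whole_blood.shape != t.shape:
            raise ValidationError("cp and whole_blood must match the time grid")
        if np.any(self.cp < 0):
            raise ValidationError("cp must be non-negative (clip before constructing)")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def cp_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.cp)

    def blood_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.whole_blood)


# ---------------------------------------------------------------------------
# dispersion


def _dispersion_kernel(tau_min: float, dt: float) -> np.ndarray:
    """Discrete causal kernel (1/tau) exp(-t/tau), normalized to unit sum."""
    n = max(int(np.ceil(8.0 * tau_min / dt)), 2)
    k = np.exp(-np.arange(n) * dt / tau_min)
    return k / k.sum()


def dispersion_convolve(curve: BloodCurve, tau_s: float) -> BloodCurve:
    """Forward model: smear a true blood curve through the sampling line."""
    if tau_s < 0:
        raise ValidationError("tau must be >= 0")
    if tau_s == 0:
        return BloodCurve(curve.time.copy(), curve.activity.copy(), curve.source)
    if not curve.is_uniform:
        raise ValidationError("dispersion convolution needs a uniform time grid")
    dt = float(curve.time[1] - curve.time[0])
    k = _dispersion_kernel(tau_s / 60.0, dt)
    smeared = np.convolve(curve.activity, k)[: curve.time.size]
    return BloodCurve(curve.time.copy(), smeared, curve.source)


def _analytic_deconvolve(time: np.ndarray, measured: np.ndarray, tau_min: float) -> np.ndarray:
    """Closed-form inverse of the monoexponential smearing:
    g(t) = m(t) + tau * m'(t).  Exact for the continuous operator."""
    return measured + tau_min * np.gradient(measured, time)


def dispersion_correct(
    measured: BloodCurve, model: DispersionModel, method: str = "rl"
) -> BloodCurve:
    """Remove sampling-line dispersion from a continuously sampled curve.

    ``method="rl"`` Gaussian-smooths the measurement
    (``model.smoothing_fwhm_s``; set 0 to disable) to curb noise
    amplification, then runs Richardson-Lucy multiplicative updates
    seeded from the analytic inverse.  ``method="analytic"`` returns
    the closed-form inverse g = m + tau m' directly and serves as an
    independent cross-check.
    """
    if model.tau_s == 0:
        return BloodCurve(measured.time.copy(), measured.activity.copy(), measured.source)
    if not measured.is_uniform:
        raise ValidationError("dispersion correction needs a uniform time grid")
    t = measured.time
    m = np.clip(measured.activity, 0.0, None)
    dt = float(t[1] - t[0])
    tau_min = model.tau_s / 60.0

    if method == "analytic":
        g = np.clip(_analytic_deconvolve(t, m, tau_min), 0.0, None)
        return BloodCurve(t.copy(), g, measured.source)
    if method != "rl":
        raise ValidationError(f"unknown deconvolution method {method!r}")

    if model.smoothing_fwhm_s > 0:
        sigma = model.smoothing_fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0))) / (dt * 60.0)
        m = ndimage.gaussian_filter1d(m, sigma, mode="nearest")
    k = _dispersion_kernel(tau_min, dt)
    g = np.clip(_analytic_deconvolve(t, m, tau_min), 0.0, None)
    if not np.any(g > 0):
        return BloodCurve(t.copy(), g, measured.source)
    eps = 1e-12 * float(m.max() if m.max() > 0 else 1.0)
    k_flip = k[::-1]
    n = m.size
    # window sensitivity K^T 1 normalizes the update at the record end,
    # where the flipped kernel runs off the data
    sens = np.convolve(np.ones(n), k_flip)[k.size - 1 : k.size - 1 + n]
    for _ in range(model.n_iter):
        pred = np.convolve(g, k)[:n]
        ratio = m / (pred + eps)
        corr = np.convolve(ratio, k_flip)[k.size - 1 : k.size - 1 + n]
        g = g * corr / sens
    return BloodCurve(t.copy(), np.clip(g, 0.0, None), measured.source)


# ---------------------------------------------------------------------------
# merging


def merge_blood_samples(
    auto: BloodCurve,
    manual: BloodCurve,
    grid: np.ndarray | None = None,
    scale_to_manual: bool = True,
    tail_n: int = 3,
) -> BloodCurve:
    """Combine the (already dispersion-corrected) sampler curve with
    timed manual samples into one whole-blood curve on a dense grid.

    The sampler curve is used over its own support; manual samples take
    over beyond it, bridged by log-linear interpolation, and a single
    exponential fitted to the last ``tail_n`` manual samples extrapolates
    past the final draw.  When a manual sample falls inside the sampler
    window the sampler curve is rescaled so the two agree at the first
    such time (cross-calibration); pass ``scale_to_manual=False`` to skip.

    Before interpolation the sampler record is rebinned adaptively —
    bin width grows roughly as t/8, from 2 s at the bolus to 30 s late —
    which averages down counting noise where the curve carries no fast
    structure while preserving the peak.
    """
    if grid is None:
        grid = default_dense_grid()
    grid = np.asarray(grid, dtype=float)
    auto_end = float(auto.time[-1])
    late = manual.time > auto_end
    if grid[-1] > auto_end and not late.any():
        raise ValidationError(
            "no manual samples beyond the sampler window: cannot extrapolate the tail"
        )

    auto_t, auto_act = _rebin_adaptive(auto.time, np.clip(auto.activity, 0.0, None))
    if scale_to_manual:
        overlap = manual.time <= auto_end
        if overlap.any():
            t0 = float(manual.time[overlap][0])
            ref = float(np.interp(t0, auto_t, auto_act))
            if ref > 0:
                auto_act = auto_act * float(manual.activity[overlap][0]) / ref

    # knots beyond the sampler window: (auto_end, auto value) then late manual
    end_val = float(np.interp(auto_end, auto_t, auto_act))
    knot_t = np.concatenate([[auto_end], manual.time[late]])
    knot_a = np.concatenate([[end_val], np.clip(manual.activity[late], 0.0, None)])

    out = np.empty_like(grid)
    in_auto = grid <= auto_end
    out[in_auto] = np.interp(grid[in_auto], auto_t, auto_act)

    mid = (~in_auto) & (grid <= knot_t[-1])
    if mid.any():
        out[mid] = _loglinear_interp(grid[mid], knot_t, knot_a)

    beyond = grid > knot_t[-1]
    if beyond.any():
        lam, a0, t_ref = _fit_tail(manual.time[late], np.clip(manual.activity[late], 0, None), tail_n)
        out[beyond] = a0 * np.exp(-lam * (grid[beyond] - t_ref))
    return BloodCurve(grid, np.clip(out, 0.0, None), "merged")


def _rebin_adaptive(
    time: np.ndarray, act: np.ndarray, min_width_s: float = 2.0, max_width_s: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average a densely sampled curve into bins whose width grows as
    ~t/8 (bounded to [min_width_s, max_width_s]); returns bin centroids.

    Counting noise scales down with the square root of the bin width;
    pairing the mean activity with the mean time within each bin keeps
    the rebinned curve unbiased to first order.  Sparse records
    (spacing already above the target width) pass through unchanged.
    """
    if time.size < 8:
        return time, act
    dt = float(np.median(np.diff(time)))
    edges = [float(time[0])]
    while edges[-1] < time[-1]:
        w_s = float(np.clip(edges[-1] * 60.0 / 8.0, min_width_s, max_width_s))
        edges.append(edges[-1] + max(w_s / 60.0, dt))
    t_c, a_c = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (time >= lo) & (time < hi)
        if sel.any():
            t_c.append(float(time[sel].mean()))
            a_c.append(float(act[sel].mean()))
    return np.asarray(t_c), np.asarray(a_c)


def _loglinear_interp(x, xp, fp):
    """Exponential (log-linear) interpolation, falling back to linear
    wherever a knot is non-positive."""
    fp = np.asarray(fp, dtype=float)
    if np.all(fp > 0):
        return np.exp(np.interp(x, xp, np.log(fp)))
    return np.interp(x, xp, fp)


def _fit_tail(t, a, tail_n: int):
    """Least-squares single exponential through the last >= tail_n samples."""
    if t.size < max(tail_n, 2):
        raise ValidationError(
            f"need >= {max(tail_n, 2)} late manual samples for tail extrapolation"
        )
    t_fit, a_fit = t[-tail_n:], a[-tail_n:]
    if np.any(a_fit <= 0):
        return 0.0, float(a_fit[-1]), float(t_fit[-1])
    slope, intercept = np.polyfit(t_fit, np.log(a_fit), 1)
    lam = max(-slope, 0.0)
    t_ref = float(t_fit[-1])
    return lam, float(np.exp(intercept + slope * t_ref)), t_ref


# ---------------------------------------------------------------------------
# component-model fits


def fit_blood_to_plasma(time, ratio, max_rate: float = 1.0) -> BloodPlasmaRatioModel:
    """Least-squares bi-exponential fit to blood-to-plasma ratio samples.

    Rates are bounded to [0, ``max_rate``]/min and amplitudes by the
    data scale: ratio kinetics (cell partitioning, protein binding) are
    slow, and unconstrained fast components — invisible at the manual
    sampling times — would blow up when the model is extrapolated to
    the early bolus window.
    """
    t = np.asarray(time, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if t.size < 4:
        raise ValidationError("need >= 4 ratio observations for a bi-exponential fit")
    if np.any(r <= 0):
        raise ValidationError("blood-to-plasma ratios must be positive")

    def resid(p):
        a1, l1, a2, l2 = p
        return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) - r

    r0 = float(r[0])
    a_max = 2.0 * float(r.max())
    starts = [
        (0.3 * r0, 0.1, 0.7 * r0, 1e-3),
        (0.5 * r0, 0.5, 0.5 * r0, 1e-2),
        (r0, 1e-4, 1e-3 * r0, 0.3),
    ]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                resid,
                x0,
                bounds=([0, 0, 0, 0], [a_max, max_rate, a_max, max_rate]),
                ftol=1e-15,
                xtol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NumericalError("bi-exponential ratio fit failed from every start")
    a1, l1, a2, l2 = best.x
    model = BloodPlasmaRatioModel(float(a1), float(l1), float(a2), float(l2))
    if np.any(model(np.linspace(0, max(t[-1], 1.0), 50)) <= 0):
        raise ModelError("fitted blood-to-plasma ratio is non-positive on the scan window")
    return model


def fit_hill_parent_fraction(time, parent_fraction) -> ParentFractionModel:
    """Least-squares Hill fit to parent-fraction observations in [0, 1]."""
    t = np.asarray(time, dtype=float)
    f = np.asarray(parent_fraction, dtype=float)
    if t.size < 4:
        raise ValidationError("need >= 4 parent-fraction observations")
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("parent fractions must lie in [0, 1]")
    if np.allclose(f, 1.0):
        return ParentFractionModel(0.0, 1.0, 1.0)

    def resid(p):
        a, b, log_c = p
        tb = np.power(np.clip(t, 1e-12, None), b)
        return (1.0 - a * tb / (np.exp(log_c) + tb)) - f

    drop = float(1.0 - f.min())
    best = None
    t_mid = max(float(np.median(t)), 1.0)
    for b0 in (0.5, 1.0, 2.0, 4.0):
        x0 = (min(max(drop, 0.05), 1.0), b0, b0 * np.log(t_mid))
        try:
            res = optimize.least_squares(
                resid, x0, bounds=([0.0, 1e-3, -30.0], [1.0, 12.0, 60.0])
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NumericalError("Hill parent-fraction fit failed from every start")
    a, b, log_c = best.x
    return ParentFractionModel(float(a), float(b), float(np.exp(log_c)))


# ---------------------------------------------------------------------------
# assembly


def build_plasma_input(
    blood: BloodCurve,
    b2p: BloodPlasmaRatioModel,
    fp: ParentFractionModel,
    grid: np.ndarray | None = None,
) -> PlasmaInputFunction:
    """cp(t) = blood(t) / r(t) * fp(t) on the dense grid, clipped at 0.

    ``blood`` must already be dispersion-corrected and merged.
    """
    if grid is None:
        grid = blood.time if blood.time[0] == 0 else default_dense_grid(float(blood.time[-1]))
    grid = np.asarray(grid, dtype=float)
    r = b2p(grid)
    if np.any(r <= 0):
        raise ModelError("blood-to-plasma ratio model is non-positive on the grid")
    wb = np.clip(np.interp(grid, blood.time, blood.activity), 0.0, None)
    cp = np.clip(wb / r * fp(grid), 0.0, None)
    return PlasmaInputFunction(
        grid, cp, wb, components={"b2p": b2p, "parent_fraction": fp}
    )


def construct_input_function(
    auto: BloodCurve,
    manual: pd.DataFrame,
    dispersion: DispersionModel | None = None,
    grid: np.ndarray | None = None,
) -> PlasmaInputFunction:
    """Full chain: dispersion-correct the sampler curve, merge with manual
    samples, fit the ratio and parent-fraction models, build cp(t).

    ``manual`` columns: time_min, activity_kBq_ml, plasma_activity_kBq_ml,
    parent_fraction (NaN allowed where a sample contributes no assay).
    """
    dispersion = dispersion or DispersionModel()
    corrected = dispersion_correct(auto, dispersion)
    manual_curve = BloodCurve(
        manual["time_min"].to_numpy(float),
        manual["activity_kBq_ml"].to_numpy(float),
        "manual",
    )
    merged = merge_blood_samples(corrected, manual_curve, grid=grid)

    has_plasma = manual["plasma_activity_kBq_ml"].notna()
    ratios = (
        manual.loc[has_plasma, "activity_kBq_ml"]
        / manual.loc[has_plasma, "plasma_activity_kBq_ml"]
    )
    b2p = fit_blood_to_plasma(manual.loc[has_plasma, "time_min"].to_numpy(float), ratios)

    has_fp = manual["parent_fraction"].notna()
    fp = fit_hill_parent_fraction(
        manual.loc[has_fp, "time_min"].to_numpy(float),
        manual.loc[has_fp, "parent_fraction"].to_numpy(float),
    )
    pif = build_plasma_input(merged, b2p, fp, grid=merged.time)
    pif.components["dispersion"] = dispersion
    return pif


def read_blood_table(path) -> tuple[BloodCurve, pd.DataFrame]:
    """Split a blood CSV into the sampler curve and the manual-sample frame."""
    from .tac_io import _read_delimited  # shared delimiter sniffing

    df = _read_delimited(path)
    for col in ("time_min", "activity_kBq_ml", "source"):
        if col not in df.columns:
            raise ValidationError(f"blood table missing column {col!r}")
    for col in ("plasma_activity_kBq_ml", "parent_fraction"):
        if col not in df.columns:
            df[col] = np.nan
    auto_df = df[df["source"] == "auto"]
    if len(auto_df) == 0:
        raise ValidationError("blood table contains no sampler (source='auto') rows")
    auto = BloodCurve(
        auto_df["time_min"].to_numpy(float), auto_df["activity_kBq_ml"].to_numpy(float), "auto"
    )
    manual = df[df["source"] == "manual"].reset_index(drop=True)
    return auto, manual
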
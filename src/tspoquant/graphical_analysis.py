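"""Logan graphical analysis: ROI VT estimates and voxel-wise parametric
VT images.

For reversible tracer kinetics, plotting Y(t) = int_0^t C ds / C(t)
against X(t) = int_0^t cp ds / C(t) becomes linear once the system has
equilibrated (t >= t*), with slope equal to VT.  Integrals use the
trapezoid rule on frame mid-times anchored at (0, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, ndimage

from .errors import NumericalError, ValidationError
from .input_function import PlasmaInputFunction
from .tac_io import DynamicImage, TimeActivityCurve

__all__ = ["LoganFit", "ParametricImage", "logan_vt", "choose_t_star", "parametric_logan"]

DEFAULT_T_STAR_MIN = 30.0


@dataclass
class LoganFit:
    vt: float  # slope, mL/cm^3
    intercept: float  # minutes
    t_star: float  # minutes
    n_points: int
    max_rel_dev: float  # worst relative residual of the used points


@dataclass
class ParametricImage:
    """Voxel-wise VT map; NaN outside the mask or where the fit failed."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")


def _logan_points(tac: TimeActivityCurve, input_fn: PlasmaInputFunction):
    """(mid_times, X, Y, usable) for all frames; usable requires C > 0."""
    mid = tac.schedule.mid_times
    C = tac.activity
    t_anchor = np.concatenate([[0.0], mid])
    C_anchor = np.concatenate([[0.0], C])
    int_C = integrate.cumulative_trapezoid(C_anchor, t_anchor, initial=0.0)[1:]
    cum_cp = integrate.cumulative_trapezoid(input_fn.cp, input_fn.time, initial=0.0)
    int_cp = np.interp(mid, input_fn.time, cum_cp)
    usable = C > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.where(usable, int_cp / C, np.nan)
        Y = np.where(usable, int_C / C, np.nan)
    return mid, X, Y, usable


def logan_vt(
    tac: TimeActivityCurve, input_fn: PlasmaInputFunction, t_star: float = DEFAULT_T_STAR_MIN
) -> LoganFit:
    """Ordinary least squares over frames with mid-time >= t*; the slope
    is the Logan VT.  Frames with non-positive activity are excluded."""
    if t_star >= tac.schedule.scan_end:
        raise ValidationError("t* lies at or beyond the end of the scan")
    mid, X, Y, usable = _logan_points(tac, input_fn)
    sel = usable & (mid >= t_star)
    if sel.sum() < 3:
        raise ValidationError(
            f"only {int(sel.sum())} usable Logan points after t* = {t_star} min (need >= 3)"
        )
    slope, intercept = np.polyfit(X[sel], Y[sel], 1)
    pred = slope * X[sel] + intercept
    denom = np.maximum(np.abs(pred), 1e-12)
    max_rel_dev = float(np.max(np.abs(Y[sel] - pred) / denom))
    return LoganFit(
        vt=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=int(sel.sum()),
        max_rel_dev=max_rel_dev,
    )


def choose_t_star(
    tac: TimeActivityCurve,
    input_fn: PlasmaInputFunction,
    criterion: float = 0.10,
    final_fraction: float = 1 / 3,
) -> float:
    """Earliest frame mid-time from which the Logan plot is linear.

    A reference line is fitted to the final ``final_fraction`` of usable
    points (at least 3); the returned t* is the mid-time of the earliest
    frame such that every later point deviates from that line by at most
    ``criterion`` (relative, in Y).  Falls back to the scan midpoint with
    a warning when no frame qualifies.
    """
    if not (0.0 < criterion < 0.5):
        raise ValidationError("linearity criterion must lie in (0, 0.5)")
    mid, X, Y, usable = _logan_points(tac, input_fn)
    idx = np.flatnonzero(usable)
    if idx.size < 3:
        raise ValidationError("fewer than 3 usable Logan points")
    n_ref = max(3, int(np.ceil(idx.size * final_fraction)))
    ref = idx[-n_ref:]
    slope, intercept = np.polyfit(X[ref], Y[ref], 1)
    pred = slope * X[idx] + intercept
    rel = np.abs(Y[idx] - pred) / np.maximum(np.abs(pred), 1e-12)
    ok_from = None
    for j in range(idx.size):
        if np.all(rel[j:] <= criterion):
            ok_from = idx[j]
            break
    if ok_from is None:
        warnings.warn(
            "no start time satisfies the Logan linearity criterion; using the scan midpoint",
            RuntimeWarning,
        )
        return float(tac.schedule.scan_end / 2.0)
    return float(mid[ok_from])


def parametric_logan(
    image: DynamicImage,
    input_fn: PlasmaInputFunction,
    t_star: float = DEFAULT_T_STAR_MIN,
    mask: np.ndarray | None = None,
    smooth_fwhm_mm: float = 0.0,
) -> ParametricImage:
    """Voxel-wise Logan VT inside a mask.

    Optional spatial Gaussian pre-smoothing of each frame
    (``smooth_fwhm_mm`` > 0) trades resolution for voxel-level noise;
    with it off, each voxel equals ``logan_vt`` on that voxel's TAC
    exactly.  Failed voxels are NaN.
    """
    if mask is None:
        mask = np.ones(image.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.spatial_shape:
        raise ValidationError("mask shape does not match image spatial shape")
    if not mask.any():
        raise ValidationError("mask selects no voxels")

    voxels = image.voxels
    if smooth_fwhm_mm > 0:
        sigma_vox = smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / image.voxel_size
        voxels = np.stack(
            [ndimage.gaussian_filter(voxels[..., k], sigma_vox) for k in range(voxels.shape[-1])],
            axis=-1,
        )

    values = np.full(image.spatial_shape, np.nan)
    n_failed = 0
    for i, j, k in zip(*np.nonzero(mask)):
        tac = TimeActivityCurve(image.schedule, voxels[i, j, k, :], noisy=True)
        try:
            values[i, j, k] = logan_vt(tac, input_fn, t_star).vt
        except (ValidationError, NumericalError):
            n_failed += 1
    if n_failed:
        warnings.warn(f"Logan fit failed in {n_failed} voxels (set to NaN)", RuntimeWarning)
    return ParametricImage(values=values, mask=mask, voxel_size=image.voxel_size)
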
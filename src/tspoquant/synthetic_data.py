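"""Synthetic FEPPA-like data with stored ground truth.

No raw PET data ships with this package; every pipeline stage is
exercised against generated data whose true input function, rate
constants and VT are known.  The generator emulates:

* a bolus plasma curve (linear rise to an early peak, tri-exponential
  washout), metabolite loss following a Hill parent-fraction curve,
  a bi-exponential blood-to-plasma ratio, and monoexponential sampler
  dispersion (tau = 16 s);
* the 34-frame / 125-min acquisition schedule and the arterial
  sampling protocol (continuous withdrawal to 22.5 min, manual draws
  at 2.5, 7, 12, 15, 30, 45, 60, 90 and 120 min);
* reversible 2-TCM tissue kinetics with a 5% blood volume and
  count-rate-like proportional TAC noise;
* a genotype-stratified cohort (11/11 HC and 14/16 PD subjects for
  MAB/HAB) whose regional VT distributions are calibrated to published
  FEPPA group means — HABs run roughly 30-45% above MABs — with a null
  disease effect by default (``disease_effect`` shifts PD cells).

Cell means default to the published per-(ROI, genotype) values pooled
across disease, which makes the disease null exact; pass per-
(roi, disease, genotype) keys in ``roi_means`` to reproduce the
published cell-level table instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartment_model import TwoTissueParams, compute_vt, fit_2tcm, qc_filter, simulate_2tcm
from .errors import ValidationError
from .input_function import (
    BloodCurve,
    BloodPlasmaRatioModel,
    DispersionModel,
    ParentFractionModel,
    PlasmaInputFunction,
    default_dense_grid,
    dispersion_convolve,
)
from .pvc import PointSpreadFunction, TissueProbabilityMaps, smooth_with_psf
from .tac_io import CohortTable, DynamicImage, FrameSchedule, default_feppa_schedule

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "REFERENCE_ROIS",
    "REFERENCE_CELL_MEANS",
    "REFERENCE_CELL_SDS",
    "REFERENCE_N_PER_CELL",
    "pooled_genotype_means",
    "simulate_input_function",
    "params_for_target_vt",
    "simulate_cohort",
    "simulate_phantom",
    "calibrate_noise_for_qc",
]

MANUAL_SAMPLE_TIMES_MIN: tuple[float, ...] = (2.5, 7.0, 12.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
AUTO_SAMPLER_END_MIN = 22.5

REFERENCE_ROIS: tuple[str, ...] = (
    "frontal",
    "temporal",
    "cingulate",
    "occipital",
    "insula",
    "hippocampus",
    "cerebellum",
    "thalamus",
    "caudate",
    "putamen",
)

#: Calibration targets: regional VT cell means (mL/cm^3) and SDs for a
#: FEPPA TSPO cohort, keyed (roi, disease, genotype).
REFERENCE_CELL_MEANS: dict[tuple[str, str, str], float] = {
    ("frontal", "HC", "MAB"): 13.9, ("frontal", "HC", "HAB"): 19.4,
    ("frontal", "PD", "MAB"): 11.8, ("frontal", "PD", "HAB"): 18.7,
    ("temporal", "HC", "MAB"): 11.9, ("temporal", "HC", "HAB"): 16.1,
    ("temporal", "PD", "MAB"): 11.4, ("temporal", "PD", "HAB"): 16.6,
    ("cingulate", "HC", "MAB"): 9.9, ("cingulate", "HC", "HAB"): 12.3,
    ("cingulate", "PD", "MAB"): 8.2, ("cingulate", "PD", "HAB"): 13.7,
    ("occipital", "HC", "MAB"): 12.3, ("occipital", "HC", "HAB"): 17.2,
    ("occipital", "PD", "MAB"): 13.6, ("occipital", "PD", "HAB"): 18.3,
    ("insula", "HC", "MAB"): 10.6, ("insula", "HC", "HAB"): 14.0,
    ("insula", "PD", "MAB"): 9.8, ("insula", "PD", "HAB"): 15.7,
    ("hippocampus", "HC", "MAB"): 8.7, ("hippocampus", "HC", "HAB"): 10.4,
    ("hippocampus", "PD", "MAB"): 8.6, ("hippocampus", "PD", "HAB"): 12.4,
    ("cerebellum", "HC", "MAB"): 9.6, ("cerebellum", "HC", "HAB"): 14.8,
    ("cerebellum", "PD", "MAB"): 9.2, ("cerebellum", "PD", "HAB"): 14.7,
    ("thalamus", "HC", "MAB"): 12.8, ("thalamus", "HC", "HAB"): 16.8,
    ("thalamus", "PD", "MAB"): 13.5, ("thalamus", "PD", "HAB"): 19.9,
    ("caudate", "HC", "MAB"): 8.1, ("caudate", "HC", "HAB"): 12.4,
    ("caudate", "PD", "MAB"): 7.2, ("caudate", "PD", "HAB"): 12.9,
    ("putamen", "HC", "MAB"): 8.0, ("putamen", "HC", "HAB"): 13.5,
    ("putamen", "PD", "MAB"): 7.8, ("putamen", "PD", "HAB"): 12.4,
}

REFERENCE_CELL_SDS: dict[tuple[str, str, str], float] = {
    ("frontal", "HC", "MAB"): 2.8, ("frontal", "HC", "HAB"): 2.8,
    ("frontal", "PD", "MAB"): 0.2, ("frontal", "PD", "HAB"): 1.6,
    ("temporal", "HC", "MAB"): 2.9, ("temporal", "HC", "HAB"): 1.8,
    ("temporal", "PD", "MAB"): 1.2, ("temporal", "PD", "HAB"): 1.2,
    ("cingulate", "HC", "MAB"): 1.6, ("cingulate", "HC", "HAB"): 1.5,
    ("cingulate", "PD", "MAB"): 0.0, ("cingulate", "PD", "HAB"): 1.1,
    ("occipital", "HC", "MAB"): 2.7, ("occipital", "HC", "HAB"): 2.4,
    ("occipital", "PD", "MAB"): 3.0, ("occipital", "PD", "HAB"): 1.4,
    ("insula", "HC", "MAB"): 1.8, ("insula", "HC", "HAB"): 1.6,
    ("insula", "PD", "MAB"): 0.6, ("insula", "PD", "HAB"): 1.3,
    ("hippocampus", "HC", "MAB"): 1.9, ("hippocampus", "HC", "HAB"): 1.4,
    ("hippocampus", "PD", "MAB"): 2.4, ("hippocampus", "PD", "HAB"): 1.2,
    ("cerebellum", "HC", "MAB"): 2.2, ("cerebellum", "HC", "HAB"): 1.6,
    ("cerebellum", "PD", "MAB"): 0.7, ("cerebellum", "PD", "HAB"): 1.3,
    ("thalamus", "HC", "MAB"): 3.6, ("thalamus", "HC", "HAB"): 2.6,
    ("thalamus", "PD", "MAB"): 2.2, ("thalamus", "PD", "HAB"): 2.0,
    ("caudate", "HC", "MAB"): 1.8, ("caudate", "HC", "HAB"): 1.6,
    ("caudate", "PD", "MAB"): 0.3, ("caudate", "PD", "HAB"): 1.0,
    ("putamen", "HC", "MAB"): 1.8, ("putamen", "HC", "HAB"): 1.3,
    ("putamen", "PD", "MAB"): 0.4, ("putamen", "PD", "HAB"): 1.1,
}

REFERENCE_N_PER_CELL: dict[tuple[str, str], int] = {
    ("HC", "MAB"): 11,
    ("HC", "HAB"): 11,
    ("PD", "MAB"): 14,
    ("PD", "HAB"): 16,
}

#: injected amount (mCi): mean, SD per disease group
REFERENCE_INJECTED = {"HC": (4.8, 0.22), "PD": (5.0, 0.27)}


def pooled_genotype_means(
    cell_means: dict | None = None,
    cell_sds: dict | None = None,
    n_per_cell: dict | None = None,
) -> tuple[dict, dict]:
    """Per-(roi, genotype) means and SDs pooled across disease (n-weighted
    means; SDs pooled as root-mean-square).  The default cohort design
    uses these so the disease effect is exactly null."""
    cell_means = cell_means or REFERENCE_CELL_MEANS
    cell_sds = cell_sds or REFERENCE_CELL_SDS
    n_per_cell = n_per_cell or REFERENCE_N_PER_CELL
    means: dict[tuple[str, str], float] = {}
    sds: dict[tuple[str, str], float] = {}
    for roi in REFERENCE_ROIS:
        for gen in ("MAB", "HAB"):
            ns = [n_per_cell[(d, gen)] for d in ("HC", "PD")]
            ms = [cell_means[(roi, d, gen)] for d in ("HC", "PD")]
            vs = [cell_sds[(roi, d, gen)] ** 2 for d in ("HC", "PD")]
            w = np.asarray(ns, float) / sum(ns)
            means[(roi, gen)] = float(np.dot(w, ms))
            sds[(roi, gen)] = float(np.sqrt(np.dot(w, vs)))
    return means, sds


@dataclass
class CohortDesign:
    """Study design for the cohort simulator.

    ``roi_means``/``roi_sds`` may be keyed per (roi, genotype) — the
    default, disease-null — or per (roi, disease, genotype) for explicit
    cell-level calibration.  ``disease_effect`` is an additive VT shift
    applied to PD cells (default 0: no disease effect).
    """

    n_per_cell: dict = field(default_factory=lambda: dict(REFERENCE_N_PER_CELL))
    roi_means: dict = field(default_factory=lambda: pooled_genotype_means()[0])
    roi_sds: dict = field(default_factory=lambda: pooled_genotype_means()[1])
    disease_effect: float = 0.0
    noise_pct: float = 5.0
    #: sigma of the lognormal per-subject noise multiplier: fit quality
    #: is largely subject-driven (plasma assay, dose, motion), so QC
    #: failures co-occur across a subject's ROIs
    subject_noise_sigma: float = 0.6
    qc_pass_target: float | None = None
    qc_threshold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_cell.values()):
            raise ValidationError("cell sizes must be >= 0")
        if any(m <= 0 for m in self.roi_means.values()):
            raise ValidationError("VT means must be positive")
        if self.noise_pct < 0:
            raise ValidationError("noise percentage must be >= 0")

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[0] for k in self.roi_means))

    def cell_mean(self, roi: str, disease: str, genotype: str) -> float:
        base = self.roi_means.get((roi, disease, genotype), self.roi_means.get((roi, genotype)))
        if base is None:
            raise ValidationError(f"no mean configured for ({roi}, {disease}, {genotype})")
        return base + (self.disease_effect if disease == "PD" else 0.0)

    def cell_sd(self, roi: str, disease: str, genotype: str) -> float:
        sd = self.roi_sds.get((roi, disease, genotype), self.roi_sds.get((roi, genotype)))
        if sd is None:
            raise ValidationError(f"no SD configured for ({roi}, {disease}, {genotype})")
        return sd


@dataclass
class GroundTruth:
    """Oracle storage for a generated dataset."""

    vt_table: pd.DataFrame  # subject_id, roi, true_vt (+ context columns)
    params: dict = field(default_factory=dict)  # (subject_id, roi) -> TwoTissueParams
    input_fn: PlasmaInputFunction | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.params.items():
            row = self.vt_table[
                (self.vt_table["subject_id"] == key[0]) & (self.vt_table["roi"] == key[1])
            ]
            if len(row) and not np.isclose(
                float(row["true_vt"].iloc[0]), compute_vt(p), rtol=1e-9
            ):
                raise ValidationError(f"stored true VT inconsistent with params for {key}")


# ---------------------------------------------------------------------------
# input function


def simulate_input_function(
    peak_time_min: float = 0.6,
    peak_value_kbq_ml: float = 120.0,
    washout_fractions: tuple[float, float, float] = (0.72, 0.22, 0.06),
    washout_rates_per_min: tuple[float, float, float] = (4.0, 0.35, 0.015),
    b2p: BloodPlasmaRatioModel | None = None,
    fp: ParentFractionModel | None = None,
    tau_s: float = 16.0,
    seed: int = 0,
    auto_noise_pct: float = 1.0,
    manual_noise_pct: float = 1.0,
    grid: np.ndarray | None = None,
) -> tuple[PlasmaInputFunction, dict]:
    """Ground-truth plasma input plus the raw observations a scanner
    session would yield.

    Total plasma activity rises linearly to an early peak and washes
    out tri-exponentially; parent plasma is total times the Hill parent
    fraction; whole blood is total times the bi-exponential blood-to-
    plasma ratio.  Observations: the dispersion-smeared, noisy sampler
    curve at 1 s over the first 22.5 min, and the manual-sample table
    (whole blood, plasma and parent fraction at the manual draw times).

    Returns ``(truth, obs)`` where obs has keys ``auto`` (BloodCurve)
    and ``manual`` (DataFrame).
    """
    if peak_time_min <= 0:
        raise ValidationError("peak time must be positive")
    if any(r <= 0 for r in washout_rates_per_min):
        raise ValidationError("washout rates must be positive")
    rng = np.random.default_rng(seed)
    # blood/plasma partitioning drifts slowly (tens of minutes), staying
    # near 0.8 over the scan
    b2p = b2p or BloodPlasmaRatioModel(0.10, 0.05, 0.72, 0.001)
    fp = fp or ParentFractionModel(0.90, 2.0, 400.0)
    grid = default_dense_grid() if grid is None else np.asarray(grid, float)

    def plasma_total(t):
        t = np.asarray(t, dtype=float)
        fr = np.asarray(washout_fractions) / np.sum(washout_fractions)
        decay = np.sum(
            fr[:, None] * np.exp(-np.outer(washout_rates_per_min, np.clip(t - peak_time_min, 0, None))),
            axis=0,
        )
        rise = np.clip(t / peak_time_min, 0.0, 1.0)
        return peak_value_kbq_ml * np.where(t < peak_time_min, rise, decay)

    P = plasma_total(grid)
    cp_true = P * fp(grid)
    wb_true = P * b2p(grid)
    truth = PlasmaInputFunction(
        grid, cp_true, wb_true, components={"b2p": b2p, "parent_fraction": fp}
    )

    auto_t = grid[grid <= AUTO_SAMPLER_END_MIN]
    wb_auto = wb_true[: auto_t.size]
    smeared = dispersion_convolve(BloodCurve(auto_t, wb_auto, "auto"), tau_s).activity
    if auto_noise_pct > 0:
        smeared = smeared * (1.0 + auto_noise_pct / 100.0 * rng.standard_normal(smeared.size))
    auto = BloodCurve(auto_t, np.clip(smeared, 0.0, None), "auto")

    t_m = np.asarray(MANUAL_SAMPLE_TIMES_MIN)
    noise = lambda n: 1.0 + manual_noise_pct / 100.0 * rng.standard_normal(n)
    manual = pd.DataFrame(
        {
            "time_min": t_m,
            "activity_kBq_ml": np.clip(plasma_total(t_m) * b2p(t_m) * noise(t_m.size), 0, None),
            "plasma_activity_kBq_ml": np.clip(plasma_total(t_m) * noise(t_m.size), 0, None),
            "parent_fraction": np.clip(fp(t_m) * noise(t_m.size), 0.0, 1.0),
            "source": "manual",
        }
    )
    return truth, {"auto": auto, "manual": manual}


# ---------------------------------------------------------------------------
# kinetics


#: FEPPA-plausible micro-parameter priors (rates in 1/min)
DEFAULT_SHAPE_PRIORS = {"k2": (0.05, 0.30), "k3_over_k4": (0.5, 4.0), "k4": (0.01, 0.06)}


def params_for_target_vt(
    target_vt: float,
    shape_priors: dict | None = None,
    seed: int | np.random.Generator = 0,
    vb: float = 0.05,
    k1_max: float = 0.6,
) -> TwoTissueParams:
    """Random micro-parameters whose VT equals ``target_vt`` exactly.

    (k2, k4, k3/k4) are drawn from the priors; K1 is then solved from
    K1 = VT * k2 / (1 + k3/k4), so compute_vt is exact by construction.
    Draws are rejected until K1 <= ``k1_max`` (delivery-limited influx:
    FEPPA K1 sits well below 1 mL/cm^3/min).
    """
    if target_vt <= 0:
        raise ValidationError("target VT must be positive")
    priors = dict(DEFAULT_SHAPE_PRIORS)
    priors.update(shape_priors or {})
    for key, (lo, hi) in priors.items():
        if not (0 < lo <= hi):
            raise ValidationError(f"empty or invalid prior range for {key}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(1000):
        k2 = rng.uniform(*priors["k2"])
        k4 = rng.uniform(*priors["k4"])
        ratio = rng.uniform(*priors["k3_over_k4"])
        K1 = target_vt * k2 / (1.0 + ratio)
        if K1 <= k1_max:
            return TwoTissueParams(K1, k2, ratio * k4, k4, vb)
    raise ValidationError(
        f"priors cannot reach VT = {target_vt} with K1 <= {k1_max}; widen the ranges"
    )


def _noisy_tac(tac, noise_pct: float, rng) -> np.ndarray:
    """Zero-mean Gaussian noise with SD proportional to activity and to
    1/sqrt(frame duration), normalized to 300 s frames."""
    dur_s = tac.schedule.durations * 60.0
    sd = noise_pct / 100.0 * tac.activity * np.sqrt(300.0 / dur_s)
    return tac.activity + sd * rng.standard_normal(tac.activity.size)


def _draw_true_vt(rng, mean: float, sd: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValidationError(f"cannot draw positive VT from N({mean}, {sd})")


def simulate_cohort(
    design: CohortDesign,
    kinetics: str = "direct",
    input_fn: PlasmaInputFunction | None = None,
    schedule: FrameSchedule | None = None,
    apply_qc: bool = True,
) -> tuple[CohortTable, GroundTruth]:
    """Generate a genotype-stratified cohort of per-ROI VT values.

    ``kinetics="direct"`` draws the subject-level VT (the quantity the
    statistics consume) straight from the design distributions and
    attaches a lognormal %COV spread — fast enough for repeated power/
    level studies.  ``kinetics="fit"`` renders a noisy TAC per
    (subject, ROI) through the full 2-TCM forward model and recovers VT
    with :func:`fit_2tcm`, so fitted VT and %COV carry genuine fit
    error.  ``kinetics="onetcm"`` is the closed-form single-compartment
    mode (k3 = k4 = 0) for validation independent of the 2-TCM fitter.
    """
    if kinetics not in ("direct", "fit", "onetcm"):
        raise ValidationError(f"unknown kinetics mode {kinetics!r}")
    rng = np.random.default_rng(design.seed)
    if kinetics in ("fit", "onetcm"):
        if input_fn is None:
            input_fn, _ = simulate_input_function(
                seed=design.seed, auto_noise_pct=0.0, manual_noise_pct=0.0,
                grid=default_dense_grid(step_min=2.0 / 60.0),
            )
        schedule = schedule or default_feppa_schedule()

    rows, truth_rows, params_map = [], [], {}
    for (disease, genotype), n in sorted(design.n_per_cell.items()):
        for i in range(n):
            subject = f"{disease}-{genotype}-{i + 1:02d}"
            inj_mean, inj_sd = REFERENCE_INJECTED[disease]
            injected = float(rng.normal(inj_mean, inj_sd))
            quality = float(rng.lognormal(0.0, design.subject_noise_sigma))
            for roi in design.rois:
                true_vt = _draw_true_vt(
                    rng, design.cell_mean(roi, disease, genotype),
                    design.cell_sd(roi, disease, genotype),
                )
                if kinetics == "direct":
                    vt_fit = true_vt
                    pct_cov = float(rng.lognormal(mean=np.log(12.0), sigma=0.5))
                else:
                    if kinetics == "onetcm":
                        k2 = rng.uniform(*DEFAULT_SHAPE_PRIORS["k2"])
                        p = TwoTissueParams(true_vt * k2, k2, 0.0, 0.0, 0.05)
                    else:
                        p = params_for_target_vt(true_vt, seed=rng)
                    params_map[(subject, roi)] = p
                    tac = simulate_2tcm(p, input_fn, schedule, label=roi)
                    if design.noise_pct > 0:
                        act = np.asarray(_noisy_tac(tac, design.noise_pct * quality, rng))
                        tac = type(tac)(schedule, act, label=roi, noisy=True)
                    fit = fit_2tcm(tac, input_fn, vb=0.05)
                    vt_fit, pct_cov = fit.vt, fit.pct_cov
                rows.append(
                    {
                        "subject_id": subject,
                        "disease": disease,
                        "genotype": genotype,
                        "roi": roi,
                        "vt": vt_fit,
                        "pct_cov": pct_cov,
                        "injected_amount": injected,
                    }
                )
                truth_rows.append({"subject_id": subject, "roi": roi, "true_vt": true_vt})

    df = pd.DataFrame(rows, columns=[
        "subject_id", "disease", "genotype", "roi", "vt", "pct_cov", "injected_amount"
    ])
    truth = GroundTruth(
        vt_table=pd.DataFrame(truth_rows, columns=["subject_id", "roi", "true_vt"]),
        params=params_map,
        input_fn=input_fn,
        extras={"design": design, "unfiltered": df.copy()},
    )
    if apply_qc and len(df):
        kept, n_roi = qc_filter(df, threshold=design.qc_threshold)
        truth.extras["n_retained_per_roi"] = n_roi
        df = kept
    return CohortTable(df.reset_index(drop=True)), truth


def calibrate_noise_for_qc(
    target_pass: float,
    input_fn: PlasmaInputFunction,
    schedule: FrameSchedule,
    design: CohortDesign | None = None,
    threshold: float = 20.0,
    n_pilot: int = 200,
    ref_noise: float = 15.0,
    seed: int = 0,
) -> float:
    """Pilot-based calibration of the TAC noise level to a QC pass rate.

    Pilot (subject, ROI) trials are drawn from the design's VT
    distribution with the design's subject-quality spread.  %COV scales
    roughly linearly with the noise level for a given curve, so a
    single fit per trial at ``ref_noise`` yields the whole pass-rate
    curve through the %COV quantiles: pass(noise) = P(cov * noise /
    ref <= threshold).  One direct re-fit evaluation at the first
    estimate measures the residual bias of the linear approximation
    and corrects the quantile once.
    """
    if not (0 < target_pass < 1):
        raise ValidationError("target pass fraction must lie in (0, 1)")
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    cells = [key for key, n in design.n_per_cell.items() for _ in range(max(n, 0))]
    trials, covs = [], []
    for _ in range(n_pilot):
        disease, genotype = cells[rng.integers(len(cells))]
        roi = design.rois[rng.integers(len(design.rois))]
        vt = _draw_true_vt(
            rng, design.cell_mean(roi, disease, genotype), design.cell_sd(roi, disease, genotype)
        )
        p = params_for_target_vt(vt, seed=rng)
        quality = float(rng.lognormal(0.0, design.subject_noise_sigma))
        tac = simulate_2tcm(p, input_fn, schedule)
        trials.append((tac, quality))
        noisy = type(tac)(tac.schedule, _noisy_tac(tac, ref_noise * quality, rng), noisy=True)
        covs.append(fit_2tcm(noisy, input_fn).pct_cov)
    covs = np.asarray(covs)

    def predicted_noise(p_target: float) -> float:
        q = float(np.quantile(covs, np.clip(p_target, 0.05, 0.95)))
        return threshold * ref_noise / max(q, 1e-9)

    est = predicted_noise(target_pass)
    n_pass = 0
    for tac, quality in trials:  # direct evaluation with fresh noise
        noisy = type(tac)(tac.schedule, _noisy_tac(tac, est * quality, rng), noisy=True)
        n_pass += fit_2tcm(noisy, input_fn).pct_cov <= threshold
    bias = n_pass / len(trials) - target_pass
    return predicted_noise(target_pass - bias)


# ---------------------------------------------------------------------------
# phantom


def simulate_phantom(
    dims: tuple[int, int, int] = (32, 32, 32),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    wm_radius_mm: float = 8.0,
    gm_outer_radius_mm: float = 20.0,
    gm_params: TwoTissueParams | None = None,
    wm_params: TwoTissueParams | None = None,
    input_fn: PlasmaInputFunction | None = None,
    schedule: FrameSchedule | None = None,
    psf: PointSpreadFunction | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> tuple[DynamicImage, TissueProbabilityMaps, GroundTruth]:
    """Spherical two-tissue phantom: a WM core inside a GM shell, in air.

    Tissue TACs come from the 2-TCM forward model; each frame is
    PSF-blurred (pass ``psf=None`` for no blurring) and optionally
    degraded with proportional Gaussian noise.  Probability maps are the
    binary geometry, so they sum to 1 in tissue and 0 in background.
    """
    dims = tuple(int(d) for d in dims)
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    half_extent = min(d * v for d, v in zip(dims, voxel_size)) / 2.0
    if not (0 < wm_radius_mm < gm_outer_radius_mm):
        raise ValidationError("need 0 < wm_radius < gm_outer_radius")
    if gm_outer_radius_mm >= half_extent:
        raise ValidationError("phantom geometry exceeds the volume extent")

    rng = np.random.default_rng(seed)
    if input_fn is None:
        input_fn, _ = simulate_input_function(
            seed=seed, auto_noise_pct=0.0, manual_noise_pct=0.0,
            grid=default_dense_grid(step_min=2.0 / 60.0),
        )
    schedule = schedule or default_feppa_schedule()
    gm_params = gm_params or TwoTissueParams(0.30, 0.10, 0.06, 0.03, 0.05)
    wm_params = wm_params or TwoTissueParams(0.10, 0.05, 0.015, 0.03, 0.05)

    centers = [(d - 1) / 2.0 for d in dims]
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r = np.sqrt(sum(((g - c) * v) ** 2 for g, c, v in zip(grids, centers, voxel_size)))
    wm_mask = r <= wm_radius_mm
    gm_mask = (r > wm_radius_mm) & (r <= gm_outer_radius_mm)

    gm_tac = simulate_2tcm(gm_params, input_fn, schedule, label="gm")
    wm_tac = simulate_2tcm(wm_params, input_fn, schedule, label="wm")

    frames = np.zeros(dims + (schedule.n_frames,))
    for k in range(schedule.n_frames):
        vol = gm_tac.activity[k] * gm_mask + wm_tac.activity[k] * wm_mask
        if psf is not None:
            vol = smooth_with_psf(vol, psf, voxel_size)
        if noise_pct > 0:
            vol = vol + noise_pct / 100.0 * np.abs(vol) * rng.standard_normal(dims)
        frames[..., k] = vol

    maps = TissueProbabilityMaps(
        gm=gm_mask.astype(float),
        wm=wm_mask.astype(float),
        csf=np.zeros(dims),
        voxel_size=voxel_size,
    )
    image = DynamicImage(frames, schedule, voxel_size)
    truth = GroundTruth(
        vt_table=pd.DataFrame(
            {
                "subject_id": ["phantom", "phantom"],
                "roi": ["gm", "wm"],
                "true_vt": [compute_vt(gm_params), compute_vt(wm_params)],
            }
        ),
        params={("phantom", "gm"): gm_params, ("phantom", "wm"): wm_params},
        input_fn=input_fn,
        extras={
            "gm_mask": gm_mask,
            "wm_mask": wm_mask,
            "gm_tac": gm_tac,
            "wm_tac": wm_tac,
        },
    )
    return image, maps, truth
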
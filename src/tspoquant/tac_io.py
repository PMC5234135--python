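"""Framed PET data model and tabular/NIfTI I/O.

Everything downstream works in minutes and kBq/mL.  Tables are plain
delimited text (comma or tab, auto-detected) with a named header row;
images are NIfTI-1.  Activity is assumed decay-corrected on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, NumericalError, ScheduleError, ValidationError

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DynamicImage",
    "CohortTable",
    "default_feppa_schedule",
    "read_tac_table",
    "write_tac_table",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_cohort_table",
    "write_cohort_table",
    "extract_roi_tac",
]

#: Frame durations in seconds after the initial variable-length frame:
#: 5 x 30 s, 1 x 45 s, 2 x 60 s, 1 x 90 s, 1 x 120 s, 1 x 210 s, 22 x 300 s.
#: These sum to 7335 s; the leading frame (until activity reaches the
#: field of view) is configurable and defaults to 30 s.
FEPPA_FRAME_DURATIONS_S: tuple[float, ...] = (
    (30.0,) * 5 + (45.0,) + (60.0,) * 2 + (90.0,) + (120.0,) + (210.0,) + (300.0,) * 22
)

GENOTYPES = ("HAB", "MAB")
DISEASE_GROUPS = ("HC", "PD")


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing in minutes.

    Frames must be strictly ordered and non-overlapping; gaps are
    permitted (the scanner may idle between frames).
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ScheduleError("frame_start and frame_end must be equal-length 1-D sequences")
        if not np.all(np.diff(start) > 0):
            raise ScheduleError("frame starts must be strictly increasing")
        if not np.all(end > start):
            raise ScheduleError("each frame_end must exceed its frame_start")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ScheduleError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.frame_start + self.frame_end) / 2.0

    @property
    def durations(self) -> np.ndarray:
        """Frame durations in minutes."""
        return self.frame_end - self.frame_start

    @property
    def scan_end(self) -> float:
        return float(self.frame_end[-1])


def default_feppa_schedule(initial_frame_s: float = 30.0) -> FrameSchedule:
    """The packaged 34-frame / ~125 min FEPPA acquisition schedule.

    Parameters
    ----------
    initial_frame_s:
        Duration of the leading variable-length frame (seconds), the
        time until radioactivity appears in the field of view.
    """
    if initial_frame_s <= 0:
        raise ScheduleError("initial frame duration must be positive")
    durations_min = np.asarray((initial_frame_s,) + FEPPA_FRAME_DURATIONS_S) / 60.0
    end = np.cumsum(durations_min)
    start = end - durations_min
    return FrameSchedule(start, end)


@dataclass
class TimeActivityCurve:
    """Activity concentration (kBq/mL) per frame for one ROI or voxel."""

    schedule: FrameSchedule
    activity: np.ndarray
    label: str = ""
    noisy: bool = False  # negative excursions allowed when True

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        self.activity = act
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise ValidationError(
                f"activity length {act.size} does not match frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(act)):
            raise ValidationError("activity must be finite")
        if not self.noisy and np.any(act < 0):
            raise ValidationError(
                "negative activity in a curve not flagged as noisy; set noisy=True "
                "for reconstruction-noise-bearing data"
            )


@dataclass
class DynamicImage:
    """4-D dynamic PET volume with its acquisition schedule."""

    voxels: np.ndarray
    schedule: FrameSchedule
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        vsize = np.asarray(self.voxel_size, dtype=float)
        self.voxels = vox
        self.voxel_size = vsize
        if vox.ndim != 4:
            raise ValidationError("dynamic image must be 4-D (x, y, z, frame)")
        if vox.shape[3] != self.schedule.n_frames:
            raise ScheduleError(
                f"4th dimension ({vox.shape[3]}) does not match frame count "
                f"({self.schedule.n_frames})"
            )
        if vsize.shape != (3,) or np.any(vsize <= 0):
            raise ValidationError("voxel_size must be a strictly positive 3-vector (mm)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


_COHORT_REQUIRED = ("subject_id", "disease", "genotype", "roi", "vt")
_COHORT_OPTIONAL = (
    "pct_cov",
    "injected_amount",
    "updrs3",
    "ledd",
    "disease_duration",
)


@dataclass
class CohortTable:
    """Per-subject, per-ROI VT with genotype/disease labels.

    Wraps a validated :class:`pandas.DataFrame`.  Low-affinity binders
    (LAB) are rejected outright: FEPPA shows no quantifiable specific
    binding in Thr147/Thr147 carriers.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COHORT_REQUIRED))

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing required columns: {missing}")
        if len(df):
            bad_gen = set(df["genotype"].unique()) - set(GENOTYPES)
            if bad_gen:
                if "LAB" in bad_gen:
                    raise ValidationError(
                        "genotype 'LAB' is not permitted: FEPPA VT is not quantifiable "
                        "in low-affinity binders; only HAB and MAB are accepted"
                    )
                raise ValidationError(f"unknown genotype labels: {sorted(bad_gen)}")
            bad_dis = set(df["disease"].unique()) - set(DISEASE_GROUPS)
            if bad_dis:
                raise ValidationError(f"unknown disease labels: {sorted(bad_dis)}")
            dup = df.duplicated(subset=["subject_id", "roi"])
            if dup.any():
                pairs = df.loc[dup, ["subject_id", "roi"]].values.tolist()
                raise ValidationError(f"duplicate (subject, roi) rows: {pairs[:5]}")
            vt = pd.to_numeric(df["vt"], errors="coerce")
            if (vt[vt.notna()] <= 0).any():
                raise ValidationError("vt must be positive where present")
            df["vt"] = vt
            df["disease"] = pd.Categorical(df["disease"], categories=DISEASE_GROUPS)
            df["genotype"] = pd.Categorical(df["genotype"], categories=GENOTYPES)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rois(self) -> list[str]:
        return list(pd.unique(self.df["roi"]))


# ---------------------------------------------------------------------------
# delimited-table helpers


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()
    first = head[0] if head else ""
    return "\t" if "\t" in first else ","


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=_sniff_sep(path))
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse delimited table {path}: {exc}") from exc


_TIME_SCALE = {"frame_start": 1.0, "frame_start_s": 1 / 60.0, "frame_start_sec": 1 / 60.0}


def _frame_columns(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Locate frame timing columns, converting seconds to minutes if the
    header declares them (`*_s` / `*_sec` suffix)."""
    for start_col, scale in _TIME_SCALE.items():
        end_col = start_col.replace("start", "end")
        if start_col in df.columns and end_col in df.columns:
            return (
                df[start_col].to_numpy(dtype=float) * scale,
                df[end_col].to_numpy(dtype=float) * scale,
            )
    raise FormatError("table must contain frame_start/frame_end columns (minutes or *_s)")


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read ROI time-activity curves from a delimited table.

    One `frame_start`/`frame_end` pair of columns plus one activity
    column (kBq/mL) per ROI; all curves share the schedule.
    """
    df = _read_delimited(path)
    start, end = _frame_columns(df)
    schedule = FrameSchedule(start, end)
    roi_cols = [c for c in df.columns if not c.startswith(("frame_start", "frame_end"))]
    curves = []
    for col in roi_cols:
        act = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(act).any():
            raise FormatError(f"non-numeric or missing activity in column {col!r}")
        curves.append(TimeActivityCurve(schedule, act, label=col, noisy=bool(np.any(act < 0))))
    return curves


def write_tac_table(curves: Sequence[TimeActivityCurve], path) -> None:
    """Write curves sharing one schedule; values keep >= 6 significant digits."""
    path = Path(path)
    if curves:
        schedule = curves[0].schedule
        for c in curves[1:]:
            if not (
                np.array_equal(c.schedule.frame_start, schedule.frame_start)
                and np.array_equal(c.schedule.frame_end, schedule.frame_end)
            ):
                raise ValidationError("all curves must share one schedule")
        data = {"frame_start": schedule.frame_start, "frame_end": schedule.frame_end}
        for i, c in enumerate(curves):
            data[c.label or f"roi{i}"] = c.activity
        df = pd.DataFrame(data)
    else:
        df = pd.DataFrame(columns=["frame_start", "frame_end"])
    df.to_csv(path, index=False, float_format="%.10g")


def read_dynamic_image(path, schedule: FrameSchedule) -> DynamicImage:
    """Load a 4-D NIfTI dynamic series; voxel size comes from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D NIfTI, got {data.ndim}-D")
    if data.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"NIfTI has {data.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DynamicImage(data, schedule, voxel_size)


def write_dynamic_image(image: DynamicImage, path) -> None:
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), affine), str(path))


def read_cohort_table(path) -> CohortTable:
    df = _read_delimited(path)
    if len(df) == 0:
        cols = list(df.columns) or list(_COHORT_REQUIRED)
        return CohortTable(pd.DataFrame(columns=cols))
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path) -> None:
    table.df.to_csv(path, index=False, float_format="%.10g")


def extract_roi_tac(
    image: DynamicImage, mask: np.ndarray, label: str = "", noisy: bool = True
) -> TimeActivityCurve:
    """Mean TAC over a boolean ROI mask, ignoring NaN voxels (e.g. after PVC)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.spatial_shape:
        raise ValidationError("mask shape does not match image spatial shape")
    if not mask.any():
        raise ValidationError("ROI mask is empty")
    voxels = image.voxels[mask, :]  # (n_voxels, n_frames)
    with np.errstate(invalid="ignore"):
        act = np.nanmean(voxels, axis=0)
    if np.isnan(act).any():
        raise NumericalError("ROI mean undefined: all voxels NaN in at least one frame")
    return TimeActivityCurve(image.schedule, act, label=label, noisy=noisy)
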
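"""Cohort-level statistics on regional VT.

The design is a 2x2 between-subjects factorial — disease (HC vs PD) by
TSPO genotype (HAB vs MAB) — analysed per ROI with a Type-III ANCOVA
(effects coding) controlling for injected amount as a nuisance
covariate.  Levene's test of equal error variances gates the per-ROI
significance level: ROIs with unequal variances (Levene p < 0.05) are
tested at the stricter alpha = 0.01.  Second-level analyses are pooled-
variance independent t tests of genotype within each disease stratum,
and Pearson correlations between VT and clinical measures.

Group contrasts are reported as the percentage difference of cell
means relative to their midpoint:

    %diff = 100 * (HAB - MAB) / ((HAB + MAB) / 2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import NumericalError, ValidationError
from .tac_io import DISEASE_GROUPS, GENOTYPES, CohortTable

__all__ = [
    "StatTestResult",
    "RegionSummary",
    "percent_difference",
    "two_way_ancova",
    "levene_test",
    "stratified_t_tests",
    "clinical_correlations",
    "region_summary",
    "overall_percent_difference",
    "significance_level",
]


@dataclass
class StatTestResult:
    effect: str
    statistic: float
    df: tuple
    p: float

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class RegionSummary:
    roi: str
    cell_means: dict  # (disease, genotype) -> mean VT
    cell_sds: dict
    cell_ns: dict
    pct_diff_hc: float
    pct_diff_pd: float
    anova: dict = field(default_factory=dict)  # effect -> StatTestResult
    levene_p: float = np.nan
    alpha: float = 0.05


def percent_difference(mean_mab: float, mean_hab: float) -> float:
    """Percentage difference of two group means relative to their midpoint.

    Antisymmetric (swap flips the sign) and scale-invariant.  Reporting
    layers round to 1 decimal.
    """
    if mean_mab <= 0 or mean_hab <= 0:
        raise ValidationError("group means must be positive")
    return 100.0 * (mean_hab - mean_mab) / ((mean_hab + mean_mab) / 2.0)


def _roi_frame(table: CohortTable, roi: str) -> pd.DataFrame:
    df = table.df
    sub = df[df["roi"] == roi].copy()
    if len(sub) == 0:
        raise ValidationError(f"no rows for ROI {roi!r}")
    return sub


def two_way_ancova(
    table: CohortTable, roi: str, covariate: str | None = "injected_amount"
) -> dict[str, StatTestResult]:
    """Type-III factorial ANCOVA of VT on disease x genotype for one ROI.

    Effects-coded contrasts with the covariate partialled out; returns
    F tests for both main effects and the interaction (and the
    covariate when present).
    """
    sub = _roi_frame(table, roi)
    for dis in DISEASE_GROUPS:
        for gen in GENOTYPES:
            n = int(((sub["disease"] == dis) & (sub["genotype"] == gen)).sum())
            if n < 2:
                raise ValidationError(
                    f"cell ({dis}, {gen}) of ROI {roi!r} has {n} subjects (need >= 2)"
                )
    rhs = "C(disease, Sum) * C(genotype, Sum)"
    if covariate is not None:
        if covariate not in sub.columns or sub[covariate].isna().any():
            raise ValidationError(f"covariate {covariate!r} missing for ROI {roi!r}")
        rhs = f"{covariate} + {rhs}"
    model = smf.ols(f"vt ~ {rhs}", data=sub).fit()
    aov = anova_lm(model, typ=3)
    mapping = {
        "C(disease, Sum)": "disease",
        "C(genotype, Sum)": "genotype",
        "C(disease, Sum):C(genotype, Sum)": "disease:genotype",
    }
    if covariate is not None:
        mapping[covariate] = covariate
    df_resid = int(aov.loc["Residual", "df"])
    out = {}
    for row, effect in mapping.items():
        out[effect] = StatTestResult(
            effect=effect,
            statistic=float(aov.loc[row, "F"]),
            df=(int(aov.loc[row, "df"]), df_resid),
            p=float(aov.loc[row, "PR(>F)"]),
        )
    return out


def levene_test(*groups) -> StatTestResult:
    """Levene's test of equal error variances (deviations from the mean).

    Equivalent to a one-way ANOVA on |x - group mean|.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("each group needs >= 2 observations")
    if all(np.ptp(g) == 0 for g in arrays):
        raise NumericalError("Levene statistic undefined: zero spread in every group")
    W, p = sp_stats.levene(*arrays, center="mean")
    k = len(arrays)
    N = sum(g.size for g in arrays)
    return StatTestResult(effect="levene", statistic=float(W), df=(k - 1, N - k), p=float(p))


def significance_level(levene_p: float, alpha: float = 0.05, alpha_strict: float = 0.01) -> float:
    """Per-ROI alpha: stricter when the equal-variance assumption fails."""
    return alpha_strict if levene_p < alpha else alpha


def stratified_t_tests(table: CohortTable, within: str) -> dict[str, StatTestResult]:
    """Pooled-variance two-sided t of HAB vs MAB within one disease group,
    per ROI."""
    if within not in DISEASE_GROUPS:
        raise ValidationError(f"unknown disease stratum {within!r}")
    out = {}
    for roi in table.rois:
        sub = _roi_frame(table, roi)
        sub = sub[sub["disease"] == within]
        hab = sub.loc[sub["genotype"] == "HAB", "vt"].to_numpy(float)
        mab = sub.loc[sub["genotype"] == "MAB", "vt"].to_numpy(float)
        if hab.size < 2 or mab.size < 2:
            raise ValidationError(
                f"genotype group with < 2 subjects in stratum {within}, ROI {roi!r}"
            )
        t, p = sp_stats.ttest_ind(hab, mab, equal_var=True)
        out[roi] = StatTestResult(
            effect=f"{within}: HAB vs MAB",
            statistic=float(t),
            df=(hab.size + mab.size - 2,),
            p=float(p),
        )
    return out


def clinical_correlations(
    table: CohortTable, measures: tuple[str, ...] = ("ledd", "updrs3", "disease_duration")
) -> list[StatTestResult]:
    """Pearson r of VT against each clinical measure, per (measure, ROI,
    genotype stratum), within the PD group."""
    out = []
    df = table.df[table.df["disease"] == "PD"]
    for measure in measures:
        if measure not in df.columns:
            continue
        for roi in pd.unique(df["roi"]):
            for gen in GENOTYPES:
                sub = df[(df["roi"] == roi) & (df["genotype"] == gen)]
                paired = sub[[measure, "vt"]].dropna()
                if len(paired) < 3:
                    continue
                x = paired[measure].to_numpy(float)
                y = paired["vt"].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    raise NumericalError(
                        f"zero variance in {measure!r} or vt for ROI {roi!r}, {gen}"
                    )
                r, p = sp_stats.pearsonr(x, y)
                out.append(
                    StatTestResult(
                        effect=f"{measure} vs vt [{roi}, {gen}]",
                        statistic=float(r),
                        df=(len(paired) - 2,),
                        p=float(p),
                    )
                )
    return out


def region_summary(
    table: CohortTable,
    covariate: str | None = "injected_amount",
    alpha: float = 0.05,
    alpha_strict: float = 0.01,
    with_anova: bool = True,
) -> list[RegionSummary]:
    """Per-ROI cell means/SDs, genotype percentage differences, Levene-
    gated alpha and (optionally) the factorial ANCOVA."""
    summaries = []
    for roi in table.rois:
        sub = _roi_frame(table, roi)
        cells, sds, ns = {}, {}, {}
        for dis in DISEASE_GROUPS:
            for gen in GENOTYPES:
                v = sub.loc[(sub["disease"] == dis) & (sub["genotype"] == gen), "vt"]
                ns[(dis, gen)] = int(v.size)
                cells[(dis, gen)] = float(v.mean()) if v.size else np.nan
                sds[(dis, gen)] = float(v.std(ddof=1)) if v.size > 1 else np.nan
        pct_hc = percent_difference(cells[("HC", "MAB")], cells[("HC", "HAB")])
        pct_pd = percent_difference(cells[("PD", "MAB")], cells[("PD", "HAB")])
        groups = [
            sub.loc[(sub["disease"] == d) & (sub["genotype"] == g), "vt"].to_numpy(float)
            for d in DISEASE_GROUPS
            for g in GENOTYPES
        ]
        try:
            lev = levene_test(*groups)
            lev_p = lev.p
        except (ValidationError, NumericalError):
            lev_p = np.nan
        roi_alpha = (
            significance_level(lev_p, alpha, alpha_strict) if np.isfinite(lev_p) else alpha
        )
        anova = two_way_ancova(table, roi, covariate=covariate) if with_anova else {}
        summaries.append(
            RegionSummary(
                roi=roi,
                cell_means=cells,
                cell_sds=sds,
                cell_ns=ns,
                pct_diff_hc=pct_hc,
                pct_diff_pd=pct_pd,
                anova=anova,
                levene_p=lev_p,
                alpha=roi_alpha,
            )
        )
    return summaries


def overall_percent_difference(summaries: list[RegionSummary], disease: str) -> float:
    """Mean of the per-ROI genotype percentage differences for one
    disease group (each ROI value rounded to 1 decimal, as reported)."""
    attr = "pct_diff_hc" if disease == "HC" else "pct_diff_pd"
    vals = [round(getattr(s, attr), 1) for s in summaries]
    if not vals:
        raise ValidationError("no region summaries")
    return float(np.mean(vals))


def summary_to_frame(summaries: list[RegionSummary]) -> pd.DataFrame:
    """Flatten region summaries into the report table (1-decimal VT cells)."""
    rows = []
    for s in summaries:
        row = {"roi": s.roi}
        for (dis, gen), m in s.cell_means.items():
            row[f"{dis.lower()}_{gen.lower()}_mean"] = round(m, 1) if np.isfinite(m) else np.nan
            sd = s.cell_sds[(dis, gen)]
            row[f"{dis.lower()}_{gen.lower()}_sd"] = round(sd, 1) if np.isfinite(sd) else np.nan
            row[f"{dis.lower()}_{gen.lower()}_n"] = s.cell_ns[(dis, gen)]
        row["pct_diff_hc"] = round(s.pct_diff_hc, 1)
        row["pct_diff_pd"] = round(s.pct_diff_pd, 1)
        row["levene_p"] = s.levene_p
        row["alpha"] = s.alpha
        for effect, res in s.anova.items():
            row[f"F_{effect.replace(':', '_x_')}"] = res.statistic
            row[f"p_{effect.replace(':', '_x_')}"] = res.p
        rows.append(row)
    return pd.DataFrame(rows)
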
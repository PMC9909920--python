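"""Study statistics and assay computations.

Holm-Sidak-adjusted multiple comparisons around one-way, two-way and
longitudinal (random-intercept mixed model) ANOVA on long-format study
tables, plus the small assay layer: relative qPCR expression (2^-ddCt),
ELISA standard-curve inverse prediction (four-parameter logistic),
time-course AUC and percent-of-reference normalization.

Every group operation is fenced by ``study_id``: the study design keeps a
separate wild-type arm per study, and comparisons never pool across
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "QpcrRecord",
    "StandardCurve",
    "holm_sidak_adjust",
    "significance_stars",
    "anova_oneway",
    "anova_twoway_holm_sidak",
    "anova_longitudinal",
    "delta_delta_ct",
    "fit_standard_curve",
    "standard_curve_interpolate",
    "auc_timecourse",
    "percent_of_reference",
]


# --------------------------------------------------------------------------
# Multiple comparisons
# --------------------------------------------------------------------------


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    For raw p sorted ascending, adj(i) = 1 - (1 - p(i))^(m - i + 1)
    (1-based rank), made monotone by a running maximum and capped at 1;
    returned in the original order.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm-sidak")
    return adjusted


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """The paper-convention star string (* p<0.05 ... **** p<0.0001)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    contrast: str
    estimate: float
    statistic: float
    p_raw: float
    p_adj: float
    stars: str = ""

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = significance_stars(self.p_adj)


@dataclass
class AnovaResult:
    """Overall test(s) plus the Holm-Sidak-adjusted contrast family."""

    f_tests: dict            # name -> (F, df1, df2, p)
    comparisons: list[ComparisonResult] = field(default_factory=list)


def _single_study(study: pd.DataFrame) -> pd.DataFrame:
    ids = study["study_id"].unique()
    if len(ids) != 1:
        raise ValueError(
            f"operation spans multiple studies {sorted(map(str, ids))}; "
            "statistical analysis is only performed within a study"
        )
    return study


def _adjust_family(results: list[ComparisonResult]) -> list[ComparisonResult]:
    if not results:
        return results
    adj = holm_sidak_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.stars = significance_stars(r.p_adj)
    return results


# --------------------------------------------------------------------------
# ANOVA layers
# --------------------------------------------------------------------------


def _measure_frame(study: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = _single_study(study)
    sub = sub[sub["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    return sub.copy()


def anova_oneway(study: pd.DataFrame, measure: str, group_col: str = "genotype",
                 groups: list[str] | None = None,
                 comparisons: list[tuple[str, str]] | None = None) -> AnovaResult:
    """Ordinary one-way ANOVA with Holm-Sidak pairwise comparisons.

    Pairwise contrasts are t tests on group means using the pooled ANOVA
    mean-square error (df = N - k); the Holm-Sidak family is exactly the
    requested ``comparisons`` (default: all pairs).
    """
    sub = _measure_frame(study, measure)
    if groups is None:
        groups = list(pd.unique(sub[group_col]))
    data = {g: sub.loc[sub[group_col] == g, "value"].to_numpy() for g in groups}
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n={len(v)} < 2")
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n_total = sum(len(v) for v in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df1, df2 = k - 1, n_total - k
    mse = ss_within / df2
    f = (ss_between / df1) / mse if mse > 0 else float("inf")
    p_overall = float(sps.f.sf(f, df1, df2))

    if comparisons is None:
        comparisons = [(groups[i], groups[j])
                       for i in range(k) for j in range(i + 1, k)]
    results = []
    for a, b in comparisons:
        if a not in data or b not in data:
            raise ValueError(f"contrast ({a!r}, {b!r}) references unknown group")
        va, vb = data[a], data[b]
        diff = va.mean() - vb.mean()
        se = math.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        t = diff / se if se > 0 else float("inf")
        p = float(2 * sps.t.sf(abs(t), df2))
        results.append(ComparisonResult(f"{a} vs {b}", float(diff), float(t),
                                        p, p))
    return AnovaResult(f_tests={"group": (float(f), df1, df2, p_overall)},
                       comparisons=_adjust_family(results))


def anova_twoway_holm_sidak(study: pd.DataFrame, measure: str,
                            factor_a: str = "genotype",
                            factor_b: str = "timepoint",
                            comparisons: list[tuple[tuple, tuple]] | None = None
                            ) -> AnovaResult:
    """Two-way ANOVA (main effects + interaction) with Holm-Sidak cellwise
    contrasts.

    ``comparisons`` lists pairs of cells, each cell a (level_a, level_b)
    tuple; the contrast t statistic uses the residual mean square of the
    full factorial model.  Default family: within each level of factor B,
    all pairs of factor-A levels (the across-genotype-at-one-timepoint
    comparisons of the study design).
    """
    sub = _measure_frame(study, measure)
    cells = sub.groupby([factor_a, factor_b])["value"]
    sizes = cells.size()
    full = len(sub[factor_a].unique()) * len(sub[factor_b].unique())
    if len(sizes) < full or (sizes < 2).any():
        raise ValueError("two-way ANOVA requires every cell filled with n >= 2")
    model = smf.ols(f"value ~ C({factor_a}) * C({factor_b})", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(model.df_resid)
    mse = float(model.mse_resid)
    f_tests = {}
    for name, label in ((f"C({factor_a})", factor_a),
                        (f"C({factor_b})", factor_b),
                        (f"C({factor_a}):C({factor_b})", "interaction")):
        row = table.loc[name]
        f_tests[label] = (float(row["F"]), float(row["df"]), df_resid,
                          float(row["PR(>F)"]))

    means = cells.mean()
    if comparisons is None:
        a_levels = list(pd.unique(sub[factor_a]))
        comparisons = [
            ((a1, b), (a2, b))
            for b in pd.unique(sub[factor_b])
            for i, a1 in enumerate(a_levels)
            for a2 in a_levels[i + 1:]
        ]
    results = []
    for cell1, cell2 in comparisons:
        n1, n2 = sizes[cell1], sizes[cell2]
        diff = means[cell1] - means[cell2]
        se = math.sqrt(mse * (1 / n1 + 1 / n2))
        t = diff / se if se > 0 else float("inf")
        p = float(2 * sps.t.sf(abs(t), df_resid))
        results.append(ComparisonResult(f"{cell1} vs {cell2}", float(diff),
                                        float(t), p, p))
    return AnovaResult(f_tests=f_tests, comparisons=_adjust_family(results))


def anova_longitudinal(study: pd.DataFrame, measure: str,
                       group_col: str = "genotype",
                       time_col: str = "timepoint") -> AnovaResult:
    """ANOVA with random effects for longitudinal data.

    Linear mixed model with a per-animal random intercept (REML) and
    group, time and group x time fixed effects; per-timepoint group
    contrasts are Wald t tests on the fitted cell means, Holm-Sidak
    adjusted, with denominator degrees of freedom by the containment
    method (animals minus groups).  If no animal is observed at more than
    one timepoint the model is unidentifiable and the function falls back
    to :func:`anova_oneway` on the group factor with a warning flag in the
    result.
    """
    sub = _measure_frame(study, measure)
    per_animal = sub.groupby("animal_id")[time_col].nunique()
    if (per_animal <= 1).all():
        import warnings

        warnings.warn("no repeated measures; falling back to one-way ANOVA",
                      stacklevel=2)
        return anova_oneway(study, measure, group_col=group_col)

    sub = sub.copy()
    sub["_group"] = sub[group_col].astype(str)
    sub["_time"] = sub[time_col].astype(str)
    model = smf.mixedlm("value ~ _group * _time", data=sub,
                        groups=sub["animal_id"])
    fit = model.fit(reml=True)

    exog_names = list(fit.model.exog_names)
    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:len(params), :len(params)]
    groups_ = sorted(sub["_group"].unique())
    times_ = sorted(sub["_time"].unique())

    def cell_design(g: str, t: str) -> np.ndarray:
        # treatment (reference) coding of _group * _time
        row = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                row[i] = 1.0
            elif name == f"_group[T.{g}]" or name == f"_time[T.{t}]":
                row[i] = 1.0
            elif name == f"_group[T.{g}]:_time[T.{t}]":
                row[i] = 1.0
        return row

    # Containment degrees of freedom: the group effect is tested between
    # animals (animals - groups); time and group x time are within-animal
    # (residual df after the animal stratum).
    n_animals = sub["animal_id"].nunique()
    n_obs = len(sub)
    df_between = max(n_animals - len(groups_), 1)
    df_within = max(
        n_obs - n_animals - (len(times_) - 1) * len(groups_), 1
    )

    # Wald F tests for the fixed-effect terms
    f_tests = {}
    for label, keys, df_denom in (
        ("group",
         [n for n in exog_names if n.startswith("_group") and ":" not in n],
         df_between),
        ("time",
         [n for n in exog_names if n.startswith("_time") and ":" not in n],
         df_within),
        ("interaction", [n for n in exog_names if ":" in n], df_within),
    ):
        idx = [exog_names.index(n) for n in keys]
        if not idx:
            continue
        contrast = np.zeros((len(idx), len(params)))
        for r, i in enumerate(idx):
            contrast[r, i] = 1.0
        est = contrast @ params
        vc = contrast @ cov @ contrast.T
        fstat = float(est @ np.linalg.solve(vc, est) / len(idx))
        p = float(sps.f.sf(fstat, len(idx), df_denom))
        f_tests[label] = (fstat, float(len(idx)), float(df_denom), p)

    results = []
    for t in times_:
        for i, g1 in enumerate(groups_):
            for g2 in groups_[i + 1:]:
                c = cell_design(g1, t) - cell_design(g2, t)
                est = float(c @ params)
                se = math.sqrt(float(c @ cov @ c))
                tstat = est / se if se > 0 else float("inf")
                # group contrasts cross the animal stratum -> between-animal df
                p = float(2 * sps.t.sf(abs(tstat), df_between))
                results.append(ComparisonResult(
                    f"{g1} vs {g2} @ {t}", est, tstat, p, p))
    res = AnovaResult(f_tests=f_tests, comparisons=_adjust_family(results))
    res.mixed_fit = fit
    return res


def detects_group_time_effect(result: AnovaResult, alpha: float = 0.05,
                              baseline: str | None = None) -> bool:
    """Whether a longitudinal fit shows a group-by-time effect.

    True if the interaction F test is significant or any Holm-Sidak-
    adjusted per-timepoint group contrast (excluding the baseline
    timepoint, if given) is — the way random-effects ANOVA results are
    conventionally reported, as significant group differences at specific
    timepoints.  Family-wise error stays controlled because the contrast
    family is jointly adjusted.
    """
    if "interaction" in result.f_tests and result.f_tests["interaction"][3] < alpha:
        return True
    for c in result.comparisons:
        if baseline is not None and c.contrast.endswith(f"@ {baseline}"):
            continue
        if c.p_adj < alpha:
            return True
    return False


# --------------------------------------------------------------------------
# Assays
# --------------------------------------------------------------------------


@dataclass
class QpcrRecord:
    sample: str
    group: str
    ct_target: float
    ct_reference: float
    delta_ct: float = float("nan")
    delta_delta_ct: float = float("nan")
    fold: float = float("nan")


def delta_delta_ct(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean(dCt of
    the control group); fold = 2^-ddCt.  The control group's geometric
    mean fold is 1 by construction.  ``records`` needs columns sample,
    group, ct_target, ct_reference.
    """
    df = records.copy()
    for col in ("ct_target", "ct_reference"):
        if df[col].isna().any():
            raise ValueError(f"missing values in {col}")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    control = df.loc[df["group"] == control_group, "delta_ct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} not found")
    df["delta_delta_ct"] = df["delta_ct"] - control.mean()
    df["fold"] = np.power(2.0, -df["delta_delta_ct"])
    return df


def _four_pl(x, a, b, c, d):
    # a = response at zero dose, d = response at infinite dose,
    # c = inflection concentration, b = Hill slope
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class StandardCurve:
    """Fitted ELISA standard curve (four-parameter logistic by default).

    Fit on standards spanning the assay range (e.g. 39-2500 pg/ml); inverse
    prediction flags responses outside the standards' fitted response range
    as out-of-range rather than extrapolating.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    params: tuple
    model: str                      # "4pl" or "loglog"

    def predict(self, conc) -> np.ndarray:
        x = np.asarray(conc, dtype=float)
        if self.model == "4pl":
            return _four_pl(x, *self.params)
        slope, intercept = self.params
        return np.exp(intercept + slope * np.log(x))

    def response_range(self) -> tuple[float, float]:
        fitted = self.predict(self.concentrations)
        return float(fitted.min()), float(fitted.max())

    def inverse(self, response: float) -> float:
        if self.model == "4pl":
            a, b, c, d = self.params
            ratio = (a - d) / (response - d) - 1.0
            return float(c * ratio ** (1.0 / b))
        slope, intercept = self.params
        return float(np.exp((np.log(response) - intercept) / slope))


def fit_standard_curve(concentrations, responses) -> StandardCurve:
    """Fit a monotone standard curve; 4PL with a log-log linear fallback."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("standard concentrations must be strictly increasing")
    monotone = np.all(np.diff(y) > 0) or np.all(np.diff(y) < 0)
    if not monotone:
        raise ValueError("standard responses are not monotone; cannot fit")
    try:
        p0 = (float(y[0]), 1.0, float(np.median(x)), float(y[-1]))
        popt, _ = curve_fit(_four_pl, x, y, p0=p0, maxfev=20000)
        curve = StandardCurve(x, y, tuple(popt), "4pl")
        fitted = curve.predict(x)
        if np.any(~np.isfinite(fitted)) or np.any(np.diff(fitted) * np.diff(y)[0] < 0):
            raise RuntimeError("non-monotone 4PL fit")
    except RuntimeError:
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        curve = StandardCurve(x, y, (float(slope), float(intercept)), "loglog")
    return curve


def standard_curve_interpolate(curve: StandardCurve, responses
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-predict concentrations for measured responses.

    Returns ``(concentrations, out_of_range)``; responses outside the
    fitted response range of the standards get NaN and a True flag instead
    of an extrapolated value.
    """
    resp = np.atleast_1d(np.asarray(responses, dtype=float))
    lo, hi = curve.response_range()
    out = np.zeros(resp.shape, dtype=bool)
    conc = np.full(resp.shape, np.nan)
    for i, r in enumerate(resp):
        if not (lo <= r <= hi):
            out[i] = True
            continue
        conc[i] = curve.inverse(r)
    return conc, out


def auc_timecourse(times, values) -> float:
    """Trapezoidal area under a fluorescence (or other) time course."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("times and values must be equal-length, >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    return float(np.trapezoid(v, t))


def percent_of_reference(values, reference_values) -> np.ndarray:
    """100 x value / mean(reference): the reference set maps to mean 100.

    The normalization used for ATP survival (untreated = 100%) and for
    per-nucleus fluorescence readouts.
    """
    ref = np.asarray(reference_values, dtype=float)
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * np.asarray(values, dtype=float) / ref_mean
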
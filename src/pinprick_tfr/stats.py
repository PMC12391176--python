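"""Group-level and clinical-association models.

Implements the study's statistical stage: a one-way ANOVA of SEP
peak-to-peak amplitude on GROUP with Tukey-corrected post-hoc contrasts and
Cohen's d; a linear mixed model POWER ~ GROUP x FEATURE with a participant
random intercept; and linear regressions of clinical scores (FMA, EmNSA,
PTT; at T1 or as T2-T1 change) on the EEG features, stroke type, and each
feature x stroke-type interaction, reduced by backward-stepwise elimination.

Backward elimination removes, at each step, the highest-p eliminable term
with p >= alpha, where a term is eliminable only while no retained
higher-order interaction contains it (marginality); ties break by fixed term
order (the later term in the initial ordering is dropped first). Wald F
statistics use residual denominator degrees of freedom (n_obs minus the
number of fixed-effect columns) — a simple, documented approximation.

Cohen's d uses the pooled SD of the two contrasted cells with (n-1) weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .core import ROI_FEATURES, ParameterError, PipelineError

ALPHA = 0.05

EEG_FEATURES = ("amplitude",) + tuple(ROI_FEATURES)


@dataclass
class ModelResult:
    """A fitted model plus its reporting surface."""

    kind: str
    terms: pd.DataFrame  # term, estimate (when 1-df), F/t, p
    formula: str
    adj_r2: float | None = None
    posthoc: pd.DataFrame | None = None
    dropped: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)
    fit: object | None = None


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Mean difference over the (n-1)-weighted pooled SD of the two samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    return float((x.mean() - y.mean()) / pooled)


def remove_residual_outliers(df: pd.DataFrame, formula: str,
                             z_max: float = 3.0) -> tuple[pd.DataFrame, list]:
    """Drop rows whose studentized-style residual z exceeds ``z_max``.

    The documented stand-in for quantile-plot-based outlier screening: fit
    the model once, z-score the residuals, drop |z| > z_max.
    """
    fit = smf.ols(formula, data=df).fit()
    resid = fit.resid
    z = (resid - resid.mean()) / resid.std(ddof=1)
    bad = df.index[np.abs(z) > z_max].tolist()
    return df.drop(index=bad), bad


# --------------------------------------------------------------------------
# ANOVA on amplitude + Tukey post-hocs
# --------------------------------------------------------------------------


def anova_amplitude(table: pd.DataFrame, value: str = "np_amplitude",
                    group: str = "group", remove_outliers: bool = False,
                    posthoc: bool = True) -> ModelResult:
    """One-way fixed-effect ANOVA of SEP amplitude on group.

    Post-hoc contrasts are computed when requested regardless of the omnibus
    p-value (the exploratory convention of this analysis).
    """
    df = table.dropna(subset=[value, group]).copy()
    counts = df.groupby(group)[value].count()
    if len(counts) < 2:
        raise ParameterError("need at least two groups")
    small = counts[counts < 2]
    if len(small):
        raise ParameterError(f"group(s) with < 2 observations: {list(small.index)}")
    notes = {}
    formula = f"{value} ~ C({group})"
    if remove_outliers:
        df, dropped = remove_residual_outliers(df, formula)
        notes["outliers_removed"] = dropped
    fit = smf.ols(formula, data=df).fit()
    if fit.ssr == 0 and fit.ess == 0:
        warnings.warn("zero variance in every group; F undefined", stacklevel=2)
    aov = sm.stats.anova_lm(fit, typ=1)
    terms = pd.DataFrame({
        "term": [f"C({group})"],
        "F": [float(aov.loc[f"C({group})", "F"])],
        "df1": [float(aov.loc[f"C({group})", "df"])],
        "df2": [float(aov.loc["Residual", "df"])],
        "p": [float(aov.loc[f"C({group})", "PR(>F)"])],
    })
    res = ModelResult(kind="anova", terms=terms, formula=formula,
                      adj_r2=float(fit.rsquared_adj), notes=notes, fit=fit)
    if posthoc:
        res.posthoc = tukey_posthoc(df, value=value, group=group)
    return res


def tukey_posthoc(table: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """All pairwise group contrasts, studentized-range adjusted, with Cohen's d."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table.dropna(subset=[value, group])
    tk = pairwise_tukeyhsd(df[value].to_numpy(), df[group].to_numpy())
    frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    ds = []
    for _, row in frame.iterrows():
        a = df.loc[df[group] == row["group1"], value].to_numpy()
        b = df.loc[df[group] == row["group2"], value].to_numpy()
        ds.append(cohens_d(b, a))  # group2 - group1, matching meandiff sign
    frame["cohens_d"] = ds
    frame.rename(columns={"p-adj": "p_adj"}, inplace=True)
    return frame


# --------------------------------------------------------------------------
# Backward-stepwise machinery
# --------------------------------------------------------------------------


def _is_contained(term: str, other: str) -> bool:
    """True when ``term``'s factors are a proper subset of ``other``'s."""
    a, b = set(term.split(":")), set(other.split(":"))
    return a < b


def _term_pvalues(fit, terms: list[str]) -> dict[str, tuple[float, float]]:
    """Per-term Wald F-test p-values (and estimates for 1-df terms).

    Uses the design-info term slices of the fitted model; denominator df is
    residual (n - p). Returns {term: (p, estimate_or_nan)}.
    """
    di = fit.model.data.design_info
    params = np.asarray(fit.fe_params if hasattr(fit, "fe_params") else fit.params)
    k = len(params)
    cov = np.asarray(fit.cov_params())[:k, :k]
    nobs = int(fit.model.nobs if hasattr(fit.model, "nobs") else fit.nobs)
    df2 = max(nobs - k, 1)
    out = {}
    for term in terms:
        sl = di.term_name_slices[term]
        idx = np.arange(k)[sl]
        beta = params[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        Fstat = float(beta @ np.linalg.solve(V, beta) / q)
        p = float(sps.f.sf(Fstat, q, df2))
        est = float(beta[0]) if q == 1 else np.nan
        out[term] = (p, est)
    return out


def backward_select(fit_fn, terms: list[str], alpha: float = ALPHA):
    """Generic p-based backward elimination with marginality.

    ``fit_fn(terms)`` returns a fitted statsmodels result for the given
    fixed-effect terms (intercept always included). Deterministic given the
    data: ties in p break by dropping the term latest in the current order.
    Returns (final_fit, final_terms, dropped_in_order).
    """
    terms = list(terms)
    dropped: list[str] = []
    fit = fit_fn(terms)
    while terms:
        pvals = _term_pvalues(fit, terms)
        eliminable = [t for t in terms
                      if not any(_is_contained(t, u) for u in terms)]
        worst, worst_p = None, -1.0
        for t in eliminable:  # >= keeps the later tied term as the victim
            if pvals[t][0] >= worst_p:
                worst, worst_p = t, pvals[t][0]
        if worst is None or worst_p < alpha:
            break
        terms.remove(worst)
        dropped.append(worst)
        fit = fit_fn(terms)
    return fit, terms, dropped


def _terms_frame(fit, terms: list[str]) -> pd.DataFrame:
    pvals = _term_pvalues(fit, terms)
    return pd.DataFrame({
        "term": terms,
        "estimate": [pvals[t][1] for t in terms],
        "p": [pvals[t][0] for t in terms],
    })


# --------------------------------------------------------------------------
# Mixed model on ROI power
# --------------------------------------------------------------------------


def mixed_model_power(long: pd.DataFrame, alpha: float = ALPHA,
                      remove_outliers: bool = False) -> ModelResult:
    """POWER ~ GROUP x FEATURE with participant random intercept.

    Long-form input: columns ``participant``, ``group``, ``feature``,
    ``power``. Fixed effects are backward-reduced; Tukey-corrected group
    contrasts per feature are reported for the final model. A singular
    random-intercept fit falls back to ordinary regression with a prominent
    warning.
    """
    df = long.dropna(subset=["power"]).copy()
    notes: dict = {"df_method": "residual (n_obs - n_fixed_columns)"}
    if remove_outliers:
        df, bad = remove_residual_outliers(df, "power ~ C(group) * C(feature)")
        notes["outliers_removed"] = bad
    full_terms = ["C(group)", "C(feature)", "C(group):C(feature)"]

    def fit_fn(terms):
        rhs = " + ".join(terms) if terms else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(f"power ~ {rhs}", data=df, groups=df["participant"])
                res = md.fit(reml=True)
                if not np.isfinite(res.cov_re.iloc[0, 0]):
                    raise np.linalg.LinAlgError
                return res
            except Exception:
                warnings.warn("singular random-intercept fit; refitting without "
                              "random intercept", stacklevel=2)
                return smf.ols(f"power ~ {rhs}", data=df).fit()

    fit, terms, dropped = backward_select(fit_fn, full_terms, alpha)
    res = ModelResult(kind="mixed_model", terms=_terms_frame(fit, terms),
                      formula="power ~ " + (" + ".join(terms) if terms else "1"),
                      dropped=dropped, notes=notes, fit=fit)
    res.posthoc = _group_contrasts_by_feature(df)
    return res


def _group_contrasts_by_feature(df: pd.DataFrame) -> pd.DataFrame:
    """Tukey-corrected pairwise group contrasts within each feature cell."""
    frames = []
    for feat, sub in df.groupby("feature"):
        tk = tukey_posthoc(sub, value="power", group="group")
        tk.insert(0, "feature", feat)
        frames.append(tk)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Clinical regressions
# --------------------------------------------------------------------------


def clinical_regression(features: pd.DataFrame, outcome: str,
                        change: bool = False, alpha: float = ALPHA) -> ModelResult:
    """Backward-stepwise linear model of a clinical score on the EEG features.

    Stroke participants only. Starting model: peak-to-peak amplitude, the
    five ROI powers, stroke type (sensorimotor vs motor), and every EEG
    feature x stroke type interaction; features whose ROI was not discovered
    in a given cohort (no such column) are simply not offered. ``change=True``
    models the T2 - T1 difference; otherwise the T1 score. Reports term
    estimates, p-values and adjusted R² of the final model.
    """
    df = features[features["group"].isin(["motor", "sensorimotor"])].copy()
    df["stroke_type"] = (df["group"] == "sensorimotor").astype(float)
    t1, t2 = f"{outcome}_t1", f"{outcome}_t2"
    if change:
        df["y"] = df[t2] - df[t1]
    else:
        df["y"] = df[t1]
    feats = [f for f in EEG_FEATURES if f in df.columns]
    if not feats:
        raise ParameterError("no EEG feature columns present")
    df = df.dropna(subset=["y", *feats])
    terms = feats + ["stroke_type"] + [f"{f}:stroke_type" for f in feats]
    if len(df) <= len(terms) + 1:
        raise ParameterError(
            f"n = {len(df)} observations cannot support {len(terms)} starting "
            "terms; reduce the model or add data")

    def fit_fn(ts):
        rhs = " + ".join(ts) if ts else "1"
        return smf.ols(f"y ~ {rhs}", data=df).fit()

    fit, final_terms, dropped = backward_select(fit_fn, terms, alpha)
    return ModelResult(
        kind="clinical_change" if change else "clinical_t1",
        terms=_terms_frame(fit, final_terms),
        formula=f"{outcome}{'_change' if change else '_t1'} ~ "
                + (" + ".join(final_terms) if final_terms else "1"),
        adj_r2=float(fit.rsquared_adj), dropped=dropped, fit=fit,
        notes={"n": int(fit.nobs), "outcome": outcome, "change": change})


def report(result: ModelResult) -> str:
    """Human-readable summary of a ModelResult."""
    lines = [f"[{result.kind}] {result.formula}"]
    if result.adj_r2 is not None:
        lines.append(f"  adjusted R2 = {result.adj_r2:.3f}")
    for _, r in result.terms.iterrows():
        est = "" if np.isnan(r.get("estimate", np.nan)) else f" estimate = {r['estimate']:.3f},"
        extra = f" F = {r['F']:.3f}," if "F" in r else ""
        lines.append(f"  {r['term']}:{est}{extra} p = {r['p']:.4f}")
    if result.dropped:
        lines.append("  dropped (in order): " + ", ".join(result.dropped))
    if result.posthoc is not None and len(result.posthoc):
        lines.append("  post-hoc contrasts:")
        for _, r in result.posthoc.iterrows():
            feat = f"[{r['feature']}] " if "feature" in r else ""
            lines.append(
                f"    {feat}{r['group1']} vs {r['group2']}: "
                f"diff = {float(r['meandiff']):.3f}, p_adj = {float(r['p_adj']):.4f}, "
                f"d = {float(r['cohens_d']):.3f}")
    return "\n".join(lines)
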
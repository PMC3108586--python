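"""Between-group rhythm comparison, factorial ANOVA and group-mean summaries.

The rhythm comparison follows the classical parameter test on the linearized
cosinor coefficients: for the joint test, both groups are stacked into one
regression with group-specific mesors and the equality of the (beta, gamma)
pairs is tested by a nested-model F statistic with (2, n_A + n_B - 6)
degrees of freedom — the pooled-variance Hotelling-type T^2 on the rhythm
coefficient vector expressed as an exact F test. Single-parameter
comparisons (acrophase, amplitude) use the delta-method z statistic from
each group's own fit, with acrophase differences taken on the shortest arc.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, _as_time_value, fit_cosinor
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    UnbalancedDesignWarning,
    UndefinedRatioError,
)

__all__ = [
    "RhythmComparison",
    "compare_rhythms",
    "factorial_anova",
    "group_summaries",
    "group_mean_correlation",
    "fold_change",
]

# spec-facing factor aliases -> tidy column names
_FACTOR_COLUMNS = {"zt": "zt_h", "strain": "strain", "sex": "sex",
                   "timing": "timing"}


@dataclass(frozen=True)
class RhythmComparison:
    parameter: str  # "joint" | "acrophase" | "amplitude" | "mesor"
    groups: tuple
    statistic: float  # F (joint) or squared z (single parameter); >= 0
    df: tuple
    p_value: float
    estimate: float  # group A minus group B difference (NaN for joint)


def _shortest_arc(delta_h: float, period_h: float) -> float:
    """Signed circular difference mapped into (-period/2, period/2]."""
    d = (delta_h + period_h / 2.0) % period_h - period_h / 2.0
    if d == -period_h / 2.0:
        d = period_h / 2.0
    return d


def compare_rhythms(samples_a, samples_b, parameter: str = "joint",
                    period_h: float = 24.0,
                    groups: tuple = ("A", "B")) -> RhythmComparison:
    """Compare rhythm parameters between two independently fitted groups.

    ``parameter="joint"`` tests equality of the (beta, gamma) rhythm
    coefficient vectors; ``"acrophase"``, ``"amplitude"`` and ``"mesor"``
    compare the single derived parameter by a delta-method z test (reported
    as the squared statistic against chi-square(1), so the result is
    invariant to group order). Acrophase differences are shortest-arc.
    """
    fit_a = samples_a if isinstance(samples_a, CosinorFit) else fit_cosinor(samples_a, period_h)
    fit_b = samples_b if isinstance(samples_b, CosinorFit) else fit_cosinor(samples_b, period_h)

    if parameter == "joint":
        if isinstance(samples_a, CosinorFit) or isinstance(samples_b, CosinorFit):
            raise ValueError("joint comparison needs the raw samples, not fits")
        return _joint_comparison(samples_a, samples_b, fit_a, fit_b,
                                 period_h, groups)

    if parameter == "acrophase":
        for label, f in zip(groups, (fit_a, fit_b)):
            if not f.acrophase_defined:
                raise DegenerateDesignError(
                    f"group {label}: acrophase undefined (zero amplitude)")
        diff = _shortest_arc(fit_a.acrophase_h - fit_b.acrophase_h, period_h)
        se = np.hypot(fit_a.se_acrophase_h, fit_b.se_acrophase_h)
    elif parameter == "amplitude":
        diff = fit_a.amplitude - fit_b.amplitude
        se = np.hypot(fit_a.se_amplitude, fit_b.se_amplitude)
    elif parameter == "mesor":
        diff = fit_a.mesor - fit_b.mesor
        se = np.hypot(fit_a.se_mesor, fit_b.se_mesor)
    else:
        raise ValueError(f"unknown parameter {parameter!r}")

    if se == 0.0:
        stat = 0.0 if diff == 0.0 else float("inf")
    else:
        stat = (diff / se) ** 2
    p = float(stats.chi2.sf(stat, 1)) if np.isfinite(stat) else 0.0
    return RhythmComparison(parameter=parameter, groups=tuple(groups),
                            statistic=float(stat), df=(1, float("nan")),
                            p_value=p, estimate=float(diff))


def _joint_comparison(samples_a, samples_b, fit_a, fit_b, period_h, groups):
    t_a, y_a = _as_time_value(samples_a, period_h)
    t_b, y_b = _as_time_value(samples_b, period_h)
    n = len(y_a) + len(y_b)
    dof = n - 6
    if dof < 1:
        raise DegenerateDesignError("joint comparison needs n_A + n_B - 6 >= 1")
    w = 2.0 * np.pi / period_h
    t = np.concatenate([t_a, t_b])
    y = np.concatenate([y_a, y_b])
    in_a = np.concatenate([np.ones(len(y_a)), np.zeros(len(y_b))])
    # reduced model: separate mesors, shared rhythm coefficients
    X_red = np.column_stack([in_a, 1.0 - in_a, np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    resid = y - X_red @ coef
    rss_red = float(resid @ resid)
    rss_full = fit_a.rss + fit_b.rss
    if rss_full <= 0.0:
        f_stat = 0.0 if rss_red <= 1e-12 * max(rss_red, 1.0) else float("inf")
    else:
        f_stat = max(0.0, (rss_red - rss_full) / 2.0 / (rss_full / dof))
    p = float(stats.f.sf(f_stat, 2, dof)) if np.isfinite(f_stat) else 0.0
    return RhythmComparison(parameter="joint", groups=tuple(groups),
                            statistic=float(f_stat), df=(2, dof),
                            p_value=p, estimate=float("nan"))


def factorial_anova(samples: pd.DataFrame, factors,
                    response: str = "value") -> pd.DataFrame:
    """Fixed-effects factorial ANOVA with all interactions.

    Factors may use the aliases ``zt``/``strain``/``sex``/``timing`` or the
    tidy column names directly. Balanced designs use sequential (Type I)
    sums of squares; unbalanced designs use Type III with sum-to-zero
    contrasts. The choice is recorded in ``result.attrs``; empty design
    cells raise an :class:`UnbalancedDesignWarning` naming the cells.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cols = [_FACTOR_COLUMNS.get(f, f) for f in factors]
    if not cols:
        raise ValueError("at least one factor required")
    data = samples[cols + [response]].copy()
    for c in cols:
        levels = data[c].nunique()
        if levels < 2:
            raise DegenerateDesignError(f"factor {c!r} has {levels} level(s); need >= 2")

    sizes = data.groupby(cols, observed=True).size()
    n_cells_expected = int(np.prod([data[c].nunique() for c in cols]))
    empty = n_cells_expected - len(sizes)
    if empty > 0:
        observed = set(sizes.index if len(cols) > 1 else [(i,) for i in sizes.index])
        full = [tuple(combo) for combo in
                pd.MultiIndex.from_product([sorted(data[c].unique()) for c in cols])]
        missing = [combo for combo in full if combo not in observed]
        warnings.warn(f"empty design cells: {missing}", UnbalancedDesignWarning)
    balanced = empty == 0 and sizes.nunique() == 1

    terms = "*".join(f"C(Q('{c}'), Sum)" for c in cols)
    model = ols(f"Q('{response}') ~ {terms}", data=data).fit()
    if model.df_resid < 1:
        raise DegenerateDesignError("no residual degrees of freedom")
    ss_type = 1 if balanced else 3
    table = sm.stats.anova_lm(model, typ=ss_type)

    def _clean(term: str) -> str:
        return ":".join(re.sub(r"C\(Q\('([^']+)'\), Sum\)", r"\1", p)
                        for p in term.split(":"))

    out = table.rename(index=_clean).reset_index(names="term")
    out = out.rename(columns={"PR(>F)": "p_value", "df": "df", "F": "F"})
    out = out[~out["term"].isin(["Intercept"])].reset_index(drop=True)
    # constant response: every F is 0/0 float noise; report the exact null
    y = data[response].to_numpy(dtype=float)
    if np.sum((y - y.mean()) ** 2) <= 1e-12 * max(1.0, y.mean() ** 2) * len(y):
        not_resid = out["term"] != "Residual"
        out.loc[not_resid, "F"] = 0.0
        out.loc[not_resid, "p_value"] = 1.0
    out.attrs["ss_type"] = ss_type
    out.attrs["balanced"] = balanced
    out.attrs["response"] = response
    return out


def group_summaries(samples: pd.DataFrame,
                    by=("strain", "sex", "zt_h"),
                    value: str = "value") -> pd.DataFrame:
    """Per-cell mean, SEM (sd/sqrt(n), ddof=1) and n."""
    by = list(by)
    g = samples.groupby(by, observed=True)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def group_mean_correlation(summaries_x: pd.DataFrame,
                           summaries_y: pd.DataFrame,
                           join_on=("strain", "sex", "zt_h")):
    """Pearson correlation of matched group means (e.g. protein vs mRNA).

    Returns ``(r, p, n_pairs)``; p is two-sided from the t transform.
    """
    join_on = list(join_on)
    merged = summaries_x.merge(summaries_y, on=join_on, suffixes=("_x", "_y"))
    n = len(merged)
    if n < 3:
        raise InsufficientDataError(
            f"correlation needs >= 3 matched cells, got {n}")
    r, p = stats.pearsonr(merged["mean_x"], merged["mean_y"])
    return float(r), float(p), n


def fold_change(summaries: pd.DataFrame):
    """Peak-to-trough ratio of per-ZT group means.

    Returns ``(peak_zt, trough_zt, ratio)`` with ratio = max mean / min mean.
    Ties resolve to the earliest ZT; a nonpositive trough mean is undefined.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("fold change needs >= 2 ZT cells")
    s = summaries.sort_values("zt_h").reset_index(drop=True)
    peak = s.loc[s["mean"].idxmax()]
    trough = s.loc[s["mean"].idxmin()]
    if trough["mean"] <= 0:
        raise UndefinedRatioError(
            f"trough mean {trough['mean']} <= 0: fold change undefined")
    return float(peak["zt_h"]), float(trough["zt_h"]), float(peak["mean"] / trough["mean"])
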
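"""Histologic toxicity grading and dosing-time incidence analysis.

A mouse ileum slide is scored "1" for each of three damaged compartments —
surface epithelium, villi structure, crypt glands — and the toxicity grade
is the sum, ranging 0 (normal) to 3 (all compartments altered). Incidence
analyses summarise the proportion of lesion-free animals (grade 0) by
dosing-timing label, strain and sex, compare proportions with the Pearson
chi-square test on the 2x2 free-vs-lesioned table (Fisher's exact test as
an alternative), and analyse the grade with factorial ANOVA treating the
ordinal grade as numeric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import compare
from .errors import (
    DegenerateTableError,
    EmptyStratumWarning,
    InsufficientDataError,
    MissingDataError,
    ValidationError,
)

__all__ = [
    "ContingencyResult",
    "score_grade",
    "add_grades",
    "lesion_free_incidence",
    "chi2_incidence",
    "grade_anova",
]

LESION_COLUMNS = ["lesion_epithelium", "lesion_villi", "lesion_crypt"]


def _as_indicator(x, name: str) -> int:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        raise MissingDataError(f"missing lesion indicator {name!r}")
    if isinstance(x, (bool, np.bool_)):
        return int(x)
    if x in (0, 1):
        return int(x)
    raise MissingDataError(f"lesion indicator {name!r} must be boolean, got {x!r}")


def score_grade(lesion_epithelium, lesion_villi, lesion_crypt) -> int:
    """Toxicity grade 0-3: the count of lesioned ileum compartments."""
    return sum(_as_indicator(x, name) for x, name in
               zip((lesion_epithelium, lesion_villi, lesion_crypt), LESION_COLUMNS))


def add_grades(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``grade`` column; rows with a missing indicator
    are excluded with a logged warning."""
    out = records.copy()
    ok = out[LESION_COLUMNS].notna().all(axis=1)
    if not ok.all():
        dropped = out.index[~ok].tolist()
        warnings.warn(f"excluding {len(dropped)} record(s) with missing lesion "
                      f"indicators: rows {dropped}", UserWarning)
        out = out[ok]
    out["grade"] = out[LESION_COLUMNS].astype(int).sum(axis=1)
    return out


def lesion_free_incidence(records: pd.DataFrame,
                          stratify_by=("timing",),
                          include_controls: bool = False) -> pd.DataFrame:
    """Per-stratum lesion-free (grade 0) counts, proportion and binomial SEM.

    Controls are excluded by default (summarise them separately with
    ``include_controls=True``). SEM = sqrt(p*(1-p)/n).
    """
    df = add_grades(records) if "grade" not in records.columns else records.copy()
    if not include_controls and "timing" in df.columns:
        df = df[df["timing"] != "control"]
    if df.empty:
        raise InsufficientDataError("no non-control records to summarise")
    by = list(stratify_by)
    grouped = df.groupby(by, observed=True)["grade"]
    out = grouped.agg(n_free=lambda g: int((g == 0).sum()),
                      n_total="count").reset_index()
    # warn about strata implied by the observed levels but absent from data
    expected = int(np.prod([df[c].nunique() for c in by]))
    if len(out) < expected:
        observed = set(map(tuple, out[by].itertuples(index=False)))
        full = [tuple(c) for c in
                pd.MultiIndex.from_product([sorted(df[c].unique()) for c in by])]
        missing = [c for c in full if c not in observed]
        warnings.warn(f"empty strata omitted: {missing}", EmptyStratumWarning)
    out["proportion"] = out["n_free"] / out["n_total"]
    out["sem"] = np.sqrt(out["proportion"] * (1 - out["proportion"]) / out["n_total"])
    return out


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray  # rows = groups, cols = (free, lesioned)
    chi2: float
    df: int
    p_value: float
    proportions: tuple  # per-row lesion-free fraction
    method: str = "pearson"
    correction: bool = False


def chi2_incidence(counts_a, counts_b, correction: bool = False,
                   method: str = "pearson") -> ContingencyResult:
    """Compare two lesion-free incidences on the 2x2 free-vs-lesioned table.

    ``counts_a``/``counts_b`` are ``(n_free, n_total)`` pairs. Pearson
    chi-square with df = 1 by default (Yates continuity correction off);
    ``method="fisher"`` gives the exact hypergeometric test instead.
    """
    table = []
    for free, total in (counts_a, counts_b):
        if not (0 <= free <= total) or total <= 0:
            raise ValidationError(
                f"counts must satisfy 0 <= free <= total with total > 0, "
                f"got ({free}, {total})")
        table.append([free, total - free])
    table = np.asarray(table, dtype=int)
    col_sums = table.sum(axis=0)
    if (col_sums == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"degenerate 2x2 table (a zero margin gives expected count 0): "
            f"{table.tolist()}")
    props = tuple(table[i, 0] / table[i].sum() for i in range(2))
    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return ContingencyResult(table=table, chi2=float("nan"), df=1,
                                 p_value=float(p), proportions=props,
                                 method="fisher", correction=False)
    if method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if props[0] == props[1]:
        chi2, p = 0.0, 1.0  # identical proportions, exact null
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return ContingencyResult(table=table, chi2=float(chi2), df=1,
                             p_value=float(p), proportions=props,
                             method="pearson", correction=correction)


def grade_anova(records: pd.DataFrame, factors) -> pd.DataFrame:
    """Factorial ANOVA of the toxicity grade (ordinal treated as numeric).

    Delegates to :func:`chronostat.compare.factorial_anova` with the grade as
    response; the metadata notes the ordinal-as-numeric convention.
    """
    df = add_grades(records) if "grade" not in records.columns else records
    out = compare.factorial_anova(df, factors, response="grade")
    out.attrs["response_scale"] = "ordinal grade 0-3 treated as numeric"
    return out
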
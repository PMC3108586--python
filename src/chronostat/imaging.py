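"""Confocal image-quantification arithmetic for protein expression.

Starts from already-extracted numbers per image — background-subtracted
fluorescent area and nucleus count — and reproduces the quantification
chain: area per nucleus, percent of a single control reference section,
per-section mean over the (nominally three) images, and per-group
mean ± SEM over sections.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import (
    IncompleteSectionWarning,
    InsufficientDataError,
    NormalizationError,
    UndefinedRatioError,
)

__all__ = [
    "area_per_nucleus",
    "normalize_to_control",
    "process_records",
    "summarize_sections",
]


def area_per_nucleus(fluor_area: float, n_nuclei: int) -> float:
    """Mean fluorescent area per nucleus for one image."""
    if n_nuclei < 1:
        raise UndefinedRatioError(f"n_nuclei must be >= 1, got {n_nuclei}")
    if fluor_area < 0:
        raise ValueError(f"fluor_area must be >= 0, got {fluor_area}")
    return fluor_area / n_nuclei


def normalize_to_control(values, control_mean: float):
    """Express values as a percentage of the control area-per-nucleus."""
    if control_mean <= 0:
        raise NormalizationError(
            f"control mean must be positive, got {control_mean}")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


def process_records(records: pd.DataFrame, control_mean: float) -> pd.DataFrame:
    """Add derived per-image columns ``area_per_nucleus`` and ``pct_of_control``.

    Fluorescent areas are assumed background-subtracted upstream and are
    clipped at 0 on ingestion.
    """
    out = records.copy()
    if (out["n_nuclei"] < 1).any():
        raise UndefinedRatioError("records with n_nuclei < 1 present")
    out["fluor_area"] = out["fluor_area"].clip(lower=0.0)
    out["area_per_nucleus"] = out["fluor_area"] / out["n_nuclei"]
    out["pct_of_control"] = normalize_to_control(out["area_per_nucleus"], control_mean)
    return out


def summarize_sections(records: pd.DataFrame, control_mean: float,
                       group_keys=("group", "zt_h"),
                       expected_images: int = 3):
    """Per-section and per-group summaries of percent-of-control expression.

    Returns ``(section_df, group_df)``: the per-section mean of its images'
    pct-of-control values, and per-group mean ± SEM over sections. Sections
    with fewer than ``expected_images`` images are kept with a warning.
    """
    if records.empty:
        raise InsufficientDataError("no image records to summarise")
    df = process_records(records, control_mean)
    keys = list(group_keys)
    sections = (df.groupby(keys + ["section_id"], observed=True)["pct_of_control"]
                  .agg(section_mean="mean", n_images="count").reset_index())
    short = sections[sections["n_images"] < expected_images]
    if not short.empty:
        warnings.warn(
            f"{len(short)} section(s) have fewer than {expected_images} images: "
            f"{short['section_id'].tolist()}", IncompleteSectionWarning)
    g = sections.groupby(keys, observed=True)["section_mean"]
    groups = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_sections="count").reset_index()
    groups["sem"] = groups["sd"] / np.sqrt(groups["n_sections"])
    return sections, groups.drop(columns="sd")
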
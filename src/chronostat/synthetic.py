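"""Synthetic study-data generators.

Emulates the three data streams of a mouse circadian dosing-time study so
every downstream analysis is testable without animal data:

* cross-sectional expression sampling — one animal per timepoint, sinusoidal
  24-h mean structure with additive Gaussian (or optional log-normal) noise,
  5 animals at each of 6 or 8 equispaced Zeitgeber times per group;
* per-animal ileum toxicity records — three Bernoulli lesion-site indicators
  (surface epithelium, villi, crypt glands) whose probabilities depend on
  dosing-timing label, strain and sex; controls are lesion free;
* confocal image quantification — three images per tissue section, each with
  a fluorescent area and nucleus count whose area-per-nucleus ratio scales a
  control reference by a group-specific multiplier.

All generators are deterministic given their seed and write the tidy CSV
schemas consumed by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionDesign",
    "ToxicityGroup",
    "ToxicityDesign",
    "generate_expression",
    "generate_toxicity",
    "generate_image_quant",
]

EXPRESSION_COLUMNS = ["subject_id", "strain", "sex", "tissue", "zt_h", "value"]
TOXICITY_COLUMNS = ["mouse_id", "strain", "sex", "timing", "day",
                    "lesion_epithelium", "lesion_villi", "lesion_crypt"]
IMAGING_COLUMNS = ["image_id", "section_id", "group", "zt_h",
                   "fluor_area", "n_nuclei"]


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


@dataclass(frozen=True)
class ExpressionDesign:
    """Sampling design and ground truth for one strain/sex/tissue group.

    ``value = mesor + rel_amplitude*mesor * cos(2*pi*(t - acrophase_h)/24) + noise``.
    """

    zts: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    n_per_zt: int = 5
    mesor: float = 1.0
    rel_amplitude: float = 0.72
    acrophase_h: float = 10.33
    noise_sd: float = 0.25
    strain: str = "B6D2F1"
    sex: str = "male"
    tissue: str = "mucosa"
    noise_model: str = "additive"  # or "lognormal" (multiplicative)
    seed: int = 0

    def __post_init__(self):
        zts = tuple(float(z) for z in self.zts)
        object.__setattr__(self, "zts", zts)
        _require(len(zts) > 0, "zts: must be non-empty")
        _require(all(0.0 <= z < 24.0 for z in zts),
                 "zts: sampling times must lie in [0, 24)")
        _require(len(set(np.mod(zts, 24.0))) == len(zts),
                 "zts: sampling times must be distinct modulo 24")
        _require(int(self.n_per_zt) >= 1, "n_per_zt: must be >= 1")
        _require(self.mesor > 0, "mesor: must be positive")
        _require(0.0 <= self.rel_amplitude <= 1.0,
                 "rel_amplitude: must lie in [0, 1]")
        _require(0.0 <= self.acrophase_h < 24.0,
                 "acrophase_h: must lie in [0, 24)")
        _require(self.noise_sd >= 0.0, "noise_sd: must be nonnegative")
        _require(self.noise_model in ("additive", "lognormal"),
                 "noise_model: must be 'additive' or 'lognormal'")

    @property
    def amplitude(self) -> float:
        return self.rel_amplitude * self.mesor


def generate_expression(design: ExpressionDesign) -> pd.DataFrame:
    """Simulate one animal per row at each designed Zeitgeber time.

    Deterministic given ``design.seed``; with ``noise_sd = 0`` the values lie
    exactly on the cosine curve.
    """
    rng = np.random.default_rng(design.seed)
    zts = np.repeat(design.zts, design.n_per_zt)
    signal = design.mesor + design.amplitude * np.cos(
        2.0 * np.pi * (zts - design.acrophase_h) / 24.0)
    if design.noise_sd == 0.0:
        values = signal
    elif design.noise_model == "additive":
        values = signal + rng.normal(0.0, design.noise_sd, size=zts.size)
    else:
        values = signal * rng.lognormal(0.0, design.noise_sd, size=zts.size)
    prefix = f"{design.strain}-{design.sex[:1]}-{design.tissue[:3]}"
    return pd.DataFrame({
        "subject_id": [f"{prefix}-{i:03d}" for i in range(zts.size)],
        "strain": design.strain,
        "sex": design.sex,
        "tissue": design.tissue,
        "zt_h": zts,
        "value": values,
    }, columns=EXPRESSION_COLUMNS)


@dataclass(frozen=True)
class ToxicityGroup:
    """One treated or control group of the dosing-time toxicity arm."""

    timing_label: str  # "best" | "worst" | "control"
    strain: str
    sex: str
    sacrifice_day: int
    n: int
    p_epithelium: float = 0.0
    p_villi: float = 0.0
    p_crypt: float = 0.0

    def __post_init__(self):
        _require(self.timing_label in ("best", "worst", "control"),
                 f"timing_label: {self.timing_label!r} not in best/worst/control")
        _require(self.sacrifice_day in (2, 4, 6),
                 "sacrifice_day: must be 2, 4 or 6")
        _require(int(self.n) >= 1, "n: must be >= 1")
        for name in ("p_epithelium", "p_villi", "p_crypt"):
            p = getattr(self, name)
            _require(0.0 <= p <= 1.0, f"{name}: probability {p} outside [0, 1]")
        if self.timing_label == "control":
            _require(self.p_epithelium == self.p_villi == self.p_crypt == 0.0,
                     "control groups must have all lesion probabilities 0")

    @property
    def probabilities(self) -> tuple:
        return (self.p_epithelium, self.p_villi, self.p_crypt)


@dataclass(frozen=True)
class ToxicityDesign:
    groups: tuple = ()
    shared_frailty: float = 0.0  # prob. the three sites share one latent draw
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        _require(len(self.groups) > 0, "groups: must be non-empty")
        _require(0.0 <= self.shared_frailty <= 1.0,
                 "shared_frailty: must lie in [0, 1]")


def generate_toxicity(design: ToxicityDesign) -> pd.DataFrame:
    """Simulate per-animal lesion-site indicators.

    Each animal draws three Bernoulli indicators with its group's site
    probabilities. By default sites are independent; with probability
    ``shared_frailty`` an animal uses a single shared uniform latent for all
    three sites, inducing positive inter-site correlation.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    counter = 0
    for g in design.groups:
        probs = np.asarray(g.probabilities)
        for _ in range(g.n):
            if design.shared_frailty > 0.0 and rng.random() < design.shared_frailty:
                u = np.full(3, rng.random())
            else:
                u = rng.random(3)
            lesions = (u < probs).astype(int)
            rows.append((f"m{counter:04d}", g.strain, g.sex, g.timing_label,
                         g.sacrifice_day, *lesions))
            counter += 1
    return pd.DataFrame(rows, columns=TOXICITY_COLUMNS)


def generate_image_quant(groups, control_mean_area_per_nucleus: float,
                         effect_multipliers, noise_cv: float = 0.1,
                         seed: int = 0, n_sections: int = 3,
                         images_per_section: int = 3,
                         mean_nuclei: float = 120.0) -> pd.DataFrame:
    """Simulate confocal image-quantification records.

    Parameters
    ----------
    groups
        Sequence of ``(group_label, zt_h)`` pairs.
    control_mean_area_per_nucleus
        Fluorescent area per nucleus of the control reference section.
    effect_multipliers
        One positive multiplier per group: the group's mean area-per-nucleus
        relative to the control.
    noise_cv
        Coefficient of variation of the per-image ratio around the group mean.

    Each section contributes ``images_per_section`` images; nucleus counts are
    Poisson around ``mean_nuclei`` and the fluorescent area is the (noisy)
    target ratio times the nucleus count, so the area/nuclei ratio has group
    mean ``multiplier * control_mean_area_per_nucleus``.
    """
    _require(control_mean_area_per_nucleus > 0,
             "control_mean_area_per_nucleus: must be positive")
    _require(noise_cv >= 0.0, "noise_cv: must be nonnegative")
    multipliers = list(effect_multipliers)
    _require(len(multipliers) == len(list(groups)),
             "effect_multipliers: one multiplier per group required")
    _require(all(m > 0 for m in multipliers),
             "effect_multipliers: must all be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for (label, zt), mult in zip(groups, multipliers):
        target = mult * control_mean_area_per_nucleus
        for s in range(n_sections):
            section_id = f"{label}-s{s:02d}"
            for i in range(images_per_section):
                n_nuclei = int(rng.poisson(mean_nuclei)) + 1
                ratio = target * max(0.0, 1.0 + noise_cv * rng.standard_normal())
                rows.append((f"{section_id}-i{i}", section_id, label,
                             float(zt), ratio * n_nuclei, n_nuclei))
    return pd.DataFrame(rows, columns=IMAGING_COLUMNS)
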
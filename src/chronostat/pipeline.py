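"""End-to-end orchestration: simulate → fit → compare → toxicity report.

A run is driven by a single :class:`RunConfig` (loadable from YAML) whose
seed feeds every generator through spawned child seeds, so re-running the
same config reproduces every output byte for byte. Each run directory gets
a manifest echoing the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, imaging, toxicity
from .cosinor import fit_cosinor
from .errors import ValidationError
from .synthetic import (
    ExpressionDesign,
    ToxicityDesign,
    ToxicityGroup,
    generate_expression,
    generate_image_quant,
    generate_toxicity,
)

log = logging.getLogger("chronostat")

__all__ = ["RunConfig", "default_config", "run_pipeline", "fit_groups"]

# four strain/sex groups with study-like rhythm truths: (mesor, relative
# amplitude, acrophase h). B6CBAF1 mesor doubled relative to B6D2F1.
_DEFAULT_EXPRESSION_GROUPS = [
    {"strain": "B6D2F1", "sex": "male", "mesor": 1.0,
     "rel_amplitude": 0.72, "acrophase_h": 10.33},
    {"strain": "B6D2F1", "sex": "female", "mesor": 1.0,
     "rel_amplitude": 0.70, "acrophase_h": 9.5},
    {"strain": "B6CBAF1", "sex": "male", "mesor": 2.0,
     "rel_amplitude": 0.68, "acrophase_h": 11.67},
    {"strain": "B6CBAF1", "sex": "female", "mesor": 2.0,
     "rel_amplitude": 0.51, "acrophase_h": 11.83},
]

# dosing-time toxicity arm: per-site lesion probabilities by timing label,
# constant across strain/sex/day by default (see docs/methods.md).
_DEFAULT_SITE_P = {"best": 0.23, "worst": 0.515, "control": 0.0}
_DEFAULT_TOX_N = {"best": 7, "worst": 7, "control": 3}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/demo"
    period_h: float = 24.0
    level: float = 0.95
    zts: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    n_per_zt: int = 5
    noise_sd: float = 0.25
    expression_groups: list = field(
        default_factory=lambda: [dict(g) for g in _DEFAULT_EXPRESSION_GROUPS])
    site_p: dict = field(default_factory=lambda: dict(_DEFAULT_SITE_P))
    tox_n: dict = field(default_factory=lambda: dict(_DEFAULT_TOX_N))
    imaging_zts: tuple = (0.0, 3.0, 12.0, 15.0)
    control_mean_area_per_nucleus: float = 10.0
    imaging_noise_cv: float = 0.1
    n_sections: int = 3
    correction: bool = False
    ci_method: str = "delta"
    expression_csv: str | None = None  # optional pre-existing inputs
    toxicity_csv: str | None = None
    imaging_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.zts = tuple(float(z) for z in cfg.zts)
        cfg.imaging_zts = tuple(float(z) for z in cfg.imaging_zts)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zts"] = list(self.zts)
        d["imaging_zts"] = list(self.imaging_zts)
        return d


def default_config(seed: int = 0, outdir: str = "runs/demo") -> RunConfig:
    return RunConfig(seed=seed, outdir=outdir)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def simulate_datasets(config: RunConfig):
    """Generate the three study tables from the config seed."""
    seeds = _child_seeds(config.seed, len(config.expression_groups) + 2)
    expr_frames = []
    for g, s in zip(config.expression_groups, seeds):
        design = ExpressionDesign(zts=config.zts, n_per_zt=config.n_per_zt,
                                  noise_sd=config.noise_sd, seed=s, **g)
        expr_frames.append(generate_expression(design))
    expression = pd.concat(expr_frames, ignore_index=True)

    groups = []
    for timing in ("best", "worst", "control"):
        p = config.site_p[timing]
        for strain in ("B6D2F1", "B6CBAF1"):
            for sex in ("male", "female"):
                for day in (2, 4, 6):
                    n = config.tox_n[timing]
                    # split each strain/sex/timing cohort across sacrifice days
                    n_day = max(1, round(n / 3))
                    groups.append(ToxicityGroup(
                        timing_label=timing, strain=strain, sex=sex,
                        sacrifice_day=day, n=n_day,
                        p_epithelium=p, p_villi=p, p_crypt=p))
    tox = generate_toxicity(ToxicityDesign(groups=tuple(groups),
                                           seed=seeds[-2]))

    img_groups, multipliers = [], []
    w = 2.0 * np.pi / config.period_h
    for g in config.expression_groups:
        for zt in config.imaging_zts:
            label = f"{g['strain']}-{g['sex']}-ZT{zt:g}"
            img_groups.append((label, zt))
            multipliers.append(
                1.0 + g["rel_amplitude"] * np.cos(w * (zt - g["acrophase_h"])))
    imaging_df = generate_image_quant(
        img_groups, config.control_mean_area_per_nucleus, multipliers,
        noise_cv=config.imaging_noise_cv, seed=seeds[-1],
        n_sections=config.n_sections)
    return expression, tox, imaging_df


def fit_groups(expression: pd.DataFrame, group_by=("strain", "sex", "tissue"),
               period_h: float = 24.0, level: float = 0.95,
               ci_method: str = "delta") -> pd.DataFrame:
    """Fit a cosinor per group; one tidy row per fit."""
    rows = []
    for keys, sub in expression.groupby(list(group_by), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        fit = fit_cosinor(sub, period_h=period_h, level=level, ci_method=ci_method)
        rows.append({**dict(zip(group_by, keys)), **fit.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full deterministic run; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run start: seed=%d outdir=%s", config.seed, outdir)

    if config.expression_csv:
        for path in (config.expression_csv, config.toxicity_csv, config.imaging_csv):
            if path and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
        expression = pd.read_csv(config.expression_csv)
        tox = pd.read_csv(config.toxicity_csv) if config.toxicity_csv else None
        imaging_df = pd.read_csv(config.imaging_csv) if config.imaging_csv else None
    else:
        expression, tox, imaging_df = simulate_datasets(config)

    expression.to_csv(outdir / "expression.csv", index=False)
    fits = fit_groups(expression, period_h=config.period_h, level=config.level,
                      ci_method=config.ci_method)
    fits.to_csv(outdir / "fits.csv", index=False)
    fits.to_json(outdir / "fits.json", orient="records", indent=2)

    anova = compare.factorial_anova(expression, ("zt", "strain", "sex"))
    anova.to_csv(outdir / "anova_expression.csv", index=False)

    comp_rows = []
    for strain in expression["strain"].unique():
        sub = expression[expression["strain"] == strain]
        males = sub[sub["sex"] == "male"]
        females = sub[sub["sex"] == "female"]
        if len(males) and len(females):
            for param in ("joint", "acrophase"):
                c = compare.compare_rhythms(males, females, parameter=param,
                                            period_h=config.period_h,
                                            groups=(f"{strain}-male",
                                                    f"{strain}-female"))
                comp_rows.append({"strain": strain, "parameter": param,
                                  "statistic": c.statistic, "p_value": c.p_value,
                                  "estimate": c.estimate})
    pd.DataFrame(comp_rows).to_csv(outdir / "rhythm_comparisons.csv", index=False)

    summaries = compare.group_summaries(expression)
    summaries.to_csv(outdir / "expression_summaries.csv", index=False)

    if tox is not None:
        tox.to_csv(outdir / "toxicity.csv", index=False)
        graded = toxicity.add_grades(tox)
        inc_timing = toxicity.lesion_free_incidence(graded, ("timing",))
        inc_timing.to_csv(outdir / "incidence_timing.csv", index=False)
        toxicity.lesion_free_incidence(graded, ("timing", "strain", "sex")) \
            .to_csv(outdir / "incidence_by_group.csv", index=False)
        toxicity.lesion_free_incidence(graded, ("timing", "day")) \
            .to_csv(outdir / "incidence_by_day.csv", index=False)
        best = inc_timing[inc_timing["timing"] == "best"].iloc[0]
        worst = inc_timing[inc_timing["timing"] == "worst"].iloc[0]
        chi = toxicity.chi2_incidence(
            (int(best["n_free"]), int(best["n_total"])),
            (int(worst["n_free"]), int(worst["n_total"])),
            correction=config.correction)
        with open(outdir / "chi2_timing.json", "w") as fh:
            json.dump({"chi2": chi.chi2, "df": chi.df, "p_value": chi.p_value,
                       "proportions": list(chi.proportions),
                       "table": chi.table.tolist()}, fh, indent=2)
        toxicity.grade_anova(graded, ("timing", "strain", "sex")) \
            .to_csv(outdir / "grade_anova.csv", index=False)

    if imaging_df is not None:
        imaging_df.to_csv(outdir / "imaging.csv", index=False)
        sections, img_groups = imaging.summarize_sections(
            imaging_df, config.control_mean_area_per_nucleus)
        sections.to_csv(outdir / "imaging_sections.csv", index=False)
        img_groups.to_csv(outdir / "imaging_group_summary.csv", index=False)
        # protein vs mRNA correlation on matched strain/sex/ZT cells
        parts = img_groups["group"].str.rsplit("-ZT", n=1)
        img_cells = img_groups.copy()
        img_cells[["strain", "sex"]] = (
            parts.str[0].str.rsplit("-", n=1, expand=True))
        corr_in = img_cells[["strain", "sex", "zt_h", "mean"]]
        mrna_cells = summaries[summaries["zt_h"].isin(img_cells["zt_h"].unique())]
        try:
            r, p, n_pairs = compare.group_mean_correlation(
                corr_in, mrna_cells[["strain", "sex", "zt_h", "mean"]])
            with open(outdir / "protein_mrna_correlation.json", "w") as fh:
                json.dump({"r": r, "p_value": p, "n_pairs": n_pairs}, fh, indent=2)
        except Exception as exc:  # noqa: BLE001 - correlation is optional output
            log.warning("protein/mRNA correlation skipped: %s", exc)

    _write_figures(outdir, expression, fits, tox)

    manifest = {"config": config.to_dict(), "seed": config.seed,
                "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %d outputs", len(manifest["outputs"]))
    return outdir


def _write_figures(outdir: Path, expression, fits, tox) -> None:
    """Convenience figures: cosine overlays and incidence bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    tgrid = np.linspace(0, 24, 241)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for _, row in fits.iterrows():
        label = "-".join(str(row[k]) for k in ("strain", "sex") if k in row)
        summ = compare.group_summaries(
            expression[(expression["strain"] == row.get("strain")) &
                       (expression["sex"] == row.get("sex"))])
        ax.errorbar(summ["zt_h"], summ["mean"], yerr=summ["sem"],
                    fmt="o", capsize=2, label=label)
        if np.isfinite(row["acrophase_h"]):
            w = 2 * np.pi / row["period_h"]
            ax.plot(tgrid, row["mesor"] + row["amplitude"] *
                    np.cos(w * (tgrid - row["acrophase_h"])), lw=1)
    ax.set_xlabel("Zeitgeber time (h)")
    ax.set_ylabel("normalized expression")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "expression_cosinor.png", dpi=120)
    plt.close(fig)

    if tox is not None:
        graded = toxicity.add_grades(tox)
        inc = toxicity.lesion_free_incidence(graded, ("timing",))
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.bar(inc["timing"], 100 * inc["proportion"],
               yerr=100 * inc["sem"], capsize=4)
        ax.set_ylabel("% mice free of ileum lesions (grade 0)")
        fig.tight_layout()
        fig.savefig(figdir / "incidence_timing.png", dpi=120)
        plt.close(fig)
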
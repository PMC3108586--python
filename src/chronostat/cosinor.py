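"""Single-cosinor rhythmometry with a fixed period.

Fits the linearized cosine model

    y_i = M + beta * cos(w t_i) + gamma * sin(w t_i) + e_i,   w = 2*pi/period

by ordinary least squares and reports the chronobiological parameters:
mesor M (rhythm-adjusted mean), amplitude A = sqrt(beta^2 + gamma^2)
(half the peak-to-trough extent), and acrophase phi (clock time of the
fitted maximum, in Zeitgeber-time hours referred to ZT0, so that
y_hat(t) = M + A*cos(w*(t - phi))).

Rhythm detection uses the zero-amplitude F test comparing the cosinor fit
against the intercept-only model. Confidence limits for amplitude and
acrophase come from the delta method on the (beta, gamma) covariance by
default; a conservative construction that projects the joint elliptical
confidence region of (beta, gamma) is available with ``ci_method="ellipse"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    PerfectFitWarning,
    UndefinedRatioError,
)

__all__ = [
    "CosinorFit",
    "fit_cosinor",
    "zero_amplitude_test",
    "acrophase_to_zt_string",
    "relative_amplitude",
    "predict",
]

#: Unicode ratio character used in ZT clock labels (e.g. "ZT13∶35").
_ZT_SEPARATOR = "∶"


def _as_time_value(samples, period_h: float):
    """Coerce samples into (t, y) float arrays.

    Accepts a tidy DataFrame with ``zt_h``/``value`` columns or a
    ``(t, y)`` pair of array-likes. Times are reduced modulo the period.
    """
    if isinstance(samples, pd.DataFrame):
        t = samples["zt_h"].to_numpy(dtype=float)
        y = samples["value"].to_numpy(dtype=float)
    else:
        t, y = samples
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise DegenerateDesignError("times and values must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise DegenerateDesignError("non-finite time or value in cosinor input")
    return np.mod(t, period_h), y


@dataclass
class CosinorFit:
    """Fitted single-cosinor model for one group of cross-sectional samples."""

    mesor: float
    amplitude: float
    acrophase_h: float  # NaN when the rhythm is degenerate (A == 0)
    period_h: float
    beta: float
    gamma: float
    n: int
    rss: float
    rss0: float  # intercept-only residual sum of squares
    dof: int
    level: float
    p_zero_amplitude: float
    se_mesor: float
    se_amplitude: float
    se_acrophase_h: float
    ci_mesor: tuple[float, float]
    ci_amplitude: tuple[float, float]
    ci_acrophase_h: tuple[float, float]
    rel_amplitude_pct: float
    ci_rel_amplitude_pct: tuple[float, float]
    coef_cov: np.ndarray = field(repr=False)
    ci_method: str = "delta"

    @property
    def acrophase_defined(self) -> bool:
        return math.isfinite(self.acrophase_h)

    def predict(self, t_h):
        return predict(self, t_h)

    def to_dict(self) -> dict:
        """Flat JSON-serializable summary (arrays dropped)."""
        d = {
            "mesor": self.mesor,
            "amplitude": self.amplitude,
            "acrophase_h": self.acrophase_h,
            "acrophase_zt": acrophase_to_zt_string(self.acrophase_h),
            "period_h": self.period_h,
            "beta": self.beta,
            "gamma": self.gamma,
            "n": self.n,
            "rss": self.rss,
            "p_zero_amplitude": self.p_zero_amplitude,
            "rel_amplitude_pct": self.rel_amplitude_pct,
            "level": self.level,
            "ci_method": self.ci_method,
        }
        for name in ("mesor", "amplitude", "acrophase_h", "rel_amplitude_pct"):
            lo, hi = getattr(self, f"ci_{name}" if name != "rel_amplitude_pct" else "ci_rel_amplitude_pct")
            d[f"ci_{name}_lo"], d[f"ci_{name}_hi"] = lo, hi
        return d


def fit_cosinor(samples, period_h: float = 24.0, level: float = 0.95,
                ci_method: str = "delta") -> CosinorFit:
    """Fit the fixed-period cosinor model to one group of samples.

    Parameters
    ----------
    samples
        Tidy DataFrame with ``zt_h`` and ``value`` columns (one row per
        animal; cross-sectional design), or a ``(t, y)`` array pair.
    period_h
        Fixed period in hours; 24 for a light-entrained circadian design.
    level
        Confidence level for all reported intervals.
    ci_method
        ``"delta"`` (default) or ``"ellipse"`` — see module docstring.

    Raises
    ------
    DegenerateDesignError
        Fewer than 4 samples or fewer than 3 distinct sampling times.
    """
    if ci_method not in ("delta", "ellipse"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    t, y = _as_time_value(samples, period_h)
    n = len(y)
    if n < 4:
        raise DegenerateDesignError(f"cosinor needs >= 4 samples, got {n}")
    if len(np.unique(np.round(t, 9))) < 3:
        raise DegenerateDesignError(
            "cosinor needs >= 3 distinct sampling times (3-parameter model)")

    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise DegenerateDesignError("design matrix is rank deficient")
    resid = y - X @ coef
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    mesor, beta, gamma = (float(c) for c in coef)

    dof = n - 3
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)

    flat = np.ptp(y) == 0.0
    amplitude = 0.0 if flat else float(np.hypot(beta, gamma))
    if amplitude == 0.0:
        acrophase = float("nan")
    else:
        acrophase = float(np.mod(math.atan2(gamma, beta) / w, period_h))

    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    se_mesor = float(np.sqrt(cov[0, 0]))
    ci_mesor = (mesor - tcrit * se_mesor, mesor + tcrit * se_mesor)

    cov_bg = cov[1:, 1:]
    if amplitude > 0.0:
        grad_a = np.array([beta, gamma]) / amplitude
        se_amp = float(np.sqrt(grad_a @ cov_bg @ grad_a))
        # d(theta)/d(beta,gamma) for theta = atan2(gamma, beta), scaled to hours
        grad_phi = np.array([-gamma, beta]) / amplitude**2 / w
        se_phi = float(np.sqrt(grad_phi @ cov_bg @ grad_phi))
    else:
        se_amp = float(np.sqrt(np.trace(cov_bg) / 2.0))
        se_phi = float("inf")

    if ci_method == "ellipse":
        ci_amp, ci_phi = _elliptical_limits(
            beta, gamma, cov_bg, dof, level, w, period_h)
    else:
        ci_amp = (max(0.0, amplitude - tcrit * se_amp), amplitude + tcrit * se_amp)
        half = tcrit * se_phi
        if not math.isfinite(acrophase) or half >= period_h / 2.0:
            ci_phi = (0.0, period_h)  # the interval covers the whole cycle
        else:
            ci_phi = (np.mod(acrophase - half, period_h),
                      np.mod(acrophase + half, period_h))

    rel_pct, ci_rel = _relative_amplitude_from(mesor, amplitude, ci_amp)
    p_zero = _zero_amplitude_p(rss, rss0, dof, amplitude, warn=False)

    return CosinorFit(
        mesor=mesor, amplitude=amplitude, acrophase_h=acrophase,
        period_h=period_h, beta=beta, gamma=gamma, n=n, rss=rss, rss0=rss0,
        dof=dof, level=level, p_zero_amplitude=p_zero,
        se_mesor=se_mesor, se_amplitude=se_amp, se_acrophase_h=se_phi,
        ci_mesor=ci_mesor, ci_amplitude=ci_amp, ci_acrophase_h=ci_phi,
        rel_amplitude_pct=rel_pct, ci_rel_amplitude_pct=ci_rel,
        coef_cov=cov, ci_method=ci_method,
    )


def _elliptical_limits(beta, gamma, cov_bg, dof, level, w, period_h):
    """Amplitude/acrophase ranges over the joint confidence ellipse of (beta, gamma).

    The boundary of ``(b - bhat)' S^-1 (b - bhat) <= 2 F(level; 2, dof)`` is
    traced numerically; the projected polar ranges give conservative limits.
    An ellipse containing the origin leaves the acrophase unconstrained.
    """
    radius2 = 2.0 * stats.f.ppf(level, 2, dof)
    center = np.array([beta, gamma])
    L = np.linalg.cholesky(cov_bg)
    ang = np.linspace(0.0, 2.0 * np.pi, 3601)
    boundary = center[:, None] + math.sqrt(radius2) * (
        L @ np.vstack([np.cos(ang), np.sin(ang)]))
    amps = np.hypot(boundary[0], boundary[1])
    quad_at_origin = center @ np.linalg.solve(cov_bg, center)
    if quad_at_origin <= radius2:
        return (0.0, float(amps.max())), (0.0, period_h)
    theta_hat = math.atan2(gamma, beta)
    dev = np.angle(np.exp(1j * (np.arctan2(boundary[1], boundary[0]) - theta_hat)))
    lo = np.mod((theta_hat + dev.min()) / w, period_h)
    hi = np.mod((theta_hat + dev.max()) / w, period_h)
    return (float(amps.min()), float(amps.max())), (float(lo), float(hi))


def _zero_amplitude_p(rss, rss0, dof, amplitude, warn: bool) -> float:
    if rss0 == 0.0:
        return 1.0  # flat data: no variance to explain
    if rss <= 1e-12 * rss0:
        if amplitude > 0.0 and warn:
            warnings.warn(
                "residual sum of squares is numerically zero (perfect fit); "
                "zero-amplitude p-value reported as 0", PerfectFitWarning)
        return 0.0 if amplitude > 0.0 else 1.0
    f_stat = ((rss0 - rss) / 2.0) / (rss / dof)
    return float(stats.f.sf(f_stat, 2, dof))


def zero_amplitude_test(fit: CosinorFit) -> float:
    """F test of H0: amplitude = 0 (no 24-h rhythm).

    F = [(RSS0 - RSS)/2] / [RSS/(n-3)] with RSS0 the intercept-only
    residual sum of squares; p from F(2, n-3). A perfect fit (RSS = 0 with
    positive amplitude) reports p = 0 with a :class:`PerfectFitWarning`.
    """
    if fit.dof < 1:
        raise DegenerateDesignError("zero-amplitude test needs n - 3 >= 1")
    return _zero_amplitude_p(fit.rss, fit.rss0, fit.dof, fit.amplitude, warn=True)


def acrophase_to_zt_string(acrophase_h: float) -> str:
    """Format an acrophase as a ZT clock label, e.g. 13.583 -> ``"ZT13∶35"``.

    Minutes round to the nearest minute; 23.999 h wraps to ``ZT0∶00``.
    An undefined acrophase (NaN) yields the sentinel ``"ZT—"``.
    """
    if acrophase_h is None or not math.isfinite(acrophase_h):
        return "ZT—"
    if not 0.0 <= acrophase_h < 24.0:
        raise ValueError(f"acrophase_h must lie in [0, 24), got {acrophase_h}")
    minutes = round(acrophase_h * 60.0) % (24 * 60)
    return f"ZT{minutes // 60}{_ZT_SEPARATOR}{minutes % 60:02d}"


def _relative_amplitude_from(mesor, amplitude, ci_amplitude):
    if mesor <= 0:
        return float("nan"), (float("nan"), float("nan"))
    pct = 100.0 * amplitude / mesor
    lo, hi = ci_amplitude
    return pct, (100.0 * lo / mesor, 100.0 * hi / mesor)


def relative_amplitude(fit: CosinorFit):
    """Amplitude as percent of mesor, with confidence limits.

    The limits are the amplitude confidence limits divided by the mesor
    point estimate (mesor uncertainty is not propagated) — the simplest
    construction consistent with symmetric printed intervals.
    """
    if fit.mesor <= 0:
        raise UndefinedRatioError(
            f"relative amplitude undefined for mesor {fit.mesor} <= 0")
    return _relative_amplitude_from(fit.mesor, fit.amplitude, fit.ci_amplitude)


def predict(fit: CosinorFit, t_h):
    """Fitted value M + A*cos(w*(t - phi)); periodic in the fixed period."""
    t = np.asarray(t_h, dtype=float)
    if not fit.acrophase_defined:
        out = np.full_like(t, fit.mesor, dtype=float)
        return float(out) if np.isscalar(t_h) else out
    w = 2.0 * np.pi / fit.period_h
    out = fit.mesor + fit.amplitude * np.cos(w * (t - fit.acrophase_h))
    return float(out) if np.isscalar(t_h) else out
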
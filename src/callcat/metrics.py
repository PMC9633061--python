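"""Signal-detection, psychometric and model-behavior comparison statistics.

d' is the difference of standard-normal quantiles of hit and false-alarm
rates, with a floor of 0.01 and a ceiling of 0.99 imposed on both rates
before the transform (so an error-free classifier tops out at d' = 4.65).
Psychometric curves are Weibull-based with a lapse term and a free
amplitude so they can be fitted directly to d' data.  Trialwise effects are
assessed by likelihood-ratio tests between nested logistic models, with
the subject effect approximated by per-subject intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RateSummary",
    "PsychometricFit",
    "TrialModelResult",
    "dprime",
    "weibull_psychometric",
    "fit_psychometric",
    "model_behavior_agreement",
    "trialwise_lrt",
    "catch_trial_summary",
    "DPRIME_CEILING",
]

RATE_FLOOR = 0.01
RATE_CEILING = 0.99
DPRIME_CEILING = float(stats.norm.ppf(RATE_CEILING) - stats.norm.ppf(RATE_FLOOR))


@dataclass
class RateSummary:
    n_go_trials: int
    n_nogo_trials: int
    hits: int
    false_alarms: int
    floor: float = RATE_FLOOR
    ceiling: float = RATE_CEILING

    def __post_init__(self) -> None:
        if self.hits > self.n_go_trials or self.false_alarms > self.n_nogo_trials:
            raise ValueError("counts exceed trial totals")

    @property
    def hit_rate(self) -> float:
        if self.n_go_trials == 0:
            raise ValueError("no Go trials")
        return float(np.clip(self.hits / self.n_go_trials, self.floor, self.ceiling))

    @property
    def fa_rate(self) -> float:
        if self.n_nogo_trials == 0:
            raise ValueError("no No-go trials")
        return float(np.clip(self.false_alarms / self.n_nogo_trials, self.floor, self.ceiling))


def dprime(summary: RateSummary) -> float:
    """Sensitivity index: z(hit rate) - z(FA rate), rates clamped first."""
    return float(stats.norm.ppf(summary.hit_rate) - stats.norm.ppf(summary.fa_rate))


# ---------------------------------------------------------------------------
# psychometric fitting

def weibull_psychometric(x, alpha, beta, lam, amplitude=1.0):
    """amplitude * (1 - lam) * (1 - exp(-(x/alpha)^beta)) for x > 0."""
    x = np.asarray(x, dtype=float)
    return amplitude * (1 - lam) * (1 - np.exp(-np.power(x / alpha, beta)))


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    lam: float
    amplitude: float
    threshold_at_dprime1: float
    threshold_extrapolated: bool
    x_offset: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, levels) -> np.ndarray:
        x = np.asarray(levels, dtype=float) + self.x_offset
        return weibull_psychometric(x, self.alpha, self.beta, self.lam, self.amplitude)


def fit_psychometric(
    levels: Sequence[float],
    values: Sequence[float],
    fit_amplitude: bool = True,
) -> PsychometricFit:
    """Nonlinear least-squares fit of a lapse-rate Weibull to performance
    data (Go proportions or d' values; the free amplitude accommodates the
    d' scale).

    Levels need not be positive: non-positive stimulus axes (e.g. SNR in
    dB) are shifted internally by a recorded offset, and the d'=1 threshold
    is reported in the original units.  The threshold is flagged when it
    falls outside the tested level range.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 levels")
    order = np.argsort(x)
    x, y = x[order], y[order]
    offset = 0.0
    if x.min() <= 0:
        offset = -x.min() + 0.1 * (np.ptp(x) if np.ptp(x) > 0 else 1.0)
    xs = x + offset

    ymax = max(y.max(), 1e-6)

    def model(xv, alpha, beta, lam, amp):
        return weibull_psychometric(xv, alpha, beta, lam, amp)

    p0 = [np.median(xs), 2.0, 0.02, ymax if fit_amplitude else 1.0]
    bounds = (
        [1e-9, 1e-9, 0.0, (1e-9 if fit_amplitude else 1.0 - 1e-12)],
        [np.inf, np.inf, 1 - 1e-9, (np.inf if fit_amplitude else 1.0 + 1e-12)],
    )
    try:
        popt, _ = optimize.curve_fit(model, xs, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(
            f"psychometric fit did not converge: {e}; residuals at p0 = "
            f"{y - model(xs, *p0)}"
        ) from e
    alpha, beta, lam, amp = map(float, popt)

    # level at which the fitted curve crosses d' (or proportion) = 1
    ceil = amp * (1 - lam)
    if ceil <= 1.0:
        thr_shifted = float("inf")
    else:
        thr_shifted = alpha * (-np.log(1 - 1 / ceil)) ** (1 / beta)
    threshold = thr_shifted - offset
    extrapolated = not (x.min() <= threshold <= x.max())
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        lam=lam,
        amplitude=amp,
        threshold_at_dprime1=threshold,
        threshold_extrapolated=extrapolated,
        x_offset=offset,
        residuals=y - model(xs, alpha, beta, lam, amp),
    )


def model_behavior_agreement(
    d_model: Sequence[float], d_behavior: Sequence[float]
) -> tuple[float, float]:
    """R^2 of the least-squares line of model d' on behavioral d', and the
    mean absolute error between the raw vectors."""
    m = np.asarray(d_model, float)
    b = np.asarray(d_behavior, float)
    if m.size != b.size or m.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.var(b) == 0:
        raise ValueError("behavior vector has zero variance; R^2 undefined")
    res = stats.linregress(b, m)
    return float(res.rvalue**2), float(np.mean(np.abs(m - b)))


# ---------------------------------------------------------------------------
# trialwise logistic models

@dataclass
class TrialModelResult:
    coefficients: dict[str, float]
    loglik_full: float
    loglik_null: float
    chi2: float
    df: int
    p: float


def trialwise_lrt(
    trials: pd.DataFrame,
    full_formula: str,
    null_formula: str,
) -> TrialModelResult:
    """Likelihood-ratio test between nested trialwise logistic models.

    ``trials`` needs a binary response column plus the predictors named in
    the formulas (patsy syntax).  The subject effect is modelled as
    per-subject fixed intercepts, e.g. ``response ~ stimulus_type + value +
    stimulus_type:value + C(subject)`` vs ``response ~ stimulus_type +
    C(subject)``; degrees of freedom are the parameter-count difference.
    """
    import statsmodels.formula.api as smf

    full = smf.logit(full_formula, data=trials).fit(disp=0, maxiter=200)
    null = smf.logit(null_formula, data=trials).fit(disp=0, maxiter=200)
    if not (full.mle_retvals.get("converged", True) and null.mle_retvals.get("converged", True)):
        raise RuntimeError("logistic fit failed to converge (separation or degenerate design?)")
    df = int(full.df_model - null.df_model)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return TrialModelResult(
        coefficients=dict(full.params),
        loglik_full=float(full.llf),
        loglik_null=float(null.llf),
        chi2=float(chi2),
        df=df,
        p=p,
    )


def catch_trial_summary(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Go rates per (syllable category, regular/chimeric) cell plus a paired
    t-test of regular vs chimeric Go rates across subjects.

    ``trials`` columns: subject, category (syllable identity), is_catch
    (bool), response ('go'/'nogo').
    """
    t = trials.copy()
    t["go"] = (t["response"] == "go").astype(float)
    t["condition"] = np.where(t["is_catch"], "chimeric", "regular")
    cells = (
        t.groupby(["category", "condition", "subject"])["go"].mean().reset_index(name="go_rate")
    )
    if cells.groupby(["category", "condition"]).size().min() == 0:
        raise ValueError("empty cell in catch-trial design")
    wide = cells.pivot_table(
        index=["category", "subject"], columns="condition", values="go_rate"
    ).dropna()
    if len(wide) < 2:
        raise ValueError("paired comparison needs >= 2 subject cells")
    a, b = wide["regular"].to_numpy(), wide["chimeric"].to_numpy()
    if np.allclose(a, b):
        test = {"t": float("nan"), "p": float("nan"), "identical": True}
    else:
        res = stats.ttest_rel(a, b)
        test = {"t": float(res.statistic), "p": float(res.pvalue), "identical": False}
    summary = cells.groupby(["category", "condition"])["go_rate"].mean().reset_index()
    return summary, test
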
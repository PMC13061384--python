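"""Observed-vs-expected logit additivity test for enzyme inhibition.

The dose-equivalence route to testing Loewe additivity of a binary
mixture on AChE inhibition:

1. fit log-logit regression lines to each single agent,
   ``Y = Y0 + b * log10(C)`` with ``Y = logit(I/100)`` and I the percent
   inhibition (natural-log logits; inhibition clipped to [0.5, 99.5]%
   before the transform, clip events counted);
2. convert each tested concentration of agent A into the equivalent
   concentration of agent B -- the concentration of B producing the same
   logit inhibition;
3. the expected mixture inhibition at (cA, cB) is agent B's line
   evaluated at the summed concentration,
   ``X = log10(equiv_B(cA) + cB)``, ``Y_expected = Y0_B + b_B * X``;
4. regress the observed logit inhibition on the expected values (per-
   concentration medians by default) and test the slope against the
   additive expectation of 1.0 with a coefficient t-test.

Under concentration addition with parallel single-agent lines the
observed and expected logits agree and the slope converges to 1.  The
test's power against departures comes from shape changes of the observed
curve over the tested range; a pure potency shift moves the intercept,
not the slope, unless the inhibition scale saturates within the range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogitLine",
    "SlopeTestResult",
    "LogitEquivalenceModel",
    "LogitEquivalenceResults",
    "logit_inhibition",
    "fit_logit_line",
    "line_from_log_logistic",
    "equivalent_concentration",
    "expected_inhibition",
    "slope_test",
]

DEFAULT_CLIP = (0.5, 99.5)  # percent inhibition bounds before the logit


def logit_inhibition(percent_inhibition, clip: tuple = DEFAULT_CLIP):
    """Natural-log logit of the inhibition fraction, with clipping.

    Returns ``(logits, n_clipped_low, n_clipped_high)``.
    """
    i = np.asarray(percent_inhibition, dtype=float)
    lo, hi = clip
    n_lo = int(np.sum(i < lo))
    n_hi = int(np.sum(i > hi))
    q = np.clip(i, lo, hi) / 100.0
    return np.log(q / (1.0 - q)), n_lo, n_hi


@dataclass(frozen=True)
class LogitLine:
    """Log-logit regression line of one agent: Y = intercept + slope*log10(C)."""

    agent: str
    intercept: float
    slope: float
    n: int
    residual_se: float
    n_clipped_low: int = 0
    n_clipped_high: int = 0
    clip: tuple = DEFAULT_CLIP

    def predict(self, concentration):
        c = np.asarray(concentration, dtype=float)
        return self.intercept + self.slope * np.log10(c)


def fit_logit_line(
    concentration,
    percent_activity,
    agent: str = "",
    clip: tuple = DEFAULT_CLIP,
) -> LogitLine:
    """OLS of logit inhibition on log10 concentration for a single agent.

    ``percent_activity`` is percent of solvent control; inhibition is
    100 - activity.  Requires at least 3 distinct positive
    concentrations; rejects data where every point clips on the same
    side (an uninformative flat series).
    """
    import statsmodels.api as sm

    c = np.asarray(concentration, dtype=float)
    a = np.asarray(percent_activity, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValueError("concentration and activity must be 1-D and aligned")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    y, n_lo, n_hi = logit_inhibition(100.0 - a, clip)
    if n_lo == c.size or n_hi == c.size:
        raise ValueError("all points clipped on the same side; line is uninformative")
    X = sm.add_constant(np.log10(c))
    res = sm.OLS(y, X).fit()
    return LogitLine(
        agent=agent,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=int(c.size),
        residual_se=float(np.sqrt(res.scale)),
        n_clipped_low=n_lo,
        n_clipped_high=n_hi,
        clip=clip,
    )


def line_from_log_logistic(ic50: float, hill: float, agent: str = "") -> LogitLine:
    """Exact logit line of a log-logistic inhibition curve.

    For activity 100/(1 + (C/IC50)^h) the natural-log logit of the
    inhibition fraction is exactly linear in log10 C:

        logit(I/100) = h*ln(10) * (log10 C - log10 IC50)

    so the slope is h*ln(10) and the intercept -h*ln(10)*log10(IC50).
    Useful as ground truth for simulation and as an oracle for
    :func:`fit_logit_line` on noiseless data.
    """
    if ic50 <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill slope must be positive")
    b = hill * math.log(10.0)
    return LogitLine(
        agent=agent,
        intercept=-b * math.log10(ic50),
        slope=b,
        n=0,
        residual_se=0.0,
    )


def equivalent_concentration(c_a, line_a: LogitLine, line_b: LogitLine):
    """Concentration of agent B with the same logit inhibition as ``c_a`` of A.

        equiv = 10 ** ((Y_A(c_a) - Y0_B) / b_B)
    """
    if line_b.slope == 0:
        raise ValueError("agent B line has zero slope; equivalence undefined")
    c = np.asarray(c_a, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    y_a = line_a.predict(c)
    out = 10.0 ** ((y_a - line_b.intercept) / line_b.slope)
    return float(out) if out.shape == () else out


def expected_inhibition(c_a, c_b, line_a: LogitLine, line_b: LogitLine):
    """Expected mixture logit inhibition at component concentrations (cA, cB).

    ``c_a`` may contain zeros (degenerate mixture reduces to agent B).
    """
    ca = np.asarray(c_a, dtype=float)
    cb = np.asarray(c_b, dtype=float)
    ca, cb = np.broadcast_arrays(ca, cb)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("concentrations must be non-negative")
    equiv = np.zeros(ca.shape)
    pos = ca > 0
    if np.any(pos):
        equiv[pos] = equivalent_concentration(ca[pos], line_a, line_b)
    total = equiv + cb
    if np.any(total <= 0):
        raise ValueError("summed mixture concentration must be positive")
    y = line_b.intercept + line_b.slope * np.log10(total)
    return float(y) if y.shape == () else y


@dataclass(frozen=True)
class SlopeTestResult:
    """Coefficient t-test of the observed-vs-expected slope against 1.0."""

    slope: float
    slope_se: float
    intercept: float
    p_value: float
    n_points: int
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def reject_at_alpha(self) -> bool:
        return self.p_value < self.alpha


def slope_test(
    observed,
    expected,
    concentrations=None,
    use_medians: bool = True,
    alpha: float = 0.05,
    null_slope: float = 1.0,
) -> SlopeTestResult:
    """OLS of observed on expected logit inhibition; t-test of slope vs 1.

    With ``use_medians`` (default, matching the median-per-concentration
    analysis) and ``concentrations`` given, replicate observations are
    reduced to their per-concentration medians (of both observed and
    expected) before the regression.  A perfect linear fit (zero
    residual) returns the exact slope with ``degenerate=True`` and
    p-value 1 rather than raising.
    """
    obs = np.asarray(observed, dtype=float)
    exp_ = np.asarray(expected, dtype=float)
    if obs.shape != exp_.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D and aligned")
    if use_medians and concentrations is not None:
        df = pd.DataFrame(
            {"c": np.asarray(concentrations, dtype=float), "o": obs, "e": exp_}
        )
        med = df.groupby("c", as_index=False).median().sort_values("c")
        obs, exp_ = med["o"].to_numpy(), med["e"].to_numpy()
    n = obs.size
    if np.unique(exp_).size < 2:
        raise ValueError("expected values have zero variance; slope undefined")
    if n < 3:
        raise ValueError("need at least 3 points (distinct concentrations)")

    xbar, ybar = exp_.mean(), obs.mean()
    sxx = float(np.sum((exp_ - xbar) ** 2))
    slope = float(np.sum((exp_ - xbar) * (obs - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = obs - (intercept + slope * exp_)
    rss = float(np.sum(resid**2))
    dof = n - 2
    scale = max(np.mean(obs**2), 1.0)
    if rss <= 1e-24 * scale * n:
        return SlopeTestResult(slope, 0.0, intercept, 1.0, n, alpha, degenerate=True)
    se = math.sqrt(rss / dof / sxx)
    t = (slope - null_slope) / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return SlopeTestResult(slope, se, intercept, float(p), n, alpha)


class LogitEquivalenceModel:
    """End-to-end logit-equivalence additivity analysis of one mixture.

    Parameters
    ----------
    single_a, single_b : DataFrames with columns ``concentration_uM`` and
        ``percent_activity`` for each agent alone.
    mixture : DataFrame with the same columns for the mixture, where
        ``concentration_uM`` is the *total* mixture concentration.
    fractions : (f_a, f_b) of the total mixture, summing to 1.
    agents : names used in the report.
    """

    def __init__(
        self,
        single_a: pd.DataFrame,
        single_b: pd.DataFrame,
        mixture: pd.DataFrame,
        fractions: tuple = (0.5, 0.5),
        agents: tuple = ("A", "B"),
        clip: tuple = DEFAULT_CLIP,
    ):
        if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
            raise ValueError("fractions must be positive and sum to 1")
        self.single_a = single_a
        self.single_b = single_b
        self.mixture = mixture
        self.fractions = tuple(float(f) for f in fractions)
        self.agents = agents
        self.clip = clip

    def fit(self, alpha: float = 0.05, use_medians: bool = True):
        line_a = fit_logit_line(
            self.single_a["concentration_uM"],
            self.single_a["percent_activity"],
            agent=self.agents[0],
            clip=self.clip,
        )
        line_b = fit_logit_line(
            self.single_b["concentration_uM"],
            self.single_b["percent_activity"],
            agent=self.agents[1],
            clip=self.clip,
        )
        c_total = self.mixture["concentration_uM"].to_numpy(float)
        f_a, f_b = self.fractions
        expected = expected_inhibition(f_a * c_total, f_b * c_total, line_a, line_b)
        observed, _, _ = logit_inhibition(
            100.0 - self.mixture["percent_activity"].to_numpy(float), self.clip
        )
        test = slope_test(
            observed, expected, concentrations=c_total,
            use_medians=use_medians, alpha=alpha,
        )
        points = pd.DataFrame(
            {
                "concentration_total_uM": c_total,
                "observed_logit": observed,
                "expected_logit": expected,
            }
        )
        return LogitEquivalenceResults(self, line_a, line_b, points, test)


class LogitEquivalenceResults:
    def __init__(self, model, line_a, line_b, points, test: SlopeTestResult):
        self.model = model
        self.line_a = line_a
        self.line_b = line_b
        self.points = points
        self.slope_test = test

    def summary(self) -> str:
        t = self.slope_test
        a, b = self.model.agents
        lines = [
            "Logit-equivalence additivity test (natural-log logits, clip "
            f"{self.model.clip[0]}-{self.model.clip[1]}% inhibition)",
            "=" * 66,
            f"line {a}: Y = {self.line_a.intercept:+.4f} "
            f"{self.line_a.slope:+.4f}*log10(C)   (n={self.line_a.n})",
            f"line {b}: Y = {self.line_b.intercept:+.4f} "
            f"{self.line_b.slope:+.4f}*log10(C)   (n={self.line_b.n})",
            f"slope (observed ~ expected): {t.slope:.4f}  SE {t.slope_se:.4f}",
            f"H0 slope = 1.0: p = {t.p_value:.4g}"
            + ("  [degenerate perfect fit]" if t.degenerate else ""),
            f"reject at alpha={t.alpha}: {t.reject_at_alpha}",
        ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        t = self.slope_test
        return {
            "agents": list(self.model.agents),
            "fractions": list(self.model.fractions),
            "clip_pct": list(self.model.clip),
            "logit_base": "natural",
            "lines": {
                self.model.agents[0]: {
                    "intercept": self.line_a.intercept,
                    "slope": self.line_a.slope,
                    "n": self.line_a.n,
                    "n_clipped": [self.line_a.n_clipped_low, self.line_a.n_clipped_high],
                },
                self.model.agents[1]: {
                    "intercept": self.line_b.intercept,
                    "slope": self.line_b.slope,
                    "n": self.line_b.n,
                    "n_clipped": [self.line_b.n_clipped_low, self.line_b.n_clipped_high],
                },
            },
            "slope": t.slope,
            "slope_se": t.slope_se,
            "p_value": t.p_value,
            "n_points": t.n_points,
            "alpha": t.alpha,
            "reject_at_alpha": t.reject_at_alpha,
            "degenerate": t.degenerate,
        }
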
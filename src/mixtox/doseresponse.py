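"""Log-logistic inhibition curve fitting for AChE activity data.

The model is the two-parameter log-logistic with the asymptotes fixed at
0 and 100 percent of solvent-control activity:

    activity(C) = 100 / (1 + (C / IC50)^h)

so that percent inhibition is I(C) = 100 - activity(C), I(IC50) = 50.
Only the IC50 and the Hill slope h are fitted.  Effect-level
concentrations follow in closed form:

    ICp = IC50 * (p / (100 - p))^(1/h).

Fitting is nonlinear least squares on (log IC50, log h), which enforces
positivity without bounds, multi-started from a grid of log-spaced IC50
seeds over the tested range.  Standard errors come from the local
curvature (Gauss-Newton J'J) of the objective at the optimum.  Activities
outside [0, 100] are retained: the asymptotes are fixed, so clipping
would only bias the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LogLogisticInhibition",
    "LogLogisticResults",
    "EffectLevel",
    "effect_level",
    "log_logistic_activity",
]


def log_logistic_activity(c, ic50: float, hill: float):
    """Percent activity at concentration(s) ``c`` (fixed 0/100 asymptotes)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, c / ic50, 0.0)
        act = 100.0 / (1.0 + ratio**hill)
    return np.where(c > 0, act, 100.0)


@dataclass(frozen=True)
class EffectLevel:
    """Concentration ``icp`` producing ``p`` percent inhibition."""

    p: float
    icp: float


def effect_level(fit, p: float) -> EffectLevel:
    """ICp from a fitted curve (or an ``(ic50, hill)`` pair).

    ``effect_level(fit, 50)`` returns the IC50 exactly.
    """
    if not 0 < p < 100:
        raise ValueError(f"effect level p must be in (0, 100), got {p}")
    if hasattr(fit, "ic50"):
        if not fit.converged:
            raise ValueError("effect levels require a converged fit")
        ic50, hill = fit.ic50, fit.hill
    else:
        ic50, hill = fit
    return EffectLevel(p, float(ic50) * (p / (100.0 - p)) ** (1.0 / float(hill)))


class LogLogisticInhibition:
    """Two-parameter log-logistic inhibition model of percent activity.

    Parameters
    ----------
    concentration : array-like of positive concentrations (uM).  At least
        4 distinct values are required.  Zero-concentration rows (solvent
        controls) are the normalisation reference, not curve data, and are
        rejected.
    activity : array-like, percent of solvent control (may fall outside
        [0, 100]; values are used as-is).
    aggregate : {'replicates', 'means'}
        'replicates' (default) fits every observation; 'means' fits the
        per-concentration means, mirroring summary-level fitting.
    """

    def __init__(self, concentration, activity, aggregate: str = "replicates"):
        c = np.asarray(concentration, dtype=float)
        y = np.asarray(activity, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentration and activity must be 1-D and aligned")
        if np.any(~np.isfinite(c)) or np.any(~np.isfinite(y)):
            raise ValueError("non-finite values in input")
        if np.any(c <= 0):
            raise ValueError(
                "concentrations must be strictly positive (controls enter only "
                "through the percent-of-control normalisation)"
            )
        if np.unique(c).size < 4:
            raise ValueError("need at least 4 distinct positive concentrations")
        if aggregate not in ("replicates", "means"):
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        if aggregate == "means":
            df = pd.DataFrame({"c": c, "y": y}).groupby("c", as_index=False).mean()
            c, y = df["c"].to_numpy(), df["y"].to_numpy()
        self.concentration = c
        self.activity = y
        self.aggregate = aggregate

    @classmethod
    def from_records(
        cls,
        data: pd.DataFrame,
        concentration: str = "concentration_uM",
        activity: str = "percent_activity",
        condition: str | None = None,
        **kwargs,
    ) -> "LogLogisticInhibition":
        """Build the model from a long-format activity table.

        ``condition`` restricts to one condition when the table holds
        several.  Zero-concentration (control) rows are dropped.
        """
        df = data
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df[df[concentration] > 0]
        return cls(df[concentration].to_numpy(), df[activity].to_numpy(), **kwargs)

    def fit(self, n_starts: int = 5) -> "LogLogisticResults":
        c, y = self.concentration, self.activity
        n = y.size

        if np.allclose(y, y[0]):
            # flat data: the IC50 is unidentifiable
            return LogLogisticResults(self, np.nan, np.nan, np.nan, np.nan, False)

        def resid(theta):
            ic50, hill = np.exp(theta)
            return y - log_logistic_activity(c, ic50, hill)

        starts = np.geomspace(c.min(), c.max(), n_starts)
        best = None
        for s in starts:
            try:
                sol = optimize.least_squares(resid, x0=[np.log(s), 0.0], method="lm")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            return LogLogisticResults(self, np.nan, np.nan, np.nan, np.nan, False)

        ic50, hill = np.exp(best.x)
        # an IC50 wildly outside the tested range means the optimiser ran
        # to a boundary: report non-convergence rather than extrapolate
        in_range = c.min() / 1e4 < ic50 < c.max() * 1e4
        converged = bool(best.success and in_range and hill > 0)

        dof = max(n - 2, 1)
        rss = 2.0 * best.cost
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            se_log = np.sqrt(np.diag(cov))
            ic50_se = ic50 * se_log[0]  # delta method from log scale
            hill_se = hill * se_log[1]
        except np.linalg.LinAlgError:
            ic50_se = hill_se = np.nan
            converged = False
        if converged and not (np.isfinite(ic50_se) and np.isfinite(hill_se)):
            converged = False
        return LogLogisticResults(
            self, float(ic50), float(hill), float(ic50_se), float(hill_se), converged
        )


class LogLogisticResults:
    """Fit results: IC50, Hill slope, their standard errors and diagnostics."""

    lower_limit = 0.0
    upper_limit = 100.0

    def __init__(self, model, ic50, hill, ic50_se, hill_se, converged):
        self.model = model
        self.ic50 = ic50
        self.hill = hill
        self.ic50_se = ic50_se
        self.hill_se = hill_se
        self.converged = converged
        self.nobs = model.activity.size
        self.df_resid = self.nobs - 2
        if converged:
            r = model.activity - self.predict(model.concentration)
            self.residual_sd = float(np.sqrt(np.sum(r**2) / max(self.df_resid, 1)))
        else:
            self.residual_sd = np.nan

    def predict(self, c):
        """Fitted percent activity at concentration(s) ``c``."""
        return log_logistic_activity(c, self.ic50, self.hill)

    def inhibition(self, c):
        """Fitted percent inhibition, 100 - activity."""
        return 100.0 - self.predict(c)

    def icp(self, p: float) -> float:
        """Concentration producing ``p`` percent inhibition."""
        return effect_level(self, p).icp

    def summary(self) -> str:
        lines = [
            "Log-logistic inhibition fit (asymptotes fixed at 0/100 %)",
            "=" * 58,
            f"{'n obs':<22}{self.nobs:>12}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'IC50 (uM)':<22}{self.ic50:>12.5g}  (SE {self.ic50_se:.3g})",
            f"{'Hill slope':<22}{self.hill:>12.5g}  (SE {self.hill_se:.3g})",
            f"{'residual SD (%)':<22}{self.residual_sd:>12.4g}",
        ]
        return "\n".join(lines)

    def to_row(self, condition: str = "") -> dict:
        """One tidy row for a fits table (CSV export)."""
        return {
            "condition": condition,
            "ic50_uM": self.ic50,
            "ic50_se_uM": self.ic50_se,
            "hill": self.hill,
            "hill_se": self.hill_se,
            "n_obs": self.nobs,
            "residual_sd_pct": self.residual_sd,
            "converged": self.converged,
        }
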
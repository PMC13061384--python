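"""Loewe concentration-addition (CA) predictions for binary mixtures.

Under Loewe additivity two chemicals behave as dilutions of one another:
at every effect level the component concentrations lie on a linear
isobole,

    C1 / EC1(E) + C2 / EC2(E) = 1,

where ``ECi(E)`` is the concentration of component *i* alone that produces
effect *E*.  For an equimolar binary mixture reported as per-component
concentration this gives the harmonic-mean prediction

    EC_mix = 1 / (1/EC1 + 1/EC2)        (per component)

and, written with the relative potency factor RPF2 = EC1/EC2,

    EC_mix = EC1 / (1 + RPF2).

For arbitrary mixing fractions f1 + f2 = 1 of the *total* mixture
concentration the analogous statement is

    EC_mix_total = 1 / (f1/EC1 + f2/EC2).

This module implements those closed forms for benchmark concentrations
(BMCs) and inhibitory concentrations (ICp), interval propagation through
them, predicted mixture inhibition curves, and the brute-force numeric
isobole solvers used both as simulation machinery and as independent
cross-checks of the algebra.

Conventions
-----------
* BMC-level functions work in per-component concentration (the screen
  reports mixtures by the concentration of each component); ``*_total``
  attributes give the corresponding total concentration (2x for
  equimolar).
* ICp-level functions (fractions ``f1``, ``f2``) work in total mixture
  concentration.
* Predictions above the concentration cap (default 10 uM, the top of the
  tested range) are flagged ``capped`` and treated as "no predicted
  effect" downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CAPrediction",
    "relative_potency",
    "predict_mixture_bmc",
    "predict_interval",
    "predict_mixture_icp",
    "predicted_curve",
    "isobole_inhibition",
    "loewe_mixture_response",
    "solve_equimolar_bmc_numeric",
    "solve_total_icp_numeric",
]

DEFAULT_CAP_UM = 10.0


def _is_active(x) -> bool:
    """An estimate counts as active when it is a finite positive number.

    ``None``, NaN and +inf all encode "no benchmark crossing / inactive"
    (an inactive component has, in the CA sense, an infinite BMC).
    """
    if x is None:
        return False
    x = float(x)
    return math.isfinite(x) and x > 0


def _check_positive(name: str, x) -> float:
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"{name} must be a finite positive concentration, got {x!r}")
    return x


@dataclass(frozen=True)
class CAPrediction:
    """A Loewe CA prediction for one readout of a binary mixture.

    Attributes
    ----------
    bmc_mix : float or None
        Predicted mixture potency in per-component uM; ``None`` when both
        components are inactive.
    rpf2 : float or None
        Relative potency factor BMC1/BMC2 (only when both inputs active).
    capped : bool
        True when the prediction exceeded ``cap`` uM; the numeric value is
        retained but the prediction is treated as no predicted effect.
    interval_lb, interval_ub : float or None
        Prediction interval obtained by pushing the single-agent interval
        bounds through the CA formula.
    inputs : tuple
        The (bmc1, bmc2) the prediction was built from, for provenance.
    """

    bmc_mix: float | None
    rpf2: float | None = None
    capped: bool = False
    cap: float = DEFAULT_CAP_UM
    interval_lb: float | None = None
    interval_ub: float | None = None
    inputs: tuple = field(default=())

    @property
    def bmc_mix_total(self) -> float | None:
        """Total-mixture concentration (2x per-component for equimolar)."""
        return None if self.bmc_mix is None else 2.0 * self.bmc_mix

    @property
    def active(self) -> bool:
        """Whether the model predicts an effect within the tested range."""
        return _is_active(self.bmc_mix) and not self.capped

    @property
    def interval(self) -> tuple[float | None, float | None]:
        return (self.interval_lb, self.interval_ub)


def relative_potency(bmc1, bmc2) -> float:
    """Relative potency factor of component 2: RPF2 = BMC1/BMC2."""
    b1 = _check_positive("bmc1", bmc1)
    b2 = _check_positive("bmc2", bmc2)
    return b1 / b2


def predict_mixture_bmc(bmc1, bmc2, cap: float = DEFAULT_CAP_UM) -> CAPrediction:
    """Predict the equimolar-mixture BMC (per component) under Loewe CA.

    Both components active: harmonic form ``1/(1/BMC1 + 1/BMC2)``.  One
    component inactive (None/NaN/inf): its BMC is treated as infinite, so
    the prediction equals the active component's BMC.  Both inactive: no
    predicted effect.  Predictions above ``cap`` are flagged and treated
    as no predicted effect.
    """
    active1, active2 = _is_active(bmc1), _is_active(bmc2)
    for name, v, act in (("bmc1", bmc1, active1), ("bmc2", bmc2, active2)):
        if v is not None and math.isfinite(float(v)) and float(v) <= 0:
            raise ValueError(f"{name} must be positive when finite, got {v!r}")
    if not active1 and not active2:
        return CAPrediction(None, None, False, cap, inputs=(bmc1, bmc2))
    if active1 and active2:
        value = 1.0 / (1.0 / float(bmc1) + 1.0 / float(bmc2))
        rpf2 = float(bmc1) / float(bmc2)
    else:
        value = float(bmc1) if active1 else float(bmc2)
        rpf2 = None
    return CAPrediction(value, rpf2, capped=value > cap, cap=cap, inputs=(bmc1, bmc2))


def _interval_of(estimate) -> tuple:
    """Extract (median, lb, ub, active) from a BMCEstimate-like object or tuple."""
    if hasattr(estimate, "bmc_median"):
        med, lb, ub = estimate.bmc_median, estimate.bmc_lb, estimate.bmc_ub
        act = bool(getattr(estimate, "active", _is_active(med)))
    else:
        med, lb, ub = estimate
        act = _is_active(med)
    if act and _is_active(lb) and _is_active(ub):
        if not (float(lb) <= float(med) <= float(ub)):
            raise ValueError(
                f"inverted interval: lb={lb!r}, median={med!r}, ub={ub!r}"
            )
    return med, lb, ub, act


def predict_interval(estimate1, estimate2, cap: float = DEFAULT_CAP_UM) -> CAPrediction:
    """CA point prediction with a propagated interval.

    The interval is formed by applying :func:`predict_mixture_bmc` to the
    pair of lower bounds and the pair of upper bounds, with the
    infinite-BMC rule applied coordinate-wise.  Because the harmonic form
    is monotone increasing in each argument the result contains the point
    prediction.

    Parameters accept :class:`mixtox.bmc.BMCEstimate` objects or plain
    ``(median, lb, ub)`` tuples (``None``/NaN marking inactive).
    """
    med1, lb1, ub1, act1 = _interval_of(estimate1)
    med2, lb2, ub2, act2 = _interval_of(estimate2)
    point = predict_mixture_bmc(med1 if act1 else None, med2 if act2 else None, cap=cap)
    if not (act1 or act2):
        return point
    lo = predict_mixture_bmc(lb1 if act1 else None, lb2 if act2 else None, cap=cap)
    hi = predict_mixture_bmc(ub1 if act1 else None, ub2 if act2 else None, cap=cap)
    return CAPrediction(
        point.bmc_mix,
        point.rpf2,
        capped=point.capped,
        cap=cap,
        interval_lb=lo.bmc_mix,
        interval_ub=hi.bmc_mix,
        inputs=((med1, lb1, ub1), (med2, lb2, ub2)),
    )


def _icp_of(fit, p: float) -> float:
    """Effect-level concentration from a fitted curve or an (ic50, hill) pair."""
    if hasattr(fit, "icp"):
        return float(fit.icp(p))
    ic50, hill = fit
    return float(ic50) * (p / (100.0 - p)) ** (1.0 / float(hill))


def _check_fractions(f1: float, f2: float) -> tuple[float, float]:
    f1, f2 = float(f1), float(f2)
    if f1 <= 0 or f2 <= 0 or abs(f1 + f2 - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {f1}, {f2}")
    return f1, f2


def predict_mixture_icp(
    fit1, fit2, p: float = 50.0, f1: float = 0.5, f2: float = 0.5
) -> float:
    """Total-mixture ICp under CA for mixing fractions (f1, f2).

        ICp_mix_total = 1 / (f1/ICp1 + f2/ICp2)

    ``fit1``/``fit2`` may be fitted dose-response results (anything with
    an ``icp(p)`` method) or plain ``(ic50, hill)`` tuples.  With
    ``f1 = f2 = 0.5`` this equals twice the per-component equimolar
    prediction of :func:`predict_mixture_bmc`.
    """
    if not 0 < p < 100:
        raise ValueError(f"effect level p must be in (0, 100), got {p}")
    f1, f2 = _check_fractions(f1, f2)
    icp1 = _check_positive("ICp1", _icp_of(fit1, p))
    icp2 = _check_positive("ICp2", _icp_of(fit2, p))
    return 1.0 / (f1 / icp1 + f2 / icp2)


def predicted_curve(
    fit1,
    fit2,
    f1: float = 0.5,
    f2: float = 0.5,
    effect_levels: Sequence[float] | None = None,
    method: str = "per_level",
) -> pd.DataFrame:
    """Predicted mixture inhibition curve as (effect level, concentration) pairs.

    Parameters
    ----------
    effect_levels : sequence of percent inhibition values in (0, 100); at
        least 5 points (default 5..95 in steps of 5).
    method : {'per_level', 'fixed_rpf'}
        ``per_level`` recomputes the CA combination at every effect level
        from the individual ICp values -- the exact isobole solution for
        any Hill slopes.  ``fixed_rpf`` is the equal-slope shortcut that
        fixes the relative potency at its IC50 value and scales component
        1's curve; it coincides with ``per_level`` at p = 50 and exactly
        everywhere when the Hill slopes are equal.

    Returns a DataFrame with columns ``p`` (percent inhibition) and
    ``c_total_uM`` (total mixture concentration), monotone in both.
    """
    if effect_levels is None:
        effect_levels = np.arange(5.0, 96.0, 5.0)
    effect_levels = np.asarray(list(effect_levels), dtype=float)
    if effect_levels.size < 5:
        raise ValueError("effect grid needs at least 5 points")
    if np.any((effect_levels <= 0) | (effect_levels >= 100)):
        raise ValueError("effect levels must lie strictly inside (0, 100)")
    effect_levels = np.sort(effect_levels)
    f1, f2 = _check_fractions(f1, f2)

    if method == "per_level":
        conc = np.array(
            [predict_mixture_icp(fit1, fit2, p, f1, f2) for p in effect_levels]
        )
    elif method == "fixed_rpf":
        rpf2_50 = _icp_of(fit1, 50.0) / _icp_of(fit2, 50.0)
        icp1 = np.array([_icp_of(fit1, p) for p in effect_levels])
        conc = icp1 / (f1 + f2 * rpf2_50)
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.any(np.diff(conc) <= 0):
        raise RuntimeError("predicted curve is not strictly monotone")
    return pd.DataFrame({"p": effect_levels, "c_total_uM": conc})


# ---------------------------------------------------------------------------
# numeric isobole solvers (brute force; independent of the closed forms)
# ---------------------------------------------------------------------------


def _bisect_decreasing(func, lo, hi, iters: int = 100):
    """Vectorised bisection for a function decreasing in its argument."""
    lo = np.broadcast_to(np.asarray(lo, dtype=float), np.shape(func(hi))).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), lo.shape).copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = func(mid)
        take_hi = g > 0  # root lies above mid where func still positive
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


def isobole_inhibition(c_total, fit1, fit2, f1: float = 0.5, f2: float = 0.5):
    """Percent inhibition of the mixture at total concentration(s) ``c_total``.

    Solves the Loewe isobole for the effect level p at which

        c_total * (f1/ICp1(p) + f2/ICp2(p)) = 1

    by bisection on p.  This is the dense numeric route; it inverts
    :func:`predict_mixture_icp` and is used as an oracle for the closed
    forms and to generate refined predicted curves.
    """
    f1, f2 = _check_fractions(f1, f2)
    c = np.asarray(c_total, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")

    def gap(p):
        icp1 = np.array([_icp_of(fit1, float(q)) for q in np.atleast_1d(p)])
        icp2 = np.array([_icp_of(fit2, float(q)) for q in np.atleast_1d(p)])
        icp1 = icp1.reshape(np.shape(p))
        icp2 = icp2.reshape(np.shape(p))
        return c * (f1 / icp1 + f2 / icp2) - 1.0

    eps = 1e-9
    p = _bisect_decreasing(gap, np.full(c.shape, eps), np.full(c.shape, 100.0 - eps))
    return p if p.shape else float(p)


def loewe_mixture_response(c1, c2, curve1, curve2, iters: int = 100):
    """Expected mixture response on the raw response scale.

    Each ``curve`` is ``(ec50, hill, max_effect)`` describing a
    log-logistic response ``R(c) = max_effect * (c/ec50)^h / (1 + (c/ec50)^h)``.
    Solves ``c1/EC1(R) + c2/EC2(R) = 1`` for R by bisection; when the
    isobole cannot be satisfied below the smaller of the two maximal
    effects the response is capped there (flag returned alongside).

    Returns
    -------
    response : ndarray (same shape as broadcast concentrations)
    capped : ndarray of bool
    """
    ec1, h1, m1 = (float(v) for v in curve1)
    ec2, h2, m2 = (float(v) for v in curve2)
    for name, v in (("ec50", ec1), ("ec50", ec2), ("hill", h1), ("hill", h2)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"non-positive {name} in mixture curve")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    c1, c2 = np.broadcast_arrays(c1, c2)
    rmax = min(m1, m2)

    def ecx(r, ec, h, m):
        frac = np.clip(r / m, 1e-300, 1 - 1e-15)
        return ec * (frac / (1.0 - frac)) ** (1.0 / h)

    def gap(r):
        return c1 / ecx(r, ec1, h1, m1) + c2 / ecx(r, ec2, h2, m2) - 1.0

    zero = (c1 <= 0) & (c2 <= 0)
    eps = rmax * 1e-12
    top = rmax * (1.0 - 1e-12)
    capped = gap(np.full(c1.shape, top)) > 0
    resp = _bisect_decreasing(gap, np.full(c1.shape, eps), np.full(c1.shape, top), iters)
    resp = np.where(capped, rmax, resp)
    resp = np.where(zero, 0.0, resp)
    if resp.shape == ():
        return float(resp), bool(capped)
    return resp, capped


def solve_equimolar_bmc_numeric(bmc1, bmc2, iters: int = 100):
    """Brute-force root of C/BMC1 + C/BMC2 = 1 at C1 = C2 = C (bisection).

    Independent numeric check of the harmonic closed form.  Accepts
    scalars or arrays (vectorised elementwise bisection).
    """
    b1 = np.asarray(bmc1, dtype=float)
    b2 = np.asarray(bmc2, dtype=float)
    if np.any(~np.isfinite(b1)) or np.any(b1 <= 0) or np.any(~np.isfinite(b2)) or np.any(b2 <= 0):
        raise ValueError("BMC inputs must be finite and positive")
    b1, b2 = np.broadcast_arrays(b1, b2)

    def gap(c):
        return 1.0 - (c / b1 + c / b2)  # decreasing in c

    hi = np.minimum(b1, b2)  # gap(hi) <= 0 always: bracket is valid
    c = _bisect_decreasing(gap, np.zeros(hi.shape), hi, iters)
    return float(c) if c.shape == () else c


def solve_total_icp_numeric(icp1, icp2, f1, f2, iters: int = 100):
    """Brute-force root of C*(f1/ICp1 + f2/ICp2) = 1 in total concentration.

    Vectorised over concentrations and fractions; the fractions arrays
    must satisfy f1 + f2 = 1 elementwise.
    """
    v1 = np.asarray(icp1, dtype=float)
    v2 = np.asarray(icp2, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("ICp inputs must be positive")
    if np.any(f1 <= 0) or np.any(f2 <= 0) or np.any(np.abs(f1 + f2 - 1.0) > 1e-9):
        raise ValueError("fractions must be positive and sum to 1")
    v1, v2, f1, f2 = np.broadcast_arrays(v1, v2, f1, f2)

    def gap(c):
        return 1.0 - c * (f1 / v1 + f2 / v2)

    hi = np.maximum(v1, v2)  # gap(hi) <= 0 since f1/v1 + f2/v2 >= 1/max
    c = _bisect_decreasing(gap, np.zeros(hi.shape), hi, iters)
    return float(c) if c.shape == () else c
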
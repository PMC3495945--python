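"""Sigmoidal concentration-response fitting and relative maximal efficacy.

Responses follow a Hill curve

    response(c) = baseline + emax * c^slope / (c^slope + ec50^slope)

fit by least squares with ec50 parametrized on the log10 scale.  The
3-parameter mode fixes slope = 1 (free parameters baseline, emax, ec50);
the 4-parameter mode also fits the slope.  For an inhibitor the amplitude
``emax`` is negative and the midpoint is reported as an IC50 in ``ec50``.
A partial agonist shows up as a lower |emax| at comparable ec50; its
relative maximal efficacy is the ratio of fitted plateau amplitudes
against a reference compound, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["SigmoidFit", "fit_sigmoid", "relative_max_efficacy"]


@dataclass
class SigmoidFit:
    ec50: float
    emax: float          # signed amplitude above baseline
    baseline: float
    slope: float
    rss: float
    converged: bool
    message: str = ""
    n_params: int = 4

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, float)
        cs = c**self.slope
        return self.baseline + self.emax * cs / (cs + self.ec50**self.slope)


def _model(theta: np.ndarray, c: np.ndarray, fix_slope: bool) -> np.ndarray:
    baseline, emax, log_ec50 = theta[:3]
    slope = 1.0 if fix_slope else theta[3]
    cs = c**slope
    ec50s = (10.0**log_ec50) ** slope
    return baseline + emax * cs / (cs + ec50s)


def fit_sigmoid(concs, responses, n_params: int = 4,
                direction: str = "agonist") -> SigmoidFit:
    """Least-squares Hill fit with multi-start initialization.

    ec50 is bounded within [min(conc)/100, max(conc)*100] and initial
    guesses span the tested range; the start with the lowest residual sum
    of squares wins.  Flat data yield ``converged=False`` with a
    diagnostic rather than an arbitrary curve.
    """
    c = np.asarray(concs, float)
    y = np.asarray(responses, float)
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    if direction not in ("agonist", "inhibitor"):
        raise ValueError(f"unknown direction {direction!r}")
    if c.size != y.size or c.size < n_params + 1:
        raise ValueError(f"need >= {n_params + 1} (conc, response) points")
    if (c <= 0).any():
        raise ValueError("concentrations must be > 0")

    scale = max(np.abs(y).max(), 1.0)
    if np.ptp(y) < 1e-10 * scale:
        return SigmoidFit(np.nan, 0.0, float(y.mean()), 1.0, 0.0, False,
                          "flat response data: no dose dependence", n_params)

    fix_slope = n_params == 3
    amp = np.ptp(y)
    sign = 1.0 if direction == "agonist" else -1.0
    base0 = y.min() if direction == "agonist" else y.max()
    lo_ec, hi_ec = np.log10(c.min() / 100.0), np.log10(c.max() * 100.0)
    lower = [-np.inf, 0.0 if sign > 0 else -np.inf, lo_ec]
    upper = [np.inf, np.inf if sign > 0 else 0.0, hi_ec]
    if not fix_slope:
        lower.append(0.2)
        upper.append(10.0)

    best = None
    for log_ec0 in np.linspace(np.log10(c.min()), np.log10(c.max()), 5):
        theta0 = [base0, sign * amp, log_ec0] + ([] if fix_slope else [1.0])
        theta0 = np.clip(theta0, lower, upper)
        try:
            res = least_squares(
                lambda th: _model(th, c, fix_slope) - y, theta0,
                bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:  # singular start; other starts may still work
            continue
        rss = float(res.cost * 2.0)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.inf, False,
                          "optimization failed from every start", n_params)
    rss, res = best
    baseline, emax, log_ec50 = res.x[:3]
    slope = 1.0 if fix_slope else float(res.x[3])
    ok = bool(res.success and np.isfinite(res.x).all())
    return SigmoidFit(float(10.0**log_ec50), float(emax), float(baseline),
                      slope, rss, ok, res.message, n_params)


def relative_max_efficacy(test: SigmoidFit, ref: SigmoidFit) -> float:
    """Fitted plateau amplitude of the test compound as a percentage of the
    reference amplitude (reference = 100%)."""
    if not (test.converged and ref.converged):
        raise ValueError("both fits must have converged")
    if ref.emax == 0:
        raise ValueError("reference amplitude is zero")
    return float(100.0 * abs(test.emax) / abs(ref.emax))
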
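"""Mass isotopomer distribution analysis of hepatic glucose fluxes.

A fasted animal is infused with three tracers at known rates:

* [U-13C]glucose dilutes in the blood-glucose pool; its M6 excess gives
  whole-body glucose turnover and hence the glucose-6-phosphatase flux;
* [2-13C]glycerol labels the triose (gluconeogenic precursor) pool; newly
  made hexose draws two trioses, so the product carries a binomial M1/M2
  signature whose ratio identifies the precursor enrichment (the MIDA
  principle) and whose magnitude gives the fractional de novo G6P synthesis;
* [1-2H]galactose enters hepatic UDP-glucose directly; its dilution in the
  urinary paracetamol-glucuronide (which samples UDP-glucose) gives the
  glycogen-synthase flux.

The committed steady-state tracer-balance model has three pools (blood
glucose, G6P, UDP-glucose), includes label recycling through glucokinase,
neglects UDP-glucose to G6P backflux and hepatic glycolysis in the fasted
state, and closes the G6P balance:

    v_GK + v_GP + v_GNG = v_G6Pase + v_GS

Solving the label balances for the plateau excess fractions g1/g2/g6
(blood glucose) and u1/u2/u6 (glucuronide) yields closed-form estimators;
see docs/methods.md for the derivation.  All fluxes are umol/kg/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

log = logging.getLogger(__name__)

__all__ = [
    "InfusionProtocol",
    "FluxEstimate",
    "natural_abundance_matrix",
    "correct_isotopomers",
    "correct_timecourse",
    "plateau_mean",
    "estimate_fluxes",
    "fluxes_from_timecourse",
]

MASS_COLS = [f"M{k}" for k in range(7)]


@dataclass
class InfusionProtocol:
    """Tracer pump rates in umol/hr (any object with these attributes and a
    body weight works, e.g. a simulation ground truth)."""

    infusion_glucose: float
    infusion_glycerol: float
    infusion_galactose: float
    body_weight_g: float = 25.0

    def rate_per_kg_min(self, umol_per_hr: float) -> float:
        return umol_per_hr / 60.0 / (self.body_weight_g / 1000.0)


def natural_abundance_matrix(n_carbons: int, p13c: float = 0.0107) -> np.ndarray:
    """Convolution matrix from excess to measured mass isotopomer fractions.

    Entry (i, j) is the probability that a molecule with j excess label
    atoms is observed at mass M_i because of natural 13C on its remaining
    ``n_carbons - j`` carbons: Binomial(n-j, p13c) evaluated at i-j.
    Columns sum to 1.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p13c < 1.0:
        raise ValueError("p13c must be in [0, 1)")
    n = n_carbons
    A = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        A[j + k, j] = stats.binom.pmf(k, n - j, p13c)
    return A


def correct_isotopomers(measured: np.ndarray, n_carbons: int = 6,
                        p13c: float = 0.0107) -> np.ndarray:
    """Excess mole fractions M0..Mn from a measured distribution.

    Solves ``measured = A @ excess`` by non-negative least squares and
    renormalizes the excess to sum 1.  Raises on an ill-conditioned or
    degenerate solve.
    """
    y = np.asarray(measured, float)
    if y.shape != (n_carbons + 1,):
        raise ValueError(f"expected {n_carbons + 1} mass fractions")
    A = natural_abundance_matrix(n_carbons, p13c)
    x, rnorm = nnls(A, y)
    if not np.isfinite(x).all() or x.sum() <= 0:
        raise ValueError(f"isotopomer correction failed (residual {rnorm:.3g})")
    return x / x.sum()


def correct_timecourse(mid: pd.DataFrame, n_carbons: int = 6,
                       p13c: float = 0.0107) -> pd.DataFrame:
    """Correct a long-format (time, mass_index, fraction) series for one
    analyte; returns a frame indexed by time with columns M0..Mn (excess)."""
    wide = mid.pivot_table(index="time", columns="mass_index",
                           values="fraction", sort=True)
    out = {}
    for t, row in wide.iterrows():
        out[t] = correct_isotopomers(row.to_numpy(float), n_carbons, p13c)
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=MASS_COLS[: n_carbons + 1]).sort_index()


def plateau_mean(excess: pd.DataFrame, rel_tol: float = 0.02,
                 n_points: int = 2, noise_sd: float = 0.0) -> pd.Series:
    """Average the final timepoints once isotopic steady state is reached.

    The total labeled excess ``1 - M0`` must change by less than ``rel_tol``
    (relative) between the final two points; the last ``n_points`` points
    are then averaged.  Earlier points are excluded even when within
    tolerance, since they still carry approach-to-plateau bias.

    ``noise_sd`` is the known fractional measurement noise per mass
    fraction (assay CV).  The detection gate is widened to four standard
    deviations of the noise propagated onto the between-point relative
    change (sd ~ sqrt(2) * noise_sd * M0/s), so noisy steady-state data are
    not rejected while a genuine ramp still trips the check.  Raises if no
    plateau.
    """
    s = 1.0 - excess["M0"]
    if len(s) < 2:
        raise ValueError("need at least two timepoints for plateau detection")
    final = s.iloc[-1]
    if final <= 0:
        raise ValueError("no labeling detected at final timepoint")
    gate = max(rel_tol,
               4.0 * np.sqrt(2.0) * noise_sd * excess["M0"].iloc[-1] / final)
    if abs(s.iloc[-2] - final) / final > gate:
        raise ValueError("no plateau: labeling still changing at end of infusion")
    return excess.iloc[-n_points:].mean(axis=0)


@dataclass
class FluxEstimate:
    """Hepatic flux rates (umol/kg/min) with balances held by construction."""

    v_GK: float
    v_G6Pase: float
    v_GS: float
    v_GP: float
    v_GNG: float
    mcr: float                       # ml/kg/min
    precursor_enrichment: float
    warnings: list[str] = field(default_factory=list)

    @property
    def glucose_balance(self) -> float:
        """Net hepatic glucose output, v_G6Pase - v_GK."""
        return self.v_G6Pase - self.v_GK

    @property
    def glycogen_balance(self) -> float:
        """Net glycogen deposition, v_GS - v_GP."""
        return self.v_GS - self.v_GP

    def as_dict(self) -> dict:
        return {
            "v_GK": self.v_GK, "v_G6Pase": self.v_G6Pase, "v_GS": self.v_GS,
            "v_GP": self.v_GP, "v_GNG": self.v_GNG,
            "glucose_balance": self.glucose_balance,
            "glycogen_balance": self.glycogen_balance,
            "mcr": self.mcr, "precursor_enrichment": self.precursor_enrichment,
            "warnings": list(self.warnings),
        }


def estimate_fluxes(glucose_excess: pd.DataFrame, glcua_excess: pd.DataFrame,
                    infusion, blood_glucose_conc: float,
                    body_weight_g: float | None = None,
                    noise_sd: float = 0.0) -> FluxEstimate:
    """Steady-state flux estimation from corrected excess MID time series.

    ``glucose_excess`` / ``glcua_excess`` are frames indexed by time with
    columns M0..M6 of excess fractions (see :func:`correct_timecourse`);
    ``infusion`` carries the tracer pump rates in umol/hr (and a body
    weight, unless given separately).  The estimator averages the plateau
    points, then applies, in order:

    1. precursor enrichment p from the glucose M2/M1 ratio,
       p = 2r/(1 + 2r) with r = g2/g1 (recycling cancels in the ratio);
    2. the glucokinase share of G6P input,
       x = v_GK/T = g2 / (g6 * ((1 - g6) * u2/u6 + g2));
    3. glucose-6-phosphatase from [U-13C]glucose dilution with recycling,
       v_G6Pase = r_glc * (1 - g6) / (g6 * (1 - x));
    4. glycogen synthase from [1-2H]galactose dilution in glucuronide,
       v_GS = r_gal * (1 - u1) / (u1 - e1)  with  e1 = e2 * 2(1-p)/p,
       e2 = x * g6 * u2/u6;
    5. total G6P turnover T = v_G6Pase + v_GS (closure), then
       v_GK = x T,  v_GNG = x (g6 u2/u6 - g2) / p^2 * T,
       v_GP = T - v_GK - v_GNG;
    6. MCR = (v_G6Pase + r_glc) / blood glucose concentration.

    Negative closed-balance fluxes are reported with a warning flag, not
    clipped.
    """
    bw = body_weight_g if body_weight_g is not None else getattr(
        infusion, "body_weight_g")
    r_glc = infusion.infusion_glucose / 60.0 / (bw / 1000.0)
    r_gly = infusion.infusion_glycerol / 60.0 / (bw / 1000.0)
    r_gal = infusion.infusion_galactose / 60.0 / (bw / 1000.0)
    if min(r_glc, r_gly, r_gal) <= 0:
        raise ValueError("all three tracer infusion rates must be positive")
    if blood_glucose_conc <= 0:
        raise ValueError("blood glucose concentration must be positive")

    g = plateau_mean(glucose_excess, noise_sd=noise_sd)
    u = plateau_mean(glcua_excess, noise_sd=noise_sd)
    g1, g2, g6 = g["M1"], g["M2"], g["M6"]
    u1, u2, u6 = u["M1"], u["M2"], u["M6"]
    if min(g1, g2, g6, u1, u2, u6) <= 0:
        raise ValueError("non-positive plateau excess fraction; tracer signal "
                         "too weak for flux estimation")

    r = g2 / g1
    p = 2.0 * r / (1.0 + 2.0 * r)
    x = g2 / (g6 * ((1.0 - g6) * u2 / u6 + g2))
    v_G6Pase = r_glc * (1.0 - g6) / (g6 * (1.0 - x))
    e6 = x * g6
    e2 = e6 * u2 / u6
    e1 = e2 * 2.0 * (1.0 - p) / p
    v_GS = r_gal * (1.0 - u1) / (u1 - e1)
    T = v_G6Pase + v_GS
    v_GK = x * T
    v_GNG = x * (g6 * u2 / u6 - g2) / p**2 * T
    v_GP = T - v_GK - v_GNG
    mcr = (v_G6Pase + r_glc) / blood_glucose_conc

    warns = [f"negative closed-balance flux {n} = {v:.3g}"
             for n, v in (("v_GK", v_GK), ("v_G6Pase", v_G6Pase),
                          ("v_GS", v_GS), ("v_GP", v_GP), ("v_GNG", v_GNG))
             if v < 0]
    for w in warns:
        log.warning(w)
    return FluxEstimate(float(v_GK), float(v_G6Pase), float(v_GS),
                        float(v_GP), float(v_GNG), float(mcr), float(p),
                        warns)


def fluxes_from_timecourse(timecourse: pd.DataFrame, infusion,
                           blood_glucose_conc: float,
                           body_weight_g: float | None = None,
                           p13c: float = 0.0107,
                           noise_sd: float = 0.0) -> FluxEstimate:
    """Convenience wrapper: long-format (analyte, time, mass_index, fraction)
    measurements -> natural-abundance correction -> flux estimation."""
    parts = {}
    for analyte in ("blood_glucose", "par_glcua"):
        sub = timecourse[timecourse["analyte"] == analyte]
        if sub.empty:
            raise ValueError(f"timecourse lacks analyte {analyte!r}")
        parts[analyte] = correct_timecourse(sub, 6, p13c)
    return estimate_fluxes(parts["blood_glucose"], parts["par_glcua"],
                           infusion, blood_glucose_conc, body_weight_g,
                           noise_sd=noise_sd)
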
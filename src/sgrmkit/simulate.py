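"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the profiling pipeline consumes in practice:

* a two-compound microarray experiment in which a test compound is a
  gene-specific partial agonist (sub-maximal induction, near-full
  repression) against a full reference agonist;
* sigmoidal concentration-response curves with partial maximal efficacy;
* paired ChIP cluster read counts with a planted occupancy ratio;
* steady-state triple-tracer mass-isotopomer time courses generated from a
  known hepatic flux configuration.

All generators take an explicit seed and are deterministic given it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import ClusterSet
from .ti import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionSimConfig",
    "FluxTruth",
    "generate_expression",
    "generate_dose_response",
    "generate_cluster_counts",
    "simulate_mida",
    "steady_state_enrichments",
    "partiality_from_log2fc",
    "NATURAL_13C_ABUNDANCE",
]

#: Natural abundance of carbon-13 (mole fraction).
NATURAL_13C_ABUNDANCE = 0.0107


def partiality_from_log2fc(ref_log2fc: float, test_log2fc: float) -> float:
    """Linear-scale efficacy fraction that maps a reference fold change onto
    a desired test-compound fold change (signed log2 units; works for both
    induction, positive, and repression, negative)."""
    return float((2.0**test_log2fc - 1.0) / (2.0**ref_log2fc - 1.0))


@dataclass
class ExpressionSimConfig:
    """Ground truth for the two-compound expression simulation.

    The reference compound induces ``n_induced`` probes by
    ``ref_induction_log2fc`` on average (per-probe effects spread
    symmetrically over ``effect_spread`` log2 units so the ranking is
    non-degenerate) and, under stimulation, represses ``n_repressed``
    stimulus-driven probes by ``ref_repression_log2fc``.  The test compound
    acts on the same probes with linear-scale efficacy fractions
    ``partiality_ind`` / ``partiality_rep`` in (0, 1]:
    ``FC_test = 1 + partiality * (FC_ref - 1)`` on the linear scale.
    Defaults plant the reference means of the worked THP-1 example
    (induced 3.61, repressed 1.76 log2 units).
    """

    n_probes: int = 1000
    n_induced: int = 25
    n_repressed: int = 25
    ref_induction_log2fc: float = 3.61
    ref_repression_log2fc: float = 1.76
    partiality_ind: float = 0.5
    partiality_rep: float = 0.9
    noise_sd: float = 0.2
    n_replicates: int = 3
    seed: int = 0
    effect_spread: float = 0.5
    stimulus_log2fc: float = 2.5
    baseline_log2: float = 7.0

    def __post_init__(self) -> None:
        if min(self.n_probes, self.n_induced, self.n_repressed,
               self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.n_induced + self.n_repressed > self.n_probes:
            raise ValueError("n_induced + n_repressed must be <= n_probes")
        for p in (self.partiality_ind, self.partiality_rep):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"partiality {p} outside (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _spread(mean: float, n: int, spread: float) -> np.ndarray:
    """Descending per-probe effects with exact mean ``mean``."""
    if n == 1:
        return np.array([mean])
    return mean + np.linspace(spread / 2.0, -spread / 2.0, n)


def generate_expression(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Simulate log2 intensities for {vehicle, reference, test} x
    {unstimulated, stimulated} with ``n_replicates`` samples each.

    Induced probes respond to compound in both strata; repressed probes are
    switched on by the stimulus (modelling inflammatory or disease-driven
    genes) and knocked down by compound only in the stimulated stratum, so
    the stimulated stratum doubles as the diseased stratum for the in-vivo
    selection mode.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    probes = [f"probe{i:05d}" for i in range(cfg.n_probes)]
    ind = slice(0, cfg.n_induced)
    rep = slice(cfg.n_induced, cfg.n_induced + cfg.n_repressed)

    ref_ind = _spread(cfg.ref_induction_log2fc, cfg.n_induced, cfg.effect_spread)
    ref_rep = -_spread(cfg.ref_repression_log2fc, cfg.n_repressed,
                       cfg.effect_spread)
    test_ind = np.log2(1.0 + cfg.partiality_ind * (2.0**ref_ind - 1.0))
    test_rep = np.log2(1.0 + cfg.partiality_rep * (2.0**ref_rep - 1.0))

    columns: dict[str, np.ndarray] = {}
    cond_rows = []
    for compound in ("vehicle", "reference", "test"):
        for stimulus in ("none", "stimulated"):
            for r in range(cfg.n_replicates):
                mu = np.full(cfg.n_probes, cfg.baseline_log2)
                if stimulus == "stimulated":
                    mu[rep] += cfg.stimulus_log2fc
                if compound == "reference":
                    mu[ind] += ref_ind
                    if stimulus == "stimulated":
                        mu[rep] += ref_rep
                elif compound == "test":
                    mu[ind] += test_ind
                    if stimulus == "stimulated":
                        mu[rep] += test_rep
                sid = f"{compound[:3]}_{'st' if stimulus == 'stimulated' else 'ns'}_{r + 1}"
                columns[sid] = mu + rng.normal(0.0, cfg.noise_sd, cfg.n_probes)
                cond_rows.append({
                    "sample": sid, "compound": compound, "stimulus": stimulus,
                    "disease": "diseased" if stimulus == "stimulated" else "healthy",
                })
    values = pd.DataFrame(columns, index=probes)
    conditions = pd.DataFrame(cond_rows).set_index("sample")
    return ExpressionMatrix(values, conditions)


def generate_dose_response(ec50: float, emax: float, baseline: float,
                           slope: float, concs: list[float],
                           noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Hill-curve responses ``baseline + emax*c^slope/(c^slope + ec50^slope)``
    with additive Gaussian noise; returns a (concentration, response) frame."""
    c = np.asarray(concs, float)
    if c.size == 0:
        raise ValueError("empty concentration list")
    if (c <= 0).any():
        raise ValueError("concentrations must be > 0")
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    rng = np.random.default_rng(seed)
    resp = baseline + emax * c**slope / (c**slope + ec50**slope)
    resp = resp + rng.normal(0.0, noise_sd, c.size)
    return pd.DataFrame({"concentration": c, "response": resp})


def generate_cluster_counts(n_clusters: int, occupancy_ratio: float,
                            dispersion: float = 10.0, seed: int = 0,
                            base_mean: float = 50.0,
                            n_chroms: int = 5) -> tuple[ClusterSet, ClusterSet]:
    """Paired per-cluster read counts on a shared, sorted, non-overlapping
    interval set.

    Counts are negative-binomially distributed with means
    ``base_mean * occupancy_ratio`` (reference) and ``base_mean`` (test), so
    the expected reference/test count ratio is ``occupancy_ratio``.
    ``dispersion`` is the NB size parameter (variance mu + mu^2/size).
    """
    if n_clusters <= 0:
        raise ValueError("n_clusters must be > 0")
    if occupancy_ratio <= 0:
        raise ValueError("occupancy_ratio must be > 0")
    rng = np.random.default_rng(seed)
    chroms = np.sort(rng.integers(1, n_chroms + 1, n_clusters))
    widths = rng.integers(200, 800, n_clusters)
    gaps = rng.integers(500, 5000, n_clusters)
    rows = []
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        pos = 0
        for i in idx:
            start = pos + int(gaps[i])
            end = start + int(widths[i])
            rows.append((f"chr{chrom}", start, end, f"cluster{i:05d}"))
            pos = end

    def _counts(mu: float) -> np.ndarray:
        p = dispersion / (dispersion + mu)
        return rng.negative_binomial(dispersion, p, n_clusters)

    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    ref = frame.assign(count=_counts(base_mean * occupancy_ratio))
    test = frame.assign(count=_counts(base_mean))
    return (ClusterSet(ref, label="reference"), ClusterSet(test, label="test"))


# ---------------------------------------------------------------------------
# Triple-tracer MIDA forward simulation
# ---------------------------------------------------------------------------

@dataclass
class FluxTruth:
    """Ground-truth hepatic fluxes and the infusion protocol that probes them.

    Fluxes are in umol/kg/min.  The steady-state closure of the
    glucose-6-phosphate pool (hepatic glycolysis neglected in the fasted
    state) is enforced:

        v_GK + v_GP + v_GNG = v_G6Pase + v_GS

    Infusion rates are pump rates in umol/hr of [U-13C]glucose (labels blood
    glucose at M6), [2-13C]glycerol (labels the triose/gluconeogenic
    precursor pool at M1 per triose) and [1-2H]galactose (labels hepatic
    UDP-glucose at M1).  ``endogenous_triose_appearance`` (umol/kg/min) sets
    the unlabeled dilution of the triose pool and hence the precursor
    enrichment; the estimator never sees it and re-derives the precursor
    enrichment from the product M2/M1 ratio.  Defaults follow the mouse
    protocol: 0.54 ml/hr of 13/160/33 umol/ml tracer solution into a 25 g
    mouse, fasting blood glucose 7 mM.
    """

    v_GK: float = 30.0
    v_G6Pase: float = 150.0
    v_GS: float = 20.0
    v_GP: float = 50.0
    v_GNG: float = 90.0
    glucose_conc: float = 7.0          # mM = umol/ml
    body_weight_g: float = 25.0
    infusion_glucose: float = 13.0 * 0.54   # umol/hr
    infusion_glycerol: float = 160.0 * 0.54
    infusion_galactose: float = 33.0 * 0.54
    endogenous_triose_appearance: float = 300.0

    def __post_init__(self) -> None:
        fluxes = (self.v_GK, self.v_G6Pase, self.v_GS, self.v_GP, self.v_GNG)
        if any(v < 0 for v in fluxes):
            raise ValueError("fluxes must be >= 0")
        lhs = self.v_GK + self.v_GP + self.v_GNG
        rhs = self.v_G6Pase + self.v_GS
        if not np.isclose(lhs, rhs, rtol=1e-9, atol=1e-9):
            raise ValueError(
                f"G6P closure violated: GK+GP+GNG={lhs} != G6Pase+GS={rhs}")

    @classmethod
    def with_closure(cls, v_GK: float, v_G6Pase: float, v_GS: float,
                     v_GP: float, **kw) -> "FluxTruth":
        """Construct with v_GNG set by the G6P steady-state closure."""
        v_GNG = v_G6Pase + v_GS - v_GK - v_GP
        if v_GNG < 0:
            raise ValueError("closure gives negative de novo G6P flux")
        return cls(v_GK=v_GK, v_G6Pase=v_G6Pase, v_GS=v_GS, v_GP=v_GP,
                   v_GNG=v_GNG, **kw)

    def rate_per_kg_min(self, umol_per_hr: float) -> float:
        return umol_per_hr / 60.0 / (self.body_weight_g / 1000.0)


def steady_state_enrichments(truth: FluxTruth) -> dict[str, float]:
    """Plateau excess mass-isotopomer fractions implied by a flux truth.

    Solves the linear steady-state label balances of the blood-glucose,
    G6P and UDP-glucose pools (single common precursor enrichment for the
    two triose units of newly made hexose; label recycling through
    glucokinase included; no UDP-glucose to G6P backflux).
    """
    t = truth
    r_glc = t.rate_per_kg_min(t.infusion_glucose)
    r_gly = t.rate_per_kg_min(t.infusion_glycerol)
    r_gal = t.rate_per_kg_min(t.infusion_galactose)
    Ra = t.v_G6Pase + r_glc
    T = t.v_GK + t.v_GP + t.v_GNG
    T_U = t.v_GS + r_gal
    p_t = r_gly / (r_gly + t.endogenous_triose_appearance) if r_gly > 0 else 0.0

    denom = T * Ra - t.v_G6Pase * t.v_GK
    g6 = r_glc * T / denom
    g1 = t.v_G6Pase * t.v_GNG * 2.0 * p_t * (1.0 - p_t) / denom
    g2 = t.v_G6Pase * t.v_GNG * p_t**2 / denom
    e6 = t.v_GK * g6 / T
    e1 = (t.v_GNG * 2.0 * p_t * (1.0 - p_t) + t.v_GK * g1) / T
    e2 = (t.v_GNG * p_t**2 + t.v_GK * g2) / T
    u6 = t.v_GS * e6 / T_U
    u1 = (r_gal + t.v_GS * e1) / T_U
    u2 = t.v_GS * e2 / T_U
    return {"g1": g1, "g2": g2, "g6": g6, "u1": u1, "u2": u2, "u6": u6,
            "p_triose": p_t, "Ra": Ra}


def simulate_mida(truth: FluxTruth, timepoints: list[float],
                  noise_sd: float = 0.0, seed: int = 0,
                  p13c: float = NATURAL_13C_ABUNDANCE,
                  tau_hr: float = 0.7) -> pd.DataFrame:
    """Measured M0-M6 mass fractions of blood glucose and urinary
    paracetamol-glucuronide over an infusion time course.

    Excess enrichments rise to the steady-state plateau as
    ``1 - exp(-t/tau_hr)`` and are convolved with natural 13C abundance
    (binomial, six carbons).  ``noise_sd`` is the relative (fractional)
    measurement noise per mass fraction; noisy fractions are clipped to
    [0, 1] and renormalized to sum 1.  Returns a long-format frame with
    columns (analyte, time, mass_index, fraction).
    """
    from .mida import natural_abundance_matrix  # local import, no cycle at module load

    tp = np.asarray(timepoints, float)
    if tp.size == 0 or tp[0] != 0 or (np.diff(tp) <= 0).any():
        raise ValueError("timepoints must be increasing and start at 0")
    ss = steady_state_enrichments(truth)
    A = natural_abundance_matrix(6, p13c)
    rng = np.random.default_rng(seed)
    clipped = 0
    rows = []
    for analyte, (m1, m2, m6) in (
            ("blood_glucose", (ss["g1"], ss["g2"], ss["g6"])),
            ("par_glcua", (ss["u1"], ss["u2"], ss["u6"]))):
        for t in tp:
            f = 1.0 - np.exp(-t / tau_hr) if tau_hr > 0 else 1.0
            excess = np.zeros(7)
            excess[1], excess[2], excess[6] = f * m1, f * m2, f * m6
            excess[0] = 1.0 - excess.sum()
            measured = A @ excess
            if noise_sd > 0:
                measured = measured * (1.0 + rng.normal(0.0, noise_sd, 7))
                lo, hi = measured < 0, measured > 1
                if lo.any() or hi.any():
                    clipped += int(lo.sum() + hi.sum())
                    measured = np.clip(measured, 0.0, 1.0)
                measured = measured / measured.sum()
            for k in range(7):
                rows.append((analyte, float(t), k, measured[k]))
    if clipped:
        log.warning("clipped %d mass fractions outside [0, 1] before "
                    "renormalization", clipped)
    return pd.DataFrame(rows, columns=["analyte", "time", "mass_index", "fraction"])
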
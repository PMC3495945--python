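"""Relative therapeutic-index (TI) scoring from gene-expression fold changes.

A selective glucocorticoid receptor modulator (SGRM) is profiled against a
reference glucocorticoid by comparing, within the same cells, how strongly
each compound *induces* genes (GRE-mediated transactivation, linked to
metabolic side effects) and how strongly it *represses* inflammatory genes
(transrepression, linked to therapeutic benefit).  For each direction the
mean log2 fold change over a top-N gene set is converted to a percent
maximal efficacy relative to the reference compound, and the relative TI is
the ratio of repression efficacy to induction efficacy:

    eff_ind = 100 * 2**(meanFC_I_test - meanFC_I_ref)        [%]
    eff_rep = 100 * 2**(meanFC_R_test - meanFC_R_ref)        [%]
    TI_rel  = 2**[(meanFC_I_ref - meanFC_R_ref) - (meanFC_I_test - meanFC_R_test)]
            = eff_rep / eff_ind

where meanFC_I / meanFC_R are mean log2 fold changes over the induced /
repressed gene sets (repression stored as a positive magnitude).  A TI_rel
of 1 means the test compound is as dissociated as the reference; larger is
better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "TISummary",
    "TIPipelineConfig",
    "compute_fold_changes",
    "fold_change_table",
    "select_top_genes",
    "mean_log2_fc",
    "relative_ti",
    "ti_from_efficacies",
    "run_ti_pipeline",
]

COMPOUNDS = ("vehicle", "reference", "test")
STIMULI = ("none", "stimulated")


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of log2 intensities with condition labels.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample; ``conditions`` is a DataFrame indexed by sample id with columns
    ``compound`` (vehicle/reference/test), ``stimulus`` (none/stimulated)
    and ``disease`` (healthy/diseased/n/a).
    """

    values: pd.DataFrame
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def samples_for(self, compound: str, stimulus: str = "none",
                    disease: str | None = None) -> list[str]:
        cond = self.conditions
        mask = (cond["compound"] == compound) & (cond["stimulus"] == stimulus)
        if disease is not None and "disease" in cond.columns:
            mask &= cond["disease"] == disease
        return [s for s in self.values.columns if s in cond.index[mask]]


def _welch_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with explicit zero-variance handling.

    With zero pooled variance the t statistic is degenerate: p is 0 for a
    non-zero mean difference and 1 otherwise (the limit of the test).
    """
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1) if nx > 1 else np.full(x.shape[0], np.nan)
    vy = y.var(axis=1, ddof=1) if ny > 1 else np.full(y.shape[0], np.nan)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = np.ones(x.shape[0])
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    zero_var = np.isclose(se2, 0.0) | ~np.isfinite(se2)
    p[zero_var & ~np.isclose(mx - my, 0.0)] = 0.0
    p[zero_var & np.isclose(mx - my, 0.0)] = 1.0
    return p


def compute_fold_changes(matrix: ExpressionMatrix, compound: str, *,
                         versus: str = "vehicle", stimulus: str = "none",
                         versus_stimulus: str | None = None,
                         disease: str | None = None,
                         versus_disease: str | None = None) -> pd.DataFrame:
    """Per-probe log2 fold change and BH-adjusted Welch p-value for one contrast.

    ``log2fc = mean(log2 compound samples) - mean(log2 versus samples)``.
    p-values require >=2 replicates on both sides; otherwise they are set
    to 1 with a warning.  Adjustment is Benjamini-Hochberg across all probes.
    """
    if versus_stimulus is None:
        versus_stimulus = stimulus
    a = matrix.samples_for(compound, stimulus, disease)
    b = matrix.samples_for(versus, versus_stimulus, versus_disease)
    if not a or not b:
        raise ValueError(
            f"contrast {compound}/{stimulus} vs {versus}/{versus_stimulus}: "
            "missing condition samples")
    if matrix.values.shape[0] == 0:
        raise ValueError("expression matrix has zero probes")
    x = matrix.values[a].to_numpy(float)
    y = matrix.values[b].to_numpy(float)
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    if x.shape[1] < 2 or y.shape[1] < 2:
        warnings.warn("fewer than 2 replicates in a condition; p-values set to 1")
        p = np.ones(x.shape[0])
    else:
        p = _welch_p(x, y)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "p": p, "p_adj": p_adj},
                        index=matrix.values.index)


def fold_change_table(matrix: ExpressionMatrix, *, stimulus: str = "none",
                      versus: str = "vehicle",
                      disease: str | None = None) -> pd.DataFrame:
    """FoldChangeTable for the reference and test compounds in one stratum.

    Columns: log2fc_ref, log2fc_test, p_adj_ref, p_adj_test, indexed by probe.
    """
    ref = compute_fold_changes(matrix, "reference", versus=versus,
                               stimulus=stimulus, disease=disease)
    test = compute_fold_changes(matrix, "test", versus=versus,
                                stimulus=stimulus, disease=disease)
    return pd.DataFrame({
        "log2fc_ref": ref["log2fc"], "p_adj_ref": ref["p_adj"],
        "log2fc_test": test["log2fc"], "p_adj_test": test["p_adj"],
    })


def _passing(fc: pd.DataFrame, compound: str, direction: str,
             thr: float, alpha: float) -> pd.Series:
    l2 = fc[f"log2fc_{compound}"]
    p = fc[f"p_adj_{compound}"]
    ok = (l2 >= thr) if direction == "induced" else (l2 <= -thr)
    return ok & (p < alpha)


def select_top_genes(fc: pd.DataFrame, direction: str, *,
                     ranked_by: str = "reference", n: int = 25,
                     min_linear_fc: float = 2.0, alpha: float = 0.05,
                     disease_filter: pd.DataFrame | None = None) -> list[str]:
    """Top-``n`` probes by fold-change magnitude, after significance filters.

    A probe passes if its linear fold change is at least ``min_linear_fc``
    in the stated ``direction`` and its BH-adjusted p-value is below
    ``alpha`` in the ranking compound (``reference``, ``test``, or
    ``either`` = passing in at least one compound, ranked by the larger
    |log2fc| of the two).  ``disease_filter`` (a fold-change frame for the
    disease-induction contrast) additionally requires repressed probes to
    be at least ``min_linear_fc``-fold up-regulated by disease.  Ties in
    |log2fc| break by probe id ascending.
    """
    if direction not in ("induced", "repressed"):
        raise ValueError(f"unknown direction {direction!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    thr = np.log2(min_linear_fc)
    if ranked_by in ("reference", "test"):
        short = "ref" if ranked_by == "reference" else "test"
        passing = _passing(fc, short, direction, thr, alpha)
        key = fc[f"log2fc_{short}"].abs()
    elif ranked_by == "either":
        p_ref = _passing(fc, "ref", direction, thr, alpha)
        p_test = _passing(fc, "test", direction, thr, alpha)
        passing = p_ref | p_test
        key = pd.concat([fc["log2fc_ref"].abs(), fc["log2fc_test"].abs()],
                        axis=1).max(axis=1)
    else:
        raise ValueError(f"unknown ranked_by {ranked_by!r}")
    if direction == "repressed" and disease_filter is not None:
        passing &= disease_filter["log2fc"].reindex(fc.index) >= thr
    sel = fc.index[passing]
    if len(sel) == 0:
        raise ValueError(
            f"no probes pass |linear FC| >= {min_linear_fc} and "
            f"p_adj < {alpha} ({direction}, ranked by {ranked_by})")
    if len(sel) < n:
        warnings.warn(f"only {len(sel)} probes pass filters (requested {n})")
    order = sorted(sel, key=lambda pid: (-key.loc[pid], str(pid)))
    return [str(p) for p in order[:n]]


def mean_log2_fc(fc: pd.DataFrame, probes: list[str], compound: str,
                 direction: str) -> float:
    """Mean log2 fold change over ``probes``; repression as positive magnitude."""
    if len(probes) == 0:
        raise ValueError("empty probe list")
    short = "ref" if compound == "reference" else "test"
    vals = fc.loc[list(probes), f"log2fc_{short}"].to_numpy(float)
    m = float(vals.mean())
    return -m if direction == "repressed" else m


@dataclass
class TISummary:
    """Mean fold changes, percent efficacies and the relative TI."""

    meanFC_I_ref: float
    meanFC_R_ref: float
    meanFC_I_test: float
    meanFC_R_test: float
    eff_ind_pct: float
    eff_rep_pct: float
    ti_rel: float
    induced_probes: list[str] = field(default_factory=list)
    repressed_probes: list[str] = field(default_factory=list)

    def rounded(self) -> dict:
        """One-decimal presentation of the headline numbers."""
        return {
            "eff_ind_pct": round(self.eff_ind_pct, 1),
            "eff_rep_pct": round(self.eff_rep_pct, 1),
            "ti_rel": round(self.ti_rel, 1),
        }

    def as_dict(self) -> dict:
        return {
            "meanFC_I_ref": self.meanFC_I_ref,
            "meanFC_R_ref": self.meanFC_R_ref,
            "meanFC_I_test": self.meanFC_I_test,
            "meanFC_R_test": self.meanFC_R_test,
            "eff_ind_pct": self.eff_ind_pct,
            "eff_rep_pct": self.eff_rep_pct,
            "ti_rel": self.ti_rel,
            "induced_probes": self.induced_probes,
            "repressed_probes": self.repressed_probes,
        }


def relative_ti(meanFC_I_ref: float, meanFC_R_ref: float,
                meanFC_I_test: float, meanFC_R_test: float) -> TISummary:
    """Relative TI and percent efficacies from the four mean log2 fold changes.

    TI_rel = 2**[(I_ref - R_ref) - (I_test - R_test)], algebraically equal
    to eff_rep_pct / eff_ind_pct.  The reference compound scores 1 against
    itself.
    """
    vals = [meanFC_I_ref, meanFC_R_ref, meanFC_I_test, meanFC_R_test]
    if not all(np.isfinite(vals)):
        raise ValueError("mean fold changes must be finite")
    if any(v < 0 for v in vals):
        raise ValueError("mean fold changes must be >= 0 (repression as magnitude)")
    eff_ind = 100.0 * 2.0 ** (meanFC_I_test - meanFC_I_ref)
    eff_rep = 100.0 * 2.0 ** (meanFC_R_test - meanFC_R_ref)
    ti = 2.0 ** ((meanFC_I_ref - meanFC_R_ref) - (meanFC_I_test - meanFC_R_test))
    return TISummary(meanFC_I_ref, meanFC_R_ref, meanFC_I_test, meanFC_R_test,
                     eff_ind, eff_rep, ti)


def ti_from_efficacies(rep_effs: list[float], ind_effs: list[float]) -> float:
    """Relative TI from already-relative percent efficacies.

    Used when a study reports per-readout maximal efficacies (reference set
    at 100%) rather than gene-set fold changes: TI = mean(repression
    efficacies) / mean(induction efficacies).
    """
    rep = np.asarray(rep_effs, float)
    ind = np.asarray(ind_effs, float)
    if rep.size == 0 or ind.size == 0:
        raise ValueError("efficacy lists must be non-empty")
    if (rep <= 0).any() or (ind <= 0).any():
        raise ValueError("efficacies must be > 0")
    return float(rep.mean() / ind.mean())


@dataclass
class TIPipelineConfig:
    """End-to-end TI pipeline parameters.

    ``mode='invitro'`` ranks gene sets by the reference compound and takes
    repression from the stimulated stratum; ``mode='invivo'`` ranks by
    either compound and applies the disease up-regulation filter to the
    repressed set (diseased-vehicle vs healthy-vehicle contrast).
    """

    mode: str = "invitro"
    top_n: int = 25
    min_linear_fc: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("invitro", "invivo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.top_n < 1 or self.min_linear_fc <= 0 or not 0 < self.alpha <= 1:
            raise ValueError("invalid pipeline parameters")


def run_ti_pipeline(matrix: ExpressionMatrix,
                    config: TIPipelineConfig | None = None) -> TISummary:
    """Fold changes -> top-N selection -> mean log2 FCs -> relative TI.

    Induction is scored in the unstimulated stratum (compound vs vehicle),
    repression in the stimulated stratum (compound vs stimulated vehicle).
    """
    cfg = config or TIPipelineConfig()
    fc_ind = fold_change_table(matrix, stimulus="none")
    fc_rep = fold_change_table(matrix, stimulus="stimulated")
    ranked_by = "reference" if cfg.mode == "invitro" else "either"
    disease_filter = None
    if cfg.mode == "invivo":
        disease_filter = compute_fold_changes(
            matrix, "vehicle", versus="vehicle",
            stimulus="stimulated", versus_stimulus="none")
    induced = select_top_genes(fc_ind, "induced", ranked_by=ranked_by,
                               n=cfg.top_n, min_linear_fc=cfg.min_linear_fc,
                               alpha=cfg.alpha)
    repressed = select_top_genes(fc_rep, "repressed", ranked_by=ranked_by,
                                 n=cfg.top_n, min_linear_fc=cfg.min_linear_fc,
                                 alpha=cfg.alpha, disease_filter=disease_filter)
    summary = relative_ti(
        mean_log2_fc(fc_ind, induced, "reference", "induced"),
        mean_log2_fc(fc_rep, repressed, "reference", "repressed"),
        mean_log2_fc(fc_ind, induced, "test", "induced"),
        mean_log2_fc(fc_rep, repressed, "test", "repressed"),
    )
    summary.induced_probes = induced
    summary.repressed_probes = repressed
    return summary
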
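# Methods

`sgrmkit` quantifies how far a candidate selective glucocorticoid receptor
modulator (SGRM) dissociates transrepression (the anti-inflammatory arm of
glucocorticoid action) from transactivation (the arm linked to metabolic
side effects), relative to a reference full agonist such as prednisolone.
Four independent analysis stages share a synthetic-data generator that
plants known ground truth, so every stage is testable end to end without
external data.

## Relative therapeutic index from expression data

For each compound-versus-vehicle contrast, per-probe log2 fold changes are
the difference of mean log2 intensities; significance is a per-probe Welch
t-test with Benjamini–Hochberg adjustment across all probes (statsmodels).
With zero within-group variance the test degenerates and p is set to 0 for
a non-zero difference and 1 otherwise, so noise-free synthetic data behave
sensibly. Moderated (limma-style) statistics would borrow variance across
probes and are the natural refinement for real microarrays; the
dependency-free Welch test was chosen so the selection rules stay explicit,
and the thresholds (`min_linear_fc`, `alpha`) are configurable.

Gene-set selection takes the top N=25 probes by |log2FC| among those with
linear fold change ≥ 2 and adjusted p < 0.05 in the ranking compound, ties
broken by probe id ascending so the selection is deterministic. Two
ranking conventions are exposed because both occur in practice: `reference`
(rank purely by the reference agonist; default for the in-vitro mode) and
`either` (union of probes passing in either compound, ranked by the larger
|log2FC|; default for the in-vivo mode, where the repressed set is
additionally required to be ≥ 2-fold up-regulated by disease induction,
i.e. diseased-vehicle vs healthy-vehicle). Probe-level analysis is used
throughout; probes are not collapsed to genes.

With meanFC_I and meanFC_R the mean log2 fold changes over the induced and
repressed sets (repression stored as a positive magnitude):

    eff_ind = 100 · 2^(meanFC_I,test − meanFC_I,ref)   [%]
    eff_rep = 100 · 2^(meanFC_R,test − meanFC_R,ref)   [%]
    TI_rel  = 2^[(meanFC_I,ref − meanFC_R,ref) − (meanFC_I,test − meanFC_R,test)]

The two routes to TI_rel (exponentiated gap difference vs efficacy ratio)
are algebraically identical and asserted to agree to machine precision.
All intermediates are kept at full precision; reports round TI and
efficacies to one decimal for presentation. When a study reports per-assay
percent maximal efficacies instead of gene sets, `ti_from_efficacies`
computes mean(repression efficacies)/mean(induction efficacies).

## Dose–response

Responses follow a Hill curve `baseline + emax·c^s/(c^s + ec50^s)` fit by
bounded least squares (scipy) with ec50 parametrized on the log10 scale,
multi-start over five initial ec50 guesses spanning the tested range, and
ec50 bounded within [min(c)/100, max(c)·100]. The 3-parameter mode fixes
the slope at 1 (free: baseline, amplitude, ec50); the 4-parameter mode fits
the slope within [0.2, 10]. Inhibitor curves carry a negative amplitude and
report the midpoint as an IC50 in the same field. Flat data are flagged
`converged=False` rather than fit. Relative maximal efficacy is the ratio
of fitted plateau amplitudes (test/reference, in percent) — the
fitted-plateau convention, not the response at the highest tested
concentration.

## ChIP occupancy

Cluster sets are 0-based half-open intervals, sorted and non-overlapping
within a set. The containment fraction is the share of query intervals
overlapping any target interval by at least `min_overlap_bp` (default 1),
found by a sweep over the sorted target set. Occupancy comparison takes
pre-paired per-cluster counts (pairing across conditions is the caller's
choice of interval universe), computes `log2((ref+0.5)/(test+0.5))` — the
0.5 pseudocount keeps zero-count clusters finite — and tests mean = 0 with
a one-sample t-test; an all-equal vector returns p = 1 by convention.
Histograms use 0.25-log2-unit bins for reporting.

## MIDA flux model

The estimator commits to an explicit steady-state tracer-balance model of
fasted hepatic glucose metabolism with three pools — blood glucose, G6P and
UDP-glucose (sampled via urinary paracetamol-glucuronide) — and five fluxes
(µmol/kg/min): glucokinase v_GK, glucose-6-phosphatase v_G6Pase, glycogen
synthase v_GS, glycogen phosphorylase v_GP and de novo G6P synthesis v_GNG.
Assumptions: hepatic glycolytic G6P consumption is negligible in the
fasted state, closing the G6P balance (v_GK + v_GP + v_GNG = v_G6Pase +
v_GS); glycogen is an unlabeled reservoir on the experiment's time scale;
UDP-glucose→G6P backflux is neglected; label recycling through glucokinase
(blood glucose → G6P → blood glucose) *is* included. Tracers:
[U-13C]glucose (M6 into blood glucose), [2-13C]glycerol (M1 per triose;
newly made hexose draws two trioses, giving the binomial M1/M2 MIDA
signature), [1-2H]galactose (M1 into UDP-glucose).

Solving the label balances for plateau excess fractions g1/g2/g6 (blood
glucose) and u1/u2/u6 (glucuronide) and inverting gives closed forms, in
order: precursor enrichment p = 2r/(1+2r) from r = g2/g1 (recycling cancels
in the ratio); the glucokinase share x = v_GK/T from g2, g6 and the
glucuronide M2/M6 ratio; v_G6Pase from [U-13C]glucose dilution corrected
for recycling; v_GS from galactose dilution in the glucuronide M1; then
T = v_G6Pase + v_GS by closure and v_GK, v_GNG, v_GP from their shares.
Glucose balance (v_G6Pase − v_GK), glycogen balance (v_GS − v_GP) and the
metabolic clearance rate (turnover / blood glucose concentration) are
derived fields, so the balance identities hold by construction. Negative
closed-balance fluxes are reported with a warning, never clipped.

Natural-abundance correction solves `measured = A · excess` by non-negative
least squares, where A's column j is Binomial(6−j, 0.0107) shifted by j —
the probability of extra mass from natural 13C on the unlabeled carbons.
The 2H label is treated as a unit mass shift like 13C; columns of A sum
to 1 and excess fractions are renormalized to sum 1.

Plateau handling: steady state requires the total labeled excess (1 − M0)
to change by less than 2% (relative) between the final two hourly points;
only the final two points are averaged, because earlier points carry
approach-to-plateau bias even when inside the tolerance. With noisy data
the between-point change is itself noisy (sd ≈ √2·CV·M0/(1−M0) for assay
coefficient of variation CV), so when the caller states the assay CV the
gate widens to four of those standard deviations — a genuine ramp still
trips it, while steady-state noise does not.

The forward simulator (`simulate_mida`) implements the same model: plateau
enrichments from the linear label balances, an exponential approach
`1 − exp(−t/τ)` with τ = 0.7 h so hourly sampling over 6 h reaches plateau,
convolution with natural abundance, multiplicative Gaussian measurement
noise (`noise_sd` is the fractional sd per mass fraction), clipping to
[0, 1] with renormalization (logged). The estimator is validated by
self-consistency with this simulator — noiseless round trips recover all
five fluxes within 1%, and with 2% measurement noise the median relative
error per flux stays below 10% over randomized flux draws. This is an
internal-consistency claim about the committed model, not a claim of
numerical equivalence with other published MIDA formulations, whose exact
equations are not reproduced here.

## Synthetic-data generator

The expression generator plants {vehicle, reference, test} ×
{unstimulated, stimulated} with 3 replicates each (a typical microarray
design; the replicate count is configurable), i.i.d. Gaussian log2 noise
(default sd 0.2), 1000 probes with 25 induced and 25 repressed. Reference
effects default to the worked-example means (induced 3.61, repressed 1.76
log2 units), spread symmetrically over 0.5 log2 units so ranking is
non-degenerate while the planted mean is exact at zero noise. The test
compound applies a linear-scale efficacy fraction per probe:
FC_test = 1 + partiality·(FC_ref − 1). Repressed probes are switched on by
the stimulus (+2.5 log2), so the stimulated stratum doubles as the
diseased stratum for the in-vivo selection filter. Cluster counts are
negative binomial (size 10, base mean 50) on shared intervals; dose–response
noise is additive Gaussian. Flux draws for recovery studies sample
v_GK ∈ [20,60], v_G6Pase ∈ [100,200], v_GS ∈ [15,40], v_GP ∈ [30,80] with
v_GNG set by closure and required ≥ 20 — a plausible fasted-mouse range.
Tracer defaults follow the infusion protocol (0.54 ml/h of 13/160/33
µmol/ml glucose/glycerol/galactose into a 25 g mouse), giving M6 excess
near 4% and glucuronide M1 near 45%. All generators take explicit seeds
and never touch global random state.

What the generators do **not** emulate: probe-level intensity-dependent
variance and cross-hybridization in microarrays, read-level ChIP artifacts
(the pipeline starts after cluster calling), GC-MS fragment chemistry and
derivatization, and any physiological transient (the labeling model is a
steady-state plateau model by design). Passing tests therefore demonstrate
correctness of the statistics and of the committed models, not robustness
to those real-data features.

## Problem sizes and numerical conventions

Test and acceptance runs use 1000-probe matrices (3 replicates per
condition), 50-seed noise studies, 100-draw flux Monte-Carlos and cluster
sets of a few thousand intervals — sizes chosen so the full suite runs in
well under a minute while keeping Monte-Carlo standard errors far below
the tolerances being checked. Ties in gene ranking break by probe id;
TI/efficacy reporting rounds to one decimal; machine-precision identities
are asserted relatively (1e-12) because the TI spans orders of magnitude.

## Known limitations

* The Welch/BH differential test is anti-conservative at 3 replicates
  compared to moderated statistics; with noisy small-n data fewer than N
  probes may pass the filters (a warning is emitted and all passing probes
  are used).
* The MIDA estimator requires all three tracers and a reached plateau; it
  has no fallback for partial protocols.
* The efficacy fractions map reference to test fold changes linearly on
  the linear scale per probe; real partial agonists can be
  receptor-occupancy- and gene-context-dependent in more complex ways.
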
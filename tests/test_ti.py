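"""Therapeutic-index scoring: fold changes, selection, means, TI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sgrmkit as sk
from sgrmkit.ti import fold_change_table

from conftest import WORKED_MEANS, planted_expression_config


def _matrix(values: np.ndarray, compounds, stimuli=None, probes=None):
    n_probes, n_samples = values.shape
    probes = probes or [f"p{i}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    stimuli = stimuli or ["none"] * n_samples
    cond = pd.DataFrame({"compound": compounds, "stimulus": stimuli,
                         "disease": ["n/a"] * n_samples}, index=samples)
    return sk.ExpressionMatrix(pd.DataFrame(values, index=probes,
                                            columns=samples), cond)


class TestComputeFoldChanges:
    def test_identical_samples_give_zero_fold_change(self):
        vals = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        m = _matrix(vals, ["vehicle", "vehicle", "reference", "reference"])
        fc = sk.compute_fold_changes(m, "reference")
        assert np.allclose(fc["log2fc"], 0.0)
        assert np.allclose(fc["p_adj"], 1.0)

    def test_planted_effect_recovered_exactly_without_noise(self):
        vals = np.full((3, 4), 7.0)
        vals[0, 2:] += 3.61
        m = _matrix(vals, ["vehicle", "vehicle", "reference", "reference"])
        fc = sk.compute_fold_changes(m, "reference")
        assert fc["log2fc"].iloc[0] == pytest.approx(3.61, abs=1e-12)
        assert fc["p_adj"].iloc[0] == 0.0  # zero-variance, non-zero difference

    def test_bh_adjustment_matches_brute_force(self):
        rng = np.random.default_rng(42)
        vals = 7.0 + rng.normal(0, 0.5, (10, 6))
        m = _matrix(vals, ["vehicle"] * 3 + ["reference"] * 3)
        fc = sk.compute_fold_changes(m, "reference")
        p = fc["p"].to_numpy()
        # brute-force BH: sort, p*m/rank, cumulative min from the largest
        order = np.argsort(p)
        m_ = len(p)
        adj = p[order] * m_ / np.arange(1, m_ + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty_like(adj)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(fc["p_adj"], expected, atol=1e-12)

    def test_missing_condition_is_an_error(self):
        m = _matrix(np.zeros((2, 2)), ["vehicle", "vehicle"])
        with pytest.raises(ValueError, match="missing condition"):
            sk.compute_fold_changes(m, "reference")

    def test_single_replicate_sets_p_to_one_with_warning(self):
        vals = np.array([[7.0, 9.0]])
        m = _matrix(vals, ["vehicle", "reference"])
        with pytest.warns(UserWarning, match="fewer than 2 replicates"):
            fc = sk.compute_fold_changes(m, "reference")
        assert fc["p_adj"].iloc[0] == 1.0
        assert fc["log2fc"].iloc[0] == pytest.approx(2.0)


def _fc_frame(l2ref, l2test=None, p_ref=None, p_test=None, probes=None):
    l2ref = np.asarray(l2ref, float)
    n = l2ref.size
    return pd.DataFrame({
        "log2fc_ref": l2ref,
        "log2fc_test": l2ref if l2test is None else np.asarray(l2test, float),
        "p_adj_ref": np.zeros(n) if p_ref is None else np.asarray(p_ref),
        "p_adj_test": np.zeros(n) if p_test is None else np.asarray(p_test),
    }, index=probes or [f"p{i:03d}" for i in range(n)])


class TestSelectTopGenes:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(30, 100)
        fc = _fc_frame(rng.normal(0, 2, n), p_ref=rng.uniform(0, 0.1, n))
        got = sk.select_top_genes(fc, "induced", n=25)
        # oracle: filter then full sort on (-|l2fc|, id)
        passing = [(pid, row.log2fc_ref) for pid, row in fc.iterrows()
                   if row.log2fc_ref >= 1.0 and row.p_adj_ref < 0.05]
        expected = [pid for pid, _ in
                    sorted(passing, key=lambda t: (-abs(t[1]), t[0]))][:25]
        assert got == expected

    def test_ties_break_by_probe_id_ascending(self):
        fc = _fc_frame([2.0, 2.0, 2.0], probes=["pz", "pa", "pm"])
        assert sk.select_top_genes(fc, "induced", n=2) == ["pa", "pm"]

    def test_no_passing_probes_is_an_error(self):
        fc = _fc_frame([0.5, 0.7])  # linear FC < 2
        with pytest.raises(ValueError, match="no probes pass"):
            sk.select_top_genes(fc, "induced")

    def test_fewer_than_n_passing_warns_and_returns_all(self):
        fc = _fc_frame([3.0, 2.5, 0.1])
        with pytest.warns(UserWarning, match="only 2 probes"):
            got = sk.select_top_genes(fc, "induced", n=25)
        assert len(got) == 2

    def test_disease_filter_restricts_repressed_set(self):
        fc = _fc_frame([-3.0, -2.5])
        disease = pd.DataFrame({"log2fc": [2.0, 0.0]}, index=fc.index)
        got = sk.select_top_genes(fc, "repressed", n=25,
                                  disease_filter=disease)
        assert got == [fc.index[0]]

    def test_either_ranking_unions_and_uses_max_magnitude(self):
        fc = _fc_frame([1.2, 3.0], l2test=[2.8, 0.5])
        got = sk.select_top_genes(fc, "induced", ranked_by="either", n=2)
        assert got == [fc.index[1], fc.index[0]]


class TestMeanLog2FC:
    def test_repression_reported_as_positive_magnitude(self):
        fc = _fc_frame([-1.76] * 4)
        probes = list(fc.index)
        assert sk.mean_log2_fc(fc, probes, "reference", "repressed") == \
            pytest.approx(1.76)

    def test_single_zero_probe(self):
        fc = _fc_frame([0.0])
        assert sk.mean_log2_fc(fc, [fc.index[0]], "reference", "induced") == 0.0

    def test_equals_independent_summation(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 25)
        fc = _fc_frame(vals)
        got = sk.mean_log2_fc(fc, list(fc.index), "reference", "induced")
        acc = 0.0
        for v in vals:
            acc += v
        assert got == pytest.approx(acc / 25, rel=1e-12)

    def test_empty_probe_list_is_an_error(self):
        with pytest.raises(ValueError):
            sk.mean_log2_fc(_fc_frame([1.0]), [], "reference", "induced")


class TestRelativeTI:
    def test_worked_example_values(self):
        s = sk.relative_ti(**WORKED_MEANS)
        assert s.eff_ind_pct == pytest.approx(18.9, abs=0.05)
        assert s.eff_rep_pct == pytest.approx(48.3, abs=0.05)
        assert round(s.ti_rel, 1) == 2.5
        # unrounded intermediates give 2.549, not the 2.53 obtained from
        # rounding the induction-repression gap first
        assert s.ti_rel == pytest.approx(2.549, abs=5e-4)

    @given(a=st.floats(0, 10), b=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_reference_against_itself_scores_one(self, a, b):
        s = sk.relative_ti(a, b, a, b)
        assert s.ti_rel == pytest.approx(1.0, rel=1e-12)
        assert s.eff_ind_pct == pytest.approx(100.0, rel=1e-12)
        assert s.eff_rep_pct == pytest.approx(100.0, rel=1e-12)

    def test_two_formulas_agree_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            i_r, r_r, i_t, r_t = rng.uniform(0, 6, 4)
            s = sk.relative_ti(i_r, r_r, i_t, r_t)
            assert abs(s.ti_rel - s.eff_rep_pct / s.eff_ind_pct) < 1e-12 * s.ti_rel

    def test_ti_strictly_decreases_in_test_induction(self):
        tis = [sk.relative_ti(3.61, 1.76, i_t, 0.71).ti_rel
               for i_t in np.linspace(0.5, 3.5, 7)]
        assert all(a > b for a, b in zip(tis, tis[1:]))

    def test_negative_mean_is_rejected(self):
        with pytest.raises(ValueError):
            sk.relative_ti(3.61, -1.76, 1.21, 0.71)


class TestTIFromEfficacies:
    @pytest.mark.parametrize("rep, ind, expected", [
        ([68, 64], [39], 1.7),    # whole-blood cytokine panel
        ([98], [58], 1.7),        # smooth-muscle MCP-1 / SAA
        ([120], [55], 2.2),       # fibroblast MMP-1 / PAI-1
        ([87.7], [25.7], 3.4),    # arthritic-muscle microarray
        ([100], [100], 1.0),
    ])
    def test_printed_efficacy_ratios(self, rep, ind, expected):
        assert round(sk.ti_from_efficacies(rep, ind), 1) == expected

    def test_rejects_empty_or_nonpositive(self):
        with pytest.raises(ValueError):
            sk.ti_from_efficacies([], [50])
        with pytest.raises(ValueError):
            sk.ti_from_efficacies([50], [0])


class TestPipeline:
    def test_zero_noise_planted_matrix_reproduces_worked_example(
            self, planted_matrix_zero_noise):
        s = sk.run_ti_pipeline(planted_matrix_zero_noise)
        assert s.rounded() == {"eff_ind_pct": 18.9, "eff_rep_pct": 48.3,
                               "ti_rel": 2.5}
        assert len(s.induced_probes) == 25 and len(s.repressed_probes) == 25

    def test_full_efficacy_test_compound_scores_ti_one(self):
        cfg = sk.ExpressionSimConfig(noise_sd=0.0, partiality_ind=1.0,
                                     partiality_rep=1.0, seed=0)
        s = sk.run_ti_pipeline(sk.generate_expression(cfg))
        assert s.ti_rel == pytest.approx(1.0, rel=1e-9)

    def test_invariant_to_probe_and_sample_permutation(
            self, planted_matrix_zero_noise):
        m = planted_matrix_zero_noise
        rng = np.random.default_rng(5)
        perm_probes = rng.permutation(m.values.index)
        perm_samples = rng.permutation(m.values.columns)
        m2 = sk.ExpressionMatrix(m.values.loc[perm_probes, perm_samples],
                                 m.conditions)
        s1, s2 = sk.run_ti_pipeline(m), sk.run_ti_pipeline(m2)
        assert s1.ti_rel == pytest.approx(s2.ti_rel, rel=1e-12)
        assert sorted(s1.induced_probes) == sorted(s2.induced_probes)

    def test_invivo_mode_applies_disease_filter(self):
        m = sk.generate_expression(planted_expression_config())
        s = sk.run_ti_pipeline(m, sk.TIPipelineConfig(mode="invivo"))
        # repressed probes are stimulus-induced in the generator, so the
        # disease filter keeps them and the result matches the in-vitro run
        assert s.rounded()["ti_rel"] == 2.5

    def test_noisy_recovery_within_ten_percent_over_seeds(self):
        truth = sk.relative_ti(**WORKED_MEANS).ti_rel
        tis = []
        for seed in range(50):
            cfg = planted_expression_config(noise_sd=0.2, seed=seed)
            tis.append(sk.run_ti_pipeline(sk.generate_expression(cfg)).ti_rel)
        rel_err = np.abs(np.array(tis) - truth) / truth
        assert abs(np.mean(tis) - truth) / truth < 0.10
        assert np.median(rel_err) < 0.10
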
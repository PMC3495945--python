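import numpy as np
import pytest

import sgrmkit as sk

# Worked-example mean log2 fold changes (reference induced/repressed,
# test induced/repressed) used across the TI tests.
WORKED_MEANS = dict(meanFC_I_ref=3.61, meanFC_R_ref=1.76,
                    meanFC_I_test=1.21, meanFC_R_test=0.71)


def planted_expression_config(noise_sd: float = 0.0, seed: int = 0,
                              effect_spread: float = 0.0,
                              n_replicates: int = 3) -> sk.ExpressionSimConfig:
    """Expression simulation planted so the top-25 means equal WORKED_MEANS."""
    return sk.ExpressionSimConfig(
        ref_induction_log2fc=WORKED_MEANS["meanFC_I_ref"],
        ref_repression_log2fc=WORKED_MEANS["meanFC_R_ref"],
        partiality_ind=sk.partiality_from_log2fc(
            WORKED_MEANS["meanFC_I_ref"], WORKED_MEANS["meanFC_I_test"]),
        partiality_rep=sk.partiality_from_log2fc(
            -WORKED_MEANS["meanFC_R_ref"], -WORKED_MEANS["meanFC_R_test"]),
        noise_sd=noise_sd, effect_spread=effect_spread,
        n_replicates=n_replicates, seed=seed)


@pytest.fixture(scope="session")
def planted_matrix_zero_noise() -> sk.ExpressionMatrix:
    return sk.generate_expression(planted_expression_config())


@pytest.fixture(scope="session")
def default_flux_truth() -> sk.FluxTruth:
    return sk.FluxTruth()


def random_flux_truth(rng: np.random.Generator) -> sk.FluxTruth:
    """Physiologically plausible random flux draw honoring the G6P closure."""
    while True:
        v_GK = rng.uniform(20, 60)
        v_G6Pase = rng.uniform(100, 200)
        v_GS = rng.uniform(15, 40)
        v_GP = rng.uniform(30, 80)
        if v_G6Pase + v_GS - v_GK - v_GP >= 20:
            return sk.FluxTruth.with_closure(v_GK=v_GK, v_G6Pase=v_G6Pase,
                                             v_GS=v_GS, v_GP=v_GP)
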
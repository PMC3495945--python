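"""Partial-agonist dose-response: fit two Hill curves and compare plateaus.

Simulates a reference full agonist and a test compound with similar potency
(same EC50) but one third of the maximal response, then reports the fitted
EC50s and the test compound's relative maximal efficacy.
"""

import numpy as np

import sgrmkit as sk

concs = list(np.logspace(-1, 3, 9))  # nM
ref_tab = sk.generate_dose_response(ec50=26.0, emax=100.0, baseline=2.0,
                                    slope=1.0, concs=concs)
test_tab = sk.generate_dose_response(ec50=5.0, emax=32.0, baseline=2.0,
                                     slope=1.0, concs=concs)

ref = sk.fit_sigmoid(ref_tab["concentration"], ref_tab["response"], n_params=3)
test = sk.fit_sigmoid(test_tab["concentration"], test_tab["response"], n_params=3)

print(f"reference: EC50 {ref.ec50:.1f} nM, plateau amplitude {ref.emax:.1f}")
print(f"test:      EC50 {test.ec50:.1f} nM, plateau amplitude {test.emax:.1f}")
print(f"relative maximal efficacy: "
      f"{sk.relative_max_efficacy(test, ref):.0f}% of the reference")
print("\nSimilar (here better) potency with a much lower plateau is the "
      "signature of a partial agonist.")
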
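"""Recover a known release effectiveness from simulated experiments.

At the quadrat scale the generator's occupancy model is linear in the
per-species probabilities, so the expected CR/CE ratio equals the true
effectiveness e_true exactly.  This script simulates experiments at three
known e_true values and compares the pipeline's estimate with the truth.
"""

import numpy as np

import crce

for e_true in (0.2, 0.5, 0.8):
    params = crce.CommunityParams(e_true=e_true)
    survey = crce.simulate_survey(params, seed=123)
    blocks = crce.full_blocks(survey.design)
    pts = crce.block_metrics(
        crce.richness_at_scale(survey, "quadrat", "focal"), blocks
    )
    estimate = float(np.mean([m.effectiveness for m in pts if m.defined]))
    truth = crce.expected_crce(params, "quadrat", "valley").effectiveness
    print(f"e_true={e_true:.1f}: estimated {estimate:.3f} "
          f"(analytic expectation {truth:.3f}, n={len(pts)} blocks)")

print("\nEstimates track the truth to within Monte-Carlo error; at coarser"
      " scales the union of quadrats makes the estimand deviate from e_true,"
      " which crce.expected_crce() quantifies.")
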
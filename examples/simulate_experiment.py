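"""Simulate a two-sided removal experiment and inspect its design.

Builds the default synthetic survey — two habitats, per habitat three full
blocks (control / competitor-removal / releasing) and four partial blocks
(control / releasing), 5 clusters x 5 quadrats per plot — and prints the
inferred design summary.
"""

import crce

params = crce.CommunityParams()  # e_true = 0.4, 60 forbs, 15 grasses
survey = crce.simulate_survey(params, seed=7)

print(survey.design.to_json())
print(f"\n{len(survey.records)} records "
      f"({int(survey.records['present'].sum())} presences)")
print("The design summary shows 34 plots in 14 blocks; the 6 'full' blocks"
      " (all three treatments) are the ones the CR-CE analysis can use.")
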
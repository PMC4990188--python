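"""Place experimental blocks in CR-CE space and estimate effectiveness.

For each full block and spatial scale: competitive exclusion CE (removal
minus control mean focal richness), competitive release CR (releasing minus
control), and their ratio — the effectiveness of the releasing factor.
Then the compensation-line regression of CR on CE per scale.
"""

import crce

survey = crce.simulate_survey(crce.CommunityParams(), seed=7)
blocks = crce.full_blocks(survey.design)

all_metrics = []
for scale in ("quadrat", "cluster", "plot"):
    rich = crce.richness_at_scale(survey, scale, "focal")
    pts = crce.block_metrics(rich, blocks)
    all_metrics.extend(pts)

    fit = crce.fit_compensation_line(pts, scale=scale)
    print(f"\n{scale}: slope={fit.slope:.3f} (SE {fit.slope_se:.3f}), "
          f"intercept={fit.intercept:.3f}, R^2={fit.r_squared:.2f}, "
          f"p(slope=1)={fit.p_slope_one:.3f}")
    for habitat in survey.design.habitats:
        s = crce.effectiveness_summary(pts, habitat=habitat, scale=scale)
        print(f"  {habitat}: effectiveness {s.mean:.2f} +/- {s.se:.2f} "
              f"(n={s.n} blocks)")

below = crce.count_below_compensation_line(all_metrics)
print(f"\n{below} of {len(all_metrics)} block points lie strictly below the "
      "compensation line y = x: the releasing factor restores only part of "
      "the excluded richness (partial compensation; the generator's true "
      "quadrat-scale effectiveness is 0.4).")
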
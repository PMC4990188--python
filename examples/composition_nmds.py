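"""Composition analysis: Jaccard dissimilarity and NMDS at the cluster scale.

Uses only clusters from full blocks (45 observation units per habitat:
3 blocks x 3 treatments x 5 clusters), computes pairwise Jaccard
dissimilarities among focal-species assemblages, ordinates them with NMDS,
and checks whether the releasing treatment's composition centroid sits
between control and removal.
"""

import crce

survey = crce.simulate_survey(crce.CommunityParams(), seed=7)
units = crce.select_composition_units(survey)

for habitat, sub in units.items():
    d = crce.jaccard_dissimilarity(
        dict(zip(sub["label"], sub["species"])), drop_empty=True
    )
    result = crce.nmds(d, k=2, n_starts=20, seed=42)
    centroid_d = crce.group_centroid_distances(
        d, dict(zip(sub["label"], sub["treatment"]))
    )
    intermediate = crce.releasing_is_intermediate_in_dissimilarity(
        d, dict(zip(sub["label"], sub["treatment"]))
    )
    print(f"\n{habitat}: {len(sub)} units, NMDS stress-1 = {result.stress:.3f}")
    for pair, dist in sorted(centroid_d.items()):
        print(f"  centroid distance {pair[0]} - {pair[1]}: {dist:.3f}")
    print(f"  releasing centroid intermediate between control and removal: "
          f"{intermediate}")

print("\nA smaller releasing-control than removal-control centroid distance"
      " means the releasing factor shifts composition only part of the way"
      " toward the competitor-free state.")
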
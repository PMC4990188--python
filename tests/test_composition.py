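import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

import crce

from conftest import make_table

species_set = st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6)


def test_jaccard_closed_forms():
    d = crce.jaccard_dissimilarity(
        {"u1": {"A", "B"}, "u2": {"A", "B"}, "u3": {"C"}, "u4": {"B", "C"}}
    )
    m = dict(zip(d.labels, d.values))
    v = d.values
    idx = {l: i for i, l in enumerate(d.labels)}
    assert v[idx["u1"], idx["u2"]] == 0.0  # identical sets
    assert v[idx["u1"], idx["u3"]] == 1.0  # disjoint sets
    assert v[idx["u1"], idx["u4"]] == pytest.approx(2 / 3)  # {A,B} vs {B,C}


def test_empty_sets_rejected_unless_dropped():
    units = {"u1": {"A"}, "u2": set(), "u3": {"B"}}
    with pytest.raises(ValueError, match="u2"):
        crce.jaccard_dissimilarity(units)
    d = crce.jaccard_dissimilarity(units, drop_empty=True)
    assert d.labels == ("u1", "u3")


@given(st.lists(species_set, min_size=2, max_size=8))
def test_jaccard_metric_properties(sets):
    d = crce.jaccard_dissimilarity({f"u{i}": s for i, s in enumerate(sets)})
    v = d.values
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 0)
    assert (v >= 0).all() and (v <= 1).all()
    n = v.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert v[i, j] <= v[i, k] + v[k, j] + 1e-12


def test_two_units_embed_exactly():
    d = crce.DissimilarityMatrix(("a", "b"), np.array([[0, 0.7], [0.7, 0]]))
    res = crce.nmds(d, k=2, n_starts=3, seed=0)
    assert res.stress == 0.0
    assert np.linalg.norm(res.coords[0] - res.coords[1]) == pytest.approx(0.7)


def test_three_equidistant_units_form_equilateral_triangle():
    """Geometric oracle: 3 equidistant units embed with zero stress in k=2
    and the recomputed pairwise distances are all equal."""
    v = np.full((3, 3), 0.6)
    np.fill_diagonal(v, 0.0)
    res = crce.nmds(crce.DissimilarityMatrix(("a", "b", "c"), v), k=2,
                    n_starts=5, seed=1)
    assert res.stress == pytest.approx(0.0, abs=1e-4)
    dists = pdist(res.coords)
    assert np.allclose(dists, dists[0], rtol=1e-2)


def test_stress_history_non_increasing(rng):
    """Majorization property: within the best start, stress-1 never rises."""
    sets = [set(rng.choice(list("abcdefghijkl"), size=4, replace=False))
            for _ in range(10)]
    d = crce.jaccard_dissimilarity({f"u{i}": s for i, s in enumerate(sets)})
    res = crce.nmds(d, k=2, n_starts=4, seed=5)
    diffs = np.diff(res.stress_history)
    assert (diffs <= 1e-8).all()


def test_rank_preserving_euclidean_input_attains_tiny_stress(rng):
    """Points already lying in the plane, with dissimilarity = a monotone
    transform of Euclidean distance, embed with stress <= 1e-3."""
    pts = rng.uniform(size=(9, 2))
    eu = pdist(pts)
    transformed = squareform(np.sqrt(eu / eu.max()))  # rank-preserving
    d = crce.DissimilarityMatrix(
        tuple(f"p{i}" for i in range(9)), transformed
    )
    res = crce.nmds(d, k=2, n_starts=10, seed=2)
    assert res.stress <= 1e-3


def test_nmds_is_deterministic_given_seed(rng):
    sets = [set(rng.choice(list("abcdefghij"), size=3, replace=False))
            for _ in range(8)]
    d = crce.jaccard_dissimilarity({f"u{i}": s for i, s in enumerate(sets)})
    r1 = crce.nmds(d, n_starts=3, seed=9)
    r2 = crce.nmds(d, n_starts=3, seed=9)
    assert r1.stress == r2.stress
    assert np.array_equal(r1.coords, r2.coords)


def test_nmds_stress_invariant_under_unit_permutation(rng):
    sets = {f"u{i}": set(rng.choice(list("abcdefghij"), size=3, replace=False))
            for i in range(8)}
    d = crce.jaccard_dissimilarity(sets)
    perm = list(reversed(list(sets)))
    dp = crce.jaccard_dissimilarity({k: sets[k] for k in perm})
    s1 = crce.nmds(d, n_starts=8, seed=4).stress
    s2 = crce.nmds(dp, n_starts=8, seed=4).stress
    assert s1 == pytest.approx(s2, abs=5e-3)


def test_nmds_matches_sklearn_stress(rng):
    """Independent route: sklearn's nonmetric MDS reaches a comparable
    Kruskal stress-1 on the same matrix."""
    from sklearn.manifold import MDS

    sets = [set(rng.choice(list("abcdefghijkl"), size=4, replace=False))
            for _ in range(12)]
    d = crce.jaccard_dissimilarity({f"u{i}": s for i, s in enumerate(sets)})
    ours = crce.nmds(d, k=2, n_starts=10, seed=3)
    ref = MDS(
        n_components=2,
        metric=False,
        dissimilarity="precomputed",
        normalized_stress=True,
        n_init=10,
        random_state=0,
        max_iter=500,
    ).fit(np.asarray(d.values))
    assert ours.stress == pytest.approx(ref.stress_, abs=0.05)


def test_invalid_matrix_rejected():
    with pytest.raises(ValueError):
        crce.DissimilarityMatrix(("a", "b"), np.array([[0, 1], [0.5, 0]]))
    with pytest.raises(ValueError):
        crce.nmds(
            crce.DissimilarityMatrix(("a", "b"), np.array([[0, 1], [1, 0]])),
            k=0,
        )


def test_case_study_design_yields_45_units_per_habitat(default_sim):
    units = crce.select_composition_units(default_sim)
    assert set(units) == {"slope", "valley"}
    for sub in units.values():
        assert len(sub) == 45  # 3 blocks x 3 treatments x 5 clusters
        assert sub["treatment"].value_counts().tolist() == [15, 15, 15]


def test_single_full_block_yields_15_units(toy_survey):
    units = crce.select_composition_units(toy_survey)
    assert len(units["valley"]) == 15


def test_no_full_blocks_errors():
    table = make_table(
        [
            ("valley", "B1", "control", "P1", 1, 1, "spA", "focal"),
            ("valley", "B1", "grazing", "P2", 1, 1, "spA", "focal"),
        ]
    )
    with pytest.raises(ValueError, match="full block"):
        crce.select_composition_units(crce.from_frame(table))


def test_empty_clusters_counted_but_droppable():
    rows = []
    for treatment in ("control", "grass-removal", "grazing"):
        for cl in range(1, 6):
            present = 0 if (treatment, cl) == ("control", 1) else 1
            rows.append(
                ("valley", "B1", treatment, f"P-{treatment}", cl, 1, "spA",
                 "focal", present)
            )
    survey = crce.from_frame(make_table(rows))
    kept = crce.select_composition_units(survey)["valley"]
    assert len(kept) == 15
    assert sum(len(s) == 0 for s in kept["species"]) == 1
    dropped = crce.select_composition_units(survey, drop_empty=True)["valley"]
    assert len(dropped) == 14


def test_centroid_distances_in_dissimilarity_space_match_euclidean(rng):
    """On Euclidean-embeddable data the dissimilarity-space centroid
    distance equals the coordinate-space centroid distance."""
    a = rng.normal(loc=0.0, size=(20, 3))
    b = rng.normal(loc=1.0, size=(20, 3))
    pts = np.vstack([a, b])
    labels = tuple(f"p{i}" for i in range(40))
    d = crce.DissimilarityMatrix(labels, squareform(pdist(pts)))
    groups = {f"p{i}": ("a" if i < 20 else "b") for i in range(40)}
    dist = crce.group_centroid_distances(d, groups)
    expected = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    assert dist[("a", "b")] == pytest.approx(expected, rel=1e-9)


def test_valley_releasing_centroid_is_intermediate(default_sim):
    units = crce.select_composition_units(default_sim)["valley"]
    d = crce.jaccard_dissimilarity(
        dict(zip(units["label"], units["species"])), drop_empty=True
    )
    treatments = dict(zip(units["label"], units["treatment"]))
    assert crce.releasing_is_intermediate_in_dissimilarity(d, treatments)
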
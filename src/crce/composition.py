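"""Composition analysis: Jaccard dissimilarity and nonmetric MDS.

The composition of focal-species assemblages is compared at the cluster
scale (1 m^2): quadrats hold too few species and plots give too few
observation units.  Only clusters from full blocks enter the analysis so
the three treatments are equally represented.  Pairwise Jaccard
dissimilarity, d(A, B) = 1 - |A n B| / |A u B|, feeds a nonmetric
multidimensional scaling (NMDS): an iterative stress-majorization (SMACOF)
with monotone (isotonic) regression of configuration distances on the
dissimilarities, minimising Kruskal's stress-1 over several random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .survey import Survey, full_blocks


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise Jaccard dissimilarities with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(np.asarray(self.values, dtype=float), checks=False)


@dataclass(frozen=True)
class OrdinationResult:
    """Best-of-starts NMDS configuration.

    ``stress`` is Kruskal's stress-1 of the best start;
    ``stress_history`` its per-iteration trajectory.
    """

    labels: tuple[str, ...]
    coords: np.ndarray = field(repr=False)
    stress: float = float("nan")
    n_starts: int = 1
    seed: int | None = None
    converged: bool = False
    stress_history: tuple[float, ...] = ()


def jaccard_dissimilarity(
    units: dict[str, set] | pd.Series, drop_empty: bool = False
) -> DissimilarityMatrix:
    """Pairwise Jaccard dissimilarities among species presence sets.

    ``units`` maps unit labels to species sets.  Empty sets make the index
    undefined for any pair involving them; they raise unless
    ``drop_empty=True``, in which case they are removed first.
    """
    if isinstance(units, pd.Series):
        units = dict(units)
    empties = [label for label, s in units.items() if not s]
    if empties:
        if not drop_empty:
            raise ValueError(
                f"empty species set(s) {empties}; Jaccard is undefined for "
                "empty pairs (pass drop_empty=True to exclude them)"
            )
        units = {label: s for label, s in units.items() if s}
    if len(units) < 2:
        raise ValueError("need at least 2 non-empty units")

    labels = tuple(units)
    species = sorted(set().union(*units.values()))
    index = {sp: i for i, sp in enumerate(species)}
    incidence = np.zeros((len(labels), len(species)), dtype=bool)
    for row, label in enumerate(labels):
        for sp in units[label]:
            incidence[row, index[sp]] = True
    mat = squareform(pdist(incidence, metric="jaccard"))
    return DissimilarityMatrix(labels=labels, values=mat)


def select_composition_units(
    survey: Survey, group: str = "focal", drop_empty: bool = False
) -> dict[str, pd.DataFrame]:
    """Cluster-scale presence sets from full blocks, per habitat.

    Returns for each habitat a DataFrame with one row per cluster of every
    full block (the case-study design yields 3 blocks x 3 treatments x 5
    clusters = 45 units per habitat): lineage columns, a ``label``, and the
    frozenset ``species`` present in the cluster's quadrats.  Empty
    clusters are retained (they count as observation units) unless
    ``drop_empty=True``.
    """
    blocks = full_blocks(survey.design)
    if not blocks:
        raise ValueError("no full blocks: every block lacks at least one treatment")
    records = survey.records
    in_full = np.array(
        [(h, b) in set(blocks) for h, b in zip(records["habitat"], records["block"])]
    )
    sel = records[records["group"].eq(group).to_numpy() & in_full]
    keys = ["habitat", "block", "treatment", "plot", "cluster"]
    roster = sel[keys].drop_duplicates()
    present = sel[sel["present"]]
    sets = (
        present.groupby(keys, sort=False)["species"]
        .agg(lambda s: frozenset(s))
        .rename("species")
    )
    table = roster.merge(sets, how="left", left_on=keys, right_index=True)
    table["species"] = table["species"].apply(
        lambda s: s if isinstance(s, frozenset) else frozenset()
    )
    table["label"] = [
        f"{b}/{t}/{p}/c{c}"
        for b, t, p, c in zip(
            table["block"], table["treatment"], table["plot"], table["cluster"]
        )
    ]
    out: dict[str, pd.DataFrame] = {}
    for habitat in sorted(table["habitat"].unique()):
        sub = table[table["habitat"] == habitat].sort_values(keys).reset_index(drop=True)
        if drop_empty:
            sub = sub[sub["species"].apply(len) > 0].reset_index(drop=True)
        out[habitat] = sub
    return out


def _classical_mds(full: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering start configuration."""
    n = full.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (full**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    pos = np.clip(eigval[order], 0, None)
    return eigvec[:, order] * np.sqrt(pos)


def _smacof_single(
    delta: np.ndarray, x0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, list[float], bool]:
    """One SMACOF start: monotone regression + Guttman transform until the
    stress-1 decrease falls below tol."""
    n = x0.shape[0]
    iso = IsotonicRegression(increasing=True)
    x = x0.copy()
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(x)
        dsq = float(np.sum(d**2))
        if dsq == 0:  # fully collapsed configuration; restart-worthy but rare
            break
        # disparities: ties in delta are averaged within tie blocks by PAVA
        dhat = iso.fit_transform(delta, d)
        stress = float(np.sqrt(np.sum((d - dhat) ** 2) / dsq))
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # normalise disparities to a fixed scale so the configuration does
        # not drift toward zero (stress-1 is scale invariant)
        dhat = dhat * np.sqrt(delta.size / np.sum(dhat**2))
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        b = squareform(-ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    final = history[-1] if history else float("nan")
    return x, final, history, converged


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling of a dissimilarity matrix.

    Runs ``n_starts`` SMACOF starts (the first from a classical-MDS
    configuration, the rest random) and returns the configuration with the
    lowest Kruskal stress-1.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    full = np.asarray(d.values, dtype=float)
    delta = d.condensed()
    n = full.shape[0]
    if n == 2:  # any positive dissimilarity embeds exactly on a segment
        coords = np.zeros((2, k))
        coords[1, 0] = delta[0]
        return OrdinationResult(
            labels=d.labels, coords=coords, stress=0.0, n_starts=n_starts,
            seed=seed, converged=True, stress_history=(0.0,),
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for start in range(n_starts):
        if start == 0:
            x0 = _classical_mds(full, k)
            if np.allclose(x0, 0):
                x0 = rng.uniform(-1, 1, size=(n, k))
        else:
            x0 = rng.uniform(-1, 1, size=(n, k))
        x, stress, history, converged = _smacof_single(delta, x0, tol, max_iter)
        if not history:
            continue
        if best is None or stress < best[0]:
            best = (stress, x, history, converged)
    if best is None:
        raise RuntimeError("all NMDS starts collapsed; cannot ordinate")
    stress, coords, history, converged = best
    coords = coords - coords.mean(axis=0)  # center for presentational stability
    return OrdinationResult(
        labels=d.labels,
        coords=coords,
        stress=stress,
        n_starts=n_starts,
        seed=seed,
        converged=converged,
        stress_history=tuple(history),
    )


def treatment_centroids(
    result: OrdinationResult, treatments: pd.Series | dict[str, str]
) -> dict[str, np.ndarray]:
    """Mean ordination coordinates per treatment group.

    ``treatments`` maps unit label -> treatment.  Used to check the
    qualitative configuration claim that the releasing-factor centroid sits
    between control and removal.
    """
    mapping = dict(treatments)
    out: dict[str, list[np.ndarray]] = {}
    for label, xy in zip(result.labels, result.coords):
        out.setdefault(mapping[label], []).append(xy)
    return {t: np.mean(v, axis=0) for t, v in out.items()}


def releasing_is_intermediate(centroids: dict[str, np.ndarray]) -> bool:
    """True when the releasing centroid is closer to control than removal is.

    distance(releasing, control) < distance(removal, control): the
    releasing factor shifts composition only part of the way toward the
    competitor-free state.
    """
    d_rel = float(np.linalg.norm(centroids["releasing"] - centroids["control"]))
    d_rem = float(np.linalg.norm(centroids["removal"] - centroids["control"]))
    return d_rel < d_rem


def group_centroid_distances(
    d: DissimilarityMatrix, groups: pd.Series | dict[str, str]
) -> dict[tuple[str, str], float]:
    """Between-group centroid distances computed in dissimilarity space.

    For groups a, b the squared centroid separation is

        mean d^2(a, b)  -  (mean within-a d^2 + mean within-b d^2) / 2,

    with within-group means taken over all ordered pairs (zero diagonal
    included) and the result clamped at zero.  On Euclidean-embeddable
    dissimilarities this equals the squared distance between group
    centroids exactly; it is the standard way to compare group centroids
    without trusting a low-dimensional ordination (which, at appreciable
    stress, need not preserve centroid geometry).  Keys are sorted (a, b)
    tuples.
    """
    mapping = dict(groups)
    labels = list(d.labels)
    idx: dict[str, list[int]] = {}
    for i, label in enumerate(labels):
        idx.setdefault(mapping[label], []).append(i)
    sq = np.asarray(d.values, dtype=float) ** 2

    def within(g: str) -> float:
        ii = idx[g]
        block = sq[np.ix_(ii, ii)]
        return float(block.sum() / (len(ii) ** 2))

    out: dict[tuple[str, str], float] = {}
    names = sorted(idx)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            between = float(sq[np.ix_(idx[a], idx[b])].mean())
            val = between - 0.5 * (within(a) + within(b))
            out[(a, b)] = float(np.sqrt(max(val, 0.0)))
    return out


def releasing_is_intermediate_in_dissimilarity(
    d: DissimilarityMatrix, treatments: pd.Series | dict[str, str]
) -> bool:
    """Intermediate-position check on the dissimilarity-space centroids."""
    dist = group_centroid_distances(d, treatments)

    def get(a: str, b: str) -> float:
        return dist[tuple(sorted((a, b)))]

    return get("releasing", "control") < get("removal", "control")
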
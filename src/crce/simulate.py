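"""Synthetic two-sided removal experiments with known ground truth.

The generator emulates the layout of a grazing / grass-removal biodiversity
experiment: two habitats, blocks holding either all three treatments
(control, competitor removal, releasing factor) or just control +
releasing, and 5 clusters x 5 quadrats per plot.  Occupancy is independent
Bernoulli per (species, quadrat) with treatment-specific probabilities:

* removal:    p = pi            (baseline occupancy, competitors absent)
* control:    p = pi * c        (c in [0, 1], competitive survival multiplier)
* releasing:  p = pi * (c + e_true * (1 - c))

so ``e_true`` interpolates releasing between control (e_true = 0) and
removal (e_true = 1), and at the quadrat scale the expected effectiveness
CR/CE equals e_true exactly (everything is linear in p).  At cluster and
plot scales richness is a union over m quadrats, E[S] = sum_i
(1 - (1 - p_i)^m), so the estimand departs from e_true — the analytic
expectations below are the oracle for that regime.

Competitor species have fixed occupancy unaffected by treatment except
removal (where they are absent), mirroring a releasing factor that
suppresses competitors without eliminating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import Survey, from_frame

QUADRATS_PER_UNIT = {"quadrat": 1, "cluster": 5, "plot": 25}


@dataclass(frozen=True)
class CommunityParams:
    """Generative parameters of the synthetic experiment.

    ``pi`` and ``c`` may be scalars or per-focal-species arrays.  Habitat
    multipliers scale ``pi`` and ``c`` per habitat (products must stay in
    [0, 1]); the default slope habitat has sparser occupancy and weaker
    competition than the valley, echoing a low- vs. high-productivity
    contrast.
    """

    n_focal: int = 60
    n_competitor: int = 15
    pi: float | np.ndarray = 0.15
    #: None = heterogeneous suppression, linspace(0.05, 0.65) across focal
    #: species (mean 0.35); species differ in competitive tolerance, which
    #: is what gives treatments distinct composition, not just richness
    c: float | np.ndarray | None = None
    e_true: float = 0.4
    pi_competitor: float = 0.45
    habitat_pi_mult: Mapping[str, float] = field(
        default_factory=lambda: {"valley": 1.0, "slope": 0.6}
    )
    habitat_c_mult: Mapping[str, float] = field(
        default_factory=lambda: {"valley": 1.0, "slope": 1.5}
    )
    n_full_blocks: int = 3
    n_partial_blocks: int = 4
    clusters_per_plot: int = 5
    quadrats_per_cluster: int = 5
    seed: int | None = None

    @property
    def habitats(self) -> tuple[str, ...]:
        return tuple(self.habitat_pi_mult)

    def focal_pi(self, habitat: str) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.pi, dtype=float) * self.habitat_pi_mult[habitat],
            (self.n_focal,),
        )

    def focal_c(self, habitat: str) -> np.ndarray:
        base = (
            np.linspace(0.05, 0.65, self.n_focal)
            if self.c is None
            else np.asarray(self.c, dtype=float)
        )
        return np.broadcast_to(base * self.habitat_c_mult[habitat], (self.n_focal,))

    def focal_occupancy(self, habitat: str, treatment: str) -> np.ndarray:
        """Per-focal-species quadrat occupancy under a treatment."""
        pi, c = self.focal_pi(habitat), self.focal_c(habitat)
        if treatment == "removal":
            p = pi
        elif treatment == "control":
            p = pi * c
        elif treatment == "releasing":
            p = pi * (c + self.e_true * (1.0 - c))
        else:
            raise ValueError(f"unknown treatment {treatment!r}")
        _check_prob(p, f"focal occupancy ({habitat}, {treatment})")
        return p

    def competitor_occupancy(self, habitat: str, treatment: str) -> np.ndarray:
        p = np.zeros(self.n_competitor) if treatment == "removal" else np.full(
            self.n_competitor, float(self.pi_competitor)
        )
        _check_prob(p, "competitor occupancy")
        return p

    def validate(self) -> "CommunityParams":
        if not 0.0 <= self.e_true <= 1.0:
            raise ValueError("e_true must be in [0, 1]")
        for habitat in self.habitats:
            for treatment in ("control", "removal", "releasing"):
                self.focal_occupancy(habitat, treatment)
                self.competitor_occupancy(habitat, treatment)
        return self


def _check_prob(p: np.ndarray, what: str) -> None:
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{what} outside [0, 1]")


def _block_layout(params: CommunityParams) -> list[tuple[str, str, tuple[str, ...]]]:
    """(habitat, block, treatments) rows; full blocks first, then partial."""
    layout = []
    for habitat in params.habitats:
        for i in range(params.n_full_blocks):
            layout.append(
                (habitat, f"B{i + 1}", ("control", "removal", "releasing"))
            )
        for i in range(params.n_partial_blocks):
            layout.append(
                (
                    habitat,
                    f"B{params.n_full_blocks + i + 1}",
                    ("control", "releasing"),
                )
            )
    return layout


def simulate_survey(params: CommunityParams, seed: int | None = None) -> Survey:
    """Draw one synthetic survey in the canonical long-format layout.

    Emits a dense table (every species x quadrat with a 0/1 presence), so
    empty sampling units and never-observed species stay registered.
    Identical seeds give identical record sets.
    """
    params.validate()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    focal_names = [f"forb{i + 1:03d}" for i in range(params.n_focal)]
    comp_names = [f"grass{i + 1:03d}" for i in range(params.n_competitor)]
    species = focal_names + comp_names
    groups = ["focal"] * params.n_focal + ["competitor"] * params.n_competitor

    n_quad = params.clusters_per_plot * params.quadrats_per_cluster
    cluster_ids = np.repeat(
        np.arange(1, params.clusters_per_plot + 1), params.quadrats_per_cluster
    )
    quadrat_ids = np.tile(
        np.arange(1, params.quadrats_per_cluster + 1), params.clusters_per_plot
    )

    frames = []
    for habitat, block, treatments in _block_layout(params):
        for treatment in treatments:
            p = np.concatenate(
                [
                    params.focal_occupancy(habitat, treatment),
                    params.competitor_occupancy(habitat, treatment),
                ]
            )
            draws = rng.random((len(species), n_quad)) < p[:, None]
            plot = f"{habitat[:1].upper()}{block}-{treatment}"
            frames.append(
                pd.DataFrame(
                    {
                        "habitat": habitat,
                        "block": block,
                        "treatment": treatment,
                        "plot": plot,
                        "cluster": np.tile(cluster_ids, len(species)),
                        "quadrat": np.tile(quadrat_ids, len(species)),
                        "species": np.repeat(species, n_quad),
                        "group": np.repeat(groups, n_quad),
                        "present": draws.ravel(),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return from_frame(table)


def expected_richness(
    params: CommunityParams,
    scale: str,
    treatment: str,
    habitat: str = "valley",
    group: str = "focal",
) -> float:
    """Expected species richness of one sampling unit under independence.

    A unit of m quadrats misses species i with probability (1 - p_i)^m, so
    E[S] = sum_i (1 - (1 - p_i)^m); m = 1, 5, 25 for quadrat, cluster, plot.
    """
    if scale not in QUADRATS_PER_UNIT:
        raise ValueError(f"unknown scale {scale!r}")
    m = QUADRATS_PER_UNIT[scale]
    if group == "focal":
        p = params.focal_occupancy(habitat, treatment)
    elif group == "competitor":
        p = params.competitor_occupancy(habitat, treatment)
    elif group == "all":
        p = np.concatenate(
            [
                params.focal_occupancy(habitat, treatment),
                params.competitor_occupancy(habitat, treatment),
            ]
        )
    else:
        raise ValueError(f"unknown group {group!r}")
    return float(np.sum(1.0 - (1.0 - p) ** m))


@dataclass(frozen=True)
class ExpectedCRCE:
    ce: float
    cr: float
    effectiveness: float  # NaN when CE = 0


def expected_crce(
    params: CommunityParams, scale: str, habitat: str = "valley"
) -> ExpectedCRCE:
    """Analytic CE, CR and effectiveness at a scale (focal group).

    At the quadrat scale effectiveness equals ``e_true`` exactly; at
    coarser scales the union nonlinearity pulls it away from e_true, and
    this function is the reference for what the estimator should recover.
    """
    e_rem = expected_richness(params, scale, "removal", habitat)
    e_con = expected_richness(params, scale, "control", habitat)
    e_rel = expected_richness(params, scale, "releasing", habitat)
    ce = e_rem - e_con
    cr = e_rel - e_con
    eff = cr / ce if ce != 0 else float("nan")
    return ExpectedCRCE(ce=ce, cr=cr, effectiveness=eff)


def with_params(params: CommunityParams, **changes) -> CommunityParams:
    """Functional update helper (frozen dataclass)."""
    return replace(params, **changes)
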
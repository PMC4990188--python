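"""Log-response-ratio effect sizes for treatment vs. control richness.

LRR = log(S_treatment / S_control), with S the mean focal richness under a
given combination of treatment, habitat and scale.  Positive values mean
the treatment raised richness.  The natural log is the default (the
convention of the effect-size literature); base 10 is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd

from .errors import UndefinedEffectError
from .richness import SCALES, richness_at_scale, plot_mean_richness
from .survey import Survey, full_blocks

_LOG = {"e": math.log, "10": math.log10, "2": math.log2}


@dataclass(frozen=True)
class EffectSize:
    habitat: str
    scale: str
    treatment: str
    lrr: float
    base: str = "e"


def log_response_ratio(
    s_treatment: float, s_control: float, base: str = "e"
) -> float:
    """log(S_treatment / S_control) in the requested base.

    Both means must be positive; a nonpositive mean makes the ratio
    meaningless and raises :class:`UndefinedEffectError` rather than
    returning +/-inf.
    """
    if base not in _LOG:
        raise ValueError(f"unsupported log base {base!r}; use one of {sorted(_LOG)}")
    if s_treatment <= 0 or s_control <= 0:
        raise UndefinedEffectError(
            f"log response ratio undefined for nonpositive means "
            f"(treatment={s_treatment}, control={s_control})"
        )
    return _LOG[base](s_treatment / s_control)


def effect_size_table(
    survey: Survey,
    base: str = "e",
    group: str = "focal",
    scales: tuple[str, ...] = SCALES,
) -> pd.DataFrame:
    """LRR of each non-control treatment per habitat x scale.

    Treatment means are computed over the full blocks only, so that the
    removal and releasing contrasts are anchored on the same blocks as the
    CR-CE analysis.
    """
    blocks = set(full_blocks(survey.design))
    rows: list[EffectSize] = []
    for scale in scales:
        per_plot = plot_mean_richness(richness_at_scale(survey, scale, group))
        per_plot = per_plot[
            [(h, b) in blocks for h, b in zip(per_plot["habitat"], per_plot["block"])]
        ]
        means = per_plot.groupby(["habitat", "treatment"])["mean_richness"].mean()
        for habitat in sorted(per_plot["habitat"].unique()):
            s_control = float(means[(habitat, "control")])
            for treatment in ("removal", "releasing"):
                rows.append(
                    EffectSize(
                        habitat=habitat,
                        scale=scale,
                        treatment=treatment,
                        lrr=log_response_ratio(
                            float(means[(habitat, treatment)]), s_control, base
                        ),
                        base=base,
                    )
                )
    return pd.DataFrame([asdict(r) for r in rows])
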
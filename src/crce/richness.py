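"""Species richness per sampling unit at the three nested spatial scales.

Richness at a unit is the number of species present anywhere within it, so
cluster and plot richness are counts over the *union* of their nested
quadrats, never averages of sub-unit counts.  This is the only reading under
which richness is non-decreasing with area.  Sampling units in which no
species of the requested group was recorded appear with S = 0 rather than
being dropped; dropping them would bias treatment means upward.
"""

from __future__ import annotations

import pandas as pd

from .survey import Survey

SCALES = ("quadrat", "cluster", "plot")
GROUP_CHOICES = ("focal", "competitor", "all")

#: design lineage columns identifying one sampling unit at each scale
UNIT_KEYS = {
    "quadrat": ["habitat", "block", "treatment", "plot", "cluster", "quadrat"],
    "cluster": ["habitat", "block", "treatment", "plot", "cluster"],
    "plot": ["habitat", "block", "treatment", "plot"],
}


def richness_at_scale(
    survey: Survey | pd.DataFrame, scale: str, group: str = "focal"
) -> pd.DataFrame:
    """Tidy table of species richness per sampling unit.

    Parameters
    ----------
    survey
        A validated :class:`~crce.survey.Survey` or a canonical record frame.
    scale
        ``quadrat`` (0.04 m^2), ``cluster`` (1 m^2, union of 5 quadrats) or
        ``plot`` (100 m^2, union of 25 quadrats).
    group
        ``focal``, ``competitor`` or ``all``.

    Returns
    -------
    DataFrame with the unit's lineage columns plus ``richness``.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if group not in GROUP_CHOICES:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUP_CHOICES}")

    records = survey.records if isinstance(survey, Survey) else survey
    keys = UNIT_KEYS[scale]
    # the unit roster comes from all rows (absences included) so that empty
    # units are represented
    units = records[keys].drop_duplicates()

    present = records[records["present"]]
    if group != "all":
        present = present[present["group"] == group]
    counts = (
        present.groupby(keys, sort=False)["species"].nunique().rename("richness")
    )
    out = units.merge(counts, how="left", left_on=keys, right_index=True)
    out["richness"] = out["richness"].fillna(0).astype(int)
    return out.sort_values(keys).reset_index(drop=True)


def plot_mean_richness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plot arithmetic mean of unit richness.

    For a quadrat- or cluster-scale table this averages over the plot's 25
    quadrats (or 5 clusters); for a plot-scale table it is the identity.
    Empty units contribute zeros to the mean.
    """
    keys = UNIT_KEYS["plot"]
    out = (
        table.groupby(keys, sort=False)["richness"]
        .mean()
        .rename("mean_richness")
        .reset_index()
    )
    return out.sort_values(keys).reset_index(drop=True)
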
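"""Reading, validation and indexing of hierarchical presence-absence survey tables.

The expected layout is a long-format CSV in which every row is one
(sampling unit, species) observation carrying its full design lineage:
habitat, block, treatment, plot, cluster, quadrat, species and species
group.  Treatment and group vocabularies are configurable; internally they
are canonicalised to ``control`` / ``removal`` / ``releasing`` and
``focal`` / ``competitor`` so that the framework is not tied to any one
releasing factor (grazing, predation, disturbance, ...).

Rows may carry an explicit 0/1 ``present`` column (dense dialect) or omit
it, in which case every row is a presence assertion.  Absence rows are
retained: they register the sampling unit and the species even when the
species was never observed there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, SchemaError

#: canonical treatment labels: no releasing factor and competitors present /
#: competitors removed (still no releasing factor) / releasing factor present.
TREATMENTS = ("control", "removal", "releasing")

#: canonical species-group labels.
GROUPS = ("focal", "competitor")

REQUIRED_COLUMNS = (
    "habitat",
    "block",
    "treatment",
    "plot",
    "cluster",
    "quadrat",
    "species",
    "group",
)

#: vocabulary accepted out of the box (case-insensitive); extend via value_map.
DEFAULT_TREATMENT_MAP = {
    "control": "control",
    "removal": "removal",
    "grass-removal": "removal",
    "grass removal": "removal",
    "grass_removal": "removal",
    "releasing": "releasing",
    "grazing": "releasing",
}

DEFAULT_GROUP_MAP = {
    "focal": "focal",
    "forb": "focal",
    "forbs": "focal",
    "competitor": "competitor",
    "grass": "competitor",
    "grasses": "competitor",
}

#: the three nested spatial scales of the sampling design, with unit areas.
SCALE_AREAS_M2 = {"quadrat": 0.04, "cluster": 1.0, "plot": 100.0}


@dataclass(frozen=True)
class SurveyDesign:
    """Summary of the experimental design inferred from a survey table.

    A *full block* contains all three treatments; a *partial block* lacks
    the competitor-removal treatment (control and releasing only).
    """

    habitats: tuple[str, ...]
    #: (habitat, block) -> frozenset of treatments present in that block
    treatments_by_block: Mapping[tuple[str, str], frozenset[str]]
    #: plot -> (habitat, block, treatment); one row per plot
    plot_table: pd.DataFrame = field(repr=False)
    n_plots: int = 0
    n_clusters: int = 0
    n_quadrats: int = 0
    scales: tuple[tuple[str, float], ...] = tuple(SCALE_AREAS_M2.items())

    @property
    def n_blocks(self) -> int:
        return len(self.treatments_by_block)

    def to_dict(self) -> dict:
        return {
            "habitats": list(self.habitats),
            "n_blocks": self.n_blocks,
            "n_plots": self.n_plots,
            "n_clusters": self.n_clusters,
            "n_quadrats": self.n_quadrats,
            "scales": {name: area for name, area in self.scales},
            "blocks": {
                f"{habitat}/{block}": sorted(treats)
                for (habitat, block), treats in sorted(
                    self.treatments_by_block.items()
                )
            },
            "full_blocks": [f"{h}/{b}" for h, b in full_blocks(self)],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class Survey:
    """Validated survey records plus the inferred design.

    ``records`` is a canonical-column DataFrame (one row per observation,
    boolean ``present``); ``species_groups`` maps every registered species
    -- observed or not -- to its group.
    """

    records: pd.DataFrame
    design: SurveyDesign
    species_groups: pd.Series  # index: species, values: focal|competitor


def _canonicalise_values(
    series: pd.Series, mapping: Mapping[str, str], what: str
) -> pd.Series:
    lookup = {str(k).strip().lower(): v for k, v in mapping.items()}
    normalised = series.astype(str).str.strip().str.lower()
    unknown = sorted(set(normalised[~normalised.isin(lookup)]))
    if unknown:
        raise ValueError(
            f"unknown {what} label(s) {unknown}; extend value_map to cover them"
        )
    return normalised.map(lookup)


def _coerce_present(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip().str.lower()
    truthy = {"1", "true", "t", "yes", "y"}
    falsy = {"0", "false", "f", "no", "n", "0.0"}
    bad = sorted(set(as_str[~as_str.isin(truthy | falsy)]))
    if bad:
        raise ValueError(f"uninterpretable presence value(s): {bad}")
    return as_str.isin(truthy)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check design invariants on a canonical-column record table.

    Raises :class:`ConsistencyError` if a plot maps to more than one
    (habitat, block, treatment) combination or a species appears in two
    groups; returns the table unchanged otherwise.
    """
    lineage = records[["plot", "habitat", "block", "treatment"]].drop_duplicates()
    dup = lineage["plot"][lineage["plot"].duplicated()]
    if not dup.empty:
        raise ConsistencyError(
            f"plot(s) {sorted(set(dup))} map to more than one "
            "(habitat, block, treatment) combination"
        )
    groups = records[["species", "group"]].drop_duplicates()
    dup = groups["species"][groups["species"].duplicated()]
    if not dup.empty:
        raise ConsistencyError(
            f"species {sorted(set(dup))} assigned to more than one group"
        )
    return records


def infer_design(records: pd.DataFrame) -> SurveyDesign:
    """Summarise the experimental design implied by validated records."""
    plot_table = (
        records[["plot", "habitat", "block", "treatment"]]
        .drop_duplicates()
        .sort_values(["habitat", "block", "treatment", "plot"])
        .reset_index(drop=True)
    )
    treatments_by_block = {
        (habitat, block): frozenset(sub["treatment"])
        for (habitat, block), sub in plot_table.groupby(
            ["habitat", "block"], sort=True
        )
    }
    return SurveyDesign(
        habitats=tuple(sorted(records["habitat"].unique())),
        treatments_by_block=treatments_by_block,
        plot_table=plot_table,
        n_plots=int(plot_table["plot"].nunique()),
        n_clusters=int(records[["plot", "cluster"]].drop_duplicates().shape[0]),
        n_quadrats=int(
            records[["plot", "cluster", "quadrat"]].drop_duplicates().shape[0]
        ),
    )


def from_frame(
    table: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    treatment_map: Mapping[str, str] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> Survey:
    """Canonicalise, validate and index an in-memory survey table.

    ``column_map`` maps canonical column names to the names used in the
    table (e.g. ``{"releasing": ..., "quadrat": "Quadrate"}``).
    ``treatment_map`` / ``group_map`` extend the default label vocabulary.
    """
    table = table.copy()
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("habitat", "block", "plot", "cluster", "quadrat", "species"):
        records[col] = records[col].astype(str).str.strip()
    records["treatment"] = _canonicalise_values(
        records["treatment"],
        {**DEFAULT_TREATMENT_MAP, **(treatment_map or {})},
        "treatment",
    )
    records["group"] = _canonicalise_values(
        records["group"], {**DEFAULT_GROUP_MAP, **(group_map or {})}, "group"
    )
    if "present" in table.columns:
        records["present"] = _coerce_present(table["present"])
    else:
        records["present"] = True

    validate_records(records)
    species_groups = (
        records[["species", "group"]]
        .drop_duplicates()
        .set_index("species")["group"]
        .sort_index()
    )
    return Survey(records=records, design=infer_design(records), species_groups=species_groups)


def read_survey_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    treatment_map: Mapping[str, str] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> Survey:
    """Read a long-format presence-absence CSV and validate it.

    Returns a :class:`Survey` bundling the canonical records, the inferred
    :class:`SurveyDesign` and the species register.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return from_frame(
        pd.read_csv(path, dtype=str),
        column_map=column_map,
        treatment_map=treatment_map,
        group_map=group_map,
    )


def write_survey_table(survey: Survey | pd.DataFrame, path: str | Path) -> None:
    """Write canonical records to CSV (round-trips through read_survey_table)."""
    records = survey.records if isinstance(survey, Survey) else survey
    out = records.copy()
    out["present"] = out["present"].astype(int)
    out.to_csv(path, index=False)


def full_blocks(design: SurveyDesign) -> list[tuple[str, str]]:
    """(habitat, block) pairs whose block contains all three treatments.

    Blocks lacking the competitor-removal treatment cannot anchor a CE
    estimate and are excluded from the CR-CE analysis.  Order is
    deterministic: sorted by habitat then block label.
    """
    required = frozenset(TREATMENTS)
    return sorted(
        key for key, treats in design.treatments_by_block.items()
        if required <= treats
    )
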
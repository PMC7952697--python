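"""Record types, CSV input/output and counting conventions.

Copulating pairs are stored one *record* per (active, passive)
combination.  A heterosexual pair (or a pair with an ITC partner) is one
record of weight 1.  A male-male pair, in which the active partner could
not be determined in the field, is split into the two possible
combinations, each of weight 0.5 and sharing a ``pair_id`` — so record
weights always sum to the number of physical pairs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .taxonomy import (
    ITC,
    MALE,
    FEMALE,
    MatingClass,
    PartnerCategory,
    Stratum,
    conspecific_female_species,
)

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "site_year",
    "level",
    "active_species",
    "active_status",
    "passive_species",
    "passive_status",
    "weight",
    "active_height_mm",
    "passive_height_mm",
    "pair_id",
    "quadrat_id",
]

CENSUS_COLUMNS = [
    "site_year",
    "level",
    "quadrat_id",
    "species",
    "status",
    "older_than_one_year",
    "infected",
    "shell_height_mm",
]


@dataclass(frozen=True)
class CopulationRecord:
    """One weighted observation of an (active, passive) mating combination."""

    stratum: Stratum
    active: PartnerCategory
    passive: PartnerCategory
    weight: float = 1.0
    active_height_mm: float | None = None
    passive_height_mm: float | None = None
    pair_id: str = ""
    quadrat_id: str = ""

    def __post_init__(self) -> None:
        if self.active.status != MALE:
            raise ValueError("active partner must be a male")
        if self.weight not in (0.5, 1.0):
            raise ValueError(f"weight must be 0.5 or 1.0, got {self.weight}")
        if self.weight == 0.5 and self.passive.status != MALE:
            raise ValueError("0.5-weight records arise only from male-male pairs")
        for h in (self.active_height_mm, self.passive_height_mm):
            if h is not None and not h > 0:
                raise ValueError("shell heights must be positive")


@dataclass(frozen=True)
class IndividualRecord:
    """One censused snail from a 0.04 m^2 quadrat."""

    stratum: Stratum
    quadrat_id: str
    category: PartnerCategory
    older_than_one_year: bool = True
    infected: bool = False
    shell_height_mm: float = 1.0

    def __post_init__(self) -> None:
        if not self.shell_height_mm > 0:
            raise ValueError("shell_height_mm must be positive")


def expand_male_male(
    stratum: Stratum,
    male_a: PartnerCategory,
    male_b: PartnerCategory,
    pair_id: str,
    height_a_mm: float | None = None,
    height_b_mm: float | None = None,
    quadrat_id: str = "",
) -> tuple[CopulationRecord, CopulationRecord]:
    """Split an unordered male-male pair into its two 0.5-weight records.

    The active partner of a male-male pair cannot be determined in the
    field, so both orderings are recorded at half weight.
    """
    if male_a.status != MALE or male_b.status != MALE:
        raise ValueError("expand_male_male requires two male partners")
    common = dict(stratum=stratum, weight=0.5, pair_id=pair_id, quadrat_id=quadrat_id)
    return (
        CopulationRecord(
            active=male_a, passive=male_b,
            active_height_mm=height_a_mm, passive_height_mm=height_b_mm, **common,
        ),
        CopulationRecord(
            active=male_b, passive=male_a,
            active_height_mm=height_b_mm, passive_height_mm=height_a_mm, **common,
        ),
    )


def classify_pair(record: CopulationRecord) -> MatingClass:
    """Assign a record to one of the four mating classes.

    Potentially productive matings are those with a mature conspecific
    female; for 1.5-row males both *L. saxatilis* and *L. arcana*
    females count as conspecific.
    """
    passive = record.passive
    if passive.status == ITC:
        return MatingClass.immature_or_castrated
    if passive.status == MALE:
        return MatingClass.male_male
    if passive.species in conspecific_female_species(record.active):
        return MatingClass.conspecific_female
    return MatingClass.heterospecific_female


# ---------------------------------------------------------------------------
# CSV input/output


def _parse_float(token: str) -> float | None:
    return None if token in ("", "NA", "nan") else float(token)


def read_pair_records(path: str | Path) -> list[CopulationRecord]:
    """Read copulating-pair records from a tidy CSV file.

    Category tokens are validated against the taxonomy; a malformed row
    raises ``ValueError`` naming the row number.
    """
    records: list[CopulationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"site_year", "level", "active_species", "active_status",
                   "passive_species", "passive_status", "weight"} - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                weight = float(row["weight"])
                records.append(
                    CopulationRecord(
                        stratum=Stratum(row["site_year"], row["level"]),
                        active=PartnerCategory.from_tokens(
                            row["active_species"], row["active_status"]
                        ),
                        passive=PartnerCategory.from_tokens(
                            row["passive_species"], row["passive_status"]
                        ),
                        weight=weight,
                        active_height_mm=_parse_float(row.get("active_height_mm", "")),
                        passive_height_mm=_parse_float(row.get("passive_height_mm", "")),
                        pair_id=row.get("pair_id", ""),
                        quadrat_id=row.get("quadrat_id", ""),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {i}: {exc}") from exc
    return records


def write_pair_records(records: Iterable[CopulationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIR_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.stratum.site_year,
                    r.stratum.level,
                    r.active.species_token,
                    r.active.status,
                    r.passive.species_token,
                    r.passive.status,
                    f"{r.weight:g}",
                    "" if r.active_height_mm is None else f"{r.active_height_mm:g}",
                    "" if r.passive_height_mm is None else f"{r.passive_height_mm:g}",
                    r.pair_id,
                    r.quadrat_id,
                ]
            )


def read_census(path: str | Path) -> list[IndividualRecord]:
    """Read quadrat-census individuals from a tidy CSV file."""
    out: list[IndividualRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    IndividualRecord(
                        stratum=Stratum(row["site_year"], row["level"]),
                        quadrat_id=row["quadrat_id"],
                        category=PartnerCategory.from_tokens(
                            row["species"], row["status"]
                        ),
                        older_than_one_year=row["older_than_one_year"].lower()
                        in ("true", "1", "yes"),
                        infected=row["infected"].lower() in ("true", "1", "yes"),
                        shell_height_mm=float(row["shell_height_mm"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {i}: {exc}") from exc
    return out


def write_census(census: Iterable[IndividualRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CENSUS_COLUMNS)
        for r in census:
            writer.writerow(
                [
                    r.stratum.site_year,
                    r.stratum.level,
                    r.quadrat_id,
                    r.category.species_token,
                    r.category.status,
                    str(r.older_than_one_year).lower(),
                    str(r.infected).lower(),
                    f"{r.shell_height_mm:g}",
                ]
            )


# ---------------------------------------------------------------------------
# Tabulation and summaries


def pairs_to_frame(records: Sequence[CopulationRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection (one row per record)."""
    return pd.DataFrame(
        {
            "site_year": [r.stratum.site_year for r in records],
            "level": [r.stratum.level for r in records],
            "stratum": [str(r.stratum) for r in records],
            "active": [r.active.label for r in records],
            "passive": [r.passive.label for r in records],
            "active_species": [r.active.species for r in records],
            "active_group": [r.active.group for r in records],
            "passive_species": [r.passive.species for r in records],
            "passive_status": [r.passive.status for r in records],
            "weight": [r.weight for r in records],
            "mating_class": [classify_pair(r).value for r in records],
            "active_height_mm": [r.active_height_mm for r in records],
            "passive_height_mm": [r.passive_height_mm for r in records],
            "pair_id": [r.pair_id for r in records],
        }
    )


def tabulate_pairs(
    records: Sequence[CopulationRecord], stratum: Stratum
) -> pd.DataFrame:
    """Observed weighted copulation frequencies for one stratum.

    Returns a passive-category x active-category matrix of summed
    weights; the grand total equals the number of pairs collected in the
    stratum.
    """
    frame = pairs_to_frame([r for r in records if r.stratum == stratum])
    if frame.empty:
        return pd.DataFrame(dtype=float)
    return (
        frame.pivot_table(
            index="passive", columns="active", values="weight",
            aggfunc="sum", fill_value=0.0,
        )
        .astype(float)
    )


def summary_counts(records: Sequence[CopulationRecord]) -> dict:
    """Aggregate weighted counts over a record collection.

    A male-male pair contributes 1 to the male-male pair count (its two
    0.5 halves); it is heterospecific when its two males differ in
    species (the 1.5-row category counting as its own).
    """
    frame = pairs_to_frame(records)
    total = float(frame["weight"].sum())
    by_class = frame.groupby("mating_class")["weight"].sum().to_dict()
    mm = frame[frame["passive_status"] == MALE]
    hetero_mm = float(
        mm.loc[mm["active_species"] != mm["passive_species"], "weight"].sum()
    )
    females = frame[frame["passive_status"] == FEMALE]
    by_active = {}
    for species, g in females.groupby("active_species"):
        consp = float(
            g.loc[g["mating_class"] == MatingClass.conspecific_female.value, "weight"].sum()
        )
        het = g[g["mating_class"] == MatingClass.heterospecific_female.value]
        by_active[species] = {
            "mature_female_pairs": float(g["weight"].sum()),
            "conspecific": consp,
            "heterospecific": float(het["weight"].sum()),
            "heterospecific_by_species": het.groupby("passive_species")["weight"]
            .sum()
            .to_dict(),
        }
    return {
        "total_pairs": total,
        "pairs_by_site_year": frame.groupby("site_year")["weight"].sum().to_dict(),
        "pairs_by_stratum": frame.groupby("stratum")["weight"].sum().to_dict(),
        "pairs_by_class": {c.value: float(by_class.get(c.value, 0.0)) for c in MatingClass},
        "pairs_by_active_group": frame.groupby("active_group")["weight"].sum().to_dict(),
        "heterosexual_pairs": float(females["weight"].sum()),
        "heterosexual_heterospecific_pairs": float(
            by_class.get(MatingClass.heterospecific_female.value, 0.0)
        ),
        "male_male_pairs": float(mm["weight"].sum()),
        "male_male_heterospecific_pairs": hetero_mm,
        "itc_pairs": float(by_class.get(MatingClass.immature_or_castrated.value, 0.0)),
        "mature_female_pairs_by_active_species": by_active,
    }
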
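"""Category taxonomy for *Littorina* (*Neritrema*) mating analyses.

Five sympatric species are studied: *L. saxatilis*, *L. arcana* and
*L. compressa* (the "saxatilis" cryptic-species group) and *L. obtusata*
and *L. fabalis* (the "obtusata" group).  Males of the saxatilis/arcana
complex with an intermediate penial-gland arrangement (1.5 rows,
presumed hybrids) form their own active-male category.  Immature or
trematode-castrated (ITC) snails cannot be identified to species and are
recorded at species-group resolution only.

Every copulating pair has an *active* partner (the penis-inserting male)
and a *passive* partner (any category).  Analyses are stratified by
site-year and intertidal level ("stratum").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

SAXATILIS_GROUP = "saxatilis_group"
OBTUSATA_GROUP = "obtusata_group"
GROUPS = (SAXATILIS_GROUP, OBTUSATA_GROUP)

#: species token -> cryptic species group
SPECIES_GROUP = {
    "saxatilis": SAXATILIS_GROUP,
    "saxatilis_1p5": SAXATILIS_GROUP,
    "arcana": SAXATILIS_GROUP,
    "compressa": SAXATILIS_GROUP,
    "obtusata": OBTUSATA_GROUP,
    "fabalis": OBTUSATA_GROUP,
}
SPECIES = tuple(SPECIES_GROUP)
#: species that occur as passive females (the 1.5-row category is male-only)
FEMALE_SPECIES = ("saxatilis", "arcana", "compressa", "obtusata", "fabalis")

MALE = "male"
FEMALE = "female"
ITC = "immature_or_castrated"
STATUSES = (MALE, FEMALE, ITC)

LEVELS = ("upper", "lower")


class MatingClass(str, enum.Enum):
    """Outcome class of one copulation record, from the active male's side."""

    conspecific_female = "conspecific_female"
    heterospecific_female = "heterospecific_female"
    male_male = "male_male"
    immature_or_castrated = "immature_or_castrated"


@dataclass(frozen=True, order=True)
class Stratum:
    """A site-year x intertidal-level analysis unit, e.g. ``DZ2015/upper``."""

    site_year: str
    level: str

    def __post_init__(self) -> None:
        if not self.site_year:
            raise ValueError("site_year must be non-empty")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")

    def __str__(self) -> str:
        return f"{self.site_year}/{self.level}"


@dataclass(frozen=True, order=True)
class PartnerCategory:
    """A partner type: species group, species (or ``unknown`` for ITC), status.

    Invariants enforced on construction:

    * ITC individuals have ``species == "unknown"`` but a known group;
    * the 1.5-row category exists only as a male;
    * group is consistent with species for identified individuals.
    """

    group: str
    species: str
    status: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == ITC:
            if self.species != "unknown":
                raise ValueError("ITC individuals carry species='unknown'")
        else:
            if self.species not in SPECIES:
                raise ValueError(f"unknown species {self.species!r}")
            if SPECIES_GROUP[self.species] != self.group:
                raise ValueError(
                    f"species {self.species!r} is not in group {self.group!r}"
                )
            if self.species == "saxatilis_1p5" and self.status != MALE:
                raise ValueError("the 1.5-row category occurs only as a male")

    # -- constructors -------------------------------------------------
    @classmethod
    def male(cls, species: str) -> "PartnerCategory":
        return cls(SPECIES_GROUP[species], species, MALE)

    @classmethod
    def female(cls, species: str) -> "PartnerCategory":
        return cls(SPECIES_GROUP[species], species, FEMALE)

    @classmethod
    def itc(cls, group: str) -> "PartnerCategory":
        return cls(group, "unknown", ITC)

    @classmethod
    def from_tokens(cls, species_token: str, status_token: str) -> "PartnerCategory":
        """Build a category from CSV tokens.

        ITC rows carry the *group* token (``saxatilis_group`` /
        ``obtusata_group``) in the species column, because ITC snails are
        identifiable only to group.
        """
        if status_token == ITC:
            if species_token not in GROUPS:
                raise ValueError(
                    "ITC rows must carry a group token in the species column, "
                    f"got {species_token!r}"
                )
            return cls.itc(species_token)
        if species_token not in SPECIES:
            raise ValueError(f"unknown species token {species_token!r}")
        return cls(SPECIES_GROUP[species_token], species_token, status_token)

    # -- serialization ------------------------------------------------
    @property
    def species_token(self) -> str:
        """Token written to the species CSV column (group token for ITC)."""
        return self.group if self.status == ITC else self.species

    @property
    def label(self) -> str:
        """Stable human-readable label, e.g. ``saxatilis_female``."""
        if self.status == ITC:
            return f"{self.group}_itc"
        return f"{self.species}_{self.status}"


def parse_label(label: str) -> PartnerCategory:
    """Inverse of :attr:`PartnerCategory.label`."""
    if label.endswith("_itc"):
        return PartnerCategory.itc(label[: -len("_itc")])
    species, _, status = label.rpartition("_")
    if status not in (MALE, FEMALE):
        raise ValueError(f"cannot parse category label {label!r}")
    return PartnerCategory.from_tokens(species, status)


def conspecific_female_species(active: PartnerCategory) -> tuple[str, ...]:
    """Female species counted as conspecific for an active male.

    For 1.5-row males both *L. saxatilis* and *L. arcana* females count
    as conspecific (the category is a presumed hybrid of the two).
    """
    if active.status != MALE:
        raise ValueError("conspecificity is defined for active males")
    if active.species == "saxatilis_1p5":
        return ("saxatilis", "arcana")
    return (active.species,)


#: canonical ordering of all passive categories (Table-style layout)
ALL_PASSIVE_CATEGORIES = tuple(
    [PartnerCategory.female(s) for s in FEMALE_SPECIES]
    + [PartnerCategory.male(s) for s in SPECIES]
    + [PartnerCategory.itc(g) for g in GROUPS]
)

#: canonical ordering of active-male categories
ALL_ACTIVE_CATEGORIES = tuple(PartnerCategory.male(s) for s in SPECIES)
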
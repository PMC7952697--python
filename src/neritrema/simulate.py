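"""Synthetic censuses and copulating-pair datasets.

The generator emulates the sampling design of the field study: multi-
species quadrat censuses (0.04 m^2 frames, Poisson counts per quadrat)
with species-specific densities, sex ratios, immature/castrated
fractions and log-normal shell-height distributions, and a mating
process in which an active male is drawn according to copulatory
activity and abundance and a passive partner according to population
composition, a species-preference matrix and an optional Gaussian
size-assortment kernel:

    w(passive) ∝ composition x Psi[active sp., passive cat.]
                 x exp(-beta (h_active - h_passive - delta)^2)

With a uniform preference matrix, beta = 0 and a male-male rate
matching the population's male share, the process reduces exactly to
the random-mating null model, which makes the generator the test bed
for every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CopulationRecord, IndividualRecord, expand_male_male
from .taxonomy import FEMALE, MALE, PartnerCategory, SPECIES_GROUP, Stratum


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species census parameters for one stratum.

    density
        mean adults per 0.04 m^2 quadrat (Poisson).
    sex_ratio
        fraction of mature adults that are female.
    itc_fraction
        fraction of adults that are immature or trematode-castrated
        (identifiable only to species group).
    size_log_mean, size_log_sd
        log-normal shell-height parameters (log mm).
    """

    density: float
    sex_ratio: float = 0.55
    itc_fraction: float = 0.2
    size_log_mean: float = math.log(8.0)
    size_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.sex_ratio <= 1 or not 0 <= self.itc_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.density < 0:
            raise ValueError("density must be non-negative")


@dataclass(frozen=True)
class StratumConfig:
    stratum: Stratum
    species: dict[str, SpeciesParams]
    n_quadrats: int = 10
    n_pairs: int = 1000
    #: probability a generated pair is an unordered male-male pair;
    #: None means "match the population's male share" (null-model regime)
    male_male_rate: float | None = None
    #: copulatory-activity weight per male species (default 1)
    activity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Full synthetic-study configuration.

    ``preference`` maps active male species -> passive category label ->
    non-negative weight (missing entries default to 1; an all-zero row
    for a drawn active male is an error).  ``size_beta`` (per mm^2) and
    ``size_delta`` (mm) parameterize the Gaussian size-assortment
    kernel; beta = 0 disables size effects.
    """

    strata: tuple[StratumConfig, ...]
    preference: dict[str, dict[str, float]] = field(default_factory=dict)
    size_beta: float = 0.0
    size_delta: float = 0.0
    seed: int = 0


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> list[IndividualRecord]:
    """Draw a quadrat census with the configured composition."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: list[IndividualRecord] = []
    for scfg in config.strata:
        for q in range(1, scfg.n_quadrats + 1):
            quadrat = f"{scfg.stratum.site_year}-{scfg.stratum.level}-Q{q:02d}"
            for species, params in scfg.species.items():
                n = rng.poisson(params.density)
                for _ in range(n):
                    height = float(
                        rng.lognormal(params.size_log_mean, params.size_log_sd)
                    )
                    u = rng.random()
                    if u < params.itc_fraction:
                        cat = PartnerCategory.itc(SPECIES_GROUP[species])
                    elif rng.random() < params.sex_ratio and species != "saxatilis_1p5":
                        cat = PartnerCategory.female(species)
                    else:
                        cat = PartnerCategory.male(species)
                    out.append(
                        IndividualRecord(
                            stratum=scfg.stratum,
                            quadrat_id=quadrat,
                            category=cat,
                            older_than_one_year=True,
                            infected=False,
                            shell_height_mm=height,
                        )
                    )
    return out


def _psi(config: SimulationConfig, active_species: str, passive_label: str) -> float:
    return config.preference.get(active_species, {}).get(passive_label, 1.0)


def simulate_matings(
    population: Sequence[IndividualRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[CopulationRecord]:
    """Generate copulating-pair records from a census.

    For each pair the active male species is drawn with probability
    proportional to activity weight x male abundance and the individual
    uniformly within species.  With probability ``male_male_rate`` the
    passive partner is a male (emitting two 0.5-weight records);
    otherwise a female or ITC individual, weighted by composition,
    preference and the size kernel.  Passive partners are drawn with
    replacement across pairs (the species are polygamous).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    records: list[CopulationRecord] = []
    for scfg in config.strata:
        adults = [
            r for r in population if r.stratum == scfg.stratum and r.older_than_one_year
        ]
        if not adults:
            raise ValueError(f"empty population for stratum {scfg.stratum}")
        labels = np.array([r.category.label for r in adults])
        heights = np.array([r.shell_height_mm for r in adults])
        quadrats = np.array([r.quadrat_id for r in adults])
        species_arr = np.array([r.category.species for r in adults])
        status = np.array([r.category.status for r in adults])

        male_idx = np.flatnonzero(status == MALE)
        nonmale_idx = np.flatnonzero(status != MALE)
        if len(male_idx) == 0:
            raise ValueError(f"no mature males in stratum {scfg.stratum}")
        mm_rate = (
            len(male_idx) / len(adults)
            if scfg.male_male_rate is None
            else scfg.male_male_rate
        )
        male_species = sorted(set(species_arr[male_idx]))
        sp_weights = np.array(
            [
                scfg.activity.get(s, 1.0) * np.sum(species_arr[male_idx] == s)
                for s in male_species
            ],
            dtype=float,
        )
        if sp_weights.sum() <= 0:
            raise ValueError("no active males with positive activity weight")
        sp_probs = sp_weights / sp_weights.sum()
        males_by_species = {
            s: male_idx[species_arr[male_idx] == s] for s in male_species
        }

        # per-species preference weights over the whole adult pool
        psi_vec = {
            s: np.array([_psi(config, s, lab) for lab in labels])
            for s in male_species
        }

        active_draw = np.array(
            [male_species[k] for k in rng.choice(len(male_species), size=scfg.n_pairs, p=sp_probs)]
        )
        a_ids = np.array(
            [
                males_by_species[s][rng.integers(len(males_by_species[s]))]
                for s in active_draw
            ]
        )
        is_mm = rng.random(scfg.n_pairs) < mm_rate
        if len(nonmale_idx) == 0:
            is_mm[:] = True
        if len(male_idx) <= 1:
            is_mm[:] = False

        def categorical(pool: np.ndarray, w: np.ndarray, size: int) -> np.ndarray:
            total = w.sum()
            if total <= 0:
                raise ValueError(f"all-zero preference row in {scfg.stratum}")
            cum = np.cumsum(w)
            pos = np.searchsorted(cum, rng.random(size) * total, side="right")
            return pool[np.minimum(pos, len(pool) - 1)]

        passive_ids = np.empty(scfg.n_pairs, dtype=np.int64)
        if config.size_beta > 0:
            for i in range(scfg.n_pairs):
                pool = male_idx if is_mm[i] else nonmale_idx
                a = int(a_ids[i])
                w = psi_vec[active_draw[i]][pool].copy()
                w[pool == a] = 0.0
                diff = heights[a] - heights[pool] - config.size_delta
                passive_ids[i] = categorical(
                    pool, w * np.exp(-config.size_beta * diff**2), 1
                )[0]
        else:
            for s in male_species:
                for mm_flag, pool in ((False, nonmale_idx), (True, male_idx)):
                    mask = (active_draw == s) & (is_mm == mm_flag)
                    k = int(mask.sum())
                    if k == 0:
                        continue
                    draws = categorical(pool, psi_vec[s][pool], k)
                    if mm_flag:  # a male cannot pair with himself
                        actives = a_ids[mask]
                        for _ in range(1000):
                            coll = draws == actives
                            if not coll.any():
                                break
                            draws[coll] = categorical(
                                pool, psi_vec[s][pool], int(coll.sum())
                            )
                    passive_ids[mask] = draws

        for i in range(scfg.n_pairs):
            active_sp = active_draw[i]
            a = int(a_ids[i])
            active_cat = PartnerCategory.male(active_sp)
            pair_id = f"{scfg.stratum.site_year}-{scfg.stratum.level}-s{i:06d}"
            p = int(passive_ids[i])
            passive = adults[p].category
            if passive.status == MALE:
                records.extend(
                    expand_male_male(
                        scfg.stratum,
                        active_cat,
                        passive,
                        pair_id=pair_id,
                        height_a_mm=float(heights[a]),
                        height_b_mm=float(heights[p]),
                        quadrat_id=str(quadrats[p]),
                    )
                )
            else:
                records.append(
                    CopulationRecord(
                        stratum=scfg.stratum,
                        active=active_cat,
                        passive=passive,
                        weight=1.0,
                        active_height_mm=float(heights[a]),
                        passive_height_mm=float(heights[p]),
                        pair_id=pair_id,
                        quadrat_id=str(quadrats[p]),
                    )
                )
    return records


def expected_composition(scfg: StratumConfig) -> pd.Series:
    """Theoretical adult composition implied by a stratum config."""
    probs: dict[str, float] = {}
    for species, params in scfg.species.items():
        d = params.density
        itc_label = f"{SPECIES_GROUP[species]}_itc"
        probs[itc_label] = probs.get(itc_label, 0.0) + d * params.itc_fraction
        mature = d * (1 - params.itc_fraction)
        if species != "saxatilis_1p5":
            probs[f"{species}_{FEMALE}"] = mature * params.sex_ratio
            probs[f"{species}_{MALE}"] = mature * (1 - params.sex_ratio)
        else:
            probs[f"{species}_{MALE}"] = mature
    s = pd.Series(probs).sort_index()
    return s / s.sum()


# ---------------------------------------------------------------------------
# Scenario presets

_BASE_SPECIES = {
    "saxatilis": SpeciesParams(density=12.0, sex_ratio=0.55, itc_fraction=0.20,
                               size_log_mean=math.log(8.0), size_log_sd=0.25),
    "arcana": SpeciesParams(density=5.0, sex_ratio=0.60, itc_fraction=0.20,
                            size_log_mean=math.log(8.0), size_log_sd=0.25),
    "compressa": SpeciesParams(density=3.0, sex_ratio=0.55, itc_fraction=0.15,
                               size_log_mean=math.log(4.5), size_log_sd=0.22),
    "obtusata": SpeciesParams(density=8.0, sex_ratio=0.55, itc_fraction=0.20,
                              size_log_mean=math.log(10.0), size_log_sd=0.22),
    "fabalis": SpeciesParams(density=4.0, sex_ratio=0.55, itc_fraction=0.15,
                             size_log_mean=math.log(8.0), size_log_sd=0.22),
}

FEMALE_LABELS = tuple(f"{s}_{FEMALE}" for s in _BASE_SPECIES)


def diagonal_preference(
    on: float = 1.0, off: float = 0.0, species: Sequence[str] = tuple(_BASE_SPECIES)
) -> dict[str, dict[str, float]]:
    """Preference matrix with within-species female weight ``on`` and
    cross-species female weight ``off`` (males and ITC keep weight 1)."""
    psi: dict[str, dict[str, float]] = {}
    for a in species:
        row = {f"{p}_{FEMALE}": (on if p == a else off) for p in species}
        psi[a] = row
    return psi


def scenario(name: str) -> SimulationConfig:
    """Documented preset configurations with fixed seeds.

    ``random``
        uniform preferences, no size assortment, male-male rate matched
        to composition — the random-mating null in generative form.
    ``assortative``
        diagonal-dominant preferences (own female weight 8, cross 0.25).
    ``arcana_asymmetric``
        *L. arcana* males prefer *L. saxatilis* females over their own
        (the field study's peculiar pattern); other species assortative.
    ``size_assortative``
        uniform preferences but a strong size kernel (beta = 0.5 per
        mm^2, delta = -1 mm: males slightly smaller than partners).
    """
    base = StratumConfig(
        stratum=Stratum("SIM1", "lower"),
        species=dict(_BASE_SPECIES),
        n_quadrats=10,
        n_pairs=1000,
    )
    if name == "random":
        return SimulationConfig(
            strata=(replace(base, n_pairs=10_000, male_male_rate=None),),
            preference={},
            size_beta=0.0,
            seed=101,
        )
    if name == "assortative":
        return SimulationConfig(
            strata=(replace(base, male_male_rate=0.15),),
            preference=diagonal_preference(on=8.0, off=0.25),
            size_beta=0.0,
            seed=202,
        )
    if name == "arcana_asymmetric":
        psi = diagonal_preference(on=6.0, off=0.2)
        psi["arcana"] = {**psi["arcana"],
                        "saxatilis_female": 6.0, "arcana_female": 0.2}
        psi["saxatilis"] = {**psi["saxatilis"], "saxatilis_female": 6.0}
        return SimulationConfig(
            strata=(replace(base, n_pairs=2000, male_male_rate=0.2),),
            preference=psi,
            size_beta=0.0,
            seed=303,
        )
    if name == "size_assortative":
        return SimulationConfig(
            strata=(replace(base, male_male_rate=0.1),),
            preference={},
            size_beta=0.5,
            size_delta=-1.0,
            seed=404,
        )
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("random", "assortative", "arcana_asymmetric", "size_assortative")
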
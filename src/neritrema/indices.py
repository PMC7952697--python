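"""Fidelity Index, precopulatory isolation index, and bootstrap inference.

The Fidelity Index of a focal male category measures the prevalence of
potentially productive matings relative to the random-mating null:

    FI = (O_consp - S_consp) / sum_i S_{i,focal}

where ``O_consp`` and ``S_consp`` are the observed and expected numbers
of copulations with conspecific mature females and the denominator sums
expected copulations of the focal males over all passive categories.
By the column-conservation property of the expected table the
denominator equals the focal males' observed weighted total.  FI ranges
from -1 (avoidance) through 0 (random mating) to 1 (assortative
mating).  The female-side index mirrors this with roles swapped.

The precopulatory isolation index for a species pair (X, Y) is a joint
isolation index computed on observed/expected ratios of the four
male x mature-female cells, r_ij = O_ij / S_ij:

    I_PC = (r_XX + r_YY - r_XY - r_YX) / (r_XX + r_YY + r_XY + r_YX)

Only copulations with mature females enter; 1.5-row males are excluded.

Uncertainty is quantified by bootstrap resampling of copulating-pair
records within a stratum (male-male halves are resampled as their whole
pair, preserving the 0.5-count structure); the census composition is
held fixed.  The two-tail p-value for H0: index = 0 uses the +1-
corrected replicate-count estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .null_model import ExpectedTable, build_expected_table
from .records import CopulationRecord, IndividualRecord
from .taxonomy import PartnerCategory, Stratum, conspecific_female_species

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexEstimate:
    """Point estimate of a mating index with bootstrap summaries."""

    index_name: str
    focal: str
    stratum: Stratum
    point: float
    boot_mean: float
    boot_sd: float
    p_two_tail: float
    n_iter: int
    seed: int
    n_dropped: int = 0
    valid: bool = True
    #: raw replicate values (only populated on request)
    replicates: tuple[float, ...] | None = None


class _Statistic:
    """Mating-index statistic computable from an observed cell matrix."""

    name: str = ""
    focal: str = ""

    def bind(self, table: ExpectedTable) -> None:
        """Resolve category positions against a table layout."""
        raise NotImplementedError

    def evaluate(self, observed: np.ndarray, q: np.ndarray, t: float) -> float:
        """Compute the statistic from a passive x active count matrix.

        Returns NaN when undefined (zero denominator) so bootstrap
        replicates can be dropped.
        """
        raise NotImplementedError

    def from_table(self, table: ExpectedTable) -> float:
        self.bind(table)
        value = self.evaluate(
            table.observed.to_numpy(), table.p_passive.to_numpy(), table.t
        )
        if math.isnan(value):
            raise ValueError(f"{self.name}({self.focal}) undefined: zero denominator")
        return value


class FidelityIndex(_Statistic):
    """FI of a focal male species (role="male") or female species (role="female")."""

    def __init__(self, focal_species: str, role: str = "male"):
        if role not in ("male", "female"):
            raise ValueError("role must be 'male' or 'female'")
        self.species = focal_species
        self.role = role
        self.name = "FI_male" if role == "male" else "FI_female"
        self.focal = focal_species
        self._j: int | None = None
        self._rows: np.ndarray | None = None
        self._i: int | None = None

    def bind(self, table: ExpectedTable) -> None:
        passive = list(table.observed.index)
        active = list(table.observed.columns)
        if self.role == "male":
            focal_cat = PartnerCategory.male(self.species)
            if focal_cat.label not in active:
                raise ValueError(f"no observed {focal_cat.label} in {table.stratum}")
            self._j = active.index(focal_cat.label)
            consp = [
                f"{s}_female" for s in conspecific_female_species(focal_cat)
            ]
            rows = [passive.index(c) for c in consp if c in passive]
            if not rows:
                raise ValueError(
                    f"no conspecific female category of {self.species} in the census "
                    f"for {table.stratum}"
                )
            self._rows = np.array(rows)
        else:
            focal_label = f"{self.species}_female"
            consp_label = f"{self.species}_male"
            if focal_label not in passive:
                raise ValueError(f"{focal_label} absent from {table.stratum} census")
            self._i = passive.index(focal_label)
            self._j = active.index(consp_label) if consp_label in active else None

    def evaluate(self, observed: np.ndarray, q: np.ndarray, t: float) -> float:
        if self.role == "male":
            a_focal = observed[:, self._j].sum()
            if a_focal <= 0:
                return math.nan
            o_consp = observed[self._rows, self._j].sum()
            s_consp = a_focal * q[self._rows].sum()
            return float((o_consp - s_consp) / a_focal)
        # female side: denominator sum_j S_{focal,j} = q_focal * t
        q_focal = q[self._i]
        denom = q_focal * t
        if denom <= 0:
            return math.nan
        if self._j is None:
            o_consp = 0.0
            s_consp = 0.0
        else:
            a_consp = observed[:, self._j].sum()
            o_consp = observed[self._i, self._j]
            s_consp = a_consp * q_focal
        return float((o_consp - s_consp) / denom)


class IsolationIndex(_Statistic):
    """Precopulatory isolation index I_PC for a species pair."""

    name = "IPC"

    def __init__(self, species_x: str, species_y: str):
        if "saxatilis_1p5" in (species_x, species_y):
            raise ValueError("1.5-row males are excluded from I_PC")
        self.pair = tuple(sorted((species_x, species_y)))
        self.focal = "-".join(self.pair)
        self._rows: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._q_rows: np.ndarray | None = None

    def bind(self, table: ExpectedTable) -> None:
        passive = list(table.observed.index)
        active = list(table.observed.columns)
        x, y = self.pair
        try:
            self._rows = np.array([passive.index(f"{x}_female"), passive.index(f"{y}_female")])
            self._cols = np.array([active.index(f"{x}_male"), active.index(f"{y}_male")])
        except ValueError as exc:
            raise ValueError(
                f"I_PC({self.focal}) not computable in {table.stratum}: {exc}"
            ) from exc
        q = table.p_passive.to_numpy()[self._rows]
        if (q <= 0).any():
            raise ValueError(
                f"I_PC({self.focal}) in {table.stratum}: zero expected female frequency"
            )
        self._q_rows = q

    def evaluate(self, observed: np.ndarray, q: np.ndarray, t: float) -> float:
        a = observed[:, self._cols].sum(axis=0)  # focal male totals
        if (a <= 0).any():
            return math.nan
        o = observed[np.ix_(self._rows, self._cols)]
        s = np.outer(self._q_rows, a)
        r = o / s
        total = r.sum()
        if total <= 0:
            return math.nan
        return float((r[0, 0] + r[1, 1] - r[0, 1] - r[1, 0]) / total)


def fidelity_index(table: ExpectedTable, focal_species: str) -> float:
    """FI of a focal male species on an observed/expected table."""
    return FidelityIndex(focal_species, role="male").from_table(table)


def fidelity_index_female(table: ExpectedTable, focal_species: str) -> float:
    """FI of a focal female species (how often she is engaged by conspecifics)."""
    return FidelityIndex(focal_species, role="female").from_table(table)


def ipc(table: ExpectedTable, species_pair: tuple[str, str]) -> float:
    """Precopulatory isolation index for a species pair in one stratum."""
    return IsolationIndex(*species_pair).from_table(table)


# ---------------------------------------------------------------------------
# Bootstrap


def _resampling_units(
    records: Sequence[CopulationRecord], table: ExpectedTable
) -> tuple[np.ndarray, np.ndarray]:
    """Group records into whole-pair resampling units.

    Returns ``(unit_type, type_cells)`` where ``unit_type[u]`` indexes a
    distinct cell-weight signature and ``type_cells`` is the
    (n_types, n_cells) matrix of per-unit contributions to the flattened
    observed matrix.  Records whose passive category was excluded from
    the table are not resampled.
    """
    passive_pos = {lab: i for i, lab in enumerate(table.observed.index)}
    active_pos = {lab: j for j, lab in enumerate(table.observed.columns)}
    n_cells = len(passive_pos) * len(active_pos)
    width = len(active_pos)

    units: dict[str, list[tuple[int, float]]] = {}
    singleton = 0
    for rec in records:
        if rec.stratum != table.stratum:
            continue
        if rec.passive.label not in passive_pos:
            continue  # excluded category
        cell = passive_pos[rec.passive.label] * width + active_pos[rec.active.label]
        key = rec.pair_id
        if not key:
            singleton += 1
            key = f"__singleton_{singleton}"
        units.setdefault(key, []).append((cell, rec.weight))

    signatures: dict[tuple, int] = {}
    unit_type = np.empty(len(units), dtype=np.int64)
    vectors: list[np.ndarray] = []
    for u, contribs in enumerate(units.values()):
        sig = tuple(sorted(contribs))
        if sig not in signatures:
            vec = np.zeros(n_cells)
            for cell, w in contribs:
                vec[cell] += w
            signatures[sig] = len(vectors)
            vectors.append(vec)
        unit_type[u] = signatures[sig]
    return unit_type, np.array(vectors)


def bootstrap_index(
    records: Sequence[CopulationRecord],
    census: Sequence[IndividualRecord],
    statistic: _Statistic,
    stratum: Stratum,
    n_iter: int = 10_000,
    seed: int | None = None,
    composition_method: str = "pooled",
    keep_replicates: bool = False,
) -> IndexEstimate:
    """Bootstrap a mating index by resampling copulating-pair records.

    Each replicate resamples the stratum's pair units (whole male-male
    pairs) with replacement at the observed sample size, recomputes the
    observed matrix and active frequencies against the fixed census
    composition, and re-evaluates the statistic.  Replicates where the
    statistic is undefined are dropped and counted; an estimate with
    more than half its replicates dropped is flagged invalid.
    """
    if seed is None:
        raise ValueError("bootstrap_index requires an explicit seed")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    table = build_expected_table(
        records, census, stratum, composition_method=composition_method
    )
    point = statistic.from_table(table)

    unit_type, type_cells = _resampling_units(records, table)
    n_units = len(unit_type)
    n_types = type_cells.shape[0]
    shape = table.observed.shape
    q = table.p_passive.to_numpy()

    rng = np.random.default_rng(seed)
    reps = np.empty(n_iter)
    for b in range(n_iter):
        idx = rng.integers(0, n_units, size=n_units)
        counts = np.bincount(unit_type[idx], minlength=n_types).astype(float)
        observed = (counts @ type_cells).reshape(shape)
        reps[b] = statistic.evaluate(observed, q, table.t)

    valid = reps[~np.isnan(reps)]
    n_dropped = n_iter - len(valid)
    if n_dropped:
        logger.info(
            "%s(%s) %s: %d/%d bootstrap replicates undefined and dropped",
            statistic.name, statistic.focal, stratum, n_dropped, n_iter,
        )
    kept = tuple(reps) if keep_replicates else None
    if len(valid) == 0:
        return IndexEstimate(
            statistic.name, statistic.focal, stratum, point,
            math.nan, math.nan, math.nan, n_iter, seed, n_dropped,
            valid=False, replicates=kept,
        )
    n_valid = len(valid)
    p = 2.0 * min((valid <= 0).sum() + 1, (valid >= 0).sum() + 1) / (n_valid + 1)
    return IndexEstimate(
        index_name=statistic.name,
        focal=statistic.focal,
        stratum=stratum,
        point=point,
        boot_mean=float(valid.mean()),
        boot_sd=float(valid.std(ddof=0)),
        p_two_tail=min(1.0, float(p)),
        n_iter=n_iter,
        seed=seed,
        n_dropped=int(n_dropped),
        valid=n_dropped <= n_iter / 2,
        replicates=kept,
    )


def estimates_to_frame(estimates: Sequence[IndexEstimate]) -> pd.DataFrame:
    """Long-format table of index estimates (one row per index/focal/stratum)."""
    return pd.DataFrame(
        {
            "index": [e.index_name for e in estimates],
            "focal": [e.focal for e in estimates],
            "site_year": [e.stratum.site_year for e in estimates],
            "level": [e.stratum.level for e in estimates],
            "point": [e.point for e in estimates],
            "boot_mean": [e.boot_mean for e in estimates],
            "boot_sd": [e.boot_sd for e in estimates],
            "p_two_tail": [e.p_two_tail for e in estimates],
            "n_iter": [e.n_iter for e in estimates],
            "n_dropped": [e.n_dropped for e in estimates],
            "seed": [e.seed for e in estimates],
            "valid": [e.valid for e in estimates],
        }
    )
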
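"""Random-mating null model: expected copulation frequencies.

Under the null hypothesis of random mating, the probability of being
the passive partner of a copulation equals the category's share of the
adult population at that site and level, while the probability of being
the active partner is estimated from the copulating pairs themselves
(male species differ in copulatory activity).  The expected count for a
cell is then

    S_ij = P_active(j) * P_passive(i) * t

with ``t`` the total weighted number of pairs in the stratum.  The
expected matrix therefore conserves both the grand total and every
active-male column total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CopulationRecord, IndividualRecord, pairs_to_frame, tabulate_pairs
from .taxonomy import Stratum

logger = logging.getLogger(__name__)


@dataclass
class ExpectedTable:
    """Observed and expected copulation frequencies for one stratum.

    ``observed`` and ``expected`` are passive x active matrices sharing
    index and columns; ``p_passive`` and ``p_active`` are the underlying
    probabilities; ``excluded`` lists passive categories observed in
    copulation but absent from the census (their expected frequency is
    undefined, so they are dropped from the table).
    """

    stratum: Stratum
    observed: pd.DataFrame
    expected: pd.DataFrame
    p_passive: pd.Series
    p_active: pd.Series
    t: float
    excluded: list[str] = field(default_factory=list)

    def validate(self, atol: float = 1e-9) -> None:
        """Assert the conservation invariants of the null model."""
        assert abs(self.p_passive.sum() - 1.0) < atol
        assert abs(self.p_active.sum() - 1.0) < atol
        assert abs(self.expected.to_numpy().sum() - self.t) < atol
        col_obs = self.observed.sum(axis=0)
        col_exp = self.expected.sum(axis=0)
        assert np.allclose(col_obs.to_numpy(), col_exp.to_numpy(), atol=atol)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (stratum, passive, active, observed, expected) table."""
        rows = []
        for passive in self.observed.index:
            for active in self.observed.columns:
                rows.append(
                    {
                        "stratum": str(self.stratum),
                        "passive": passive,
                        "active": active,
                        "observed": self.observed.at[passive, active],
                        "expected": self.expected.at[passive, active],
                    }
                )
        return pd.DataFrame(rows)


def passive_composition(
    census: Sequence[IndividualRecord],
    stratum: Stratum,
    method: str = "pooled",
) -> pd.Series:
    """Probabilities of being a potential passive partner, by category.

    All adults (``older_than_one_year``) are potential passive partners
    — males, females and ITC individuals of every species; juveniles are
    excluded.  ``method="pooled"`` pools individuals across quadrats
    (quadrat areas are equal); ``method="per_quadrat"`` averages
    per-quadrat proportions instead.
    """
    eligible = [
        r for r in census if r.stratum == stratum and r.older_than_one_year
    ]
    if not eligible:
        raise ValueError(f"no eligible adults in census for stratum {stratum}")
    labels = [r.category.label for r in eligible]
    if method == "pooled":
        counts = pd.Series(labels).value_counts().sort_index()
        return counts / counts.sum()
    if method == "per_quadrat":
        frame = pd.DataFrame(
            {"quadrat": [r.quadrat_id for r in eligible], "label": labels}
        )
        per_q = (
            frame.groupby("quadrat")["label"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        mean_props = per_q.mean(axis=0)
        return (mean_props / mean_props.sum()).sort_index()
    raise ValueError(f"unknown composition method {method!r}")


def active_frequencies(
    records: Sequence[CopulationRecord], stratum: Stratum
) -> tuple[pd.Series, float]:
    """Per-category probabilities of being the active partner, and t.

    Probabilities are weighted copulation counts divided by the total
    weighted pair count; 0.5 halves of male-male pairs contribute their
    fractional weight.
    """
    frame = pairs_to_frame([r for r in records if r.stratum == stratum])
    t = float(frame["weight"].sum()) if not frame.empty else 0.0
    if t <= 0:
        raise ValueError(f"no copulation records in stratum {stratum}")
    totals = frame.groupby("active")["weight"].sum().sort_index()
    return totals / t, t


def expected_counts(p_active: pd.Series, p_passive: pd.Series, t: float) -> pd.DataFrame:
    """Outer-product expected matrix S_ij = P_active(j) * P_passive(i) * t."""
    if t <= 0:
        raise ValueError("t must be positive")
    for name, p in (("p_active", p_active), ("p_passive", p_passive)):
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} is not a probability vector")
    return pd.DataFrame(
        np.outer(p_passive.to_numpy(), p_active.to_numpy()) * t,
        index=p_passive.index,
        columns=p_active.index,
    )


def build_expected_table(
    records: Sequence[CopulationRecord],
    census: Sequence[IndividualRecord],
    stratum: Stratum,
    composition_method: str = "pooled",
) -> ExpectedTable:
    """Assemble the full observed/expected table for one stratum.

    Passive categories observed in copulation but absent from the field
    census have undefined expected frequencies; they are excluded from
    the table and logged, mirroring the treatment of such categories in
    the field study.
    """
    p_passive = passive_composition(census, stratum, method=composition_method)
    p_active, t = active_frequencies(records, stratum)
    observed = tabulate_pairs(records, stratum)

    excluded = sorted(set(observed.index) - set(p_passive.index))
    if excluded:
        logger.info(
            "stratum %s: passive categories %s observed in copulation but absent "
            "from the census; excluded from the expected table",
            stratum, excluded,
        )
        observed = observed.drop(index=excluded)

    # full passive margin = census categories (observed-zero rows included)
    passive_index = p_passive.index
    active_index = p_active.index
    observed = observed.reindex(index=passive_index, columns=active_index, fill_value=0.0)
    # renormalize active margin to the retained records
    t_kept = float(observed.to_numpy().sum())
    if t_kept <= 0:
        raise ValueError(f"no records left after exclusions in stratum {stratum}")
    p_active_kept = observed.sum(axis=0) / t_kept
    expected = expected_counts(p_active_kept, p_passive, t_kept)
    table = ExpectedTable(
        stratum=stratum,
        observed=observed,
        expected=expected,
        p_passive=p_passive,
        p_active=p_active_kept,
        t=t_kept,
        excluded=excluded,
    )
    table.validate()
    return table
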
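"""Shared fixtures: field-data transcriptions and small synthetic datasets."""

from __future__ import annotations

import pytest

from neritrema import load_table2_pairs, load_table3_combinations
from neritrema.records import IndividualRecord
from neritrema.taxonomy import PartnerCategory, Stratum


@pytest.fixture(scope="session")
def table2_records():
    return load_table2_pairs()


@pytest.fixture(scope="session")
def table3_matrix():
    return load_table3_combinations()


def make_census(
    stratum: Stratum,
    counts: dict[str, int],
    n_quadrats: int = 4,
    base_height: float = 8.0,
) -> list[IndividualRecord]:
    """Deterministic census with given per-category-label adult counts.

    Individuals are dealt round-robin over quadrats with slightly
    varying heights so size-based code has non-degenerate input.
    """
    from neritrema.taxonomy import parse_label

    out = []
    i = 0
    for label, n in sorted(counts.items()):
        cat = parse_label(label)
        for k in range(n):
            i += 1
            out.append(
                IndividualRecord(
                    stratum=stratum,
                    quadrat_id=f"Q{(i % n_quadrats) + 1}",
                    category=cat,
                    older_than_one_year=True,
                    shell_height_mm=base_height + 0.1 * (k % 17) + 0.01 * (i % 7),
                )
            )
    return out


@pytest.fixture(scope="session")
def fixture_census(table2_records):
    """Synthetic stand-in census for the transcribed field strata.

    The study's quadrat compositions live in unpublished supplementary
    data, so tests needing a census pair the transcribed copulation
    records with this synthetic composition in which every observed
    category is present.
    """
    census = []
    strata = sorted({r.stratum for r in table2_records})
    for stratum in strata:
        observed = {r.passive.label for r in table2_records if r.stratum == stratum}
        observed |= {r.active.label for r in table2_records if r.stratum == stratum}
        counts = {}
        for j, label in enumerate(sorted(observed)):
            counts[label] = 20 + 5 * j  # unequal but fixed composition
        census.extend(make_census(stratum, counts))
    return census


@pytest.fixture()
def toy_stratum():
    return Stratum("TOY2020", "lower")
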
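"""Packaged field-data fixtures.

``table2_pairs.csv`` transcribes the published per-stratum mating table
as weighted copulation records (male-male pairs split into 0.5-weight
halves).  ``table3_combinations.csv`` transcribes the published binary
matrix of observed partner-type combinations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import CopulationRecord, read_pair_records


def _data_path(name: str):
    return resources.files("neritrema").joinpath("data", name)


def load_table2_pairs() -> list[CopulationRecord]:
    """Weighted copulating-pair records for all six strata (317 pairs)."""
    with resources.as_file(_data_path("table2_pairs.csv")) as path:
        return read_pair_records(path)


def load_table3_combinations() -> pd.DataFrame:
    """Boolean passive x active matrix of observed partner-type combinations."""
    with resources.as_file(_data_path("table3_combinations.csv")) as path:
        frame = pd.read_csv(path, index_col="passive")
    return frame.astype(bool)
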
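"""Fidelity Index, isolation index and bootstrap inference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neritrema.indices import (
    FidelityIndex,
    IsolationIndex,
    bootstrap_index,
    fidelity_index,
    fidelity_index_female,
    ipc,
)
from neritrema.null_model import ExpectedTable, build_expected_table
from neritrema.records import CopulationRecord, expand_male_male
from neritrema.taxonomy import PartnerCategory, Stratum

from conftest import make_census

M = PartnerCategory.male
F = PartnerCategory.female


def manual_table(stratum, passive, active, observed, p_passive) -> ExpectedTable:
    """ExpectedTable built directly from an observed matrix and composition."""
    obs = pd.DataFrame(observed, index=passive, columns=active, dtype=float)
    q = pd.Series(p_passive, index=passive, dtype=float)
    t = float(obs.to_numpy().sum())
    a = obs.sum(axis=0)
    expected = pd.DataFrame(
        np.outer(q.to_numpy(), a.to_numpy()), index=passive, columns=active
    )
    table = ExpectedTable(
        stratum=stratum, observed=obs, expected=expected,
        p_passive=q, p_active=a / t, t=t,
    )
    table.validate()
    return table


class TestFidelityIndex:
    def test_zero_under_exact_random_mating(self, toy_stratum):
        census = make_census(
            toy_stratum, {"saxatilis_female": 30, "saxatilis_male": 20,
                          "arcana_female": 50}
        )
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"))
                for _ in range(5)]
        table = build_expected_table(recs, census, toy_stratum)
        table.observed = table.expected.copy()  # force O = S
        assert fidelity_index(table, "saxatilis") == pytest.approx(0.0, abs=1e-12)
        assert fidelity_index_female(table, "saxatilis") == pytest.approx(0.0, abs=1e-12)

    def test_all_conspecific_with_rare_females(self, toy_stratum):
        # a = 10 all with conspecific females, P_consp = 0.1 -> FI = 0.9
        census = make_census(
            toy_stratum, {"saxatilis_female": 10, "saxatilis_male": 40,
                          "saxatilis_group_itc": 50}
        )
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"))
                for _ in range(10)]
        table = build_expected_table(recs, census, toy_stratum)
        assert fidelity_index(table, "saxatilis") == pytest.approx(0.9)

    def test_zero_conspecific_gives_minus_p_consp(self, toy_stratum):
        census = make_census(
            toy_stratum, {"saxatilis_female": 25, "saxatilis_male": 25,
                          "saxatilis_group_itc": 50}
        )
        recs = [
            CopulationRecord(toy_stratum, M("saxatilis"),
                             PartnerCategory.itc("saxatilis_group"))
            for _ in range(10)
        ]
        table = build_expected_table(recs, census, toy_stratum)
        assert fidelity_index(table, "saxatilis") == pytest.approx(-0.25)

    def test_denominator_identity(self, table2_records, fixture_census):
        """sum_i S_{i,focal} equals the focal male's observed weighted total."""
        for stratum in sorted({r.stratum for r in table2_records}):
            table = build_expected_table(table2_records, fixture_census, stratum)
            np.testing.assert_allclose(
                table.expected.sum(axis=0).to_numpy(),
                table.observed.sum(axis=0).to_numpy(),
            )

    def test_female_index_on_hand_computed_2x2(self, toy_stratum):
        table = manual_table(
            toy_stratum,
            passive=["saxatilis_female", "obtusata_female"],
            active=["saxatilis_male", "obtusata_male"],
            observed=[[6.0, 0.0], [0.0, 4.0]],
            p_passive=[0.4, 0.6],
        )
        # FI = (6 - 6*0.4) / (0.4 * 10) = 0.9
        assert fidelity_index_female(table, "saxatilis") == pytest.approx(0.9)

    def test_female_with_no_matings_received(self, toy_stratum):
        table = manual_table(
            toy_stratum,
            passive=["saxatilis_female", "obtusata_female"],
            active=["saxatilis_male", "obtusata_male"],
            observed=[[0.0, 0.0], [6.0, 4.0]],
            p_passive=[0.4, 0.6],
        )
        # FI = -S_consp / sum_j S = -(6*0.4) / (0.4*10) = -0.6
        assert fidelity_index_female(table, "saxatilis") == pytest.approx(-0.6)

    def test_bounds(self, toy_stratum):
        for obs in ([[9, 0], [1, 0], [0, 10]], [[0, 5], [10, 5], [0, 0]]):
            table = manual_table(
                toy_stratum,
                passive=["saxatilis_female", "saxatilis_male", "obtusata_female"],
                active=["saxatilis_male", "obtusata_male"],
                observed=obs,
                p_passive=[0.2, 0.3, 0.5],
            )
            fi = fidelity_index(table, "saxatilis")
            assert -1.0 <= fi <= 1.0

    def test_undefined_focal_raises(self, toy_stratum):
        census = make_census(toy_stratum, {"saxatilis_female": 10})
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"))]
        table = build_expected_table(recs, census, toy_stratum)
        with pytest.raises(ValueError):
            fidelity_index(table, "obtusata")


class TestIsolationIndex:
    def ipc_table(self, toy_stratum, o_xx, o_yy, o_xy, o_yx, fill):
        passive = ["saxatilis_female", "obtusata_female", "saxatilis_group_itc"]
        active = ["saxatilis_male", "obtusata_male"]
        observed = [[o_xx, o_yx], [o_xy, o_yy], list(fill)]
        return manual_table(
            toy_stratum, passive, active, observed, p_passive=[0.25, 0.25, 0.5]
        )

    def test_equal_ratios_give_zero(self, toy_stratum):
        table = self.ipc_table(toy_stratum, 1, 1, 1, 1, fill=(2, 2))
        assert ipc(table, ("saxatilis", "obtusata")) == pytest.approx(0.0)

    def test_complete_assortment_gives_one(self, toy_stratum):
        table = self.ipc_table(toy_stratum, 2, 2, 0, 0, fill=(2, 2))
        assert ipc(table, ("saxatilis", "obtusata")) == pytest.approx(1.0)

    def test_hand_computed_ratio_case(self, toy_stratum):
        # r = (2, 2, 1, 1) -> (4 - 2) / 6 = 1/3
        table = self.ipc_table(toy_stratum, 2, 2, 1, 1, fill=(1, 1))
        s = table.expected
        r = table.observed / s
        assert r.at["saxatilis_female", "saxatilis_male"] == pytest.approx(2.0)
        assert r.at["obtusata_female", "saxatilis_male"] == pytest.approx(1.0)
        assert ipc(table, ("saxatilis", "obtusata")) == pytest.approx(1 / 3)

    def test_label_swap_symmetry(self, toy_stratum):
        table = self.ipc_table(toy_stratum, 3, 1, 2, 0.5, fill=(0.5, 1))
        assert ipc(table, ("saxatilis", "obtusata")) == pytest.approx(
            ipc(table, ("obtusata", "saxatilis"))
        )

    def test_1p5_males_rejected(self):
        with pytest.raises(ValueError):
            IsolationIndex("saxatilis", "saxatilis_1p5")

    def test_zero_expected_cell_excluded(self, toy_stratum):
        census = make_census(
            toy_stratum, {"saxatilis_female": 10, "saxatilis_male": 10}
        )
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"))]
        table = build_expected_table(recs, census, toy_stratum)
        with pytest.raises(ValueError):
            ipc(table, ("saxatilis", "obtusata"))


class TestBootstrap:
    def small_dataset(self, toy_stratum):
        census = make_census(
            toy_stratum,
            {"saxatilis_female": 30, "saxatilis_male": 25, "arcana_female": 15,
             "arcana_male": 10, "saxatilis_group_itc": 20},
        )
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"),
                                 pair_id=f"h{i}") for i in range(8)]
        recs += [CopulationRecord(toy_stratum, M("saxatilis"), F("arcana"),
                                  pair_id="h8")]
        recs += [CopulationRecord(toy_stratum, M("arcana"), F("saxatilis"),
                                  pair_id="h9")]
        recs += list(expand_male_male(toy_stratum, M("saxatilis"), M("arcana"), "mm0"))
        return recs, census

    def test_requires_seed(self, toy_stratum):
        recs, census = self.small_dataset(toy_stratum)
        with pytest.raises(ValueError):
            bootstrap_index(recs, census, FidelityIndex("saxatilis"), toy_stratum,
                            n_iter=3)

    def test_degenerate_data_has_zero_sd(self, toy_stratum):
        census = make_census(
            toy_stratum, {"saxatilis_female": 10, "saxatilis_male": 10}
        )
        recs = [CopulationRecord(toy_stratum, M("saxatilis"), F("saxatilis"),
                                 pair_id=f"p{i}") for i in range(5)]
        est = bootstrap_index(recs, census, FidelityIndex("saxatilis"),
                              toy_stratum, n_iter=50, seed=3)
        assert est.boot_sd == 0.0
        assert est.boot_mean == pytest.approx(est.point)

    def test_matches_naive_resampler(self, toy_stratum):
        """B = 3 replicates equal an independently coded brute-force resampler."""
        recs, census = self.small_dataset(toy_stratum)
        stat = FidelityIndex("saxatilis")
        seed = 11
        est = bootstrap_index(recs, census, stat, toy_stratum, n_iter=3, seed=seed,
                              keep_replicates=True)

        # naive oracle: regroup records into whole pairs, resample with the
        # same RNG stream, rebuild the full table, recompute the index
        units: dict[str, list] = {}
        singleton = 0
        for r in recs:
            key = r.pair_id
            if not key:
                singleton += 1
                key = f"s{singleton}"
            units.setdefault(key, []).append(r)
        unit_list = list(units.values())
        rng = np.random.default_rng(seed)
        oracle = []
        for _ in range(3):
            idx = rng.integers(0, len(unit_list), size=len(unit_list))
            resampled = [r for i in idx for r in unit_list[i]]
            table = build_expected_table(resampled, census, toy_stratum)
            oracle.append(FidelityIndex("saxatilis").from_table(table))
        np.testing.assert_allclose(est.replicates, oracle, rtol=1e-12)

    def test_replicates_respect_index_bounds(self, toy_stratum):
        recs, census = self.small_dataset(toy_stratum)
        est = bootstrap_index(recs, census, FidelityIndex("saxatilis"),
                              toy_stratum, n_iter=200, seed=5,
                              keep_replicates=True)
        reps = np.array(est.replicates)
        reps = reps[~np.isnan(reps)]
        assert ((reps >= -1) & (reps <= 1)).all()
        assert 0 < est.p_two_tail <= 1
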
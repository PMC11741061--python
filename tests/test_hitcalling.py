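"""Control-referenced hit calling: statistics, rules, assembly."""

import numpy as np
import pandas as pd
import pytest

import amidasekit as ak
from amidasekit.hitcalling import (
    COLORIMETRIC,
    HPLC,
    MEASUREMENT_COLUMNS,
    HitCallingError,
    assemble_activity_matrix,
    call_hplc_hits,
    call_plate_hits,
    compute_yield,
    filter_control_outliers,
    relative_removal,
)

from helpers import naive_call_hits, random_measurement_table


@pytest.mark.parametrize(
    "a0, a24, expected",
    [(100, 100, 0.0), (100, 25, 75.0), (100, 110, -10.0)],
)
def test_relative_removal_definition(a0, a24, expected):
    assert relative_removal(a0, a24) == pytest.approx(expected)


def test_relative_removal_rejects_nonpositive_t0():
    with pytest.raises(HitCallingError, match="t0"):
        relative_removal(0.0, 10.0)


@pytest.mark.parametrize(
    "od, ref, expected", [(0.6, 0.6, 100.0), (0.0, 0.6, 0.0), (0.3, 0.6, 50.0)]
)
def test_yield_definition(od, ref, expected):
    assert compute_yield(od, ref) == pytest.approx(expected)
    with pytest.raises(HitCallingError):
        compute_yield(0.3, 0.0)


class TestControlOutlierFilter:
    def test_tukey_fences_remove_the_outlier(self):
        # Q1=1, Q3=3, IQR=2, upper fence 6: 100 is the only casualty
        kept, removed = filter_control_outliers([0, 1, 2, 3, 100], multiplier=1.5)
        assert sorted(kept) == [0, 1, 2, 3]
        assert list(removed) == [100]

    def test_identical_values_all_survive(self):
        kept, removed = filter_control_outliers([5.0] * 6)
        assert len(kept) == 6 and len(removed) == 0

    def test_median_always_survives(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.normal(0, 10, size=int(rng.integers(3, 12)))
            kept, _ = filter_control_outliers(vals)
            assert np.median(vals) >= min(kept) and np.median(vals) <= max(kept)

    def test_too_few_replicates(self):
        with pytest.raises(HitCallingError, match="3"):
            filter_control_outliers([1.0, 2.0])


def _removals_frame(control, samples):
    rows = [("CTRL", "S1", i, True, v) for i, v in enumerate(control)]
    for enzyme_id, vals in samples.items():
        rows += [(enzyme_id, "S1", i, False, v) for i, v in enumerate(vals)]
    return pd.DataFrame(
        rows, columns=["enzyme_id", "substrate_id", "replicate", "is_control", "relative_removal"]
    )


class TestHplcRules:
    def test_both_conditions_met(self):
        # control {0,2,4}: median 2, IQR 2 -> statistic 5; sample median 60
        dec = call_hplc_hits(
            _removals_frame([0, 2, 4], {"E1": [60, 60, 60]}), ak.HitCallingConfig()
        )
        assert dec["hit"].tolist() == [1]
        assert dec["control_statistic"].iloc[0] == pytest.approx(5.0)

    def test_absolute_threshold_fails(self):
        dec = call_hplc_hits(
            _removals_frame([0, 2, 4], {"E1": [40, 40, 40]}), ak.HitCallingConfig()
        )
        assert dec["hit"].tolist() == [0]

    def test_control_statistic_fails(self):
        # control {50,55,60}: median 55, IQR 5 -> statistic 62.5; sample 60
        dec = call_hplc_hits(
            _removals_frame([50, 55, 60], {"E1": [60, 60, 60]}), ak.HitCallingConfig()
        )
        assert dec["hit"].tolist() == [0]

    def test_missing_control_errors(self):
        frame = _removals_frame([0, 2, 4], {"E1": [60]})
        frame = frame[~frame["is_control"]]
        with pytest.raises(HitCallingError, match="S1"):
            call_hplc_hits(frame, ak.HitCallingConfig())


def _plate_frame(substrate, t_eval, control_ods, sample_ods, ref_od=1.0, grid=(0.0, 60.0, 120.0)):
    rows = []
    for rep, od in enumerate(control_ods):
        for t in grid:
            rows.append(("CTRL", substrate, rep, COLORIMETRIC, t, od, True, False))
    for enzyme_id, ods in sample_ods.items():
        for rep, od in enumerate(ods):
            for t in grid:
                rows.append((enzyme_id, substrate, rep, COLORIMETRIC, t, od, False, False))
    for rep in range(3):
        for t in grid:
            rows.append(("REF", substrate, rep, COLORIMETRIC, t, ref_od, False, True))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


class TestPlateRules:
    def test_zero_sd_control_margin(self):
        # control yields {10,10,10}: SD 0; sample mean 10.1 exceeds the mean
        frame = _plate_frame("S1", 60.0, [0.10] * 3, {"E1": [0.101] * 3})
        cfg = ak.HitCallingConfig(evaluation_times={"S1": 60.0})
        dec = call_plate_hits(frame, cfg)
        assert dec["hit"].tolist() == [1]

    def test_ester_floor(self):
        # mean yield 25% clears the control threshold but not the 30% floor
        frame = _plate_frame("S1", 60.0, [0.01] * 3, {"E1": [0.25] * 3})
        cfg = ak.HitCallingConfig(evaluation_times={"S1": 60.0}, ester_substrates=["S1"])
        dec = call_plate_hits(frame, cfg)
        assert dec["hit"].tolist() == [0]
        dec2 = call_plate_hits(
            frame, ak.HitCallingConfig(evaluation_times={"S1": 60.0})
        )
        assert dec2["hit"].tolist() == [1]

    def test_missing_evaluation_time_on_grid(self):
        frame = _plate_frame("S1", 60.0, [0.1] * 3, {"E1": [0.2] * 3})
        cfg = ak.HitCallingConfig(evaluation_times={"S1": 77.0})
        with pytest.raises(HitCallingError, match="interpolation"):
            call_plate_hits(frame, cfg)

    def test_default_evaluation_times_match_panel(self):
        substrates = ak.generate_substrate_set(ak.SyntheticConfig())
        cfg = ak.synthetic.default_hitcalling_config(substrates)
        assert cfg.evaluation_times["paracetamol"] == 2600.0
        assert cfg.evaluation_times["4NP-butyrate"] == 100.0
        assert cfg.evaluation_times["4NP-trimethylacetate"] == 600.0
        assert set(cfg.ester_substrates) == {"4NP-butyrate", "4NP-trimethylacetate"}


class TestAssembly:
    def test_full_screen_grid_size(self):
        cfg = ak.SyntheticConfig(seed=2, n_enzymes=40)
        _, _, subs, truth, meas = ak.generate_study(cfg)
        matrix = ak.call_hits(meas, ak.synthetic.default_hitcalling_config(subs))
        assert matrix.n_cells() == 680

    def test_row_filtering_to_modelling_set(self):
        values = pd.DataFrame(
            np.eye(16, 17, dtype=int), index=[f"E{i}" for i in range(16)],
            columns=[f"S{j}" for j in range(17)],
        )
        decisions = values.stack().rename("hit").reset_index()
        decisions.columns = ["enzyme_id", "substrate_id", "hit"]
        decisions["route"] = HPLC
        matrix = assemble_activity_matrix(decisions, None, drop_inactive_enzymes=True)
        assert matrix.n_cells() == 272

    def test_all_inactive_warns_and_empties(self):
        decisions = pd.DataFrame(
            {"enzyme_id": ["E1", "E2"], "substrate_id": ["S1", "S1"], "hit": [0, 0], "route": HPLC}
        )
        with pytest.warns(UserWarning, match="E1"):
            matrix = assemble_activity_matrix(decisions, None, drop_inactive_enzymes=True)
        assert matrix.values.empty and matrix.dropped_enzymes == ["E1", "E2"]

    def test_conflicting_duplicates_error(self):
        decisions = pd.DataFrame(
            {"enzyme_id": ["E1", "E1"], "substrate_id": ["S1", "S1"], "hit": [0, 1], "route": HPLC}
        )
        with pytest.raises(HitCallingError, match="conflict"):
            assemble_activity_matrix(decisions, None)


class TestAgainstNaiveReference:
    def test_randomized_tables_agree_cell_for_cell(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            meas, cfg = random_measurement_table(rng)
            matrix = ak.call_hits(meas, cfg)
            expected = naive_call_hits(meas, cfg)
            for (e, s), hit in expected.items():
                assert matrix.values.at[e, s] == hit, (e, s)

    def test_monotonicity_in_t24(self):
        """Raising a t24 area (less removal) never turns a non-hit into a hit."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            meas, cfg = random_measurement_table(rng)
            hplc = meas[(meas["route"] == HPLC) & ~meas["is_control"] & (meas["time"] == 24.0)]
            if hplc.empty:
                continue
            row = hplc.sample(1, random_state=int(rng.integers(2**31))).iloc[0]
            before = ak.call_hits(meas, cfg).values.at[row["enzyme_id"], row["substrate_id"]]
            bumped = meas.copy()
            bumped.loc[row.name, "value"] = row["value"] * 1.5 + 100
            after = ak.call_hits(bumped, cfg).values.at[row["enzyme_id"], row["substrate_id"]]
            assert after <= before


def test_provenance_covers_every_cell(study):
    _, _, substrates, truth, measurements = study
    matrix = ak.call_hits(measurements, ak.synthetic.default_hitcalling_config(substrates))
    for e in matrix.enzyme_ids:
        for s in matrix.substrate_ids:
            assert (e, s) in matrix.provenance
            assert matrix.provenance[(e, s)]["route"] in (HPLC, COLORIMETRIC)
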
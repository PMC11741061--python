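"""Synthetic study generator: determinism, structure, planted signal."""

import numpy as np
import pandas as pd
import pytest

import amidasekit as ak
from amidasekit.synthetic import (
    CONTROL_ENZYME_ID,
    SyntheticError,
    generate_enzyme_set,
    generate_substrate_set,
    plant_activity_model,
    simulate_measurements,
)


class TestEnzymeGeneration:
    def test_seeded_determinism(self, default_cfg):
        a1, _ = generate_enzyme_set(default_cfg)
        a2, _ = generate_enzyme_set(default_cfg)
        assert a1 == a2

    def test_shape_contract(self):
        cfg = ak.SyntheticConfig(n_enzymes=16, alignment_length=400, seed=3)
        alignment, records = generate_enzyme_set(cfg)
        assert len(alignment) == 16
        assert all(len(seq) == 400 for seq in alignment.values())
        assert len(records) == 16

    def test_triad_and_motif_conserved(self, default_cfg, study):
        alignment = study[0]
        rows = list(alignment.values())
        for col, residue in zip(default_cfg.triad_columns, "SSK"):
            assert {row[col] for row in rows} == {residue}
        for col in range(*default_cfg.motif_columns):
            letters = {row[col] for row in rows}
            assert len(letters) == 1 and letters <= {"G", "S"}

    def test_planted_columns_vary(self, default_cfg, study):
        alignment = study[0]
        for p in default_cfg.planted_enzyme_columns:
            assert len({seq[p.column] for seq in alignment.values()}) >= 2

    def test_overlapping_planted_column_rejected(self):
        with pytest.raises((SyntheticError, ValueError), match="planted|triad"):
            ak.SyntheticConfig(
                planted_enzyme_columns=[
                    ak.synthetic.PlantedEnzymeEffect(column=114, factor=3, effect=1.0)
                ]
            )


class TestSubstrateGeneration:
    def test_panel_of_17_unique_ids(self, study):
        substrates = study[2]
        ids = [s.substrate_id for s in substrates]
        assert len(ids) == 17 and len(set(ids)) == 17

    def test_generated_anilides_carry_the_indicator(self, study):
        for s in study[2]:
            feats = ak.chemical_descriptors(s.smiles, s.special_case).values
            if s.special_case in ("standard_anilide", "treat_as_anilide"):
                assert feats["ANILIDE"] == 1.0

    def test_determinism_and_extension(self):
        a = generate_substrate_set(ak.SyntheticConfig(n_substrates=60, seed=5))
        b = generate_substrate_set(ak.SyntheticConfig(n_substrates=60, seed=5))
        assert [s.smiles for s in a] == [s.smiles for s in b]
        assert len({s.substrate_id for s in a}) == 60
        for s in a:
            assert ak.chemical_descriptors(s.smiles, s.special_case).values["MW"] > 0

    def test_routes_cover_both_assays(self, study):
        routes = {s.route for s in study[2]}
        assert routes == {"hplc", "colorimetric"}


class TestPlantedModel:
    def test_null_effects_give_half_probability(self):
        cfg = ak.SyntheticConfig(
            seed=1,
            intercept=0.0,
            planted_chemical_effects=ak.synthetic.PlantedChemicalEffects(
                mw_bond=0, mw=0, formal_charge=0
            ),
            planted_enzyme_columns=[],
        )
        alignment, _ = generate_enzyme_set(cfg)
        truth = plant_activity_model(alignment, generate_substrate_set(cfg), cfg)
        assert np.allclose(truth.activation_probability.to_numpy(), 0.5)

    def test_strongly_negative_intercept_silences_everything(self):
        cfg = ak.SyntheticConfig(seed=1, intercept=-60.0)
        alignment, _ = generate_enzyme_set(cfg)
        truth = plant_activity_model(alignment, generate_substrate_set(cfg), cfg)
        assert truth.activity.to_numpy().sum() == 0

    def test_tail_mass_monotonicity(self):
        """A strongly negative amide-tail coefficient must depress activity
        among heavy-tailed substrates (Monte-Carlo over 1000 substrates)."""
        cfg = ak.SyntheticConfig(
            seed=9,
            n_substrates=1000,
            planted_chemical_effects=ak.synthetic.PlantedChemicalEffects(
                mw_bond=-3.0, mw=0.0, formal_charge=0.0
            ),
            planted_enzyme_columns=[],
        )
        alignment, _ = generate_enzyme_set(cfg)
        substrates = generate_substrate_set(cfg)
        truth = plant_activity_model(alignment, substrates, cfg)
        tails = np.array(
            [
                ak.chemical_descriptors(s.smiles, s.special_case).values["MW_bond"]
                for s in substrates
            ]
        )
        rates = truth.activity.to_numpy().mean(axis=0)
        top = rates[tails >= np.quantile(tails, 0.75)].mean()
        bottom = rates[tails <= np.quantile(tails, 0.25)].mean()
        assert top < bottom

    def test_probabilities_and_activity_consistent(self, study):
        truth = study[3]
        prob = truth.activation_probability.to_numpy()
        act = truth.activity.to_numpy()
        assert ((prob >= 0) & (prob <= 1)).all()
        assert set(np.unique(act)) <= {0, 1}


class TestMeasurements:
    def test_noise_free_round_trip_recovers_planted_removal(self):
        cfg = ak.SyntheticConfig(
            seed=4,
            noise_sd_hplc=0.0,
            noise_sd_plate=0.0,
            control_removal_sd=0.0,
            active_removal_sd=0.0,
            active_removal_mean=90.0,
            deterministic_activity=True,
        )
        alignment, _ = generate_enzyme_set(cfg)
        substrates = generate_substrate_set(cfg)
        truth = plant_activity_model(alignment, substrates, cfg)
        meas = simulate_measurements(truth, cfg)
        removals = ak.hitcalling.removal_records(meas)
        active_pairs = truth.activity.stack()
        for rec in removals.itertuples():
            if rec.is_control:
                assert rec.relative_removal == pytest.approx(0.0)
            elif active_pairs.loc[(rec.enzyme_id, rec.substrate_id)] == 1:
                assert rec.relative_removal == pytest.approx(90.0)

    def test_noise_free_exact_recovery_of_truth(self):
        cfg = ak.SyntheticConfig(
            seed=4,
            noise_sd_hplc=0.0,
            noise_sd_plate=0.0,
            control_removal_sd=0.0,
            active_removal_sd=0.0,
            deterministic_activity=True,
        )
        alignment, _, substrates, truth, meas = ak.generate_study(cfg)
        matrix = ak.call_hits(meas, ak.synthetic.default_hitcalling_config(substrates))
        called = matrix.values.loc[truth.activity.index, truth.activity.columns]
        assert (called.to_numpy() == truth.activity.to_numpy()).all()

    def test_control_rows_for_every_substrate(self, study):
        measurements = study[4]
        controls = measurements[measurements["is_control"]]
        assert set(controls["substrate_id"]) == set(measurements["substrate_id"])
        assert set(controls["enzyme_id"]) == {CONTROL_ENZYME_ID}

    def test_noisy_recovery_at_least_95_percent(self, study):
        _, _, substrates, truth, measurements = study
        matrix = ak.call_hits(measurements, ak.synthetic.default_hitcalling_config(substrates))
        called = matrix.values.loc[truth.activity.index, truth.activity.columns]
        agreement = (called.to_numpy() == truth.activity.to_numpy()).mean()
        assert agreement >= 0.95

    def test_measurement_determinism(self, default_cfg, study):
        again = simulate_measurements(study[3], default_cfg)
        pd.testing.assert_frame_equal(again, study[4])


def test_write_run_artifacts(tmp_path, default_cfg):
    paths = ak.synthetic.write_run(default_cfg, tmp_path / "run")
    for key in ("alignment", "substrates", "measurements", "ground_truth"):
        assert key in paths
    aln = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(paths["alignment"], "fasta"):
        aln[rec.id] = str(rec.seq)
    assert len(aln) == default_cfg.n_enzymes
    truth = pd.read_csv(paths["ground_truth"], index_col=0)
    assert truth.shape == (default_cfg.n_enzymes, default_cfg.n_substrates)
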
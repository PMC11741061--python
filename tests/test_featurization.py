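"""Alignment trimming, factor encoding, chemical descriptors, table build."""

import numpy as np
import pandas as pd
import pytest

import amidasekit as ak
from amidasekit.featurization import (
    ATCHLEY_FACTORS,
    AMIDE_UNIT_MASS,
    FeaturizationError,
    VarianceFilterConfig,
    atchley_encode_alignment,
    build_feature_table,
    chemical_descriptors,
    detect_triad,
    trim_to_signature,
)

# Atomic masses for the independent summation oracle.
MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "Cl": 35.453, "F": 18.998, "S": 32.06}


def formula_mass(formula: dict) -> float:
    return sum(MASS[el] * n for el, n in formula.items())


class TestTrimming:
    def test_explicit_span(self):
        aln = {"A": "M" * 400, "B": "M" * 400}
        block = trim_to_signature(aln, span=(10, 170))
        assert block.n_columns == 160
        assert block.column_map[0] == 10

    def test_span_exceeding_alignment_errors(self):
        aln = {"A": "M" * 100}
        with pytest.raises(FeaturizationError, match="span"):
            trim_to_signature(aln, span=(0, 200))

    def test_detected_triad_inside_trimmed_block(self, default_cfg, study):
        alignment = study[0]
        s1, s2, k = detect_triad(alignment)
        assert {s1, s2, k} == set(default_cfg.triad_columns)
        block = trim_to_signature(alignment)
        assert set(default_cfg.triad_columns) <= set(block.column_map)

    def test_no_triad_and_no_span_errors(self):
        aln = {"A": "MAEL" * 50, "B": "MAEL" * 50}
        with pytest.raises(FeaturizationError, match="span"):
            trim_to_signature(aln)


class TestAtchleyEncoding:
    def test_lookup_matches_bundled_table(self):
        aln = {"A": "W", "B": "S"}
        block = trim_to_signature(aln, span=(0, 1))
        enc = atchley_encode_alignment(block)
        assert tuple(enc.loc["A"]) == ATCHLEY_FACTORS["W"]
        assert tuple(enc.loc["B"]) == ATCHLEY_FACTORS["S"]

    def test_feature_names_use_original_numbering(self):
        aln = {"A": "M" * 50}
        block = trim_to_signature(aln, span=(9, 12))
        enc = atchley_encode_alignment(block)
        assert list(enc.columns)[:4] == ["AA10_f1", "AA10_f2", "AA10_f3", "AA10_f4"]

    def test_gap_vector(self):
        aln = {"A": "-W"}
        block = trim_to_signature(aln, span=(0, 2))
        enc = atchley_encode_alignment(block)
        assert tuple(enc.loc["A"])[:4] == (0.0, 0.0, 0.0, 0.0)

    def test_unknown_residue_errors_with_context(self):
        aln = {"weird": "MX"}
        block = trim_to_signature(aln, span=(0, 2))
        with pytest.raises(FeaturizationError, match="weird"):
            atchley_encode_alignment(block)

    def test_encoding_injective_over_residues(self):
        vectors = set(ATCHLEY_FACTORS.values())
        assert len(vectors) == 20


class TestChemicalDescriptors:
    def test_paracetamol_fragmentation_against_atomic_masses(self):
        feats = chemical_descriptors("CC(=O)Nc1ccc(O)cc1").values
        assert feats["MW_bond"] == pytest.approx(formula_mass({"C": 1, "H": 3}), abs=0.01)
        assert feats["MW_ring"] == pytest.approx(
            formula_mass({"C": 6, "H": 5, "O": 1}), abs=0.01
        )
        assert feats["MW"] == pytest.approx(
            formula_mass({"C": 8, "H": 9, "N": 1, "O": 2}), abs=0.01
        )
        assert feats["ANILIDE"] == 1.0

    def test_acetanilide_and_pivalanilide_tails(self):
        acet = chemical_descriptors("CC(=O)Nc1ccccc1").values
        assert acet["MW_bond"] == pytest.approx(formula_mass({"C": 1, "H": 3}), abs=0.01)
        piv = chemical_descriptors("CC(C)(C)C(=O)Nc1ccccc1").values
        assert piv["MW_bond"] == pytest.approx(formula_mass({"C": 4, "H": 9}), abs=0.01)

    def test_mass_conservation_for_standard_anilides(self):
        """MW_bond + MW_ring + C(=O)NH unit reproduces the molecule mass."""
        cfg = ak.SyntheticConfig(n_substrates=120)
        for s in ak.generate_substrate_set(cfg):
            if s.special_case != "standard_anilide":
                continue
            feats = chemical_descriptors(s.smiles, s.special_case).values
            assert feats["MW_bond"] + feats["MW_ring"] + AMIDE_UNIT_MASS == pytest.approx(
                feats["MW"], abs=0.05
            ), s.substrate_id

    def test_acesulfame_rule_exact(self):
        feats = chemical_descriptors("CC1=CC(=O)NS(=O)(=O)O1", "acesulfame_rule").values
        assert feats["MW_bond"] == feats["MW"] / 2
        assert feats["MW_ring"] == feats["MW"] / 2

    def test_primary_amide_rule(self):
        feats = chemical_descriptors("NC(=O)c1ccccc1", "primary_amide_rule").values
        assert feats["MW_bond"] == pytest.approx(1.008)
        assert feats["MW_ring"] == pytest.approx(formula_mass({"C": 6, "H": 5}), abs=0.01)

    def test_ester_treated_as_amide(self):
        feats = chemical_descriptors(
            "CCCC(=O)Oc1ccc([N+](=O)[O-])cc1", "ester_as_amide"
        ).values
        assert feats["MW_bond"] == pytest.approx(formula_mass({"C": 3, "H": 7}), abs=0.01)
        assert feats["formal_charge_count"] == 2.0

    def test_neutral_molecule_has_zero_charge_count(self):
        assert chemical_descriptors("CC(=O)Nc1ccccc1").values["formal_charge_count"] == 0.0

    def test_unparseable_structure_errors(self):
        with pytest.raises(FeaturizationError, match="unparseable"):
            chemical_descriptors("not-a-smiles(((")

    def test_no_hydrolyzable_bond_prompts_special_case(self):
        with pytest.raises(FeaturizationError, match="special case"):
            chemical_descriptors("c1ccccc1")


class TestFeatureTable:
    def test_row_count_is_matrix_cells(self, feature_table):
        assert len(feature_table.data) == 16 * 17
        assert feature_table.labels.index.equals(feature_table.data.index)

    def test_constant_columns_removed(self, feature_table):
        variances = feature_table.data.var()
        assert (variances > 0).all()
        assert len(feature_table.removed_features) > 0

    def test_near_zero_variance_rule(self):
        data = pd.DataFrame(
            {
                "rare": [0.0] * 271 + [1.0],
                "fine": np.linspace(0, 1, 272),
            },
            index=pd.MultiIndex.from_product(
                [[f"E{i}" for i in range(16)], [f"S{j}" for j in range(17)]],
                names=["enzyme_id", "substrate_id"],
            ),
        )
        from amidasekit.featurization import _near_zero_variance

        cfg = VarianceFilterConfig(near_zero=True)
        assert _near_zero_variance(data["rare"], cfg)
        assert not _near_zero_variance(data["fine"], cfg)

    def test_filtering_never_removes_rows(self, default_cfg, study):
        alignment, _, substrates, truth, _ = study
        block = trim_to_signature(alignment, span=default_cfg.signature_span)
        table = build_feature_table(
            atchley_encode_alignment(block),
            ak.featurization.chemical_feature_table(
                ak.synthetic.substrates_to_frame(substrates)
            ),
            ak.ActivityMatrix(values=truth.activity),
            VarianceFilterConfig(near_zero=True),
        )
        assert len(table.data) == 272

    def test_missing_label_errors(self, default_cfg, study):
        alignment, _, substrates, truth, _ = study
        block = trim_to_signature(alignment, span=default_cfg.signature_span)
        enc = atchley_encode_alignment(block).drop(index=truth.activity.index[0])
        with pytest.raises(FeaturizationError, match="missing"):
            build_feature_table(
                enc,
                ak.featurization.chemical_feature_table(
                    ak.synthetic.substrates_to_frame(substrates)
                ),
                ak.ActivityMatrix(values=truth.activity),
            )

    def test_csv_round_trip(self, feature_table, tmp_path):
        path = tmp_path / "table.csv"
        feature_table.to_csv(path)
        back = ak.FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, feature_table.data)
        assert (back.labels.to_numpy() == feature_table.labels.to_numpy()).all()
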
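import pytest

import amidasekit as ak


@pytest.fixture(scope="session")
def default_cfg():
    return ak.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_cfg):
    """One full synthetic study shared across read-only tests:
    (alignment, enzyme records, substrates, ground truth, measurements)."""
    return ak.generate_study(default_cfg)


@pytest.fixture(scope="session")
def feature_table(default_cfg, study):
    alignment, _, substrates, truth, _ = study
    block = ak.trim_to_signature(alignment, span=default_cfg.signature_span)
    enzyme_features = ak.atchley_encode_alignment(block)
    chem = ak.featurization.chemical_feature_table(
        ak.synthetic.substrates_to_frame(substrates)
    )
    matrix = ak.ActivityMatrix(values=truth.activity)
    return ak.build_feature_table(enzyme_features, chem, matrix)
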
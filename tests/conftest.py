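import pytest

from interonet import (
    PredictionParameters,
    SynthConfig,
    gen_homology_table,
    gen_reference_interactomes,
    predict_network,
)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return SynthConfig(
        seed=7,
        n_proteins_ref_a=60,
        n_proteins_ref_b=45,
        n_autophagy_a=50,
        n_autophagy_b=40,
        n_interactions_a=90,
        n_interactions_b=70,
        n_target_proteins=90,
        n_conserved_interologs=24,
        n_genes=400,
        frac_up=0.1,
        frac_down=0.3,
        coexpr_cluster_sizes=[5, 4],
        noise_sd=0.1,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """Reference interactomes, homology table, truth and predicted network."""
    ref_a, ref_b = gen_reference_interactomes(small_config)
    homology, truth = gen_homology_table(ref_a, ref_b, small_config)
    params = PredictionParameters()
    predicted = predict_network(ref_a, ref_b, homology, params)
    return {
        "config": small_config,
        "ref_a": ref_a,
        "ref_b": ref_b,
        "homology": homology,
        "truth": truth,
        "params": params,
        "predicted": predicted,
    }
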
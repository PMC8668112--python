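import numpy as np
import pytest

from edscape import synthio


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config shared by the hermetic integration tests."""
    return synthio.SimConfig(
        seed=20240601,
        n_true_sites=80,
        n_snv_confounders=20,
        n_strand_bias_artifacts=15,
        n_position_bias_artifacts=15,
        n_paralog_confounders=10,
        n_mrna_transcripts=12,
        n_lncrna_transcripts=12,
        mean_depth=25.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Generated annotation + truth + evidence, shared across tests."""
    rng = np.random.default_rng(small_config.seed)
    annotation = synthio.generate_annotation(small_config, rng)
    truth = synthio.plant_editing_sites(small_config, annotation, rng)
    evidence = synthio.simulate_read_evidence(small_config, truth, rng)
    return {
        "config": small_config,
        "annotation": annotation,
        "truth": truth,
        "evidence": evidence,
        "reference": {annotation.chrom: "".join(annotation.sequence)},
    }


@pytest.fixture(scope="session")
def small_sim_dir(small_config, tmp_path_factory):
    """Full on-disk output of the generator for file-based stages."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = synthio.simulate_all(small_config, outdir)
    return paths
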
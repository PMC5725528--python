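import numpy as np
import pytest

from tailseg.simulate import (SimulationConfig, simulate_annotation,
                              simulate_coverage_pair)


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed (cleaved/uncleaved) synthetic annotation."""
    cfg = SimulationConfig(n_transcripts=40, seed=3)
    models, seqs, truth = simulate_annotation(cfg)
    return cfg, models, seqs, truth


@pytest.fixture(scope="session")
def cleaved_pipeline():
    """A fully-cleaved dataset run through the whole segmentation pipeline."""
    import warnings

    from tailseg.pipeline import segment_transcriptome

    cfg = SimulationConfig(n_transcripts=120, seed=5, cleavage_prob=1.0)
    models, seqs, truth = simulate_annotation(cfg)
    control, treated = simulate_coverage_pair(models, truth, cfg, "tex")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = segment_transcriptome(models, control, treated,
                                       mode="deplete", treatment_label="tex")
    return cfg, models, seqs, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
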
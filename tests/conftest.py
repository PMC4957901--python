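import logging

import pytest

import mirprog as mp

logging.getLogger("mirprog").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim():
    """One default synthetic dataset shared across the suite."""
    cfg = mp.SimulationConfig(seed=1)
    mirna, mrna, truth = mp.simulate_counts(cfg)
    annotations = mp.simulate_annotations(truth, cfg)
    candidates = mp.simulate_interaction_db(truth)
    return cfg, mirna, mrna, truth, annotations, candidates


@pytest.fixture(scope="session")
def pipeline_result(sim, tmp_path_factory):
    """A full default pipeline run on the shared synthetic dataset."""
    cfg, mirna, mrna, truth, annotations, candidates = sim
    pcfg = mp.PipelineConfig(seed=cfg.seed)
    outdir = tmp_path_factory.mktemp("run")
    return mp.run_pipeline(
        pcfg, outdir, mirna_counts=mirna, mrna_counts=mrna,
        candidates=candidates, annotations=annotations,
    )
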
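"""Shared fixtures: one synthetic study simulated and analyzed once per
session, reused by the recovery and end-to-end tests."""

from __future__ import annotations

import pytest

from pirome import pipeline, synthetic_data as sd

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default synthetic study: (config, ground truth, output dir)."""
    outdir = tmp_path_factory.mktemp("sim")
    config = sd.default_config(seed=SIM_SEED)
    truth = sd.simulate_all(config, outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def pipeline_run(sim):
    """Full pipeline executed on the default synthetic study."""
    config, truth, outdir = sim
    cfg_path = pipeline.write_pipeline_config(truth, outdir, SIM_SEED)
    cfg = pipeline.load_config(cfg_path)
    manifest = pipeline.run_all(cfg)
    return cfg, manifest, truth, outdir / "results"
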
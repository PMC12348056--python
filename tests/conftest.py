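"""Shared fixtures: the default study datasets, simulated once per session."""

import numpy as np
import pytest

import glycodemux as g
from glycodemux import demux, pipeline
from glycodemux.core_io import RunConfig
from glycodemux.synthdata import SC_DOUBLET_RATE, SN_DOUBLET_RATE


@pytest.fixture(scope="session")
def sc_design():
    return g.barnyard_design(2, "sc", 20_000, seed=1)


@pytest.fixture(scope="session")
def sn_design():
    return g.barnyard_design(2, "sn", 20_000, seed=1)


@pytest.fixture(scope="session")
def sc_data(sc_design):
    return g.simulate_dataset(sc_design)


@pytest.fixture(scope="session")
def sn_data(sn_design):
    return g.simulate_dataset(sn_design)


@pytest.fixture(scope="session")
def sc_config():
    return RunConfig(random_seed=1, expected_doublet_rate=SC_DOUBLET_RATE)


@pytest.fixture(scope="session")
def sn_config():
    return RunConfig(random_seed=1, expected_doublet_rate=SN_DOUBLET_RATE)


@pytest.fixture(scope="session")
def sc_calls(sc_data, sc_config):
    return demux.demux_all(sc_data[0], sc_config)


@pytest.fixture(scope="session")
def sn_calls(sn_data, sn_config):
    return demux.demux_all(sn_data[0], sn_config)


@pytest.fixture(scope="session")
def sc_report(sc_design, sc_config):
    return pipeline.run_pipeline(sc_design, sc_config, "", write_outputs=False)


@pytest.fixture(scope="session")
def sn_report(sn_design, sn_config):
    return pipeline.run_pipeline(sn_design, sn_config, "", write_outputs=False)


@pytest.fixture(scope="session")
def pbmc_run(tmp_path_factory, sn_config):
    """Full PBMC pipeline run with outputs on disk."""
    out = tmp_path_factory.mktemp("pbmc_run")
    design = g.pbmc_design(20_000, seed=1)
    report = pipeline.run_pipeline(design, sn_config, out)
    return {"design": design, "report": report, "out": out}
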
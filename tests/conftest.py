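from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fragmito.io import PipelineConfig
from fragmito.modulefind import call_mito_contigs, find_modules
from fragmito.simulate import SimConfig, simulate_assembly


@pytest.fixture(scope="session")
def sim_default():
    """Seed-1 default simulation (scrambled): contigs, coverage, truth."""
    return simulate_assembly(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_modules(sim_default):
    contigs, _, manifest = sim_default
    return find_modules(contigs, manifest.mito_refs, table_id=4)


@pytest.fixture(scope="session")
def sim_mito_calls(sim_default, sim_modules):
    contigs, _, _ = sim_default
    return call_mito_contigs(contigs, sim_modules)


@pytest.fixture()
def pipeline_cfg():
    return PipelineConfig()
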
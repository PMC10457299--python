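"""Shared fixtures: a small simulated experiment and its VCF on disk."""

import numpy as np
import pytest

from bulkscan import simbulk


@pytest.fixture(scope="session")
def demo_map() -> simbulk.GeneticMap:
    """Two small chromosomes, 100 evenly spaced sites each."""
    return simbulk.evenly_spaced_map(
        [("A01", 5_000_000, 50.0), ("A02", 4_000_000, 40.0)], 100
    )


@pytest.fixture(scope="session")
def demo_result(demo_map) -> simbulk.SimResult:
    """A null experiment (no QTL) with 5% planted artifact sites."""
    cfg = simbulk.SimConfig(seed=42, n_lines=60, bulk_size=12, artifact_fraction=0.05)
    return simbulk.simulate_dataset(demo_map, cfg, qtls=None, env_sd=1.0)


@pytest.fixture(scope="session")
def demo_vcf(demo_result, demo_map, tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("vcf") / "demo.vcf"
    simbulk.write_vcf(demo_result.sites, demo_map, str(path))
    return str(path)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
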
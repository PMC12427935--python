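"""Shared fixtures: small simulated datasets generated at test time."""

import numpy as np
import pytest

import damidte as d


def small_config(seed: int = 7, **overrides) -> d.SimulationConfig:
    """Desk-size simulation for fast pipeline tests: small genome, few TEs,
    modest depth."""
    cfg = d.SimulationConfig(
        seed=seed,
        genome_length=150_000,
        te_families={
            "LTR": d.TEFamilySpec(4, 800, 2, 4.0),
            "LINE": d.TEFamilySpec(3, 800, 2, 3.0),
            "DNA": d.TEFamilySpec(3, 800, 2, 2.0),
            "other": d.TEFamilySpec(2, 800, 1, 2.0),
        },
        reads_per_sample=5000,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return d.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_emitted(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    d.emit_dataset(small_config(), outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def manifest_for(dataset) -> d.SampleManifest:
    """In-memory manifest for a SimulatedDataset (paths unused)."""
    return d.SampleManifest(
        dataset.manifest_frame.assign(genome_alignments="-", te_alignments="-")
    )
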
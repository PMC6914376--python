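import numpy as np
import pytest

from nbspanel import (
    ReferenceSequence,
    SimulationConfig,
    build_panel,
    make_reference,
    make_truth_and_calls,
)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast unit tests: 6 kb panel, 4 pairs."""
    return SimulationConfig(
        seed=7,
        n_genes=3,
        exons_per_gene=(5, 4, 3),
        target_panel_bases=6000,
        n_truth_snvs=30,
        n_truth_indels=2,
        n_pairs=4,
        depth_window=100,
        fraction_low_coverage_windows=0.05,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    synref = make_reference(small_config)
    panel = build_panel(synref.exons, small_config.panel_padding)
    return make_truth_and_calls(small_config, synref, panel)


@pytest.fixture()
def polyt_contig():
    return ReferenceSequence("c1", "GTTTTTTC")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
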
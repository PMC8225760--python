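import numpy as np
import pytest

from classf import synthetic_data as syn


@pytest.fixture(scope="session")
def helix_spec():
    return syn.HelixSpec(n_res=21)


@pytest.fixture(scope="session")
def ideal_helix(helix_spec):
    return syn.build_ideal_helix(helix_spec)


@pytest.fixture(scope="session")
def helix_map(helix_spec):
    return syn.helix_residue_map(helix_spec)


@pytest.fixture(scope="session")
def vertex_residue(helix_spec):
    return helix_spec.residue_start + helix_spec.n_res // 2


@pytest.fixture(scope="session")
def small_ensemble(helix_spec):
    """Two short replicas with the FZD6-like kink law (seeded)."""
    return syn.generate_trajectory(
        helix_spec,
        syn.kink_preset("fzd6"),
        syn.EnsembleSpec(replica_lengths_ns=(5.0, 2.0), frame_interval_ps=100.0, seed=11),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
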
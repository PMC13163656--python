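import numpy as np
import pytest
from hypothesis import settings

import geneimage as g

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session", autouse=True)
def _warm_train_kernel():
    """Compile the training kernel once so timings reflect the algorithm."""
    model = g.init_mlp(g.MLPConfig(n_inputs=6, n_outputs=2, seed=0, max_epochs=50), ["a", "b"])
    try:
        g.train_online(
            model,
            [np.zeros(6), np.ones(6)],
            [np.eye(2)[0], np.eye(2)[1]],
        )
    except g.NonConvergenceError:
        pass


@pytest.fixture(scope="session")
def tiny_panel():
    """Four organisms with short, clearly distinct barcode proteins."""
    return [
        g.OrganismRecord("alpha", "Alpha alpha", "MKLVWA", "GHIRNDE"),
        g.OrganismRecord("beta", "Beta beta", "MKLVYA", "GHIRNDQ"),
        g.OrganismRecord("gamma", "Gamma gamma", "TTSSPP", "CCWWFF-"),
        g.OrganismRecord("delta", "Delta delta", "AAAAAA", "EEEEEEE"),
    ]


@pytest.fixture(scope="session")
def tiny_ref():
    return g.ReferenceLengths(cytb_len=6, coi_len=7)


@pytest.fixture(scope="session")
def ladder_panel():
    """A seeded 6-organism chain with known ancestry (session-cached)."""
    cfg = g.SimulationConfig(
        cytb_codons=30, coi_codons=40, topology="chain:6",
        subs_per_branch=4, kappa=3.0, seed=11,
    )
    records, truth = g.generate_panel(cfg)
    return cfg, records, truth
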
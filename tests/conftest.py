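import numpy as np
import pytest

from pepsite.features import build_residue_graph
from pepsite.fixtures import FixtureSpec, make_complex, make_helix
from pepsite.model import ModelConfig, ReciprocalAttentionNetwork
from pepsite.training import TrainConfig, TrainingExample, train

TINY_CONFIG = dict(
    d_model=32, d_i=32, d_k=16, d_v=32, heads=2, n_blocks=2, dropout=0.1,
    graph_k=8, seed=0,
)


@pytest.fixture(scope="session")
def helix40():
    return make_helix(40, seed=1)


@pytest.fixture(scope="session")
def binder_complexes():
    """Eight planted binder fixtures used as the toy training set."""
    out = []
    for i in range(8):
        record, labels = make_complex(FixtureSpec(seed=i), verify_bsa=False)
        out.append((record, labels))
    return out


@pytest.fixture(scope="session")
def training_examples(binder_complexes):
    return [
        TrainingExample(
            build_residue_graph(rec.receptor, k=8), rec.partner.sequence, labels
        )
        for rec, labels in binder_complexes
    ]


@pytest.fixture(scope="session")
def tiny_model():
    return ReciprocalAttentionNetwork(ModelConfig(**TINY_CONFIG))


@pytest.fixture(scope="session")
def overfit_run(training_examples):
    """One seeded overfit run on the eight planted binders.

    Session-scoped: the overfit-capability check and the peptide-agnostic
    discrimination check both read from this run.
    """
    model = ReciprocalAttentionNetwork(ModelConfig(**TINY_CONFIG))
    _, history = train(
        model,
        training_examples,
        training_examples[:2],
        TrainConfig(lr=1e-3, max_iters=500, seed=0, eval_every=100, patience=50),
    )
    return model, history


@pytest.fixture(scope="session")
def heldout_graphs():
    """Six held-out binders and six decoys, featurized (k = 8)."""
    binders, decoys = [], []
    for i in range(6):
        rec, _ = make_complex(FixtureSpec(seed=100 + i), verify_bsa=False)
        binders.append(build_residue_graph(rec.receptor, k=8))
        rec, _ = make_complex(FixtureSpec(seed=200 + i, patch_distance=10.0),
                              verify_bsa=False)
        decoys.append(build_residue_graph(rec.receptor, k=8))
    return binders, decoys


def random_rigid_motion(rng):
    """Haar-random rotation plus a translation drawn in [-50, 50] Å."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t
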
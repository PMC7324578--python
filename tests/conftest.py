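import numpy as np
import pytest

from simmap.model import SimmapConfig, SiteMoietyModel
from simmap.synthetic import make_planted_poses, make_toy_pocket


@pytest.fixture(scope="session")
def toy():
    """Default planted pocket: EH@ARG1, H@ASN3, V@LEU5+LEU6, rest ALA."""
    return make_toy_pocket()


@pytest.fixture(scope="session")
def pocket(toy):
    return toy.pocket()


@pytest.fixture(scope="session")
def planted100(toy):
    """100 planted poses with p_hot=1, p_bg=0: deterministic contacts."""
    poses, scores, truth = make_planted_poses(toy, 100, seed=11)
    return poses, scores, truth


@pytest.fixture(scope="session")
def fitted(toy, planted100):
    poses, scores, _ = planted100
    model = SiteMoietyModel(
        toy.structure,
        toy.ligand_coords(),
        poses,
        scores,
        SimmapConfig(top_k=100, n_shuffles=500, seed=5),
        reference_ligand_id="ACD",
    )
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
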
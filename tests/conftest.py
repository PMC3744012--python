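import numpy as np
import pytest

import facespace as fs


@pytest.fixture(scope="session")
def small_pool_params():
    return fs.PoolParams(N=3, r=0.01, alpha=3.0)


@pytest.fixture(scope="session")
def random_map():
    """A directly constructed 10-classifier map (no training) for win-region
    and discrimination geometry tests."""
    rng = np.random.default_rng(7)
    azel = rng.uniform(10, 80, size=(10, 2))
    weights = fs.azel_to_unit(azel)
    spec = fs.PopulationSpec(center_azel=(45.0, 45.0), sd_azel=(8.0, 8.0),
                             count=200, label="pop")
    points = fs.sample_face_space([spec], seed=3)
    return fs.ClassifierMap(
        weights=weights,
        classifier_azel=azel,
        params=fs.PoolParams(N=10, r=0.001, alpha=10.0),
        schedule=fs.TrainSchedule(epochs=1),
        specs=(spec,),
        seed=3,
        points=points,
    )


@pytest.fixture(scope="session")
def face_images():
    """Small two-population face set shared across image tests."""
    return fs.sample_face_population(10, 4, seed=11)


@pytest.fixture(scope="session")
def small_hierarchy(face_images):
    """A quickly trained hierarchy (reduced epochs) for interface tests."""
    cfg = fs.HierarchyConfig(N2=5, seed=11, layer1_epochs=10, layer2_epochs=20)
    return fs.train_hierarchy(face_images, cfg)
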
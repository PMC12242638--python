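import numpy as np
import pytest

from phorescreen.pharmacophore import (
    FeatureKind,
    LigandFeature,
    PharmacophoreModel,
    PharmacophorePoint,
    builtin_model,
)


@pytest.fixture(scope="session")
def rock1():
    return builtin_model("ROCK1")


@pytest.fixture(scope="session")
def rock2():
    return builtin_model("ROCK2")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_match_instance(rng):
    """One random matcher instance: features, model, required labels."""
    kinds = list(FeatureKind)
    n_points = int(rng.integers(1, 6))
    n_feats = int(rng.integers(1, 9))
    points = [
        PharmacophorePoint(
            kind=kinds[int(rng.integers(3))],
            center=tuple(rng.uniform(-5, 5, 3)),
            radius=float(rng.uniform(0.3, 2.0)),
            weight=float(rng.choice([1.0, 5.0, 10.0])),
            label=f"p{i}",
        )
        for i in range(n_points)
    ]
    model = PharmacophoreModel("random", tuple(points))
    features = [
        LigandFeature(kinds[int(rng.integers(3))], tuple(rng.uniform(-5, 5, 3)))
        for _ in range(n_feats)
    ]
    require = (points[0].label,) if rng.random() < 0.5 else ()
    return features, model, require


def exact_model_features(model):
    """Features placed exactly on the model's point centers, same kinds."""
    return [LigandFeature(p.kind, p.center) for p in model.points]
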
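import numpy as np
import pandas as pd
import pytest

from esdm.raster_io import EnvStack, GridTransform, OccurrenceSet


def stack_from_arrays(layers: dict, transform=None, crs="projected") -> EnvStack:
    """Build an EnvStack from plain 2-D arrays (helper for hand-built grids)."""
    arrays = {k: np.asarray(v, float).copy() for k, v in layers.items()}
    nrows = next(iter(arrays.values())).shape[0]
    if transform is None:
        transform = GridTransform(0.0, float(nrows) * 1000.0, 1000.0, 1000.0)
    return EnvStack(layers=arrays, transform=transform, crs=crs)


def presences_at(xy, species="sp") -> OccurrenceSet:
    xy = np.asarray(xy, float)
    return OccurrenceSet(
        species=species,
        points=pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "label": "presence"}),
    )


@pytest.fixture
def gradient_stack():
    """10×10 projected stack: 'grad' increases with column, 'flat' is constant 7."""
    grad = np.tile(np.arange(10, dtype=float), (10, 1))
    flat = np.full((10, 10), 7.0)
    return stack_from_arrays({"grad": grad, "flat": flat})


@pytest.fixture(scope="session")
def fitted_fixture():
    """A modest virtual-species dataset with one fitted model per algorithm.

    Session-scoped because fitting four algorithms dominates suite runtime.
    """
    import esdm

    stack, vs, occ = esdm.default_fixture(seed=11, shape=(60, 60), n_presence=120)
    occ_all = esdm.make_background(stack, occ, seed=12)
    table = esdm.extract_features(stack, occ_all)
    labels = (table["label"] == "presence").to_numpy().astype(int)
    features = table[stack.layer_names]
    ds = esdm.split(features, labels, seed=13)
    Xtr, ytr = ds.part("train")
    Xte, yte = ds.part("test")
    models = {
        alg: esdm.fit(alg, Xtr, ytr, variables=stack.layer_names, seed=14)
        for alg in esdm.ALGORITHMS
    }
    return {
        "stack": stack,
        "species": vs,
        "features": features,
        "labels": labels,
        "dataset": ds,
        "test": (Xte, yte),
        "models": models,
    }
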
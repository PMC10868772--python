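import numpy as np
import pytest
from hypothesis import settings

from leaftda.landmark_io import Leaf, LeafDataset, LandmarkScheme, builtin_scheme

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_leaf(
    leaf_id="leaf",
    landmarks=((0.0, 0.0), (1.0, 0.0), (0.0, 1.0)),
    group="spA",
    vine="v1",
    node=1,
    relative_node=None,
):
    return Leaf(
        leaf_id=leaf_id,
        group_label=group,
        vine_id=vine,
        node_index=node,
        landmarks=np.asarray(landmarks, dtype=float),
        relative_node=relative_node,
    )


def scheme_for(n, name=None):
    return LandmarkScheme(
        name or f"test{n}", n, tuple(f"lm{i}" for i in range(n)), axis_indices=(0, n - 1)
    )


def make_dataset(leaves, scheme=None):
    if scheme is None:
        n = leaves[0].n_landmarks
        scheme = scheme_for(n)
    return LeafDataset(scheme, tuple(leaves))


@pytest.fixture
def triangle_leaf():
    return make_leaf()


@pytest.fixture
def grapevine_scheme():
    return builtin_scheme("grapevine")


@pytest.fixture
def two_vine_dataset():
    """Two vines with different node sets (one with gaps)."""
    leaves = [
        make_leaf(f"a{n}", vine="vineA", node=n, group="sp1") for n in (1, 2, 3, 4, 5)
    ] + [make_leaf(f"b{n}", vine="vineB", node=n, group="sp2") for n in (3, 5, 9)]
    return make_dataset(leaves)
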
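"""Shared fixtures: synthetic datasets and precomputed region graphs.

The expensive fixtures are session-scoped so the learning tests, which
dominate the runtime, share one generated corpus and one set of graphs.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from gacnn.graphbuild import GraphBuildConfig, build_graph
from gacnn.network import BackboneConfig, FusionConfig, GCNConfig
from gacnn.synthetic import LabeledImageSet, SyntheticSpec, generate_dataset

DESK_SIDE = 64


@pytest.fixture(scope="session")
def graph_cfg():
    return GraphBuildConfig(max_nodes=32)


@pytest.fixture(scope="session")
def desk_backbone():
    return BackboneConfig(input_side=DESK_SIDE, width_multiplier=1 / 8)


@pytest.fixture(scope="session")
def desk_gcn():
    return GCNConfig(hidden=16)


@pytest.fixture(scope="session")
def desk_fusion():
    return FusionConfig(fused_dim=64)


@pytest.fixture(scope="session")
def tiny_set():
    """Six images per class at desk resolution, for fast functional tests."""
    return generate_dataset(SyntheticSpec(image_side=DESK_SIDE, n_per_class=6,
                                          seed=7))


@pytest.fixture(scope="session")
def tiny_graphs(tiny_set, graph_cfg):
    return [build_graph(im, graph_cfg) for im in tiny_set.images]


@pytest.fixture(scope="session")
def study_bundle(graph_cfg):
    """The desk-scale study corpus: 60/class train, 12/class held-out test.

    ``subset(n)`` returns the first n images per class of the train set
    with their (shared) graphs, for sweeps at reduced size.
    """
    train = generate_dataset(SyntheticSpec(image_side=DESK_SIDE,
                                           n_per_class=60, seed=100))
    test = generate_dataset(SyntheticSpec(image_side=DESK_SIDE,
                                          n_per_class=12, seed=200))
    train_graphs = [build_graph(im, graph_cfg) for im in train.images]
    test_graphs = [build_graph(im, graph_cfg) for im in test.images]

    def subset(n_per_class):
        labels = np.asarray(train.labels)
        keep = []
        for c in sorted(set(train.labels)):
            keep.extend(np.flatnonzero(labels == c)[:n_per_class])
        keep = sorted(keep)
        sub = LabeledImageSet([train.images[i] for i in keep],
                              [train.labels[i] for i in keep],
                              [train.ids[i] for i in keep])
        return sub, [train_graphs[i] for i in keep]

    return SimpleNamespace(train=train, test=test, train_graphs=train_graphs,
                           test_graphs=test_graphs, subset=subset)
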
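import numpy as np
import pytest
import skbio

from grinscan.synthetic_data import (
    GeneratorConfig,
    flagship_cluster,
    generate_cluster,
    plant_duplication,
)
from grinscan.window_scan import ScanParams, call_duplicated_regions, max_identity_profile


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> skbio.TreeNode:
    """Random unrooted binary tree with branch lengths in [0.05, 1.0]."""
    nodes = [
        skbio.TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        pair = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(
            skbio.TreeNode(children=pair, length=float(rng.uniform(0.05, 1.0)))
        )
    return skbio.TreeNode(children=nodes)


@pytest.fixture(scope="session")
def tandem_truth():
    """10-kb cluster with one 900-bp tandem duplicate at sub_rate 0.05."""
    cfg = GeneratorConfig(seed=7, n_modules=9, module_len=900, intermodule_len=100)
    truth = generate_cluster(cfg)
    m2 = truth.regions[1]
    return plant_duplication(truth, (m2.start, m2.end), m2.end, 0.05, seed=11, frame=0)


@pytest.fixture(scope="session")
def tandem_scan_exhaustive(tandem_truth):
    params = ScanParams(prefilter_k=None)
    profile = max_identity_profile(tandem_truth.cluster, params)
    return params, profile, call_duplicated_regions(profile, params)


@pytest.fixture(scope="session")
def flagship_truth():
    return flagship_cluster(seed=3)
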
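"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from paralog_fates.trees import SpeciesTree


def random_newick(n_leaves: int, rng: random.Random) -> str:
    """Random binary topology over s0..s{n-1} by sequential joining."""
    nodes = [f"s{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        joined = f"({nodes[i]},{nodes[j]})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0] + ";"


def brute_force_min_cost(
    tree: SpeciesTree,
    counts: pd.Series,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    max_state: int = 3,
) -> float:
    """Exhaustive minimum event cost over all internal-node state labelings."""

    def trans(s: int, t: int) -> float:
        return cost_dup * max(0, t - s) + cost_loss * max(0, s - t)

    internals = [n for n in tree.preorder_ids() if not tree.nodes[n].is_leaf]
    best = float("inf")
    for states in itertools.product(range(max_state + 1), repeat=len(internals)):
        assign = dict(zip(internals, states))
        for leaf in tree.leaf_ids():
            assign[leaf] = int(counts[leaf])
        cost = sum(
            trans(assign[tree.nodes[nid].parent], assign[nid])
            for nid in tree.preorder_ids()
            if nid != tree.root_id
        )
        best = min(best, cost)
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
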
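"""Duplication/loss timing by weighted (Sankoff) parsimony.

Given a rooted species tree and one gene family's copy numbers at the
leaves, a dynamic program over per-node copy-number states finds the
minimum-cost assignment of internal states, where moving from a parent
state ``s`` to a child state ``t`` costs ``cost_dup * max(0, t - s) +
cost_loss * max(0, s - t)``. Duplication and loss events are read off
parent-to-child state changes; among co-optimal labelings, ties break
deterministically in favor of placing events later in time (closer to
the leaves). The earliest duplication in preorder is labeled "primary"
(the event that gave rise to the major paralog groups); all other events
are "secondary".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import SpeciesTree

logger = logging.getLogger(__name__)

INF = float("inf")


@dataclass
class Event:
    branch: str
    kind: str  # "dup" | "loss"
    multiplicity: int


@dataclass
class EventMap:
    """Per-family duplication/loss reconstruction on a species tree."""

    family: str
    events: list[Event]
    total_cost: float
    root_state: int
    node_states: dict[str, int]
    primary_duplication_branch: str | None = None
    n_cooptimal: int = 1
    flags: list[str] = field(default_factory=list)
    wgd_branches: list[str] = field(default_factory=list)  # user-supplied annotation

    def duplications(self) -> list[Event]:
        return [e for e in self.events if e.kind == "dup"]

    def losses(self) -> list[Event]:
        return [e for e in self.events if e.kind == "loss"]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "total_cost": self.total_cost,
            "root_state": self.root_state,
            "n_cooptimal_labelings": self.n_cooptimal,
            "primary_duplication_branch": self.primary_duplication_branch,
            "events": [
                {"branch": e.branch, "kind": e.kind, "multiplicity": e.multiplicity}
                for e in self.events
            ],
            "node_states": self.node_states,
            "flags": self.flags,
            "wgd_branches": self.wgd_branches,
        }


def _transition_cost(s: int, t: int, cost_dup: float, cost_loss: float) -> float:
    return cost_dup * max(0, t - s) + cost_loss * max(0, s - t)


def sankoff_events(
    tree: SpeciesTree,
    counts: pd.Series,
    max_copies: int | None = None,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    root_prior: int | None = None,
    family: str = "family",
) -> EventMap:
    """Minimum-cost duplication/loss reconstruction for one family.

    Parameters
    ----------
    counts:
        copy number per leaf (indexed by leaf id); all leaves required.
    max_copies:
        largest state considered; defaults to max leaf count (+1 slack).
    root_prior:
        fixes the root state (e.g. from outgroup counts); by default the
        root state minimizing total cost is chosen, with ties broken
        toward the smallest state.

    Ties among co-optimal child states break toward keeping the child in
    its parent's state (pushing events leafward, i.e. preferring later
    duplications), then toward the smaller state; the traversal is
    preorder, so the tie-break is deterministic.
    """
    if cost_dup <= 0 or cost_loss <= 0:
        raise ValueError("event costs must be positive")
    leaves = tree.leaf_ids()
    missing = [l for l in leaves if l not in counts.index]
    if missing:
        raise ValueError(f"counts missing for leaves {missing}")
    leaf_counts = counts.loc[leaves].astype(int)
    if (leaf_counts < 0).any():
        raise ValueError("copy numbers must be >= 0")
    if max_copies is None:
        max_copies = int(max(leaf_counts.max(), root_prior or 0) + 1)
    if int(leaf_counts.max()) > max_copies:
        raise ValueError("leaf count exceeds max_copies")
    if root_prior is not None and root_prior > max_copies:
        raise ValueError("root_prior exceeds max_copies")
    n_states = max_copies + 1
    states = range(n_states)

    cost: dict[str, np.ndarray] = {}
    ncool: dict[str, np.ndarray] = {}  # co-optimal subtree labeling counts
    for nid in tree.postorder_ids():
        node = tree.nodes[nid]
        if node.is_leaf:
            c = np.full(n_states, INF)
            c[leaf_counts[nid]] = 0.0
            cost[nid] = c
            k = np.zeros(n_states)
            k[leaf_counts[nid]] = 1
            ncool[nid] = k
            continue
        c = np.zeros(n_states)
        k = np.ones(n_states)
        for child in node.children:
            child_best = np.full(n_states, INF)
            child_k = np.zeros(n_states)
            for s in states:
                tot = [
                    _transition_cost(s, t, cost_dup, cost_loss) + cost[child][t]
                    for t in states
                ]
                best = min(tot)
                child_best[s] = best
                child_k[s] = sum(
                    ncool[child][t] for t in states if tot[t] == best
                )
            c = c + child_best
            k = k * child_k
        cost[nid] = c
        ncool[nid] = k

    root_cost = cost[tree.root_id]
    if root_prior is not None:
        if not np.isfinite(root_cost[root_prior]):
            raise ValueError(f"root state {root_prior} unreachable")
        root_state = int(root_prior)
    else:
        root_state = int(np.argmin(root_cost))
    total = float(root_cost[root_state])
    if not np.isfinite(total):
        raise ValueError("no finite-cost labeling (unreachable states)")
    n_coopt = int(ncool[tree.root_id][root_state])
    if root_prior is None:
        n_coopt = int(
            sum(ncool[tree.root_id][s] for s in states if root_cost[s] == total)
        )

    # top-down backtrack with leafward tie-break
    assign: dict[str, int] = {tree.root_id: root_state}
    for nid in tree.preorder_ids():
        s = assign[nid]
        for child in tree.nodes[nid].children:
            tot = {
                t: _transition_cost(s, t, cost_dup, cost_loss) + cost[child][t]
                for t in states
            }
            best = min(tot.values())
            optimal = [t for t in states if tot[t] == best]
            if s in optimal:
                choice = s  # defer events toward the leaves
            else:
                choice = min(optimal)
            assign[child] = choice

    events: list[Event] = []
    for nid in tree.preorder_ids():
        if nid == tree.root_id:
            continue
        parent_state = assign[tree.nodes[nid].parent]
        delta = assign[nid] - parent_state
        if delta > 0:
            events.append(Event(nid, "dup", delta))
        elif delta < 0:
            events.append(Event(nid, "loss", -delta))

    emap = EventMap(
        family=family,
        events=events,
        total_cost=total,
        root_state=root_state,
        node_states=assign,
        n_cooptimal=n_coopt,
        flags=_independent_loss_flags(tree, events),
    )
    return label_primary(emap, tree)


def _independent_loss_flags(tree: SpeciesTree, events: list[Event]) -> list[str]:
    """Flag single losses placed on a branch ancestral to multiple major clades.

    Losses that parsimony merges onto one deep branch may in reality
    have occurred independently in the descendant lineages; a loss on a
    branch whose two child subtrees both contain >= 2 leaves is flagged
    rather than silently resolved.
    """
    flags = []
    for e in events:
        if e.kind != "loss":
            continue
        node = tree.nodes[e.branch]
        if node.is_leaf:
            continue
        child_leafcounts = [
            sum(1 for nid in _subtree_ids(tree, ch) if tree.nodes[nid].is_leaf)
            for ch in node.children
        ]
        if sum(1 for c in child_leafcounts if c >= 2) >= 2:
            flags.append(
                f"loss on branch {e.branch} spans multiple clades; may represent "
                "independent losses"
            )
    return flags


def _subtree_ids(tree: SpeciesTree, nid: str) -> list[str]:
    out = []
    stack = [nid]
    while stack:
        cur = stack.pop()
        out.append(cur)
        stack.extend(tree.nodes[cur].children)
    return out


def label_primary(event_map: EventMap, tree: SpeciesTree) -> EventMap:
    """Mark the duplication closest to the root (first in preorder) as primary."""
    dups = {e.branch for e in event_map.events if e.kind == "dup"}
    event_map.primary_duplication_branch = None
    if dups:
        for nid in tree.preorder_ids():
            if nid in dups:
                event_map.primary_duplication_branch = nid
                break
    return event_map


def replay_events(
    tree: SpeciesTree, event_map: EventMap, root_state: int | None = None
) -> pd.Series:
    """Recompute leaf counts by replaying the event map from the root state."""
    root = event_map.root_state if root_state is None else root_state
    deltas: dict[str, int] = {}
    for e in event_map.events:
        deltas[e.branch] = deltas.get(e.branch, 0) + (
            e.multiplicity if e.kind == "dup" else -e.multiplicity
        )
    counts: dict[str, int] = {tree.root_id: root}
    for nid in tree.preorder_ids():
        if nid == tree.root_id:
            continue
        counts[nid] = counts[tree.nodes[nid].parent] + deltas.get(nid, 0)
    leaves = tree.leaf_ids()
    return pd.Series([counts[l] for l in leaves], index=pd.Index(leaves, name="species"))


def events_for_matrix(
    tree: SpeciesTree,
    matrix: pd.DataFrame,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    root_prior: int | None = None,
    max_copies: int | None = None,
) -> dict[str, EventMap]:
    """Sankoff reconstruction for every family column of a copy-number matrix."""
    out = {}
    for family in matrix.columns:
        out[family] = sankoff_events(
            tree,
            matrix[family],
            cost_dup=cost_dup,
            cost_loss=cost_loss,
            root_prior=root_prior,
            max_copies=max_copies,
            family=str(family),
        )
    return out
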
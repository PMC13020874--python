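"""Light rooted species-tree wrapper over dendropy.

Gives every node a stable branch identifier (leaf taxon label for
leaves; the node label when present, else ``N<k>`` in preorder for
internal nodes) so that duplication/loss events can be addressed as
"the branch above node X".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy


@dataclass
class TreeNode:
    node_id: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    edge_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree with named branches.

    Branch ``b`` means the edge above the node with id ``b``; the root
    node has no branch.
    """

    def __init__(self, nodes: dict[str, TreeNode], root_id: str,
                 pre_duplication: set[str] | None = None):
        self.nodes = nodes
        self.root_id = root_id
        self.pre_duplication = set(pre_duplication or ())
        unknown = self.pre_duplication - set(self.leaf_ids())
        if unknown:
            raise ValueError(f"pre-duplication flags for unknown leaves: {sorted(unknown)}")

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str | Path,
                    pre_duplication: set[str] | None = None) -> "SpeciesTree":
        text = Path(newick).read_text() if isinstance(newick, Path) else newick
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(tree, pre_duplication=pre_duplication)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      pre_duplication: set[str] | None = None) -> "SpeciesTree":
        nodes: dict[str, TreeNode] = {}
        ids: dict[int, str] = {}
        counter = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("leaf without taxon label")
                node_id = nd.taxon.label
            elif nd.label:
                node_id = nd.label
            else:
                node_id = f"N{counter}"
            counter += 1
            if node_id in nodes:
                raise ValueError(f"duplicate node id {node_id!r}")
            ids[id(nd)] = node_id
            parent = ids[id(nd.parent_node)] if nd.parent_node is not None else None
            nodes[node_id] = TreeNode(
                node_id=node_id,
                parent=parent,
                edge_length=nd.edge.length,
            )
            if parent is not None:
                nodes[parent].children.append(node_id)
        root_id = ids[id(tree.seed_node)]
        return cls(nodes, root_id, pre_duplication=pre_duplication)

    # -- traversal ------------------------------------------------------

    def preorder_ids(self) -> list[str]:
        out: list[str] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            # push reversed so children come off in declaration order
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def postorder_ids(self) -> list[str]:
        return list(reversed(self.preorder_ids()))

    def leaf_ids(self) -> list[str]:
        return [nid for nid in self.preorder_ids() if self.nodes[nid].is_leaf]

    def path_to_root(self, node_id: str) -> list[str]:
        """Branch ids on the path from a node up to (excluding) the root."""
        path = []
        cur: str | None = node_id
        while cur is not None and cur != self.root_id:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path

    def mrca(self, leaves: list[str]) -> str:
        """Node id of the most recent common ancestor of the given leaves."""
        paths = [set(self.path_to_root(l)) | {l, self.root_id} for l in leaves]
        common = set.intersection(*paths)
        # deepest common node = the one whose path to root is longest
        return max(common, key=lambda n: len(self.path_to_root(n)))

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id))

    def branch_ids(self) -> list[str]:
        """All branch ids (every node except the root), in preorder."""
        return [nid for nid in self.preorder_ids() if nid != self.root_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes
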
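"""Shared fixtures and generators for the structphy test suite."""

from __future__ import annotations

import numpy as np
import pytest

from structphy.seqstruct_io import StructuredSequence
from structphy.trees import Node, Tree

NUC = "ACGU"


def random_structure(length: int, rng, open_p: float = 0.3,
                     close_p: float = 0.4) -> str:
    """Random balanced, nested dot-bracket string."""
    out = []
    depth = 0
    for i in range(length):
        remaining = length - i
        if depth >= remaining:  # must close everything still open
            out.append(")")
            depth -= 1
            continue
        r = rng.random()
        if depth > 0 and r < close_p:
            out.append(")")
            depth -= 1
        elif r < close_p + open_p and depth + 1 <= remaining - 1:
            out.append("(")
            depth += 1
        else:
            out.append(".")
    assert depth == 0
    return "".join(out)


def random_structured_sequence(rng, length: int | None = None,
                               ident: str = "r") -> StructuredSequence:
    length = length if length is not None else int(rng.integers(1, 60))
    seq = "".join(NUC[i] for i in rng.integers(0, 4, size=length))
    return StructuredSequence(id=ident, seq=seq,
                              struct=random_structure(length, rng))


def random_unrooted_tree(labels, rng, min_len: float = 0.1,
                         max_len: float = 1.0) -> Tree:
    """Random unrooted binary topology with positive branch lengths."""
    nodes = [Node(label=lab) for lab in labels]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    tree = Tree(Node(children=nodes), rooted=False)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(min_len + (max_len - min_len) * rng.random())
    return tree.sort()


def edge_length_map(tree: Tree) -> dict:
    """Bipartition/pendant-label -> branch length (for additive checks)."""
    from structphy.trees import internal_edges

    out = {}
    for node, side in internal_edges(tree):
        out[side] = node.length
    for leaf in tree.leaves():
        out[leaf.label] = leaf.length
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
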
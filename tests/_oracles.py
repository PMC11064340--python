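"""Independent brute-force oracles, deliberately naive.

Each oracle re-derives an expected value by enumeration or an
alternative algorithm, never by calling the code path under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from structphy.trees import Node, Tree

NEG = float("-inf")


# ---------------------------------------------------------------------------
# exhaustive global affine alignment

def brute_force_affine_score(a: str, b: str, score, gap_open: float,
                             gap_extend: float) -> float:
    """Maximum over ALL global alignments, scored by direct scanning.

    Alignments are enumerated as monotone paths; a gap run of length L
    costs gap_open + (L-1)*gap_extend.
    """
    best = NEG

    def run_cost(length):
        return gap_open + (length - 1) * gap_extend if length else 0.0

    def rec(i, j, acc, gap_state, gap_len):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc - run_cost(gap_len))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]) - run_cost(gap_len),
                None, 0)
        if i < len(a):  # gap in b
            if gap_state == "b":
                rec(i + 1, j, acc, "b", gap_len + 1)
            else:
                rec(i + 1, j, acc - run_cost(gap_len), "b", 1)
        if j < len(b):  # gap in a
            if gap_state == "a":
                rec(i, j + 1, acc, "a", gap_len + 1)
            else:
                rec(i, j + 1, acc - run_cost(gap_len), "a", 1)

    rec(0, 0, 0.0, None, 0)
    return best


# ---------------------------------------------------------------------------
# parsimony oracles

def all_unrooted_topologies(labels):
    """Every unrooted binary topology over the labels (3 -> 1, 6 -> 105)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def leaf(lab):
        return Node(label=lab, length=1.0)

    base = Tree(Node(children=[leaf(l) for l in labels[:3]]), rooted=False)
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in t.postorder() if n is not t.root]
            for k in range(len(edges)):
                t2 = t.copy()
                e2 = [n for n in t2.postorder() if n is not t2.root][k]
                par = t2.parents()[id(e2)]
                joint = Node(length=1.0, children=[e2, leaf(lab)])
                par.children[par.children.index(e2)] = joint
                nxt.append(t2)
        trees = nxt
    return trees


def sankoff_column_score(tree: Tree, states: dict, k: int) -> int:
    """Minimum substitutions for one column by Sankoff unit-cost DP.

    ``states[label]`` is the set of allowed state indices for that leaf
    (the full set for missing data).
    """

    def rec(node):
        if node.is_leaf:
            return [0 if s in states[node.label] else np.inf for s in range(k)]
        costs = [0.0] * k
        for ch in node.children:
            child = rec(ch)
            for s in range(k):
                costs[s] += min(child[t] + (0 if s == t else 1)
                                for t in range(k))
        return costs

    return int(min(rec(tree.root)))


def exhaustive_column_score(tree: Tree, states: dict, k: int) -> int:
    """Minimum substitutions by enumerating every internal assignment."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    parents = tree.parents()
    best = np.inf
    leaf_choices = [sorted(states[l.label]) for l in leaves]
    for internal_assign in itertools.product(range(k), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, internal_assign)}
        for leaf_assign in itertools.product(*leaf_choices):
            for l, s in zip(leaves, leaf_assign):
                assign[id(l)] = s
            cost = 0
            for node in tree.postorder():
                p = parents[id(node)]
                if p is not None and assign[id(node)] != assign[id(p)]:
                    cost += 1
            best = min(best, cost)
    return int(best)


# ---------------------------------------------------------------------------
# closed forms

def jc4_distance(p: float) -> float:
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc2taxon_site_likelihood(t: float, match: bool) -> float:
    """P(site pattern) for two taxa under JC separated by total length t."""
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    return 0.25 * p_same if match else 0.25 * (1.0 - p_same) / 3.0
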
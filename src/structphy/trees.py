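"""Phylogenetic trees: neighbor-joining, midpoint rooting, bootstrap
support, iterated profile neighbor-joining, and tree comparison.

The tree container is a plain rooted node structure; unrooted trees are
represented with a trifurcating root and ``rooted=False``.  Branch lengths
live on the child node of each edge (substitutions/site); bootstrap
supports (percent) live on the child node of internal edges only, with
each bipartition carrying its support exactly once even in rooted trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import distances as dist_mod
from .distances import DistanceMatrix, profile_distance_matrix
from .errors import (UndefinedStatisticError, UsageError, ValidationError)


class Node:
    __slots__ = ("label", "length", "support", "children")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self):
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, sup={self.support}, deg={len(self.children)})"


class Tree:
    """Rooted or unrooted (trifurcating-root) tree."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self):
        return [n.label for n in self.leaves()]

    def parents(self):
        par = {id(self.root): None}
        for node in self.preorder():
            for ch in node.children:
                par[id(ch)] = node
        return par

    # -- canonical form ----------------------------------------------------

    def min_labels(self):
        """id(node) -> lexicographically smallest descendant leaf label."""
        ml = {}
        for node in self.postorder():
            if node.is_leaf:
                ml[id(node)] = node.label
            else:
                ml[id(node)] = min(ml[id(c)] for c in node.children)
        return ml

    def sort(self):
        """Order children by smallest descendant label, in place."""
        ml = self.min_labels()
        for node in self.postorder():
            node.children.sort(key=lambda c: ml[id(c)])
        return self

    def copy(self):
        def rec(n):
            return Node(n.label, n.length, n.support, [rec(c) for c in n.children])
        return Tree(rec(self.root), self.rooted)

    def total_length(self):
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)


#: Field-standard name for the tree container.
PhyloTree = Tree


# ---------------------------------------------------------------------------
# bipartitions / comparison

def _clade_sets(tree: Tree):
    sets = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset([node.label])
        else:
            s = frozenset()
            for c in node.children:
                s |= sets[id(c)]
            sets[id(node)] = s
    return sets


def internal_edges(tree: Tree):
    """List of (node, canonical bipartition side) for internal edges.

    Internal edges have >= 2 leaves on both sides; the canonical side is
    the one NOT containing the overall smallest leaf label.  In rooted
    trees the two root edges describe the same bipartition; only the first
    (canonical child order) is reported.
    """
    sets = _clade_sets(tree)
    all_leaves = sets[id(tree.root)]
    n = len(all_leaves)
    ref = min(all_leaves)
    out = []
    seen = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = sets[id(node)]
        if len(s) < 2 or n - len(s) < 2:
            continue
        side = s if ref not in s else all_leaves - s
        if side in seen:
            # the two root edges of a rooted tree share one bipartition;
            # prefer whichever carries the support value
            prev = seen[side]
            if prev[0].support is None and node.support is not None:
                out[prev[1]] = (node, side)
                seen[side] = (node, prev[1])
            continue
        seen[side] = (node, len(out))
        out.append((node, side))
    return out


def bipartitions(tree: Tree):
    """Set of canonical internal bipartition sides."""
    return {side for _, side in internal_edges(tree)}


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric difference of the internal bipartition sets."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise UsageError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def average_support(tree: Tree) -> float:
    """Arithmetic mean of supports over internal edges carrying one."""
    vals = [node.support for node, _ in internal_edges(tree)
            if node.support is not None]
    if not vals:
        raise UndefinedStatisticError("tree carries no support values")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration with the Studier-Keppler Q-criterion.

    Ties in Q are broken by the lexicographically smallest pair of
    smallest-descendant labels; negative branch lengths are clamped to 0
    with the deficit shifted to the sibling edge.  Returns an unrooted
    tree (trifurcating root) for n >= 3, a cherry for n = 2.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValidationError("distance matrix contains non-finite entries")
    n = len(dm.labels)
    if n < 2:
        raise UsageError("need at least 2 taxa")
    nodes = [Node(label=lab) for lab in dm.labels]
    minlab = list(dm.labels)
    d = dm.d.copy()

    if n == 2:
        half = d[0, 1] / 2.0
        for nd in nodes:
            nd.length = half
        root = Node(children=sorted(nodes, key=lambda x: x.label))
        return Tree(root, rooted=False).sort()

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: smallest (minlab_i, minlab_j) pair.
        # q need not be bitwise symmetric, so normalize pair orientation.
        best = None
        ii, jj = np.nonzero(q == qmin)
        for a, b in zip(ii, jj):
            if a > b:
                a, b = b, a
            key = tuple(sorted((minlab[active[a]], minlab[active[b]])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        ch = sorted([ni, nj], key=lambda x: minlab[nodes.index(x)])
        new = Node(children=ch)
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        # grow matrix by one row/col for the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        d[-1, -1] = 0.0
        nodes.append(new)
        minlab.append(min(minlab[i], minlab[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    lens = [0.5 * (dij + dik - djk), 0.5 * (dij + djk - dik), 0.5 * (dik + djk - dij)]
    kids = []
    for idx, ln in zip((i, j, k), lens):
        nodes[idx].length = max(ln, 0.0)
        kids.append(nodes[idx])
    root = Node(children=kids)
    return Tree(root, rooted=False).sort()


def upgma(dm: DistanceMatrix) -> Tree:
    """UPGMA (average linkage) ultrametric tree, deterministic ties."""
    n = len(dm.labels)
    if n < 2:
        raise UsageError("need at least 2 taxa")
    nodes = [Node(label=lab) for lab in dm.labels]
    heights = [0.0] * n
    sizes = [1] * n
    minlab = list(dm.labels)
    d = dm.d.copy().astype(float)
    active = list(range(n))
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        np.fill_diagonal(sub, np.inf)
        dmin = sub.min()
        best = None
        ii, jj = np.nonzero(sub == dmin)
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = tuple(sorted((minlab[active[a]], minlab[active[b]])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        h = dmin / 2.0
        ni, nj = nodes[i], nodes[j]
        ni.length = h - heights[i]
        nj.length = h - heights[j]
        new = Node(children=[ni, nj])
        new_d = (sizes[i] * d[i, :] + sizes[j] * d[j, :]) / (sizes[i] + sizes[j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        nodes.append(new)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        minlab.append(min(minlab[i], minlab[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    return Tree(nodes[active[0]], rooted=True).sort()


# ---------------------------------------------------------------------------
# rerooting / midpoint

def _unrooted_adjacency(tree: Tree):
    """Undirected edge list view; a degree-2 root is suppressed."""
    adj = {}

    def add(u, v, length, support):
        adj.setdefault(id(u), []).append((v, length, support))
        adj.setdefault(id(v), []).append((u, length, support))

    par = tree.parents()
    skip_root = len(tree.root.children) == 2
    if skip_root:
        c1, c2 = tree.root.children
        sup = c1.support if c1.support is not None else c2.support
        add(c1, c2, (c1.length or 0.0) + (c2.length or 0.0), sup)
    for node in tree.preorder():
        for ch in node.children:
            if skip_root and node is tree.root:
                continue
            add(node, ch, ch.length or 0.0, ch.support)
    return adj


def _leaf_paths(tree: Tree, adj, start: Node):
    """Distances and predecessor edges from ``start`` over the adjacency."""
    dist = {id(start): 0.0}
    pred = {id(start): None}
    nodemap = {id(start): start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, length, support in adj.get(id(u), []):
            if id(v) in dist:
                continue
            dist[id(v)] = dist[id(u)] + length
            pred[id(v)] = (u, length, support)
            nodemap[id(v)] = v
            stack.append(v)
    return dist, pred, nodemap


def _build_rooted(adj, root_entries, block_id=None):
    """Directed tree from ``root_entries`` = [(node, length, support), ...].

    ``block_id`` names a vertex that must never be entered (the old vertex
    a new root replaces when rooting at an existing node).
    """
    new_root = Node()
    visited = set() if block_id is None else {block_id}

    def rec(old, length, support):
        visited.add(id(old))
        n = Node(label=old.label, length=length)
        for v, ln, sup in adj.get(id(old), []):
            if id(v) in visited:
                continue
            n.children.append(rec(v, ln, sup))
        if n.children and support is not None:
            n.support = support
        return n

    for node, length, support in root_entries:
        visited.add(id(node))
    for node, length, support in root_entries:
        visited.discard(id(node))
        new_root.children.append(rec(node, length, support))
        visited.add(id(node))
    return Tree(new_root, rooted=True).sort()


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-leaf path.

    Ties are broken by the lexicographically smallest leaf pair.  If the
    edge being split carries a support, it is kept on one half-edge only
    so every bipartition still carries exactly one support.
    """
    leaves = sorted(tree.leaves(), key=lambda n: n.label)
    if len(leaves) < 2:
        raise UsageError("need at least 2 leaves to midpoint-root")
    adj = _unrooted_adjacency(tree)
    best = None  # (dist, u_label, v_label, u_node, pred)
    for u in leaves:
        dist, pred, nodemap = _leaf_paths(tree, adj, u)
        for v in leaves:
            if v.label <= u.label:
                continue
            dv = dist[id(v)]
            if best is None or dv > best[0]:
                best = (dv, u.label, v.label, v, pred)
    dmax, _, _, v_end, pred = best
    if dmax <= 0:
        warnings.warn("all-zero branch lengths; rooting at first internal node")
        internal = next(n for n in tree.preorder() if not n.is_leaf)
        entries = [(nb, ln, sup) for nb, ln, sup in adj[id(internal)]]
        return _build_rooted(adj, entries, block_id=id(internal))

    # edge path from v_end back to u, then walk from u
    path = []
    cur = v_end
    while pred[id(cur)] is not None:
        prev, length, support = pred[id(cur)]
        path.append((prev, cur, length, support))
        cur = prev
    path.reverse()  # now u ... v as (a, b, length, support)

    mid = dmax / 2.0
    cum = 0.0
    for a, b, length, support in path:
        if cum + length >= mid - 1e-12:
            offset = mid - cum
            if abs(offset) < 1e-12 and not a.is_leaf:
                entries = [(nb, ln, sup) for nb, ln, sup in adj[id(a)]]
                return _build_rooted(adj, entries, block_id=id(a))
            if abs(offset - length) < 1e-12 and not b.is_leaf:
                entries = [(nb, ln, sup) for nb, ln, sup in adj[id(b)]]
                return _build_rooted(adj, entries, block_id=id(b))
            # split edge (a, b): drop it from the adjacency, hang both ends
            adj2 = {k: [e for e in v if not (
                (k == id(a) and e[0] is b) or (k == id(b) and e[0] is a))]
                for k, v in adj.items()}
            # support stays on the half-edge of whichever side is internal;
            # if both are internal, the side with the smaller entry order
            keep_a = not a.is_leaf
            keep_b = not b.is_leaf and not keep_a
            entries = [(a, offset, support if keep_a else None),
                       (b, length - offset, support if keep_b else None)]
            return _build_rooted(adj2, entries)
        cum += length
    raise AssertionError("midpoint not located on diameter path")  # pragma: no cover


def leaf_distances(tree: Tree):
    """Dict {(label_a, label_b): path length} over all leaf pairs."""
    adj = _unrooted_adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda n: n.label)
    if len(leaves) == 1:
        return {}
    out = {}
    for u in leaves:
        dist, _, _ = _leaf_paths(tree, adj, u)
        for v in leaves:
            if v.label > u.label:
                out[(u.label, v.label)] = dist[id(v)]
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(aln, builder, n_reps: int, seed: int,
                      reference: Tree | None = None) -> Tree:
    """Map column-resampling bootstrap supports onto a reference tree.

    ``builder`` is a deterministic Alignment -> Tree procedure.  Supports
    (percent of replicates containing each internal bipartition) are set
    on the internal edges of ``reference`` (default: builder(aln)).
    """
    if n_reps < 1:
        raise UsageError("need at least 1 bootstrap replicate")
    rng = np.random.default_rng(seed)
    ref = (reference if reference is not None else builder(aln)).copy().sort()
    counts = {}
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_tree = builder(aln.column_subset(cols))
        for side in bipartitions(rep_tree):
            counts[side] = counts.get(side, 0) + 1
    for node, side in internal_edges(ref):
        node.support = 100.0 * counts.get(side, 0) / n_reps
    return ref


# ---------------------------------------------------------------------------
# profile neighbor joining

@dataclass
class ProfileAssignment:
    """Disjoint profile -> member leaf ids, plus unassigned leaves."""

    profiles: dict
    unassigned: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for name, members in self.profiles.items():
            for m in members:
                if m in seen:
                    raise ValidationError(f"leaf {m!r} assigned to multiple profiles")
                seen.add(m)


@dataclass
class PnjIteration:
    """Audit record of one PNJ round."""

    index: int
    profiles: dict
    supports: dict
    merged: list
    tree: "Tree" = None


def _profile_tree(groups, counts_by_name, k, n_reps, seed, saturation):
    """NJ + bootstrap over profiles given per-group count matrices."""
    names = sorted(groups)

    def profiles_at(cols=None):
        out = []
        for name in names:
            c = counts_by_name[name]
            if cols is not None:
                c = c[cols]
            out.append(dist_mod.Profile.from_counts(name, groups[name], c))
        return out

    dm = profile_distance_matrix(profiles_at(), k, saturation=saturation)
    ref = neighbor_joining(dm)
    rng = np.random.default_rng(seed)
    L = next(iter(counts_by_name.values())).shape[0]
    counts = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_dm = profile_distance_matrix(profiles_at(cols), k, saturation=saturation)
        for side in bipartitions(neighbor_joining(rep_dm)):
            counts[side] = counts.get(side, 0) + 1
    supports = {}
    for node, side in internal_edges(ref):
        node.support = 100.0 * counts.get(side, 0) / n_reps
        supports[side] = node.support
    return ref, supports


def profile_nj(aln, assignment: ProfileAssignment, iterations: int = 2,
               bs_threshold: float = 75.0, n_reps: int = 100, seed: int = 0,
               k: int | None = None, saturation: str = "error"):
    """Iterated profile neighbor-joining with super-profile formation.

    Round 0 builds the predefined profiles, their NJ tree and bootstrap
    supports.  Each further round merges every maximal clade of the
    current profile tree with support strictly above ``bs_threshold`` into
    a super-profile (frequencies re-aggregated from leaf rows) and repeats
    NJ + bootstrap over the merged units, so the backbone is re-estimated
    independently of the topology within each super-profile.  The final
    tree is expanded back to the original profiles: every super-profile
    leaf is replaced by its subtree (with the branch lengths and supports
    of the iteration in which it was formed).  Unassigned leaves are
    excluded throughout.  Returns (final tree, [PnjIteration, ...]).
    """
    if not 0 <= bs_threshold <= 101:
        raise UsageError("bs_threshold outside [0, 101]")
    if len(assignment.profiles) < 2:
        raise UsageError("need at least 2 profiles")
    if k is None:
        k = len(dist_mod.ALPHABETS[aln.alphabet])

    groups = {name: list(members) for name, members in assignment.profiles.items()}
    base_counts = {name: dist_mod.profile_counts(aln, members)
                   for name, members in groups.items()}
    subtrees = {}  # super-profile name -> stored clade (over profile names)
    audit = []
    tree = None
    for it in range(iterations + 1):
        tree, supports = _profile_tree(groups, base_counts, k, n_reps,
                                       seed=seed + it, saturation=saturation)
        profiles_used = {n: list(m) for n, m in groups.items()}
        merged = []
        if it < iterations and len(groups) > 3:
            rooted = midpoint_root(tree)
            sets = _clade_sets(rooted)
            qualifying = [node for node, _ in internal_edges(rooted)
                          if node.support is not None and node.support > bs_threshold]
            # keep only maximal qualifying clades
            qual_ids = {id(n) for n in qualifying}
            par = rooted.parents()
            maximal = []
            for node in qualifying:
                p = par[id(node)]
                covered = False
                while p is not None:
                    if id(p) in qual_ids:
                        covered = True
                        break
                    p = par[id(p)]
                if not covered:
                    maximal.append(node)
            # deterministic merge order: highest support, then member labels
            maximal.sort(key=lambda n: (-n.support, min(sets[id(n)])))
            for node in maximal:
                names = sorted(sets[id(node)])
                if len(names) < 2:
                    continue
                if len(groups) - len(names) + 1 < 3:
                    continue  # never shrink below 3 units (NJ degenerates)
                super_name = "+".join(names)
                members = [m for nm in names for m in groups[nm]]
                counts = sum(base_counts[nm] for nm in names)
                for nm in names:
                    del groups[nm]
                    del base_counts[nm]
                groups[super_name] = members
                base_counts[super_name] = counts
                # store a copy of the clade for final re-expansion
                stored = Tree(node, rooted=True).copy().root
                subtrees[super_name] = stored
                merged.append((super_name, names))
        audit.append(PnjIteration(index=it, profiles=profiles_used,
                                  supports=supports, merged=merged, tree=tree))
    final = _expand_super_profiles(tree, subtrees)
    return final, audit


def _expand_super_profiles(tree: Tree, subtrees: dict) -> Tree:
    """Replace super-profile leaves by their stored subtrees, recursively."""
    if not subtrees:
        return tree

    def rec(node: Node) -> Node:
        if node.is_leaf and node.label in subtrees:
            stored = Tree(subtrees[node.label], rooted=True).copy().root
            stored.length = node.length  # edge to the super-profile unit
            if node.support is not None:
                stored.support = node.support  # else: support from its iteration
            stored.label = None
            stored.children = [rec(c) for c in stored.children]
            return stored
        out = Node(node.label, node.length, node.support,
                   [rec(c) for c in node.children])
        return out

    return Tree(rec(tree.root), tree.rooted).sort()


def profiles_from_tree(tree: Tree, min_size: int = 2, depth: int = 1,
                       max_size: int | None = None) -> ProfileAssignment:
    """Automatic profile definition from a rooted tree.

    With ``max_size`` set, clades are split top-down until each has at
    most ``max_size`` leaves; maximal clades with >= ``min_size`` leaves
    become profiles.  Otherwise the cut is taken ``depth`` edges below the
    root.  Leaves left over either way are unassigned.  Profiles are
    named P01, P02, ... in order of their smallest leaf label.
    """
    tree = tree.copy().sort()
    sets = _clade_sets(tree)
    clades = []
    unassigned = []

    def accept(node):
        members = sorted(sets[id(node)])
        if len(members) >= min_size:
            clades.append(members)
        else:
            unassigned.extend(members)

    def rec_depth(node, d):
        if d == depth or node.is_leaf:
            accept(node)
            return
        for ch in node.children:
            rec_depth(ch, d + 1)

    def rec_size(node):
        if node.is_leaf or len(sets[id(node)]) <= max_size:
            accept(node)
            return
        for ch in node.children:
            rec_size(ch)

    if max_size is not None:
        rec_size(tree.root)
    else:
        rec_depth(tree.root, 0)
    clades.sort(key=lambda ms: ms[0])
    profiles = {f"P{i + 1:02d}": ms for i, ms in enumerate(clades)}
    return ProfileAssignment(profiles=profiles, unassigned=sorted(unassigned))
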
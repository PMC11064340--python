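"""Maximum parsimony (Fitch + NNI search) and maximum likelihood
(GTR+I+G pruning with branch-length optimization) on nucleotide or
12-letter encoded alignments.

The likelihood model is a k-state general time-reversible process with a
proportion of invariant sites and discrete-gamma rate heterogeneity
(category rates are the means of equal-probability bins).  The rate
matrix is scaled to one expected substitution per site at stationarity
over the variable fraction, so branch lengths are substitutions/site on
variable sites.  Gaps and unknowns enter pruning as all-ones partial
likelihood vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .distances import ALPHABETS, distance_matrix
from .errors import UsageError, ValidationError
from .msa import Alignment
from .trees import Node, Tree, neighbor_joining


# ---------------------------------------------------------------------------
# Fitch parsimony

def _binarize(node: Node) -> Node:
    """Binary (possibly zero-length) resolution of a multifurcating root."""
    children = [_binarize(c) for c in node.children]
    if len(children) <= 2:
        out = Node(node.label, node.length, node.support, children)
        return out
    # fold all but the first child under a zero-length node
    rest = children[1]
    for c in children[2:]:
        rest = Node(length=0.0, children=[rest, c])
    return Node(node.label, node.length, node.support, [children[0], rest])


def _leaf_masks(aln: Alignment) -> dict:
    alphabet = ALPHABETS[aln.alphabet]
    full = (1 << len(alphabet)) - 1
    lut = {ch: 1 << i for i, ch in enumerate(alphabet)}
    masks = {}
    for rid, row in zip(aln.ids, aln.rows):
        masks[rid] = np.array([lut.get(ch, full) for ch in row], dtype=np.int64)
    return masks


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Total Fitch parsimony changes summed over columns.

    Gap/unknown characters count as the full state set (missing data).
    """
    if set(tree.leaf_labels()) != set(aln.ids):
        raise UsageError("tree leaves do not match alignment rows")
    masks = _leaf_masks(aln)
    root = _binarize(tree.root)
    score = np.zeros(aln.length, dtype=np.int64)

    def rec(node: Node) -> np.ndarray:
        if node.is_leaf:
            return masks[node.label]
        m1 = rec(node.children[0])
        m2 = rec(node.children[1])
        inter = m1 & m2
        empty = inter == 0
        score[:] += empty
        return np.where(empty, m1 | m2, inter)

    rec(root)
    return int(score.sum())


@dataclass
class ParsimonyResult:
    score: int
    tree: Tree


def _nni_neighbors(tree: Tree):
    """All NNI rearrangements of an unrooted binary tree, in scan order."""
    out = []
    base = tree.copy().sort()
    # enumerate internal edges as (parent, child) with child internal
    edges = []
    for node in base.preorder():
        for ch in node.children:
            if not ch.is_leaf:
                edges.append((node, ch))
    for p, c in edges:
        if p is base.root and len(base.root.children) == 2:
            continue  # rooted binary root edge: same unrooted edge as below
        others = [x for x in p.children if x is not c]
        if not others:
            continue
        partner = others[0]  # swapping with any one other subtree spans both NNIs
        for grandchild in c.children:
            t2 = tree.copy().sort()
            mapping = {id(a): b for a, b in zip(base.preorder(), t2.preorder())}
            p2, c2 = mapping[id(p)], mapping[id(c)]
            partner2, grandchild2 = mapping[id(partner)], mapping[id(grandchild)]
            # exchange partner (child of p) with grandchild (child of c)
            p2.children[p2.children.index(partner2)] = grandchild2
            c2.children[c2.children.index(grandchild2)] = partner2
            out.append(t2.sort())
    return out


def mp_search(aln: Alignment, seed: int = 0) -> ParsimonyResult:
    """NNI hill-climbing from the NJ starting tree.

    Deterministic: all NNI neighbors are scored each round and the best
    strictly-improving one (first in scan order on ties) is accepted until
    no move improves the Fitch score.
    """
    if aln.n_rows < 4:
        raise UsageError("parsimony search needs at least 4 rows")
    start = neighbor_joining(distance_matrix(aln, correction="p"))
    current = start
    current_score = fitch_score(current, aln)
    improved = True
    while improved:
        improved = False
        best_tree, best_score = None, current_score
        for cand in _nni_neighbors(current):
            s = fitch_score(cand, aln)
            if s < best_score:
                best_tree, best_score = cand, s
        if best_tree is not None:
            current, current_score = best_tree, best_score
            improved = True
    return ParsimonyResult(score=current_score, tree=current)


# ---------------------------------------------------------------------------
# substitution model

def discrete_gamma_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean rates of n_cat equal-probability bins of Gamma(alpha, 1/alpha)."""
    if alpha <= 0:
        raise ValidationError("gamma shape must be > 0")
    if n_cat < 1:
        raise ValidationError("need at least one rate category")
    if n_cat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_cat) / n_cat, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1.0, edges[1:] * alpha))
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return n_cat * (upper - lower)


class SubstitutionModel:
    """k-state GTR + invariant sites + discrete gamma."""

    def __init__(self, k: int, pi=None, exchangeabilities=None,
                 p_inv: float = 0.0, alpha: float | None = None, n_cat: int = 4):
        self.k = int(k)
        self.pi = (np.full(k, 1.0 / k) if pi is None
                   else np.asarray(pi, dtype=float))
        if self.pi.shape != (k,) or np.any(self.pi <= 0) or abs(self.pi.sum() - 1) > 1e-8:
            raise ValidationError("stationary frequencies must be positive and sum to 1")
        if exchangeabilities is None:
            exch = np.ones((k, k))
        else:
            exch = np.asarray(exchangeabilities, dtype=float)
        if exch.shape != (k, k) or not np.allclose(exch, exch.T) or np.any(exch < 0):
            raise ValidationError("exchangeabilities must be a symmetric non-negative matrix")
        self.exchangeabilities = exch
        if not 0 <= p_inv < 1:
            raise ValidationError("p_inv must be in [0, 1)")
        if alpha is not None and alpha <= 0:
            raise ValidationError("gamma shape must be > 0")
        self.p_inv = float(p_inv)
        self.alpha = alpha
        self.n_cat = int(n_cat)
        self._decomp = None

    @classmethod
    def jc(cls, k: int = 4, **kw) -> "SubstitutionModel":
        return cls(k=k, **kw)

    @classmethod
    def gtr(cls, pi, exchangeabilities, p_inv=0.0, alpha=None, n_cat=4):
        pi = np.asarray(pi, dtype=float)
        return cls(k=len(pi), pi=pi, exchangeabilities=exchangeabilities,
                   p_inv=p_inv, alpha=alpha, n_cat=n_cat)

    def rate_matrix(self) -> np.ndarray:
        """GTR generator scaled to mean rate 1 at stationarity."""
        q = self.exchangeabilities * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(q)))
        if mu <= 0:
            raise ValidationError("degenerate rate matrix")
        return q / mu

    def _eigen(self):
        if self._decomp is None:
            q = self.rate_matrix()
            sq = np.sqrt(self.pi)
            sym = (q * sq[:, None]) / sq[None, :]
            lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
            self._decomp = (lam, u, sq)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValidationError("branch length must be >= 0")
        lam, u, sq = self._eigen()
        inner = (u * np.exp(lam * t)) @ u.T
        p = inner / sq[:, None] * sq[None, :]
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cat)


def empirical_frequencies(aln: Alignment) -> np.ndarray:
    alphabet = ALPHABETS[aln.alphabet]
    counts = np.zeros(len(alphabet))
    for row in aln.rows:
        for ch in row:
            i = alphabet.find(ch)
            if i >= 0:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValidationError("alignment has no informative characters")
    counts = np.where(counts == 0, 0.5, counts)  # keep frequencies positive
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# likelihood

def _site_patterns(aln: Alignment):
    """Unique columns with multiplicities; codes: state index or -1 missing."""
    alphabet = ALPHABETS[aln.alphabet]
    lut = {ch: i for i, ch in enumerate(alphabet)}
    mat = np.array([[lut.get(ch, -1) for ch in row] for row in aln.rows],
                   dtype=np.int16)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def log_likelihood(tree: Tree, aln: Alignment, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood of the tree given the alignment.

    Per-site likelihood is ``p_inv * L_inv + (1 - p_inv) * mean_c L_c``
    where L_inv is the probability of the site being invariant at a state
    compatible with every row and L_c are the gamma-category likelihoods.
    """
    if set(tree.leaf_labels()) != set(aln.ids):
        raise UsageError("tree leaves do not match alignment rows")
    k = model.k
    if k != len(ALPHABETS[aln.alphabet]):
        raise UsageError("model alphabet size does not match alignment")
    patterns, weights = _site_patterns(aln)
    row_index = {rid: i for i, rid in enumerate(aln.ids)}
    nsites = patterns.shape[1]

    leaf_partials = {}
    for rid, i in row_index.items():
        part = np.ones((k, nsites))
        codes = patterns[i]
        observed = codes >= 0
        part[:, observed] = 0.0
        part[codes[observed], np.nonzero(observed)[0]] = 1.0
        leaf_partials[rid] = part

    rates = model.category_rates()
    var_sum = np.zeros(nsites)
    for rate in rates:
        def rec(node: Node) -> np.ndarray:
            if node.is_leaf:
                return leaf_partials[node.label]
            part = np.ones((k, nsites))
            for ch in node.children:
                p = model.transition_matrix((ch.length or 0.0) * rate)
                part *= p @ rec(ch)
            return part
        var_sum += model.pi @ rec(tree.root)
    site_l = (1.0 - model.p_inv) * var_sum / len(rates)
    if model.p_inv > 0:
        inv_mask = np.ones((k, nsites))
        for rid in aln.ids:
            inv_mask *= leaf_partials[rid]
        site_l = site_l + model.p_inv * (model.pi @ inv_mask)
    with np.errstate(divide="ignore"):
        logs = np.log(site_l)
    return float(np.dot(weights, logs))


def optimize_branch_lengths(tree: Tree, aln: Alignment, model: SubstitutionModel,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            max_length: float = 20.0) -> Tree:
    """Coordinate-ascent branch-length optimization at fixed topology.

    Each branch is optimized by bounded scalar search; sweeps repeat until
    the log-likelihood improves by less than ``tol``.  The log-likelihood
    is non-decreasing across sweeps.
    """
    t = tree.copy().sort()
    branches = [n for n in t.postorder() if n is not t.root]
    current = log_likelihood(t, aln, model)
    for _ in range(max_sweeps):
        start = current
        for node in branches:
            orig = node.length

            def neg(x, node=node):
                node.length = float(x)
                return -log_likelihood(t, aln, model)

            res = minimize_scalar(neg, bounds=(1e-9, max_length),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            cand = -neg(res.x)  # leaves node.length at res.x
            if cand >= current:
                current = cand
            else:  # optimizer failed to improve this branch; restore
                node.length = orig
                current = -neg(orig)
        if current - start < tol:
            break
    return t


def ml_bootstrap(aln: Alignment, model: SubstitutionModel, n_reps: int = 100,
                 seed: int = 0) -> Tree:
    """Bootstrap supports on the branch-length-optimized NJ-topology tree.

    Each replicate resamples columns and rebuilds an NJ topology;
    bipartition supports are mapped onto the reference tree whose branch
    lengths were ML-optimized.  (Supports depend only on replicate
    topologies, so per-replicate branch lengths are not re-optimized.)
    """
    from .trees import bootstrap_support

    def builder(a: Alignment) -> Tree:
        return neighbor_joining(distance_matrix(a, saturation="cap"))

    ref = optimize_branch_lengths(builder(aln), aln, model)
    return bootstrap_support(aln, builder, n_reps=n_reps, seed=seed, reference=ref)
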
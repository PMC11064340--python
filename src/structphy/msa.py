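"""Global pairwise and progressive multiple alignment.

Alignment is Needleman-Wunsch-style global with affine gap costs
(a gap of length L costs ``gap_open + (L-1)*gap_extend``), implemented as
a three-state Gotoh dynamic program.  The default 12x12 scoring matrix
decomposes additively into a nucleotide term (+2 same / -1 different) and
a structural-state term (+2 same / -1 different), so structure agreement
is rewarded independently of sequence agreement; the unknown symbol
scores 0 against everything.  Multiple alignment is progressive along a
UPGMA guide tree with frequency-weighted profile-profile scoring
("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import ENCODED_ALPHABET, NUCLEOTIDES, UNKNOWN, default_table
from .errors import UsageError, ValidationError

GAP = "-"


@dataclass
class Alignment:
    """Rectangular gapped rows over a declared alphabet."""

    ids: list
    rows: list
    alphabet: str = "encoded"  # "nuc" | "encoded"

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError("rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def to_matrix(self) -> np.ndarray:
        """(n_rows, length) array of single-character strings."""
        return np.frombuffer("".join(self.rows).encode("ascii"),
                             dtype="S1").reshape(self.n_rows, -1)

    def column_subset(self, cols) -> "Alignment":
        mat = self.to_matrix()[:, np.asarray(cols)]
        rows = [b"".join(row).decode("ascii") for row in mat]
        return Alignment(ids=list(self.ids), rows=rows, alphabet=self.alphabet)

    def subset(self, ids) -> "Alignment":
        return Alignment(ids=list(ids), rows=[self.row(i) for i in ids],
                         alphabet=self.alphabet)


@dataclass
class ScoringMatrix:
    """Symmetric substitution scores plus affine gap penalties."""

    alphabet: str
    scores: np.ndarray
    gap_open: float = 8.0
    gap_extend: float = 1.0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        m = len(self.alphabet)
        if self.scores.shape != (m, m):
            raise ValidationError("score matrix shape does not match alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise ValidationError("score matrix not symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be >= 0")
        self._index = {ch: i for i, ch in enumerate(self.alphabet)}

    def score(self, x: str, y: str) -> float:
        try:
            return float(self.scores[self._index[x], self._index[y]])
        except KeyError as exc:
            raise ValidationError(f"letter {exc.args[0]!r} not in matrix alphabet") from None

    def encode_indices(self, text: str) -> np.ndarray:
        try:
            return np.array([self._index[ch] for ch in text], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"letter {exc.args[0]!r} not in matrix alphabet") from None

    @classmethod
    def from_file(cls, path, gap_open=8.0, gap_extend=1.0):
        """First line: alphabet; then lower-triangular rows of scores."""
        with open(path, encoding="utf-8") as fh:
            tokens = [line.split() for line in fh if line.strip()]
        alphabet = "".join(tokens[0])
        m = len(alphabet)
        scores = np.zeros((m, m))
        for i, row in enumerate(tokens[1:]):
            if len(row) != i + 1:
                raise ValidationError(f"lower-triangular row {i} has {len(row)} entries")
            for j, v in enumerate(row):
                scores[i, j] = scores[j, i] = float(v)
        return cls(alphabet=alphabet, scores=scores, gap_open=gap_open,
                   gap_extend=gap_extend)


def default_matrix_12(gap_open: float = 8.0, gap_extend: float = 1.0) -> ScoringMatrix:
    """Additive sequence+structure 12x12 matrix (plus unknown symbol).

    score(x, y) = (+2 if same nucleotide else -1) + (+2 if same structural
    state else -1); the unknown symbol scores 0 against everything.
    """
    table = default_table()
    alphabet = ENCODED_ALPHABET + UNKNOWN
    m = len(alphabet)
    scores = np.zeros((m, m))
    for i, x in enumerate(ENCODED_ALPHABET):
        nx, sx = table.invert(x)
        for j, y in enumerate(ENCODED_ALPHABET):
            ny, sy = table.invert(y)
            scores[i, j] = (2 if nx == ny else -1) + (2 if sx == sy else -1)
    return ScoringMatrix(alphabet=alphabet, scores=scores,
                         gap_open=gap_open, gap_extend=gap_extend)


def default_matrix_nuc(gap_open: float = 8.0, gap_extend: float = 1.0) -> ScoringMatrix:
    """Nucleotide mode: match +2, mismatch -1, unknown 0."""
    alphabet = NUCLEOTIDES + UNKNOWN
    m = len(alphabet)
    scores = -np.ones((m, m))
    np.fill_diagonal(scores, 2.0)
    scores[-1, :] = 0.0
    scores[:, -1] = 0.0
    return ScoringMatrix(alphabet=alphabet, scores=scores,
                         gap_open=gap_open, gap_extend=gap_extend)


def _as_pair(obj):
    """Accept (id, text) tuples, EncodedSequence, or StructuredSequence."""
    if isinstance(obj, tuple):
        return obj
    if hasattr(obj, "letters"):
        return obj.id, obj.letters
    if hasattr(obj, "seq"):
        return obj.id, obj.seq
    raise UsageError(f"cannot interpret {obj!r} as a sequence")


_DIAG, _UP, _LEFT = 0, 1, 2
_NEG = -1e30


def _gotoh(expected: np.ndarray, gap_open: float, gap_extend: float):
    """Affine-gap global DP over a precomputed (la, lb) pair-score matrix.

    Returns (score, ops) with ops a list of _DIAG/_UP/_LEFT moves from the
    start; _UP consumes a row of the first profile (gap in the second).
    Tie order everywhere: diagonal > up > left.
    """
    la, lb = expected.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in b (moving up/consuming a)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, lb + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    # traceback state codes: which matrix the predecessor was in
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x[1:, 0] = 1
    tb_y[0, 1:] = 2
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        ei = expected[i - 1]
        tmi, txi, tyi = tb_m[i], tb_x[i], tb_y[i]
        for j in range(1, lb + 1):
            # M: best predecessor at (i-1, j-1), tie order M > X > Y
            best, state = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, state = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, state = Yi1[j - 1], 2
            Mi[j] = best + ei[j - 1]
            tmi[j] = state
            # X: gap in b, from (i-1, j)
            best, state = Mi1[j] - go, 0
            if Xi1[j] - ge > best:
                best, state = Xi1[j] - ge, 1
            if Yi1[j] - go > best:
                best, state = Yi1[j] - go, 2
            Xi[j] = best
            txi[j] = state
            # Y: gap in a, from (i, j-1)
            best, state = Mi[j - 1] - go, 0
            if Xi[j - 1] - go > best:
                best, state = Xi[j - 1] - go, 1
            if Yi[j - 1] - ge > best:
                best, state = Yi[j - 1] - ge, 2
            Yi[j] = best
            tyi[j] = state
    ends = (M[la, lb], X[la, lb], Y[la, lb])
    which = int(np.argmax(ends))  # argmax tie order M > X > Y
    score = float(ends[which])
    # traceback
    ops = []
    i, j, state = la, lb, which
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            ops.append(_DIAG)
            i, j = i - 1, j - 1
        elif state == 1:
            prev = tb_x[i, j]
            ops.append(_UP)
            i -= 1
        else:
            prev = tb_y[i, j]
            ops.append(_LEFT)
            j -= 1
        state = prev
    ops.reverse()
    return score, ops


@dataclass
class _ProfileRows:
    ids: list
    rows: list

    def freqs(self, matrix: ScoringMatrix) -> np.ndarray:
        """(length, alphabet) frequency over all rows; gaps carry no mass."""
        m = len(matrix.alphabet)
        L = len(self.rows[0])
        f = np.zeros((L, m))
        for row in self.rows:
            for pos, ch in enumerate(row):
                if ch != GAP:
                    f[pos, matrix._index[ch]] += 1.0
        return f / len(self.rows)


def _merge(pa: _ProfileRows, pb: _ProfileRows, matrix: ScoringMatrix):
    fa = pa.freqs(matrix)
    fb = pb.freqs(matrix)
    expected = fa @ matrix.scores @ fb.T
    score, ops = _gotoh(expected, matrix.gap_open, matrix.gap_extend)
    rows_a = [[] for _ in pa.rows]
    rows_b = [[] for _ in pb.rows]
    i = j = 0
    for op in ops:
        if op == _DIAG:
            for r, row in zip(rows_a, pa.rows):
                r.append(row[i])
            for r, row in zip(rows_b, pb.rows):
                r.append(row[j])
            i += 1
            j += 1
        elif op == _UP:
            for r, row in zip(rows_a, pa.rows):
                r.append(row[i])
            for r in rows_b:
                r.append(GAP)
            i += 1
        else:
            for r in rows_a:
                r.append(GAP)
            for r, row in zip(rows_b, pb.rows):
                r.append(row[j])
            j += 1
    merged = _ProfileRows(ids=pa.ids + pb.ids,
                          rows=["".join(r) for r in rows_a + rows_b])
    return merged, score


def _alphabet_tag(matrix: ScoringMatrix) -> str:
    return "nuc" if set(matrix.alphabet) <= set(NUCLEOTIDES + UNKNOWN) else "encoded"


def pairwise_align(a, b, matrix: ScoringMatrix):
    """Optimal global affine-gap alignment of two sequences.

    Returns (Alignment of two rows, score).  Deterministic traceback with
    tie order diagonal > up > left.
    """
    (ida, sa), (idb, sb) = _as_pair(a), _as_pair(b)
    if not sa or not sb:
        # empty-vs-something still has a defined score (one terminal gap run)
        n = max(len(sa), len(sb))
        score = 0.0 if n == 0 else -(matrix.gap_open + (n - 1) * matrix.gap_extend)
        rows = [sa or GAP * n, sb or GAP * n] if n else ["", ""]
        return Alignment(ids=[ida, idb], rows=rows,
                         alphabet=_alphabet_tag(matrix)), score
    ia = matrix.encode_indices(sa)
    ib = matrix.encode_indices(sb)
    expected = matrix.scores[np.ix_(ia, ib)]
    score, ops = _gotoh(expected, matrix.gap_open, matrix.gap_extend)
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == _DIAG:
            ra.append(sa[i]); rb.append(sb[j]); i += 1; j += 1
        elif op == _UP:
            ra.append(sa[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(sb[j]); j += 1
    aln = Alignment(ids=[ida, idb], rows=["".join(ra), "".join(rb)],
                    alphabet=_alphabet_tag(matrix))
    return aln, score


def _pairwise_identity_distance(sa: str, sb: str, matrix: ScoringMatrix) -> float:
    aln, _ = pairwise_align(("a", sa), ("b", sb), matrix)
    ra, rb = aln.rows
    if not ra:
        return 0.0
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return 1.0 - matches / len(ra)


def guide_tree(seqs, matrix: ScoringMatrix):
    """UPGMA tree on 1 - pairwise identity of optimal pairwise alignments."""
    from . import trees
    from .distances import DistanceMatrix

    pairs = [_as_pair(s) for s in seqs]
    if len(pairs) < 2:
        raise UsageError("need at least 2 sequences")
    ids = [p[0] for p in pairs]
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_identity_distance(pairs[i][1],
                                                            pairs[j][1], matrix)
    return trees.upgma(DistanceMatrix(labels=ids, d=d))


def progressive_align(seqs, matrix: ScoringMatrix, tree=None) -> Alignment:
    """Progressive multiple alignment along a guide tree (postorder merges)."""
    pairs = [_as_pair(s) for s in seqs]
    if len(pairs) < 2:
        raise UsageError("need at least 2 sequences")
    by_id = dict(pairs)
    if tree is None:
        tree = guide_tree(seqs, matrix)
    tree = tree.copy().sort()

    def rec(node):
        if node.is_leaf:
            return _ProfileRows(ids=[node.label], rows=[by_id[node.label]])
        prof = rec(node.children[0])
        for child in node.children[1:]:
            prof, _ = _merge(prof, rec(child), matrix)
        return prof

    prof = rec(tree.root)
    order = {rid: k for k, rid in enumerate(p[0] for p in pairs)}
    rows_by_id = dict(zip(prof.ids, prof.rows))
    ids = sorted(rows_by_id, key=order.get)
    aln = Alignment(ids=ids, rows=[rows_by_id[i] for i in ids],
                    alphabet=_alphabet_tag(matrix))
    for rid in ids:
        if aln.degapped(rid) != by_id[rid]:
            raise AssertionError(f"de-gapping invariant violated for {rid!r}")
    return aln
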
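"""Threshold consensus secondary structures from a sequence-structure
alignment, and their mapping onto a reference sequence's coordinates.

A consensus base pair at level c is a pair of alignment columns (i, j)
such that at least a fraction c of ALL rows base-pair their residues at
those two columns; a row gapped at either column never counts toward the
pair.  The 100% consensus is therefore literally "all taxa pair here" and
is always a subset of the 75% consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .encoding import decode, pair_table
from .errors import UsageError, ValidationError
from .msa import GAP, Alignment

_EPS = 1e-12


@dataclass
class ConsensusPairs:
    """Consensus base pairs (column i < column j, support fraction f)."""

    n_columns: int
    pairs: list  # [(i, j, f), ...] sorted by (i, j)
    threshold: float


def structures_from_encoded_alignment(aln: Alignment, table=None) -> dict:
    """Recover each row's ungapped dot-bracket string by decoding."""
    if aln.alphabet != "encoded":
        raise UsageError("alignment is not in the encoded alphabet")
    from .encoding import EncodedSequence
    out = {}
    for rid in aln.ids:
        _, struct = decode(EncodedSequence(id=rid, letters=aln.degapped(rid)), table)
        out[rid] = struct
    return out


def _column_pairs(row: str, struct: str):
    """Pairs of alignment columns base-paired in one row."""
    residue_cols = [c for c, ch in enumerate(row) if ch != GAP]
    if len(residue_cols) != len(struct):
        raise ValidationError(
            "structure length does not match the row's ungapped length")
    partner = pair_table(struct)
    for pos, j in enumerate(partner):
        if j > pos:
            yield residue_cols[pos], residue_cols[j]


def consensus_pairs(aln: Alignment, structures: dict | None = None,
                    threshold: float = 0.75,
                    denominator: str = "all") -> ConsensusPairs:
    """Count per-column-pair pairing frequencies and threshold them.

    ``structures`` maps row id -> ungapped dot-bracket string; for encoded
    alignments it defaults to decoding the rows.  ``denominator`` is
    "all" (gapped rows count as absence, the default) or "ungapped"
    (rows gapped at either column are excluded from the denominator).
    """
    if not 0 < threshold <= 1:
        raise UsageError("threshold must be in (0, 1]")
    if denominator not in ("all", "ungapped"):
        raise UsageError("denominator must be 'all' or 'ungapped'")
    if structures is None:
        structures = structures_from_encoded_alignment(aln)
    counts = {}
    for rid in aln.ids:
        for i, j in _column_pairs(aln.row(rid), structures[rid]):
            counts[(i, j)] = counts.get((i, j), 0) + 1
    n = aln.n_rows
    pairs = []
    if denominator == "ungapped":
        mat = aln.to_matrix()
    for (i, j), c in sorted(counts.items()):
        if denominator == "all":
            denom = n
        else:
            denom = int(((mat[:, i] != GAP.encode()) & (mat[:, j] != GAP.encode())).sum())
        f = c / denom
        if f >= threshold - _EPS:
            pairs.append((i, j, f))
    return ConsensusPairs(n_columns=aln.length, pairs=pairs, threshold=threshold)


def consensus_to_dotbracket(cp: ConsensusPairs):
    """Render consensus pairs as one nested dot-bracket string.

    Pairs are admitted by decreasing frequency (then left column); a pair
    sharing a column with, or crossing, an already-admitted pair is
    dropped and reported.  Output brackets are always balanced and nested.
    """
    chars = ["."] * cp.n_columns
    taken = set()
    admitted = []
    dropped = []
    for i, j, f in sorted(cp.pairs, key=lambda p: (-p[2], p[0])):
        conflict = i in taken or j in taken
        if not conflict:
            for a, b, _ in admitted:
                if (a < i < b) != (a < j < b):  # crossing
                    conflict = True
                    break
        if conflict:
            dropped.append((i, j, f))
        else:
            admitted.append((i, j, f))
            taken.update((i, j))
            chars[i], chars[j] = "(", ")"
    return "".join(chars), dropped


def map_to_reference(cp: ConsensusPairs, aln: Alignment, reference_id: str):
    """Renumber consensus pairs into the reference row's ungapped coordinates.

    Returns (mapped pairs, unmappable pairs); a pair touching a column
    where the reference is gapped is unmappable.  Mapped + unmappable
    counts always equal the input pair count.
    """
    row = aln.row(reference_id)
    col_to_ref = {}
    pos = 0
    for c, ch in enumerate(row):
        if ch != GAP:
            col_to_ref[c] = pos
            pos += 1
    mapped = []
    unmappable = []
    for i, j, f in cp.pairs:
        if i in col_to_ref and j in col_to_ref:
            mapped.append((col_to_ref[i], col_to_ref[j], f))
        else:
            unmappable.append((i, j, f))
    return mapped, unmappable
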
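"""Readers and writers: structured FASTA (Vienna 3-line dialect), plain
FASTA and relaxed-PHYLIP alignments, and Newick trees.

The structured FASTA dialect is strict: every record is exactly three
physical lines — ``>id``, the RNA sequence, and its dot-bracket structure
of identical length.  ``T`` is normalized to ``U`` and sequences are
upper-cased on input; records whose sequence and structure lengths differ
("uneven length") or whose brackets are unbalanced are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import pair_table
from .errors import FormatError, ValidationError
from .msa import Alignment
from .trees import Node, Tree

_SEQ_CHARS = set("ACGUN")
_PSEUDOKNOT = set("[]{}<>")


@dataclass(frozen=True)
class StructuredSequence:
    """One RNA sequence paired with its individual dot-bracket structure."""

    id: str
    seq: str
    struct: str

    def __post_init__(self):
        if len(self.seq) != len(self.struct):
            raise ValidationError(
                f"record {self.id!r}: uneven length (sequence {len(self.seq)} "
                f"vs structure {len(self.struct)})")
        bad = set(self.seq) - _SEQ_CHARS
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}")
        knots = set(self.struct) & _PSEUDOKNOT
        if knots:
            raise ValidationError(
                f"record {self.id!r}: pseudoknot brackets {sorted(knots)} not supported")
        try:
            pair_table(self.struct)
        except ValidationError as exc:
            raise ValidationError(f"record {self.id!r}: {exc}") from None


def normalize_seq(raw: str) -> str:
    return raw.strip().upper().replace("T", "U")


def _as_text(path_or_text) -> str:
    text = str(path_or_text)
    if text.lstrip().startswith(">"):
        return text
    with open(path_or_text, encoding="utf-8") as fh:
        return fh.read()


def read_structured_fasta(path_or_text) -> list:
    """Parse 3-line structured FASTA records into StructuredSequences."""
    lines = [ln.rstrip("\n") for ln in _as_text(path_or_text).splitlines()
             if ln.strip()]
    if len(lines) % 3:
        raise FormatError("structured FASTA must consist of 3-line records")
    records = []
    seen = set()
    for i in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[i:i + 3]
        if not header.startswith(">"):
            raise FormatError(f"expected '>' header at line {i + 1}, got {header!r}")
        rid = header[1:].split()[0]
        if not rid:
            raise FormatError(f"empty record id at line {i + 1}")
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(StructuredSequence(id=rid, seq=normalize_seq(seq_line),
                                          struct=struct_line.strip()))
    return records


def write_structured_fasta(records, path=None) -> str:
    out = "".join(f">{r.id}\n{r.seq}\n{r.struct}\n" for r in records)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# alignments

def write_fasta_alignment(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(row), id=rid, description="")
            for rid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(recs, path, "fasta")


def read_fasta_alignment(path, alphabet: str = "nuc") -> Alignment:
    recs = list(SeqIO.parse(path, "fasta"))
    if not recs:
        raise FormatError(f"no records in {path}")
    return Alignment(ids=[r.id for r in recs], rows=[str(r.seq).upper() for r in recs],
                     alphabet=alphabet)


def write_phylip_alignment(aln: Alignment, path) -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=rid) for rid, row in zip(aln.ids, aln.rows)])
    AlignIO.write(msa, path, "phylip-relaxed")


def read_phylip_alignment(path, alphabet: str = "nuc") -> Alignment:
    msa = AlignIO.read(path, "phylip-relaxed")
    return Alignment(ids=[r.id for r in msa], rows=[str(r.seq).upper() for r in msa],
                     alphabet=alphabet)


# ---------------------------------------------------------------------------
# Newick trees

def _fmt_length(x: float) -> str:
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _fmt_support(s: float) -> str:
    return str(int(round(s))) if abs(s - round(s)) < 1e-9 else f"{s:g}"


def write_newick(tree: Tree, with_support: bool = True, path=None) -> str:
    """Deterministic Newick text (children ordered by smallest label)."""
    tree = tree.copy().sort()

    def rec(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")"
            if with_support and node.support is not None:
                core += _fmt_support(node.support)
        if node.length is not None:
            core += f":{_fmt_length(node.length)}"
        return core

    text = rec(tree.root) + ";"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def read_newick(path_or_text) -> Tree:
    """Parse Newick (via dendropy); internal labels become edge supports."""
    text = str(path_or_text)
    if not text.lstrip().startswith("("):
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from None

    def rec(dnode) -> Node:
        children = [rec(c) for c in dnode.child_nodes()]
        if children:
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            return Node(length=dnode.edge.length, support=support,
                        children=children)
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label, length=dnode.edge.length)

    root = rec(dtree.seed_node)
    root.length = None
    rooted = len(root.children) <= 2
    return Tree(root, rooted=rooted).sort()
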
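"""Pseudoprotein encoding of paired RNA sequence + secondary structure.

Each position of an RNA sequence is combined with its structural state
(unpaired ``.``, helix-opening ``(`` or helix-closing ``)``) and mapped to
one letter of a 12-letter alphabet, so that protein-style alignment and
tree machinery can operate on sequence and structure simultaneously.
``N`` (unknown nucleotide) maps to a dedicated unknown symbol regardless of
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Structural states, in table order.
STATES = ("unpaired", "open", "close")

NUCLEOTIDES = "ACGU"

#: Default 12-letter code: unpaired A/C/G/U keep their letter; opening
#: positions use B/E/H/K; closing positions use D/F/I/L.
DEFAULT_CODE = {
    ("A", "unpaired"): "A", ("C", "unpaired"): "C",
    ("G", "unpaired"): "G", ("U", "unpaired"): "U",
    ("A", "open"): "B", ("C", "open"): "E",
    ("G", "open"): "H", ("U", "open"): "K",
    ("A", "close"): "D", ("C", "close"): "F",
    ("G", "close"): "I", ("U", "close"): "L",
}

#: Unknown nucleotide symbol, both in nucleotide space and encoded space.
UNKNOWN = "N"

#: Canonical ordering of the encoded alphabet (unpaired, open, close blocks).
ENCODED_ALPHABET = "ACGUBEHKDFIL"

_STATE_CHAR = {"unpaired": ".", "open": "(", "close": ")"}
_CHAR_STATE = {v: k for k, v in _STATE_CHAR.items()}


@dataclass(frozen=True)
class TranslationTable:
    """Injective map (nucleotide, structural state) -> encoded letter."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_CODE))
    unknown: str = UNKNOWN

    def __post_init__(self):
        letters = set(self.mapping.values())
        if len(self.mapping) != 12 or len(letters) != 12:
            raise ValidationError(
                f"translation table must have 12 injective entries, got "
                f"{len(self.mapping)} entries over {len(letters)} letters"
            )
        if self.unknown in letters:
            raise ValidationError("unknown symbol collides with coding letters")
        object.__setattr__(self, "_inverse", {v: k for k, v in self.mapping.items()})

    @property
    def alphabet(self) -> str:
        """Encoded alphabet in (unpaired, open, close) x (A,C,G,U) order."""
        return "".join(self.mapping[(n, s)] for s in STATES for n in NUCLEOTIDES)

    def letter(self, nucleotide: str, state: str) -> str:
        if nucleotide == self.unknown:
            return self.unknown
        try:
            return self.mapping[(nucleotide, state)]
        except KeyError:
            raise ValidationError(f"cannot encode ({nucleotide!r}, {state!r})") from None

    def invert(self, letter: str) -> tuple:
        """Return (nucleotide, state) for an encoded letter."""
        if letter == self.unknown:
            return (self.unknown, "unpaired")
        try:
            return self._inverse[letter]
        except KeyError:
            raise ValidationError(f"letter {letter!r} not in encoded alphabet") from None


def default_table() -> TranslationTable:
    """The package's fixed default 12-letter translation table."""
    return TranslationTable()


def load_table(path) -> TranslationTable:
    """Read a table from 12 lines of ``nucleotide state letter``.

    Allows substituting an alternative published code for the default one.
    """
    mapping = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            nuc, state, letter = line.split()
            if state not in STATES:
                raise ValidationError(f"unknown structural state {state!r}")
            mapping[(nuc.upper(), state)] = letter
    return TranslationTable(mapping=mapping)


def pair_table(struct: str) -> list:
    """Dot-bracket string -> partner index vector (-1 for unpaired, 0-based).

    Raises ValidationError on unbalanced or non-nested input; pseudoknot
    bracket families are rejected upstream by the IO layer.
    """
    partner = [-1] * len(struct)
    stack = []
    for i, ch in enumerate(struct):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced structure: ')' at position {i} has no partner")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise ValidationError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise ValidationError(f"unbalanced structure: '(' at position {stack[-1]} never closed")
    return partner


def struct_states(struct: str) -> list:
    """Per-position structural state names for a dot-bracket string."""
    pair_table(struct)  # validates
    return [_CHAR_STATE[ch] for ch in struct]


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence over the 12-letter alphabet (plus the unknown symbol)."""

    id: str
    letters: str


def encode(seq_record, table: TranslationTable | None = None) -> EncodedSequence:
    """Encode a StructuredSequence into its pseudoprotein string."""
    table = table or default_table()
    states = struct_states(seq_record.struct)
    if len(seq_record.seq) != len(seq_record.struct):
        raise ValidationError(
            f"record {seq_record.id!r}: uneven length (sequence {len(seq_record.seq)}"
            f" vs structure {len(seq_record.struct)})"
        )
    letters = "".join(table.letter(n, s) for n, s in zip(seq_record.seq, states))
    return EncodedSequence(id=seq_record.id, letters=letters)


def decode(encoded: EncodedSequence, table: TranslationTable | None = None) -> tuple:
    """Inverse of :func:`encode`; returns ``(seq, struct)`` strings."""
    table = table or default_table()
    seq = []
    struct = []
    for letter in encoded.letters:
        nuc, state = table.invert(letter)
        seq.append(nuc)
        struct.append(_STATE_CHAR[state])
    return "".join(seq), "".join(struct)
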
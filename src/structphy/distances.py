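"""Evolutionary distances on aligned nucleotide or 12-letter encoded data.

Distances are observed mismatch fractions (pairwise deletion of gaps and
unknowns) corrected with the k-state Jukes-Cantor transform

    d = -((k-1)/k) * ln(1 - k*p/(k-1)),

k = 4 for nucleotide alignments and k = 12 for pseudoprotein alignments.
Profiles summarize groups of rows as per-column state-frequency vectors and
admit the same corrected distance, which degenerates exactly to the
sequence distance on singleton profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .encoding import ENCODED_ALPHABET, UNKNOWN
from .errors import SaturationError, UndefinedDistanceError, UsageError, ValidationError

GAP = "-"

ALPHABETS = {"nuc": "ACGU", "encoded": ENCODED_ALPHABET}


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix in substitutions/site with row labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal not zero")

    def write_phylip(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


def _codes(rows, alphabet: str) -> np.ndarray:
    """Rows -> int matrix; gap/unknown/other -> -1."""
    lut = np.full(256, -1, dtype=np.int16)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return lut[mat].reshape(len(rows), -1)


def p_distance(row_a: str, row_b: str, alphabet: str | None = None) -> float:
    """Mismatch fraction with pairwise deletion of gap/unknown positions."""
    if len(row_a) != len(row_b):
        raise UsageError("rows have unequal length")
    comparable = 0
    mismatches = 0
    for x, y in zip(row_a, row_b):
        if x in (GAP, UNKNOWN) or y in (GAP, UNKNOWN):
            continue
        comparable += 1
        mismatches += x != y
    if comparable == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    return mismatches / comparable


def jc_k(p: float, k: int) -> float:
    """k-state Jukes-Cantor correction of a mismatch fraction."""
    if k < 2:
        raise UsageError("alphabet size must be >= 2")
    if p < 0:
        raise UsageError("mismatch fraction must be >= 0")
    pmax = (k - 1) / k
    if p >= pmax:
        raise SaturationError(f"p={p:.4f} at or beyond the {k}-state ceiling {pmax:.4f}")
    return -pmax * math.log(1.0 - p / pmax)


#: Capped distance used when `saturation="cap"`: the correction evaluated
#: just inside its domain, so saturated pairs stay finite but very large.
def _jc_cap(k: int) -> float:
    pmax = (k - 1) / k
    return -pmax * math.log(1e-3)


def distance_matrix(aln, k: int | None = None, correction: str = "jc",
                    saturation: str = "error") -> DistanceMatrix:
    """All-pairs corrected distances for an Alignment.

    correction: "jc" (default) or "p" for the raw mismatch fraction.
    saturation: "error" raises SaturationError; "cap" assigns a large
    finite distance to saturated pairs.
    """
    if len(aln.rows) < 2:
        raise UsageError("need at least 2 rows")
    alphabet = ALPHABETS[aln.alphabet]
    if k is None:
        k = len(alphabet)
    codes = _codes(aln.rows, alphabet)
    n = codes.shape[0]
    d = np.zeros((n, n))
    ok = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ok[i] & ok[j]
            comparable = int(mask.sum())
            if comparable == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}")
            p = float((codes[i, mask] != codes[j, mask]).sum()) / comparable
            if correction == "p":
                dij = p
            else:
                try:
                    dij = jc_k(p, k)
                except SaturationError:
                    if saturation == "cap":
                        dij = _jc_cap(k)
                    else:
                        raise SaturationError(
                            f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) saturated: p={p:.4f}"
                        ) from None
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(aln.ids), d=d)


@dataclass
class Profile:
    """A named group of alignment rows as per-column frequency vectors.

    ``freqs[c, s]`` is the relative frequency of state ``s`` among the
    members carrying an informative residue at column ``c`` (so each
    informative column sums to 1); ``miss[c]`` is the fraction of members
    that are gapped or unknown there.
    """

    name: str
    members: list
    freqs: np.ndarray
    miss: np.ndarray
    counts: np.ndarray = field(repr=False, default=None)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @classmethod
    def from_counts(cls, name, members, counts: np.ndarray):
        """counts: (L, k) informative state counts per column."""
        counts = np.asarray(counts, dtype=float)
        n = len(members)
        informative = counts.sum(axis=1)
        freqs = np.zeros_like(counts)
        nz = informative > 0
        freqs[nz] = counts[nz] / informative[nz, None]
        miss = 1.0 - informative / n
        return cls(name=name, members=list(members), freqs=freqs, miss=miss,
                   counts=counts)


def profile_counts(aln, member_ids) -> np.ndarray:
    """(L, k) informative state counts for a subset of rows."""
    alphabet = ALPHABETS[aln.alphabet]
    idx = [aln.ids.index(m) for m in member_ids]
    if not idx:
        raise UsageError("profile needs at least one member")
    codes = _codes([aln.rows[i] for i in idx], alphabet)
    k = len(alphabet)
    L = codes.shape[1]
    counts = np.zeros((L, k))
    for row in codes:
        ok = row >= 0
        np.add.at(counts, (np.nonzero(ok)[0], row[ok]), 1.0)
    return counts


def build_profile(aln, member_ids, name: str) -> Profile:
    """Summarize a subset of alignment rows as a Profile."""
    missing = [m for m in member_ids if m not in aln.ids]
    if missing:
        raise UsageError(f"profile {name!r} members not in alignment: {missing}")
    return Profile.from_counts(name, member_ids, profile_counts(aln, member_ids))


def profile_distance(p_prof: Profile, q_prof: Profile, k: int,
                     saturation: str = "error") -> float:
    """Corrected expected mismatch between two profiles.

    A column is comparable when both profiles have informative (non-gap,
    non-unknown) mass > 0.5; over comparable columns the expected mismatch
    is 1 - sum_s fP(s) fQ(s), then JC-k corrected.
    """
    if p_prof.freqs.shape != q_prof.freqs.shape:
        raise UsageError("profiles built on different alignments")
    comparable = ((1.0 - p_prof.miss) > 0.5) & ((1.0 - q_prof.miss) > 0.5)
    if not comparable.any():
        raise UndefinedDistanceError(
            f"no comparable columns between {p_prof.name!r} and {q_prof.name!r}")
    agree = (p_prof.freqs[comparable] * q_prof.freqs[comparable]).sum(axis=1)
    p_hat = float(np.mean(1.0 - agree))
    try:
        return jc_k(p_hat, k)
    except SaturationError:
        if saturation == "cap":
            return _jc_cap(k)
        raise


def profile_distance_matrix(profiles: list, k: int,
                            saturation: str = "error") -> DistanceMatrix:
    n = len(profiles)
    if n < 2:
        raise UsageError("need at least 2 profiles")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = profile_distance(profiles[i], profiles[j], k,
                                                 saturation=saturation)
    return DistanceMatrix(labels=[p.name for p in profiles], d=d)
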
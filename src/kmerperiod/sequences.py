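"""Sequence handling: IUPAC motif matching, pairwise distances and distograms.

The first stage of the periodicity pipeline: occurrences of a (possibly
degenerate) k-mer are mapped in each sequence, all within-sequence pairwise
start-to-start distances are computed, and the distances are pooled across the
sequence set into a single histogram (the "distogram") capped at
``max_distance`` (200 bp by default, which fixes the downstream frequency grid
at steps of 1/200 = 0.005 cycles/bp).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "IUPAC",
    "DnaSequence",
    "MotifSpec",
    "Distogram",
    "NoOccurrencesWarning",
    "expand_iupac",
    "reverse_complement",
    "map_occurrences",
    "pairwise_distances",
    "build_distogram",
]

#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they stand for.
#: N is listed as {A,C,G,T}: an N *in a pattern* expands to concrete words, but
#: an N *in a sequence* (assembly gap / masked base) never matches anything.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Any IUPAC ambiguity letter in an input *sequence* other than A/C/G/T is
# collapsed to N, so it can never fabricate a motif occurrence.
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in IUPAC} | {"U": "N"}
)


class NoOccurrencesWarning(UserWarning):
    """Raised (as a warning) when a motif has no occurrences in a sequence set."""


def expand_iupac(pattern: str) -> frozenset[str]:
    """Expand an IUPAC pattern into the set of concrete k-mers it matches.

    >>> sorted(expand_iupac("WW"))
    ['AA', 'AT', 'TA', 'TT']
    """
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    pattern = pattern.upper()
    for sym in pattern:
        if sym not in IUPAC:
            raise ValueError(f"non-IUPAC symbol {sym!r} in motif pattern {pattern!r}")
    return frozenset("".join(w) for w in product(*(sorted(IUPAC[s]) for s in pattern)))


def reverse_complement(bases: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over the alphabet {A,C,G,T,N}.

    Input is uppercase-normalized. Ambiguity letters other than A/C/G/T are
    replaced by N; any other character is rejected. Soft-masked (lowercase)
    bases are kept by default; pass ``mask_lowercase=True`` to turn them into
    N instead.
    """

    id: str
    bases: str

    @classmethod
    def from_raw(cls, id: str, raw: str, mask_lowercase: bool = False) -> "DnaSequence":
        if mask_lowercase:
            raw = "".join("N" if c.islower() else c for c in raw)
        bases = raw.upper().translate(_NORMALIZE)
        bad = set(bases) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid sequence character(s): {sorted(bad)}")
        return cls(id=id, bases=bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(id=self.id, bases=reverse_complement(self.bases))


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC pattern together with its expansion to concrete k-mers."""

    pattern: str
    k: int
    expansion: frozenset[str]
    _regex: re.Pattern = field(compare=False, repr=False, hash=False, default=None)

    @classmethod
    def from_pattern(cls, pattern: str) -> "MotifSpec":
        pattern = pattern.upper()
        expansion = expand_iupac(pattern)
        # Character classes contain concrete bases only, so a window holding
        # an N in the sequence can never match. The lookahead makes matches
        # overlapping: TT occurs at both 0 and 1 in "TTT".
        classes = "".join(f"[{''.join(sorted(IUPAC[s]))}]" for s in pattern)
        regex = re.compile(f"(?={classes})")
        return cls(pattern=pattern, k=len(pattern), expansion=expansion, _regex=regex)


def _as_motif(motif: "MotifSpec | str") -> MotifSpec:
    return motif if isinstance(motif, MotifSpec) else MotifSpec.from_pattern(motif)


def map_occurrences(seq: DnaSequence, motif: "MotifSpec | str") -> np.ndarray:
    """0-based start positions of all (overlapping) motif matches, ascending."""
    motif = _as_motif(motif)
    return np.fromiter(
        (m.start() for m in motif._regex.finditer(seq.bases)), dtype=np.int64
    )


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """All pairwise distances p_j - p_i (i < j) between sorted positions.

    Returns n·(n−1)/2 positive integers for n positions.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n = positions.size
    if n < 2:
        return np.empty(0, dtype=np.int64)
    diffs = positions[None, :] - positions[:, None]
    return diffs[np.triu_indices(n, k=1)]


@dataclass
class Distogram:
    """Histogram of pooled pairwise k-mer distances, for distances 1..max_distance.

    ``counts[d-1]`` is the number of pairs at distance d. Pairs farther apart
    than ``max_distance`` are discarded and do not count in ``n_pairs_total``.
    """

    max_distance: int
    counts: np.ndarray
    n_pairs_total: int
    n_occurrences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.max_distance,):
            raise ValueError("counts must have exactly max_distance entries")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_pairs_total:
            raise ValueError("sum(counts) must equal n_pairs_total")

    @property
    def is_degenerate(self) -> bool:
        return self.n_pairs_total == 0

    def __add__(self, other: "Distogram") -> "Distogram":
        if other.max_distance != self.max_distance:
            raise ValueError("cannot add distograms with different max_distance")
        return Distogram(
            max_distance=self.max_distance,
            counts=self.counts + other.counts,
            n_pairs_total=self.n_pairs_total + other.n_pairs_total,
            n_occurrences=self.n_occurrences + other.n_occurrences,
        )


def build_distogram(
    seqs: "list[DnaSequence] | DnaSequence",
    motif: "MotifSpec | str",
    max_distance: int = 200,
    warn_on_empty: bool = True,
) -> Distogram:
    """Pool within-sequence pairwise motif distances into one distogram.

    Distances are never computed across sequence boundaries; per-sequence
    histograms are summed. A motif with no occurrence anywhere yields an
    all-zero distogram and a :class:`NoOccurrencesWarning`.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if isinstance(seqs, DnaSequence):
        seqs = [seqs]
    motif = _as_motif(motif)
    counts = np.zeros(max_distance, dtype=np.int64)
    n_occ = 0
    for seq in seqs:
        pos = map_occurrences(seq, motif)
        n_occ += pos.size
        if pos.size < 2:
            continue
        d = pairwise_distances(pos)
        d = d[d <= max_distance]
        counts += np.bincount(d, minlength=max_distance + 1)[1:]
    if n_occ == 0 and warn_on_empty:
        warnings.warn(
            f"motif {motif.pattern!r} has no occurrences in the input sequences",
            NoOccurrencesWarning,
            stacklevel=2,
        )
    return Distogram(
        max_distance=max_distance,
        counts=counts,
        n_pairs_total=int(counts.sum()),
        n_occurrences=n_occ,
    )
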
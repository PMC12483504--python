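"""Nucleotide alignments: container, FASTA I/O, and state encoding.

Sequences are stored upper-case with U mapped to T.  IUPAC ambiguity
codes, N and gaps are retained and handled downstream as partial
observations (a gap is equivalent to N: compatible with every state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .errors import DomainError, FormatError

#: Symbol -> indicator over (A, C, G, T).  Unlisted symbols are rejected.
IUPAC_STATES = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1),
}
_SYMBOLS = sorted(IUPAC_STATES)
_SYMBOL_CODE = {s: i for i, s in enumerate(_SYMBOLS)}
#: Indicator table indexed by symbol code, shape (nsymbols, 4).
STATE_TABLE = np.array([IUPAC_STATES[s] for s in _SYMBOLS], dtype=float)


def _clean(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_STATES)
    if bad:
        raise FormatError(f"unrecognized sequence symbols: {sorted(bad)}")
    return s


@dataclass
class NucAlignment:
    """Equal-length named nucleotide sequences."""

    names: list
    sequences: list

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise DomainError("names and sequences must have equal length")
        if len(set(self.names)) != len(self.names):
            raise DomainError("sequence names must be unique")
        self.sequences = [_clean(s) for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            ragged = next(n for n, s in zip(self.names, self.sequences)
                          if len(s) != len(self.sequences[0]))
            raise FormatError(f"alignment is ragged (record {ragged!r})")

    @property
    def nsites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def ntaxa(self) -> int:
        return len(self.names)

    def sequence(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def codes(self) -> np.ndarray:
        """(ntaxa, nsites) array of symbol codes indexing STATE_TABLE."""
        return np.array([[_SYMBOL_CODE[ch] for ch in s] for s in self.sequences],
                        dtype=np.int8)

    def site_patterns(self):
        """Unique site patterns and their counts, cached: a
        (ntaxa, npatterns) code array and an int count vector."""
        cached = getattr(self, "_pattern_cache", None)
        if cached is None:
            patterns, counts = np.unique(self.codes(), axis=1, return_counts=True)
            cached = (patterns, counts)
            object.__setattr__(self, "_pattern_cache", cached)
        return cached

    def to_fasta(self) -> str:
        return "".join(f">{n}\n{s}\n" for n, s in zip(self.names, self.sequences))


def read_fasta(path) -> NucAlignment:
    """Read a gapped FASTA alignment; validates equal lengths, maps U->T
    and upper-cases.  Record order is preserved."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    if not names:
        raise FormatError(f"no FASTA records found in {path}")
    return NucAlignment(names=names, sequences=seqs)


def write_fasta(aln: NucAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(aln.to_fasta())


def empirical_frequencies(aln: NucAlignment) -> np.ndarray:
    """Observed (A, C, G, T) proportions over unambiguous sites."""
    counts = np.zeros(4)
    for s in aln.sequences:
        for i, b in enumerate("ACGT"):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        raise DomainError("alignment has no unambiguous nucleotides")
    return counts / counts.sum()
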
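"""Multiple sequence alignments and sequence-derived scalar features.

Provides aligned-FASTA / A3M reading (query first), pairwise sequence
identity, redundancy-based sequence weights, the effective alignment depth

    Meff = sum_i 1 / m_i,   m_i = #rows with identity > cutoff to row i,

and a weighted PSSM with pseudocounts.

Identity is counted as identical non-gap residues over the full column count;
gapped columns therefore count as mismatches (the alternative, non-gap
columns only, is available via ``denominator="non_gap"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMINO_ACIDS, AA_INDEX, BACKGROUND_FREQS, GAP

_VALID = set(AMINO_ACIDS) | {GAP, "X"}


@dataclass
class MSA:
    """Aligned rows over {20 amino acids, '-', 'X'}; row 0 is the query."""

    sequences: list
    names: list = None

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise ValueError("ragged alignment: rows differ in length")
        if self.names is None:
            self.names = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def ncols(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[0]

    def to_indices(self) -> np.ndarray:
        """(M, ncols) integer matrix; 0..19 amino acids, 20 gap/unknown."""
        lut = np.full(128, 20, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
        buf = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return lut[buf].reshape(self.depth, self.ncols)


@dataclass
class SequenceWeights:
    weights: np.ndarray
    identity_cutoff: float


@dataclass
class PSSM:
    values: np.ndarray  # (L, 20)
    encoding: str


def _normalize_row(seq: str, a3m: bool) -> str:
    if a3m:
        seq = "".join(c for c in seq if not c.islower() and c != ".")
    seq = seq.upper().replace(".", GAP)
    return "".join(c if c in _VALID else "X" for c in seq)


def read_msa(path: str, format: str = "aligned_fasta") -> MSA:
    """Read an alignment; the first record is taken as the query.

    For A3M input, lowercase insert states are removed per row so every row
    matches the query length.
    """
    if format not in {"a3m", "aligned_fasta"}:
        raise ValueError(f"unknown MSA format {format!r}")
    names, seqs, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
                names.append(line[1:].split()[0] if len(line) > 1 else "")
            else:
                cur.append(line)
        if cur:
            seqs.append("".join(cur))
    if not seqs:
        raise ValueError(f"no sequences found in {path!r}")
    rows = [_normalize_row(s, a3m=(format == "a3m")) for s in seqs]
    if GAP in rows[0]:
        raise ValueError("query row contains gaps after normalization")
    return MSA(rows, names)


def write_msa(msa: MSA, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(msa.names, msa.sequences):
            fh.write(f">{name}\n{seq}\n")


def seq_identity(a: str, b: str, denominator: str = "full") -> float:
    """Fraction of columns with identical non-gap residues."""
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    if denominator == "full":
        denom = len(a)
    elif denominator == "non_gap":
        denom = sum(1 for x, y in zip(a, b) if x != GAP and y != GAP)
        denom = max(denom, 1)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return matches / denom


def _identity_matrix(msa: MSA) -> np.ndarray:
    X = msa.to_indices()
    M, n = X.shape
    nongap = X < 20
    ident = np.zeros((M, M))
    for i in range(M):
        same = (X == X[i][None, :]) & nongap[i][None, :]
        ident[i] = same.sum(axis=1) / n
    return ident


def sequence_weights(msa: MSA, identity_cutoff: float = 0.7) -> SequenceWeights:
    """Redundancy weights 1/m_i, m_i = #rows with identity > cutoff to row i."""
    ident = _identity_matrix(msa)
    m = (ident > identity_cutoff).sum(axis=1)
    m = np.maximum(m, 1)  # a row is always within cutoff of itself
    return SequenceWeights(1.0 / m, identity_cutoff)


def meff(msa: MSA, identity_cutoff: float = 0.7) -> float:
    """Effective number of non-redundant rows: sum of 1/m_i."""
    return float(sequence_weights(msa, identity_cutoff).weights.sum())


def pssm(msa: MSA, weights: SequenceWeights | None = None,
         pseudocount: float = 1.0, encoding: str = "frequency") -> PSSM:
    """Weighted position-specific scoring matrix with lambda/20 pseudocounts.

    Gaps are excluded from column normalization; frequency rows sum to 1.
    ``log_odds`` encodes log(freq / background) with a fixed background.
    """
    if weights is None:
        weights = sequence_weights(msa)
    w = np.asarray(weights.weights, dtype=float)
    X = msa.to_indices()
    L = msa.ncols
    counts = np.zeros((L, 20))
    for a in range(20):
        counts[:, a] = ((X == a) * w[:, None]).sum(axis=0)
    counts += pseudocount / 20.0
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    if encoding == "frequency":
        return PSSM(freqs, encoding)
    if encoding == "log_odds":
        return PSSM(np.log(freqs / BACKGROUND_FREQS[None, :]), encoding)
    raise ValueError(f"unknown PSSM encoding {encoding!r}")
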
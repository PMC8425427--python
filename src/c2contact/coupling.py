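"""Direct-coupling analysis: raw coupling scores and their APC correction.

The engine is mean-field DCA: reweighted single/pair amino-acid frequencies
with pseudocounts, the (L*(q-1)) x (L*(q-1)) covariance matrix, its inverse as
the coupling matrix, zero-sum gauge per 20x20 residue-pair block, and the
Frobenius norm of each block as the per-pair score.  The raw channel is this
un-corrected norm; the second channel applies the average product correction

    S'_ij = S_ij - mean_i(S) * mean_j(S) / mean(S)

with row and grand means taken over the full matrix (this convention makes
the correction exactly annihilate rank-one product structure).  Externally
computed matrices
(CCMpred-style whitespace-delimited L x L text) can be ingested instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import Q
from .msa import MSA, SequenceWeights, sequence_weights


@dataclass
class CouplingScores:
    raw: np.ndarray   # (L, L), symmetric, zero diagonal
    apc: np.ndarray   # (L, L), symmetric, zero diagonal
    provenance: str = "internal_dca"


def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric score matrix.

    The corrected matrix is re-symmetrized and its diagonal zeroed.
    """
    S = np.asarray(S, dtype=float)
    L = S.shape[0]
    if S.shape != (L, L):
        raise ValueError("score matrix must be square")
    denom = S.mean()
    if denom == 0:
        warnings.warn("mean coupling score is zero; APC left as identity")
        out = S.copy()
        np.fill_diagonal(out, 0.0)
        return out
    row_mean = S.mean(axis=1)
    corrected = S - np.outer(row_mean, row_mean) / denom
    corrected = (corrected + corrected.T) / 2.0
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _weighted_frequencies(X: np.ndarray, w: np.ndarray, lam: float):
    """Pseudocounted single and pair frequencies over the q=21 alphabet."""
    M, L = X.shape
    W = w.sum()
    onehot = np.zeros((M, L, Q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    fi = np.einsum("m,mla->la", w, onehot) / W
    flat = (onehot * w[:, None, None]).reshape(M, L * Q)
    fij = (flat.T @ onehot.reshape(M, L * Q)) / W
    fij = fij.reshape(L, Q, L, Q)

    fi_pc = (1 - lam) * fi + lam / Q
    fij_pc = (1 - lam) * fij + lam / (Q * Q)
    # on-site pair term is diagonal by definition
    for i in range(L):
        fij_pc[i, :, i, :] = np.diag((1 - lam) * fi[i] + lam / Q)
    return fi_pc, fij_pc


def mean_field_dca(msa: MSA, weights: SequenceWeights | None = None,
                   pseudocount_fraction: float = 0.5) -> np.ndarray:
    """Raw coupling score matrix (Frobenius norm of zero-sum-gauge blocks)."""
    if msa.ncols < 2:
        raise ValueError("alignment must span at least two columns")
    if weights is None:
        weights = sequence_weights(msa)
    lam = pseudocount_fraction
    X = msa.to_indices()
    L = msa.ncols
    fi, fij = _weighted_frequencies(X, np.asarray(weights.weights, float), lam)

    q1 = Q - 1  # drop the gap state as the gauge reference
    C = fij[:, :q1, :, :q1] - np.einsum("ia,jb->iajb", fi[:, :q1], fi[:, :q1])
    C = C.reshape(L * q1, L * q1)
    try:
        Jflat = -np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; use a pseudocount_fraction > 0 "
            "or a deeper alignment") from exc
    J = Jflat.reshape(L, q1, L, q1)

    scores = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = J[i, :, j, :]
            # zero-sum gauge before taking the norm
            block = (block - block.mean(axis=0, keepdims=True)
                     - block.mean(axis=1, keepdims=True) + block.mean())
            scores[i, j] = scores[j, i] = np.linalg.norm(block)
    return scores


def compute_couplings(msa: MSA, weights: SequenceWeights | None = None,
                      pseudocount_fraction: float = 0.5) -> CouplingScores:
    """Both coupling channels from the internal mean-field engine."""
    raw = mean_field_dca(msa, weights, pseudocount_fraction)
    return CouplingScores(raw, apc_correct(raw), "internal_dca")


def load_couplings(path: str, L: int, apc_path: str | None = None) -> CouplingScores:
    """Ingest a CCMpred-style plain-text L x L matrix as the raw channel."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape != (L, L):
        raise ValueError(
            f"coupling matrix in {path!r} has shape {raw.shape}, expected ({L}, {L})")
    raw = (raw + raw.T) / 2.0
    np.fill_diagonal(raw, 0.0)
    if apc_path is not None:
        apc = np.loadtxt(apc_path, ndmin=2)
        if apc.shape != (L, L):
            raise ValueError(f"APC matrix in {apc_path!r} has wrong shape")
    else:
        apc = apc_correct(raw)
    return CouplingScores(raw, apc, f"ingested({path})")


def save_couplings(scores: CouplingScores, raw_path: str,
                   apc_path: str | None = None) -> None:
    np.savetxt(raw_path, scores.raw, fmt="%.8g")
    if apc_path is not None:
        np.savetxt(apc_path, scores.apc, fmt="%.8g")
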
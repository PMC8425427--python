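"""Input tensors of the contact network.

One target is encoded as

* 1D sequential features, shape (L, 31): PSSM (20) + 8-state secondary
  structure one-hot (8) + hydrophobicity channels (3);
* 2D pairwise features, shape (4, L, L) in the fixed channel order
  ``distance, docking, coupling_raw, coupling_apc``;
* a validity mask, shape (L, L), False where either residue is unobserved.

The distance channel is clipped at ``d_max`` (50 A) and scaled to [0, 1];
every pairwise channel is symmetrized by averaging with its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..coupling import CouplingScores
from ..dockmap import DockingMap
from ..msa import MSA, PSSM
from ..secstruct import one_hot_ss
from ..structures import ContactMap, DistanceMap, MonomerStructure

PAIR_CHANNELS = ("distance", "docking", "coupling_raw", "coupling_apc")
SEQ_CHANNELS = ("pssm", "ss8", "hydrophobicity")
DISTANCE_CAP = 50.0  # Angstrom


@dataclass
class FeatureBundle:
    seq_features: np.ndarray   # (L, 31)
    pair_features: np.ndarray  # (4, L, L), channels symmetric
    mask: np.ndarray           # (L, L) bool

    @property
    def length(self) -> int:
        return self.seq_features.shape[0]


def symmetrize_pairwise(X: np.ndarray) -> np.ndarray:
    """Average a square matrix with its transpose: (X + X^T) / 2."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("pairwise feature must be a square matrix")
    return (X + X.T) / 2.0


def symmetrize_labels(Y: np.ndarray) -> np.ndarray:
    """Element-wise OR with the transpose: a contact (i,j) implies (j,i)."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
        raise ValueError("label matrix must be square")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix must be binary")
    return np.maximum(Y, Y.T)


def build_features(m: MonomerStructure, pssm: PSSM, ss_labels,
                   hydrophobicity: np.ndarray, dist_map: DistanceMap,
                   dmap: DockingMap, couplings: CouplingScores,
                   distance_cap: float = DISTANCE_CAP) -> FeatureBundle:
    """Assemble the (L, 31) and (4, L, L) network inputs for one target."""
    L = len(m)
    for name, got in [("pssm", pssm.values.shape[0]), ("ss", len(ss_labels)),
                      ("hydrophobicity", hydrophobicity.shape[0]),
                      ("distance map", dist_map.values.shape[0]),
                      ("docking map", dmap.values.shape[0]),
                      ("couplings", couplings.raw.shape[0])]:
        if got != L:
            raise ValueError(f"{name} has length {got} but the structure has {L}")
    seq = np.concatenate([pssm.values, one_hot_ss(ss_labels), hydrophobicity],
                         axis=1)
    dist = np.clip(dist_map.values, 0.0, distance_cap) / distance_cap
    pair = np.stack([
        symmetrize_pairwise(dist),
        symmetrize_pairwise(dmap.values.astype(float)),
        symmetrize_pairwise(couplings.raw),
        symmetrize_pairwise(couplings.apc),
    ])
    if not np.isfinite(seq).all() or not np.isfinite(pair).all():
        raise ValueError("non-finite feature values")
    return FeatureBundle(seq, pair, dist_map.mask.copy())


def random_crop(bundle: FeatureBundle, labels: ContactMap, max_len: int = 400,
                rng: np.random.Generator | int | None = None):
    """Crop a contiguous window of at most *max_len* residues.

    The same window is applied to the sequence axis of the 1D features and to
    both axes of the 2D features, labels and mask.  A no-op when L <= max_len.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    L = bundle.length
    if L <= max_len:
        return bundle, labels
    rng = np.random.default_rng(rng)
    start = int(rng.integers(0, L - max_len + 1))
    sl = slice(start, start + max_len)
    cropped = FeatureBundle(bundle.seq_features[sl],
                            bundle.pair_features[:, sl, sl],
                            bundle.mask[sl, sl])
    clabels = ContactMap(labels.values[sl, sl], labels.mask[sl, sl])
    return cropped, clabels
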
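"""DCA baselines, evaluation statistics and the contact-guided pose filter.

The DCA baseline ranks residue pairs by a coupling channel after removing
every pair that is already close (< 12 A) within the monomer, since those
couplings are explained by the intra-chain structure.  Metrics follow the
standard contact-prediction conventions: precision among the top-n
predictions, top-L/K precision, the dataset-level accuracy rate (fraction of
targets with at least one hit in the top n), and the accuracy order (rank of
the first hit over the number of unique residue pairs, in per mille).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coupling import CouplingScores
from .structures import ContactMap, DistanceMap


@dataclass
class RankedContacts:
    """Ordered unique residue pairs (i <= j) with non-increasing scores."""

    pairs: list  # [(i, j, score), ...]
    length_L: int

    def __post_init__(self):
        seen = set()
        prev = np.inf
        for (i, j, s) in self.pairs:
            if i > j:
                raise ValueError("pairs must be ordered i <= j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair {(i, j)}")
            seen.add((i, j))
            if s > prev + 1e-12:
                raise ValueError("scores must be non-increasing")
            prev = s

    def __len__(self):
        return len(self.pairs)


@dataclass
class EvalReport:
    precision_at: dict = field(default_factory=dict)
    topLK: dict = field(default_factory=dict)
    accuracy_rate_at: dict = field(default_factory=dict)
    accuracy_order: float | None = None


def dca_baseline(couplings: CouplingScores, dmap: DistanceMap,
                 score_type: str = "apc",
                 intra_cutoff: float = 12.0) -> RankedContacts:
    """Coupling-ranked candidate inter-chain contacts.

    Candidates are unique pairs (i <= j) whose intra-monomer minimal
    heavy-atom distance exceeds *intra_cutoff*; masked pairs are excluded.
    """
    if score_type not in {"raw_di", "apc"}:
        raise ValueError("score_type must be 'raw_di' or 'apc'")
    S = couplings.raw if score_type == "raw_di" else couplings.apc
    L = S.shape[0]
    if dmap.values.shape != (L, L):
        raise ValueError("couplings and distance map differ in length")
    iu, ju = np.triu_indices(L)
    keep = (dmap.values[iu, ju] > intra_cutoff) & dmap.mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    scores = S[iu, ju]
    order = np.lexsort((ju, iu, -scores))
    pairs = [(int(iu[k]), int(ju[k]), float(scores[k])) for k in order]
    if not pairs:
        warnings.warn("no candidate pairs survive the intra-monomer filter")
    return RankedContacts(pairs, L)


def _is_true(truth: ContactMap, i: int, j: int) -> bool:
    return bool(truth.values[i, j] or truth.values[j, i])


def precision_at(pred: RankedContacts, truth: ContactMap, n: int) -> float:
    """True positives among the top n, over min(n, list length)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not pred.pairs:
        raise ValueError("empty prediction list")
    top = pred.pairs[:n]
    tp = sum(_is_true(truth, i, j) for (i, j, _) in top)
    return tp / len(top)


def topLK_precision(pred: RankedContacts, truth: ContactMap, K: int) -> float:
    """Precision of the top L/K predictions (n = floor(L/K), at least 1)."""
    n = max(1, pred.length_L // K)
    return precision_at(pred, truth, n)


def accuracy_rate(per_target_preds, n: int) -> float:
    """Fraction of targets with >= 1 correct contact among their top n."""
    if not per_target_preds:
        raise ValueError("no targets")
    hits = 0
    for pred, truth in per_target_preds:
        top = pred.pairs[:n]
        if any(_is_true(truth, i, j) for (i, j, _) in top):
            hits += 1
    return hits / len(per_target_preds)


def accuracy_order(pred: RankedContacts, truth: ContactMap) -> float | None:
    """Rank of the first hit / number of unique pairs, in per mille.

    Returns None when the target has no true contact (undefined).
    """
    if not truth.values.any():
        return None
    total = pred.length_L * (pred.length_L + 1) // 2
    for rank, (i, j, _) in enumerate(pred.pairs, start=1):
        if _is_true(truth, i, j):
            return 1000.0 * rank / total
    return None


def evaluate(pred: RankedContacts, truth: ContactMap,
             ns=(1, 10, 100), Ks=(30, 20, 10, 5, 2)) -> EvalReport:
    report = EvalReport()
    for n in ns:
        report.precision_at[n] = precision_at(pred, truth, n)
    for K in Ks:
        report.topLK[K] = topLK_precision(pred, truth, K)
    report.accuracy_order = accuracy_order(pred, truth)
    return report


def filter_poses(poses_with_maps, top_contact) -> list:
    """Stable promotion of docking poses satisfying the top predicted contact.

    ``poses_with_maps`` is a ranked list of (pose, ContactMap); poses whose
    map contains *top_contact* keep their relative order but move ahead of
    the rest.  The pose set is never reduced; with no satisfying pose the
    original ranking is returned with a warning.
    """
    i, j = top_contact
    satisfying, rest = [], []
    for item in poses_with_maps:
        cmap = item[1]
        if cmap.values[i, j] or cmap.values[j, i]:
            satisfying.append(item)
        else:
            rest.append(item)
    if not satisfying:
        warnings.warn("no pose satisfies the predicted contact; "
                      "original ranking kept")
        return list(poses_with_maps)
    return satisfying + rest
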
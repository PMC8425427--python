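"""Self-contained synthetic inputs: C2 dimers with planted interfaces,
alignments with planted covariation, and bundled mini training sets.

The dimer generator places chain A so that, after the exact 180-degree
rotation about the z axis that produces chain B, precisely the requested
interface pairs fall within 8 A between the chains while every other
inter-chain pair exceeds 10 A (a safety margin that keeps contact tests away
from the cutoff boundary).  Residues carry a CA centre plus three dummy
heavy atoms; no attempt is made at chemically realistic side chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AMINO_ACIDS, BACKGROUND_FREQS, ONE_TO_THREE
from .coupling import compute_couplings
from .dockmap import docking_map
from .model.features import build_features, symmetrize_labels
from .msa import MSA, pssm as build_pssm, sequence_weights
from .secstruct import assign_secondary_structure
from .structures import (ContactMap, DimerStructure, MonomerStructure,
                         Residue, hydrophobicity_features, intra_distance_map,
                         inter_contact_map)

_AXIS_X = 3.5     # planted residues sit this far from the two-fold (z) axis
# Half-offset of an (i, j) planted pair along y.  Chosen so that the two
# members of a pair are > 12 A apart within the monomer (13 A) while the
# inter-chain pair distance stays at 7 A: true inter-chain contacts then
# survive the 12 A intra-monomer candidate filter of the DCA baseline, the
# regime the filter is designed for.
_PAIR_Y = 6.5
_SLOT_DZ = 9.0    # z spacing between planted pairs
_ATOM_OFFSETS = np.array([
    [0.0, 0.0, 0.0],
    [0.25, 0.0, 0.0],
    [0.0, 0.25, 0.0],
    [0.0, 0.0, 0.25],
])
_ATOM_NAMES = ("CA", "CB", "CG", "CD")


@dataclass
class FixtureSpec:
    n_residues: int = 40
    seed: int = 0
    interface_pairs: tuple = ((5, 12),)
    msa_depth: int = 200
    coupling_strength: float = 0.9

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        used = set()
        for (i, j) in self.interface_pairs:
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError("planted pair index out of range")
            if {i, j} & used:
                raise ValueError(
                    "planted pairs must not share residues (geometrically "
                    "inconsistent planting)")
            used |= {i, j}
        if self.msa_depth < 1:
            raise ValueError("msa_depth must be >= 1")
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must be in [0, 1]")


def _sequence(spec: FixtureSpec) -> str:
    rng = np.random.default_rng(spec.seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=spec.n_residues))


def _residue(name3: str, centre: np.ndarray, author: int) -> Residue:
    atoms = [(an, "C", tuple(centre + off), 1.0, "")
             for an, off in zip(_ATOM_NAMES, _ATOM_OFFSETS)]
    return Residue(name3, atoms, True, (author, ""))


def make_c2_dimer(spec: FixtureSpec):
    """Synthetic C2 dimer with an exactly known interface.

    Returns ``(dimer, (rotation, translation))`` where applying the transform
    to chain A reproduces chain B.
    """
    L = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    seq = _sequence(spec)

    centres = np.zeros((L, 3))
    planted = {}
    for p, (i, j) in enumerate(spec.interface_pairs):
        z = p * _SLOT_DZ
        if i == j:
            planted[i] = np.array([_AXIS_X, 0.0, z])
        else:
            planted[i] = np.array([_AXIS_X, _PAIR_Y, z])
            planted[j] = np.array([_AXIS_X, -_PAIR_Y, z])
    # remaining residues: a bounded random walk well away from the axis
    pos = np.array([9.5, 0.0, -4.0])
    lo = np.array([7.5, -6.0, -10.0])
    hi = np.array([13.0, 6.0, 4.0])
    for k in range(L):
        if k in planted:
            centres[k] = planted[k]
            continue
        step = rng.normal(0, 1.6, size=3)
        pos = np.clip(pos + step, lo, hi)
        centres[k] = pos

    residues_a = [_residue(ONE_TO_THREE[seq[k]], centres[k], k + 1)
                  for k in range(L)]
    chain_a = MonomerStructure("A", residues_a)
    rotation = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about z
    translation = np.zeros(3)
    chain_b = chain_a.transformed(rotation, translation, chain_id="B")
    dimer = DimerStructure(chain_a, chain_b)

    expected = set()
    for (i, j) in spec.interface_pairs:
        expected.add((i, j))
        expected.add((j, i))
    got = set(zip(*np.nonzero(inter_contact_map(dimer).values)))
    if {(int(a), int(b)) for (a, b) in got} != expected:
        raise RuntimeError("fixture generation failed to plant the interface")
    return dimer, (rotation, translation)


_COMPAT_COUPLES = [("E", "K"), ("K", "E"), ("D", "R"), ("R", "D"), ("L", "I")]


def make_synthetic_msa(spec: FixtureSpec) -> MSA:
    """Query plus M-1 background rows, with covariation planted at the
    interface pairs: with probability ``coupling_strength`` the two columns
    of a pair are drawn jointly from a fixed compatible amino-acid couple."""
    rng = np.random.default_rng(spec.seed + 7919)
    L, M = spec.n_residues, spec.msa_depth
    query = _sequence(spec)
    aa = np.array(list(AMINO_ACIDS))
    rows = [query]
    pairs = [(i, j) for (i, j) in spec.interface_pairs if i != j]
    for _ in range(M - 1):
        row = rng.choice(aa, size=L, p=BACKGROUND_FREQS)
        for (i, j) in pairs:
            if rng.random() < spec.coupling_strength:
                a, b = _COMPAT_COUPLES[rng.integers(len(_COMPAT_COUPLES))]
                row[i], row[j] = a, b
        rows.append("".join(row))
    return MSA(rows)


def target_features(spec: FixtureSpec, dock_interval: float = 30.0,
                    dock_top_t: int = 30):
    """Full feature pipeline on one synthetic target.

    Returns ``(bundle, labels, dimer, msa)``.  The docking map uses coarse
    desk-scale sampling by default; pass ``dock_interval=6.0, dock_top_t=100``
    for the dense setting.
    """
    dimer, _ = make_c2_dimer(spec)
    msa = make_synthetic_msa(spec)
    weights = sequence_weights(msa)
    couplings = compute_couplings(msa, weights)
    m = dimer.chain_a
    bundle = build_features(
        m,
        build_pssm(msa, weights),
        assign_secondary_structure(m),
        hydrophobicity_features(m),
        intra_distance_map(m),
        docking_map(m, interval=dock_interval, top_t=dock_top_t),
        couplings,
    )
    raw = inter_contact_map(dimer)
    labels = ContactMap(symmetrize_labels(raw.values), raw.mask)
    return bundle, labels, dimer, msa


def _is_validation(index: int) -> bool:
    return (index * 2654435761) % (2**32) % 5 == 0


def make_training_set(n_targets: int, seed: int = 0, n_residues: int = 40,
                      msa_depth: int = 120, n_pairs: int = 3,
                      coupling_strength: float = 0.9,
                      dock_interval: float = 30.0, dock_top_t: int = 30):
    """Deterministic mini-dataset of (FeatureBundle, ContactMap) pairs.

    Targets are split into train/validation by a fixed hash of the target
    index (roughly 1 in 5 goes to validation).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    train, val = [], []
    for t in range(n_targets):
        rng = np.random.default_rng(seed * 100003 + t)
        pairs = []
        used = set()
        while len(pairs) < n_pairs:
            i, j = sorted(rng.integers(0, n_residues, size=2))
            if i != j and not ({i, j} & used):
                pairs.append((int(i), int(j)))
                used |= {i, j}
        spec = FixtureSpec(n_residues=n_residues,
                           seed=int(seed * 100003 + t),
                           interface_pairs=tuple(pairs),
                           msa_depth=msa_depth,
                           coupling_strength=coupling_strength)
        bundle, labels, _, _ = target_features(spec, dock_interval, dock_top_t)
        (val if _is_validation(t) else train).append((bundle, labels))
    if not val and len(train) > 1:
        val.append(train.pop())
    if not train:
        train, val = val, train
    return train, val


# ---------------------------------------------------------------------------
# analytic poly-alanine helix (for the secondary-structure assigner)
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d given three predecessors and internal coordinates."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(dih),
                   bond * np.sin(ang) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_ideal_helix(n_residues: int = 20, phi: float = -57.0,
                      psi: float = -47.0) -> MonomerStructure:
    """Poly-alanine chain with fixed backbone dihedrals (default: alpha helix)."""
    omega = 180.0
    coords = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([1.458, 0.0, 0.0])
    ang = np.radians(111.2)
    coords[(0, "C")] = coords[(0, "CA")] + 1.525 * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_residues):
        N, CA, C = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        if i < n_residues - 1:
            Nn = _nerf(N, CA, C, 1.329, 116.2, psi)
            CAn = _nerf(CA, C, Nn, 1.458, 121.7, omega)
            Cn = _nerf(C, Nn, CAn, 1.525, 111.2, phi)
            coords[(i + 1, "N")], coords[(i + 1, "CA")], coords[(i + 1, "C")] = Nn, CAn, Cn
            coords[(i, "O")] = _nerf(Nn, CA, C, 1.231, 120.8, 180.0)
        else:
            coords[(i, "O")] = _nerf(N, CA, C, 1.231, 120.8, psi + 180.0)
    residues = []
    for i in range(n_residues):
        atoms = [(name, "O" if name == "O" else ("N" if name == "N" else "C"),
                  tuple(coords[(i, name)]), 1.0, "")
                 for name in ("N", "CA", "C", "O")]
        residues.append(Residue("ALA", atoms, True, (i + 1, "")))
    return MonomerStructure("A", residues)
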
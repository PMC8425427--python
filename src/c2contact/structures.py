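"""Monomer/dimer structure handling and structure-derived features.

Parses single protein chains from PDB/mmCIF (via biotite), keeps unobserved
residues as explicit placeholders so that indices always run 0..L-1 over the
full chain, and computes minimal heavy-atom distance maps, inter-chain contact
maps, solvent-accessible surface areas, buried interface areas, hydrophobicity
channels and the per-record dataset filter predicates.

Conventions
-----------
* residue indices are 0-based and contiguous; file output uses author numbering
* "heavy atom" = any non-hydrogen atom of the residue, side chains included
* contacts use an inclusive cutoff: min heavy-atom distance <= cutoff
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as bt_pdb
from biotite.structure.io import pdbx as bt_pdbx
from scipy.spatial.distance import cdist

from .constants import THREE_TO_ONE, UNKNOWN, WIMLEY_WHITE, vdw_radius

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_HYDROGEN = {"H", "D"}


@dataclass
class Residue:
    """One residue: 3-letter name, heavy atoms, and an observed flag.

    ``atoms`` holds tuples ``(atom_name, element, xyz, occupancy, altloc)``;
    hydrogens are never stored.  ``observed`` is False for residues that are
    part of the chain but have no resolved coordinates.
    """

    name: str
    atoms: list = field(default_factory=list)
    observed: bool = True
    author_id: tuple = (0, "")  # (residue number, insertion code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), UNKNOWN)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) heavy-atom coordinates."""
        if not self.observed or not self.atoms:
            raise ValueError(f"residue {self.name}{self.author_id} has no coordinates")
        return np.asarray([a[2] for a in self.atoms], dtype=float)

    def atom_coord(self, name: str):
        for a in self.atoms:
            if a[0] == name:
                return np.asarray(a[2], dtype=float)
        return None


@dataclass
class MonomerStructure:
    """A single protein chain with 0-based contiguous residue indexing."""

    chain_id: str
    residues: list

    def __post_init__(self):
        for r in self.residues:
            if r.observed and not r.atoms:
                raise ValueError("observed residue without heavy atoms")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def author_numbering(self) -> list:
        return [r.author_id for r in self.residues]

    @property
    def observed_mask(self) -> np.ndarray:
        return np.asarray([r.observed for r in self.residues], dtype=bool)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None) -> "MonomerStructure":
        """Rigidly transformed copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            atoms = [(n, e, tuple(R @ np.asarray(xyz) + t), occ, al)
                     for (n, e, xyz, occ, al) in r.atoms]
            new_res.append(Residue(r.name, atoms, r.observed, r.author_id))
        return MonomerStructure(chain_id or self.chain_id, new_res)

    def to_atom_array(self) -> struc.AtomArray:
        """Observed heavy atoms as a biotite AtomArray (res_id = index + 1)."""
        n = sum(len(r.atoms) for r in self.residues if r.observed)
        arr = struc.AtomArray(n)
        k = 0
        for i, r in enumerate(self.residues):
            if not r.observed:
                continue
            for (name, element, xyz, occ, altloc) in r.atoms:
                arr.coord[k] = xyz
                arr.chain_id[k] = self.chain_id[:4] if self.chain_id else "A"
                arr.res_id[k] = i + 1
                arr.res_name[k] = r.name
                arr.atom_name[k] = name
                arr.element[k] = element
                arr.hetero[k] = False
                k += 1
        return arr

    def heavy_coords(self):
        """All heavy-atom coordinates plus the residue index of each atom."""
        coords, res_idx = [], []
        for i, r in enumerate(self.residues):
            if not r.observed:
                continue
            c = r.coords()
            coords.append(c)
            res_idx.append(np.full(len(c), i, dtype=int))
        if not coords:
            raise ValueError("structure has no observed residues")
        return np.concatenate(coords), np.concatenate(res_idx)


@dataclass
class DimerStructure:
    """Two copies of (nearly) the same chain; indices correspond 1:1."""

    chain_a: MonomerStructure
    chain_b: MonomerStructure
    residue_correspondence: dict = None

    def __post_init__(self):
        if self.residue_correspondence is None:
            if len(self.chain_a) != len(self.chain_b):
                raise ValueError(
                    "chains differ in length; supply residue_correspondence")
            self.residue_correspondence = {i: i for i in range(len(self.chain_a))}
        if not self.residue_correspondence:
            raise ValueError("empty residue correspondence")
        mism = sum(
            1 for i, j in self.residue_correspondence.items()
            if self.chain_a.residues[i].observed and self.chain_b.residues[j].observed
            and self.chain_a.residues[i].one_letter != self.chain_b.residues[j].one_letter
        )
        if mism > 0.01 * len(self.residue_correspondence):
            raise ValueError("chains are not a homodimer (sequence mismatch > 1%)")


@dataclass
class DistanceMap:
    values: np.ndarray  # (L, L) minimal heavy-atom distances, Angstrom
    mask: np.ndarray    # (L, L) True where both residues observed


@dataclass
class ContactMap:
    values: np.ndarray  # (L, L) binary
    mask: np.ndarray


@dataclass
class StructureRecord:
    """Curation metadata of one candidate dimer entry."""

    resolution: float
    n_chains: int
    chain_length: int
    chain_identity: float
    symmetry_label: str
    interface_area: float


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _load_atom_array(path: str) -> struc.AtomArray:
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in {".cif", ".mmcif", ".pdbx"}:
            f = bt_pdbx.CIFFile.read(path)
            arr = bt_pdbx.get_structure(f, model=1, altloc="occupancy",
                                        extra_fields=["occupancy"])
        else:
            f = bt_pdb.PDBFile.read(path)
            arr = f.get_structure(model=1, altloc="occupancy",
                                  extra_fields=["occupancy"])
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"could not parse structure file {path!r}: {exc}") from exc
    return arr


def parse_structure(path: str, chain: str) -> MonomerStructure:
    """Parse one chain from a PDB or mmCIF file.

    Hydrogens and waters are dropped, altloc duplicates are resolved to the
    highest-occupancy copy (ties to altloc 'A', handled by biotite), and gaps
    in the author numbering become unobserved placeholder residues so that
    internal indices stay aligned with the full chain.
    """
    arr = _load_atom_array(path)
    chains = sorted(set(arr.chain_id))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    arr = arr[arr.chain_id == chain]
    elements = np.char.upper(arr.element)
    keep = ~np.isin(elements, list(_HYDROGEN))
    keep &= ~np.isin(arr.res_name, list(_WATER_NAMES))
    keep &= struc.filter_amino_acids(arr)
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ValueError(f"chain {chain!r} has no protein heavy atoms")

    has_occ = "occupancy" in arr.get_annotation_categories()
    residues: list[Residue] = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    prev_num = None
    for s, e in zip(starts[:-1], starts[1:]):
        num = int(arr.res_id[s])
        icode = ""
        if "ins_code" in arr.get_annotation_categories():
            icode = str(arr.ins_code[s])
        if prev_num is not None and num > prev_num + 1:
            # numbering gap: keep placeholders so L matches the full chain
            for missing in range(prev_num + 1, num):
                residues.append(Residue("UNK", [], observed=False,
                                        author_id=(missing, "")))
        prev_num = num
        atoms = []
        for k in range(s, e):
            occ = float(arr.occupancy[k]) if has_occ else 1.0
            atoms.append((str(arr.atom_name[k]), str(arr.element[k]),
                          tuple(float(x) for x in arr.coord[k]), occ, ""))
        residues.append(Residue(str(arr.res_name[s]), atoms, True, (num, icode)))
    return MonomerStructure(chain, residues)


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum over all heavy-atom pairs of the Euclidean distance (Angstrom)."""
    if not (res_a.observed and res_b.observed):
        raise ValueError("distance undefined: residue has no observed coordinates")
    return float(cdist(res_a.coords(), res_b.coords()).min())


def _blockwise_min(dist: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                   la: int, lb: int) -> np.ndarray:
    """Reduce an atom-atom distance matrix to a residue-residue minimum map."""
    out = np.full((la, lb), np.inf)
    np.minimum.at(out, (idx_a[:, None], idx_b[None, :]), dist)
    return out


def intra_distance_map(m: MonomerStructure) -> DistanceMap:
    """L x L map of minimal heavy-atom distances within one monomer."""
    L = len(m)
    obs = m.observed_mask
    values = np.zeros((L, L))
    mask = np.outer(obs, obs)
    if obs.any():
        coords, res_idx = m.heavy_coords()
        d = cdist(coords, coords)
        full = _blockwise_min(d, res_idx, res_idx, L, L)
        values[mask] = full[mask]
    return DistanceMap(values, mask)


def inter_distance_map(d: DimerStructure) -> DistanceMap:
    """Minimal heavy-atom distance of residue i (chain A) vs residue j (chain B)."""
    a, b = d.chain_a, d.chain_b
    La, Lb = len(a), len(b)
    values = np.zeros((La, Lb))
    mask = np.outer(a.observed_mask, b.observed_mask)
    if mask.any():
        ca, ia = a.heavy_coords()
        cb, ib = b.heavy_coords()
        dist = cdist(ca, cb)
        full = _blockwise_min(dist, ia, ib, La, Lb)
        values[mask] = full[mask]
    return DistanceMap(values, mask)


def inter_contact_map(d: DimerStructure, cutoff: float = 8.0) -> ContactMap:
    """Binary inter-chain contact map: any heavy-atom pair within *cutoff*."""
    dm = inter_distance_map(d)
    values = ((dm.values <= cutoff) & dm.mask).astype(np.uint8)
    return ContactMap(values, dm.mask)


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def _sasa_atom_array(arr: struc.AtomArray, probe_radius: float,
                     n_points: int) -> np.ndarray:
    radii = np.array([vdw_radius(e) for e in arr.element])
    vals = struc.sasa(arr, probe_radius=probe_radius, point_number=n_points,
                      vdw_radii=radii)
    return np.nan_to_num(vals, nan=0.0)


def sasa(m: MonomerStructure, algorithm: str = "shrake_rupley",
         probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-residue absolute solvent-accessible surface area (Angstrom^2).

    Uses Shrake-Rupley point sampling (surface approximated by a deterministic
    point set on each atom sphere).  Unobserved residues get area 0.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if algorithm != "shrake_rupley":
        raise NotImplementedError(
            "only the Shrake-Rupley point-sampling algorithm is implemented")
    arr = m.to_atom_array()
    atom_sasa = _sasa_atom_array(arr, probe_radius, n_points)
    out = np.zeros(len(m))
    np.add.at(out, arr.res_id - 1, atom_sasa)
    return out


def interface_area(d: DimerStructure, probe_radius: float = 1.4,
                   n_points: int = 960) -> float:
    """Buried interface area: (SASA(A) + SASA(B) - SASA(AB)) / 2."""
    arr_a = d.chain_a.to_atom_array()
    arr_b = d.chain_b.to_atom_array()
    arr_b.chain_id[:] = "ZB"  # keep chains distinct in the merged array
    sasa_a = _sasa_atom_array(arr_a, probe_radius, n_points).sum()
    sasa_b = _sasa_atom_array(arr_b, probe_radius, n_points).sum()
    merged = arr_a + arr_b
    sasa_ab = _sasa_atom_array(merged, probe_radius, n_points).sum()
    return float((sasa_a + sasa_b - sasa_ab) / 2.0)


# ---------------------------------------------------------------------------
# hydrophobicity channels
# ---------------------------------------------------------------------------

def hydrophobicity_features(m: MonomerStructure, n_points: int = 960) -> np.ndarray:
    """L x 3 hydrophobicity channels.

    Channel 1: Shrake-Rupley per-residue SASA; channel 2: duplicate of
    channel 1 (a slice-based Lee-Richards area is not implemented); channel 3:
    Wimley-White whole-residue scale value.
    """
    sr = sasa(m, n_points=n_points)
    ww = np.zeros(len(m))
    for i, r in enumerate(m.residues):
        aa = r.one_letter
        if aa in WIMLEY_WHITE:
            ww[i] = WIMLEY_WHITE[aa]
        else:
            warnings.warn(f"unknown residue type {r.name!r}; hydrophobicity set to 0")
    return np.stack([sr, sr, ww], axis=1)


# ---------------------------------------------------------------------------
# dataset filter predicates
# ---------------------------------------------------------------------------

def passes_dataset_filters(r: StructureRecord, min_len: int = 50,
                           max_len: int = 500, max_resolution: float = 3.0,
                           min_identity: float = 0.99,
                           min_interface: float = 1000.0):
    """Apply the per-record curation predicates of the C2 homodimer set.

    Returns ``(passed, failed_rules)`` where *failed_rules* names every rule
    the record violates (empty when it passes).  All comparisons are strict
    where the selection criteria are phrased strictly ("better than 3.0 A",
    "more than 99%", "more than 1000 A^2").
    """
    failed = []
    if r.symmetry_label != "C2":
        failed.append("symmetry")
    if r.n_chains != 2:
        failed.append("n_chains")
    if not (r.resolution < max_resolution):
        failed.append("resolution")
    if not (min_len <= r.chain_length <= max_len):
        failed.append("chain_length")
    if not (r.chain_identity > min_identity):
        failed.append("chain_identity")
    if not (r.interface_area > min_interface):
        failed.append("interface_area")
    return (len(failed) == 0, failed)


# ---------------------------------------------------------------------------
# simple writers
# ---------------------------------------------------------------------------

def write_matrix(path: str, values: np.ndarray) -> None:
    """Whitespace-delimited matrix file (CCMpred-style layout)."""
    np.savetxt(path, np.asarray(values), fmt="%.6g")


def write_pdb(path: str, *monomers: MonomerStructure) -> None:
    """Write one or more chains as a PDB file (1-based residue numbering)."""
    arrays = []
    for m in monomers:
        arr = m.to_atom_array()
        arr.chain_id[:] = m.chain_id[:1] or "A"
        arrays.append(arr)
    merged = arrays[0]
    for arr in arrays[1:]:
        merged = merged + arr
    f = bt_pdb.PDBFile()
    f.set_structure(merged)
    f.write(path)
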
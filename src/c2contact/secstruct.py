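"""Eight-state secondary structure: DSSP file ingestion and an internal assigner.

The internal assigner follows the Kabsch-Sander recipe: an electrostatic
backbone hydrogen-bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond called at E < -0.5 kcal/mol, the amide H placed 1.0 A from N along
the C=O direction of the preceding residue.  States are assigned with the
usual priorities (H > E/B > G > I > T > S > '-').  Exact parity with the DSSP
program is not promised; reading a DSSP output file is the fidelity path.
"""

from __future__ import annotations

import numpy as np

from .structures import MonomerStructure

SS8_ALPHABET = "HBEGITS-"
_HB_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0


def one_hot_ss(labels) -> np.ndarray:
    """L x 8 one-hot encoding in the fixed order ``HBEGITS-``."""
    out = np.zeros((len(labels), 8))
    for i, s in enumerate(labels):
        j = SS8_ALPHABET.find(s)
        out[i, j if j >= 0 else 7] = 1.0
    return out


def parse_dssp_file(path: str, chain: str | None = None) -> list:
    """Per-residue 8-state labels from a DSSP output file.

    Chain breaks ('!' rows) are skipped; a blank structure column means coil.
    """
    labels = []
    with open(path) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            if chain is not None and line[11].strip() and line[11] != chain:
                continue
            ss = line[16]
            labels.append(ss if ss in SS8_ALPHABET and ss != " " else "-")
    if not labels:
        raise ValueError(f"no residue rows parsed from DSSP file {path!r}")
    return labels


def _backbone(m: MonomerStructure):
    """(L, 4, 3) N/CA/C/O coordinates with a per-residue completeness flag."""
    L = len(m)
    xyz = np.full((L, 4, 3), np.nan)
    ok = np.zeros(L, dtype=bool)
    for i, r in enumerate(m.residues):
        if not r.observed:
            continue
        coords = [r.atom_coord(n) for n in ("N", "CA", "C", "O")]
        if all(c is not None for c in coords):
            xyz[i] = np.stack(coords)
            ok[i] = True
    return xyz, ok


def _hbond_matrix(xyz: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """hb[i, j] True iff the C=O of residue i accepts the N-H of residue j."""
    L = len(ok)
    hb = np.zeros((L, L), dtype=bool)
    # amide H of residue j from the previous residue's C=O
    h_pos = np.full((L, 3), np.nan)
    for j in range(1, L):
        if ok[j] and ok[j - 1]:
            c_prev, o_prev = xyz[j - 1, 2], xyz[j - 1, 3]
            co = c_prev - o_prev
            nrm = np.linalg.norm(co)
            if nrm > 1e-9:
                h_pos[j] = xyz[j, 0] + co / nrm
    for i in range(L):
        if not ok[i]:
            continue
        C, O = xyz[i, 2], xyz[i, 3]
        for j in range(L):
            if abs(i - j) < 2 or not ok[j] or np.isnan(h_pos[j, 0]):
                continue
            N = xyz[j, 0]
            H = h_pos[j]
            r_on = np.linalg.norm(O - N)
            if r_on > 7.0:  # Kabsch-Sander distance pre-filter
                continue
            r_ch = np.linalg.norm(C - H)
            r_oh = np.linalg.norm(O - H)
            r_cn = np.linalg.norm(C - N)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            hb[i, j] = e < _HB_CUTOFF
    return hb


def assign_secondary_structure(m: MonomerStructure) -> list:
    """Internal 8-state assignment; residues lacking backbone atoms get '-'."""
    L = len(m)
    xyz, ok = _backbone(m)
    labels = ["-"] * L
    if not ok.any():
        return labels
    hb = _hbond_matrix(xyz, ok)

    turn = {n: np.zeros(L, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(L - n):
            if hb[i, i + n]:
                turn[n][i] = True

    # helices: two consecutive n-turns starting at i-1 and i
    def _mark_helix(n, symbol):
        for i in range(1, L - n):
            if turn[n][i - 1] and turn[n][i]:
                for k in range(i, i + n):
                    if labels[k] == "-" or (symbol == "H" and labels[k] in "GIT"):
                        labels[k] = symbol

    _mark_helix(4, "H")

    # bridges / strands
    bridge = np.zeros((L, L), dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    partners = bridge.any(axis=1)
    for i in range(L):
        if not partners[i] or labels[i] == "H":
            continue
        extended = False
        for j in np.nonzero(bridge[i])[0]:
            if (i > 0 and j + 1 < L and bridge[i - 1, j + 1]) or \
               (i + 1 < L and j > 0 and bridge[i + 1, j - 1]) or \
               (i > 0 and j > 0 and bridge[i - 1, j - 1]) or \
               (i + 1 < L and j + 1 < L and bridge[i + 1, j + 1]):
                extended = True
        labels[i] = "E" if extended else "B"

    _mark_helix(3, "G")
    _mark_helix(5, "I")

    # turns: interior of any n-turn
    for n in (3, 4, 5):
        for i in np.nonzero(turn[n])[0]:
            for k in range(i + 1, min(i + n, L)):
                if labels[k] == "-":
                    labels[k] = "T"

    # bends from the CA pseudo-angle
    for i in range(2, L - 2):
        if labels[i] != "-" or not (ok[i - 2] and ok[i] and ok[i + 2]):
            continue
        u = xyz[i, 1] - xyz[i - 2, 1]
        v = xyz[i + 2, 1] - xyz[i, 1]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            labels[i] = "S"
    return labels


def secondary_structure(m: MonomerStructure, source: str = "internal",
                        dssp_path: str | None = None) -> list:
    """Per-residue 8-state labels, from a DSSP file or the internal assigner."""
    if source == "internal":
        return assign_secondary_structure(m)
    if source == "dssp_file":
        labels = parse_dssp_file(dssp_path, chain=m.chain_id[:1])
        if len(labels) != len(m):
            raise ValueError(
                f"DSSP file has {len(labels)} residues but chain has {len(m)}")
        return labels
    raise ValueError(f"unknown secondary-structure source {source!r}")
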
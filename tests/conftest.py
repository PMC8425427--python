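"""Shared fixtures: hand-built PDB text, small synthetic targets."""

from __future__ import annotations

import numpy as np
import pytest

from c2contact.fixtures import FixtureSpec, make_c2_dimer


def pdb_line(serial, name, resname, resseq, xyz, occ=1.0, altloc=" ",
             chain="A", element=None):
    """One fixed-column ATOM record."""
    element = element or name[0]
    return (f"ATOM  {serial:>5d} {name:<4s}{altloc}{resname:>3s} "
            f"{chain}{resseq:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture
def write_pdb_text(tmp_path):
    def _write(lines, name="test.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines + ["END"]) + "\n")
        return str(path)
    return _write


@pytest.fixture(scope="session")
def small_dimer():
    """30-residue C2 dimer with two planted interface pairs."""
    spec = FixtureSpec(n_residues=30, seed=11,
                       interface_pairs=((3, 10), (15, 22)), msa_depth=150)
    dimer, transform = make_c2_dimer(spec)
    return spec, dimer, transform


def brute_force_sasa(coords, radii, probe=1.4, n_points=4000):
    """Independent Shrake-Rupley oracle: golden-spiral point sampling."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    k = np.arange(n_points)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1 - z**2, 0))
    sphere = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    areas = np.zeros(len(coords))
    ext = radii + probe
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            free &= d2 > ext[j] ** 2
        areas[i] = 4 * np.pi * ext[i] ** 2 * free.mean()
    return areas
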
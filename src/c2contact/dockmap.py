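"""Docking-map channel: C2-constrained FFT shape-complementarity scanning.

A C2 homodimer pose is fully determined by a two-fold axis and a translation
perpendicular to it: the second copy is the 180-degree rotation of the first
about that axis, shifted.  Candidate poses are enumerated by sampling axes
quasi-uniformly on the hemisphere (deterministic spherical Fibonacci lattice)
and, per axis, scanning all lattice translations of the rotated copy against
the fixed copy with an FFT correlation of surface/core grids:

    score(t) = corr(surface_A, surface_B)(t) - penalty * corr(core_A, core_B)(t)

The top translations per rotation are kept, each pose is converted to an
inter-chain contact map, and the union over all poses is the docking map fed
to the contact network as a 2D prior channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage
from scipy.spatial.distance import cdist

from .structures import ContactMap, MonomerStructure

_ATOM_RADIUS = 1.8  # Angstrom, rasterization radius of a heavy atom


@dataclass
class DockPose:
    rotation: np.ndarray     # (3, 3) orthonormal, det +1 (a 180-degree rotation)
    translation: np.ndarray  # Angstrom
    score: float
    axis: np.ndarray | None = None  # two-fold axis for C2 poses


@dataclass
class DockingMap:
    values: np.ndarray  # (L, L) binary union of per-pose contact maps
    n_poses: int


@dataclass
class Grid:
    """Cubic occupancy grid with mutually exclusive surface/core labels."""

    spacing: float
    origin: np.ndarray
    core: np.ndarray     # bool
    surface: np.ndarray  # bool

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if (self.core & self.surface).any():
            raise ValueError("core and surface labels must be exclusive")


def _ball_footprint(radius_cells: float) -> np.ndarray:
    r = max(int(np.floor(radius_cells)), 0)
    if r == 0:
        return np.ones((1, 1, 1), dtype=bool)
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius_cells**2


def rotation_about_axis(axis: np.ndarray, angle: float = np.pi) -> np.ndarray:
    """Rotation matrix; for angle=pi this is 2*a*a^T - I (an involution)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _van_der_corput(k: int) -> float:
    v, denom = 0.0, 1.0
    while k:
        denom *= 2.0
        v += (k & 1) / denom
        k >>= 1
    return v


def sample_rotation_axes(angle_interval_deg: float = 6.0) -> np.ndarray:
    """Quasi-uniform two-fold axes on the upper hemisphere.

    Axes are the prefix of a fixed low-discrepancy sequence (van der Corput
    height, golden-angle azimuth), so a finer interval yields a strict
    superset of the coarser axis set and the docking map is monotone in the
    rotation count.  The count scales as (solid angle) / interval^2: halving
    the interval roughly quadruples it.  Axes a and -a give the same
    180-degree rotation, hence only the hemisphere is sampled; chain swap
    maps each rotation to its own inverse, so no two sampled rotations are
    equivalent under the C2 quotient.
    """
    if not (0 < angle_interval_deg <= 90):
        raise ValueError("angle interval must be in (0, 90] degrees")
    theta = np.radians(angle_interval_deg)
    n = max(1, int(np.ceil(2 * np.pi / theta**2)))
    k = np.arange(n)
    z = np.array([_van_der_corput(i + 1) for i in k])
    phi = k * np.pi * (3 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(1 - z**2, 0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sample_rotations(angle_interval_deg: float = 6.0) -> list:
    """180-degree rotation matrices for the sampled two-fold axes."""
    return [rotation_about_axis(a) for a in sample_rotation_axes(angle_interval_deg)]


def _rasterize(coords: np.ndarray, spacing: float, surface_thickness: float):
    pad = _ATOM_RADIUS + surface_thickness + spacing
    origin = coords.min(axis=0) - pad
    extent = coords.max(axis=0) + pad - origin
    shape = np.ceil(extent / spacing).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    idx = np.floor((coords - origin) / spacing).astype(int)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    core = ndimage.binary_dilation(occ, structure=_ball_footprint(_ATOM_RADIUS / spacing))
    shell = ndimage.binary_dilation(
        core, structure=_ball_footprint(surface_thickness / spacing + 1))
    surface = shell & ~core
    return Grid(spacing, origin, core, surface)


def grid_project(m: MonomerStructure, spacing: float = 1.2,
                 surface_thickness: float = 1.5) -> Grid:
    """Discretize a monomer onto a cubic grid with core and surface labels."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords, _ = m.heavy_coords()
    return _rasterize(coords, spacing, surface_thickness)


def _corr_scores(grid_a: Grid, grid_b: Grid, core_penalty: float):
    """Circular FFT correlation scores over all lattice shifts of grid B."""
    shape = tuple(
        scipy.fft.next_fast_len(na + nb)
        for na, nb in zip(grid_a.core.shape, grid_b.core.shape))
    fa_s = scipy.fft.rfftn(grid_a.surface.astype(float), shape)
    fa_c = scipy.fft.rfftn(grid_a.core.astype(float), shape)
    fb_s = scipy.fft.rfftn(grid_b.surface.astype(float), shape)
    fb_c = scipy.fft.rfftn(grid_b.core.astype(float), shape)
    spec = fa_s * np.conj(fb_s) - core_penalty * fa_c * np.conj(fb_c)
    return scipy.fft.irfftn(spec, shape)


def fft_translation_scan(grid_a: Grid, grid_b: Grid, top_t: int = 100,
                         core_penalty: float = 15.0,
                         rotation: np.ndarray | None = None,
                         axis: np.ndarray | None = None) -> list:
    """Top lattice translations of grid B against grid A by FFT correlation.

    Ties are broken lexicographically by the signed (z, y, x) lattice offset.
    The returned translations are in Angstrom and already account for the two
    grid origins.
    """
    if top_t < 1:
        raise ValueError("top_t must be >= 1")
    if abs(grid_a.spacing - grid_b.spacing) > 1e-9:
        raise ValueError("grids must share the same spacing")
    scores = _corr_scores(grid_a, grid_b, core_penalty)
    shape = scores.shape
    flat = scores.ravel()
    k = min(top_t, flat.size)
    thresh = np.partition(flat, flat.size - k)[flat.size - k]
    cand = np.nonzero(flat >= thresh)[0]
    tz, ty, tx = np.unravel_index(cand, shape)
    offs = np.stack([tz, ty, tx], axis=1).astype(int)
    for d in range(3):
        offs[:, d] = np.where(offs[:, d] >= shape[d] // 2,
                              offs[:, d] - shape[d], offs[:, d])
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], -flat[cand]))
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    base = grid_a.origin - grid_b.origin
    poses = []
    for idx in order[:top_t]:
        t = base + offs[idx] * grid_a.spacing
        poses.append(DockPose(R, t, float(flat[cand[idx]]), axis=axis))
    return poses


def _residue_starts(m: MonomerStructure):
    coords, res_idx = m.heavy_coords()
    # boundaries of contiguous residue blocks in atom order
    starts = np.concatenate([[0], np.nonzero(np.diff(res_idx))[0] + 1])
    return coords, res_idx, starts


def _pairwise_min_map(coords_a, res_idx_a, starts_a, coords_b, res_idx_b,
                      starts_b, L):
    d = cdist(coords_a, coords_b)
    red = np.minimum.reduceat(d, starts_a, axis=0)
    red = np.minimum.reduceat(red, starts_b, axis=1)
    out = np.full((L, L), np.inf)
    ia = res_idx_a[starts_a]
    ib = res_idx_b[starts_b]
    out[np.ix_(ia, ib)] = red
    return out


def pose_contact_map(m: MonomerStructure, pose: DockPose,
                     cutoff: float = 8.0) -> ContactMap:
    """Inter-chain contacts of the dimer implied by one docking pose.

    The map is OR-symmetrized, matching the symmetry of an ideal C2 complex.
    """
    L = len(m)
    coords, res_idx, starts = _residue_starts(m)
    bc = coords @ np.asarray(pose.rotation, float).T + np.asarray(pose.translation, float)
    dmin = _pairwise_min_map(coords, res_idx, starts, bc, res_idx, starts, L)
    values = (dmin <= cutoff).astype(np.uint8)
    values = np.maximum(values, values.T)
    obs = m.observed_mask
    return ContactMap(values, np.outer(obs, obs))


def project_c2_translation(t: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Remove the axis-parallel component so the pose is exactly two-fold."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    t = np.asarray(t, float)
    return t - np.dot(t, a) * a


def docking_map(m: MonomerStructure, interval: float = 6.0, top_t: int = 100,
                cutoff: float = 8.0, spacing: float = 1.2,
                surface_thickness: float = 1.5, core_penalty: float = 15.0,
                enforce_c2: bool = True) -> DockingMap:
    """Union of contact maps over all sampled C2 poses.

    The union is order-independent and monotone in both the number of
    rotations and ``top_t``.
    """
    L = len(m)
    coords, res_idx, starts = _residue_starts(m)
    grid_a = _rasterize(coords, spacing, surface_thickness)
    union = np.zeros((L, L), dtype=np.uint8)
    n_poses = 0
    for a in sample_rotation_axes(interval):
        R = rotation_about_axis(a)
        rot_coords = coords @ R.T
        grid_b = _rasterize(rot_coords, spacing, surface_thickness)
        poses = fft_translation_scan(grid_a, grid_b, top_t=top_t,
                                     core_penalty=core_penalty,
                                     rotation=R, axis=a)
        for pose in poses:
            t = pose.translation
            if enforce_c2:
                t = project_c2_translation(t, a)
            bc = rot_coords + t
            dmin = _pairwise_min_map(coords, res_idx, starts, bc, res_idx,
                                     starts, L)
            contact = dmin <= cutoff
            union |= (contact | contact.T).astype(np.uint8)
            n_poses += 1
    obs = m.observed_mask
    union &= np.outer(obs, obs).astype(np.uint8)
    return DockingMap(union, n_poses)
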
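"""Rigid-body superposition and pairwise structural metrics (RMSD, DRMS).

RMSD between two conformations is evaluated after least-squares (Kabsch)
superposition by default, matching the usual treatment of trajectory
snapshots; DRMS compares intramolecular distance sets and needs no
superposition at all, which makes it exactly invariant under rigid
transforms of either input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryWarning, DimensionError, InsufficientDataError
from .structure_io import Ensemble, SiteSet, check_labels, swap_chains, swap_vector


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, in nm."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)


@dataclass
class PairwiseMatrix:
    """Symmetric M x M matrix of a frame-pair metric (nm)."""

    values: np.ndarray
    metric: str  # "rmsd" | "drms"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("pairwise matrix must be square")
        self.values = v


def _as_xyz(a) -> np.ndarray:
    if isinstance(a, SiteSet):
        return a.xyz
    a = np.asarray(a, float)
    if a.ndim == 1:
        a = a.reshape(-1, 3)
    return a


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, SiteSet) and isinstance(b, SiteSet):
        check_labels(a.labels, b.labels)
    xa, xb = _as_xyz(a), _as_xyz(b)
    if xa.shape != xb.shape:
        raise DimensionError(f"coordinate shapes differ: {xa.shape} vs {xb.shape}")
    return xa, xb


def kabsch_superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the coordinate RMSD and
    that minimal RMSD (nm). Reflections are never returned. Rank-deficient
    (collinear) site sets yield a valid but non-unique minimizer and a
    :class:`DegenerateGeometryWarning`.
    """
    xm, xr = _check_pair(mobile, reference)
    if xm.shape[0] < 3:
        warnings.warn("fewer than 3 sites: superposition is under-determined",
                      DegenerateGeometryWarning, stacklevel=2)
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    a = (xm - cm).T @ (xr - cr)  # 3x3 cross-covariance, sum_i m_i r_i^T as columns
    u, s, vt = np.linalg.svd(a.T)
    if s[0] > 0 and s[1] <= 1e-12 * s[0]:
        warnings.warn("collinear sites: rotation about the axis is arbitrary",
                      DegenerateGeometryWarning, stacklevel=2)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = cr - rot @ cm
    tf = RigidTransform(rotation=rot, translation=trans)
    resid = tf.apply(xm) - xr
    return tf, float(np.sqrt((resid ** 2).sum() / xm.shape[0]))


def rmsd(a, b, fit: bool = True) -> float:
    """Coordinate RMSD (nm); with ``fit`` the minimum over rigid transforms."""
    xa, xb = _check_pair(a, b)
    if fit:
        _, value = kabsch_superpose(xa, xb)
        return value
    return float(np.sqrt(((xa - xb) ** 2).sum() / xa.shape[0]))


def drms(a, b) -> float:
    """Distance RMS: RMS difference of all intramolecular site-site distances.

    ``sqrt(mean_{i<j} (d_ij^a - d_ij^b)^2)`` over all N(N-1)/2 pairs;
    invariant under rigid transforms of either conformation.
    """
    xa, xb = _check_pair(a, b)
    if xa.shape[0] < 2:
        raise InsufficientDataError("DRMS needs at least two sites")
    da, db = pdist(xa), pdist(xb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def swap_displacement_field(vec: np.ndarray, template: SiteSet, chain_map=None) -> np.ndarray:
    """Chain-swap a 3N displacement field defined at a symmetric template.

    Swapping a homodimer's chains maps a frame ``template + a*v`` to a rigid
    image of ``template + a*v'``; this returns ``v'``: the site-permuted
    field rotated by the superposition that maps the swapped template back
    onto the template. For an exactly C2-symmetric template the
    anti-symmetric rotation field maps to its negative and the symmetric
    alpha4-slide field to itself.
    """
    swapped = swap_chains(template, chain_map)
    tf, _ = kabsch_superpose(swapped.xyz, template.xyz)
    permuted = swap_vector(vec, template.labels, chain_map).reshape(-1, 3)
    return (permuted @ tf.rotation.T).reshape(-1)


def pairwise_matrix(e: Ensemble, metric: str = "drms") -> PairwiseMatrix:
    """All-pairs RMSD (each pair fitted independently) or DRMS over frames."""
    if e.n_frames < 2:
        raise InsufficientDataError("pairwise matrix needs at least two frames")
    if metric == "drms":
        dists = np.vstack([pdist(f) for f in e.xyz])
        p = dists.shape[1]
        values = squareform(pdist(dists) / np.sqrt(p))
    elif metric == "rmsd":
        m = e.n_frames
        values = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                values[i, j] = values[j, i] = rmsd(e.xyz[i], e.xyz[j], fit=True)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return PairwiseMatrix(values=values, metric=metric)
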
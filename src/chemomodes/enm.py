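"""Anisotropic network model (ANM) normal modes and mode-overlap analysis.

C-alpha sites within a cutoff distance R_c are connected by uniform
Hookean springs of stiffness gamma. The 3N x 3N Hessian of the network
energy at the input geometry is diagonalized; the six rigid-body zero
modes are removed and the remaining modes, sorted by increasing
eigenvalue (stiffness), are the low-frequency collective motions.
Changing gamma rescales eigenvalues but leaves mode directions intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ComparabilityError,
    DisconnectedNetworkError,
    GeometryError,
    ParameterError,
    UndefinedOverlapError,
    ValidationError,
)
from .ensemble_modes import ModeBasis, _fix_signs
from .structure_io import SiteSet


@dataclass
class AnmParameters:
    """ANM spring parameters: cutoff R_c (nm) and uniform gamma (kcal/mol/nm^2)."""

    cutoff_nm: float = 1.5
    gamma: float = 100.0

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0 or self.gamma <= 0:
            raise ParameterError("ANM cutoff and gamma must be positive")


@dataclass
class OverlapMatrix:
    """|dot products| between mode sets; rows = modes of A, cols = modes of B."""

    values: np.ndarray
    row_kind: str = ""
    col_kind: str = ""

    def to_tsv(self, path) -> None:
        rows, cols = self.values.shape
        with open(path, "w") as fh:
            fh.write("mode\t" + "\t".join(f"{self.col_kind or 'b'}{j}" for j in range(1, cols + 1)) + "\n")
            for i in range(rows):
                fh.write(f"{self.row_kind or 'a'}{i + 1}\t"
                         + "\t".join(format(v, ".10g") for v in self.values[i]) + "\n")


def _coords_of(x) -> np.ndarray:
    return x.xyz if isinstance(x, SiteSet) else np.asarray(x, float).reshape(-1, 3)


def anm_hessian(coords, params: AnmParameters | None = None) -> np.ndarray:
    """Standard ANM Hessian at the input geometry.

    Off-diagonal 3x3 block for a connected pair (i, j):
    ``H_ij = -gamma * r_ij r_ij^T / |r_ij|^2``; diagonal blocks make every
    block-row sum to zero (translation invariance).
    """
    params = params or AnmParameters()
    xyz = _coords_of(coords)
    n = xyz.shape[0]
    if n < 2:
        raise GeometryError("ANM needs at least two sites")
    d = squareform(pdist(xyz))
    if np.any(d[np.triu_indices(n, 1)] < 1e-6):
        raise GeometryError("coincident sites (< 1e-6 nm apart) in ANM input")
    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(d <= params.cutoff_nm, 1))
    for i, j in zip(ii, jj):
        r = xyz[j] - xyz[i]
        block = -params.gamma * np.outer(r, r) / (r @ r)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def anm_energy(coords, ref_coords, params: AnmParameters | None = None) -> float:
    """Network spring energy: (gamma/2) sum over connected pairs (|r| - |r0|)^2.

    Connectivity and rest lengths come from ``ref_coords``; used as the
    independent oracle for the analytic Hessian.
    """
    params = params or AnmParameters()
    x0 = _coords_of(ref_coords)
    x = _coords_of(coords)
    d0 = pdist(x0)
    d = pdist(x)
    mask = d0 <= params.cutoff_nm
    return float(0.5 * params.gamma * np.sum((d[mask] - d0[mask]) ** 2))


def _is_collinear(xyz: np.ndarray, tol: float = 1e-9) -> bool:
    c = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def anm_modes(
    h: np.ndarray,
    coords=None,
    labels: list[tuple[str, int]] | None = None,
    zero_tol: float = 1e-8,
) -> ModeBasis:
    """Normal modes of an ANM Hessian with rigid-body zero-mode removal.

    Eigenvalues below ``zero_tol * max eigenvalue`` are removed as
    rigid-body modes; finding more than 6 such modes for a generic
    (non-collinear) structure means the network has floating fragments.
    Passing ``coords`` stores them as the basis origin and enables the
    collinear exemption from the disconnected-network check.
    """
    h = np.asarray(h, float)
    if h.ndim != 2 or h.shape[0] != h.shape[1] or h.shape[0] % 3:
        raise ValidationError("Hessian must be square with 3N rows")
    if np.abs(h - h.T).max() > 1e-8 * max(1.0, np.abs(h).max()):
        raise ValidationError("Hessian must be symmetric")
    w, v = np.linalg.eigh((h + h.T) / 2.0)
    thresh = zero_tol * max(w.max(), 0.0)
    nonzero = w > thresh
    n_zero = int((~nonzero).sum())
    xyz = _coords_of(coords) if coords is not None else None
    collinear = xyz is not None and _is_collinear(xyz)
    if n_zero > 6 and not collinear:
        raise DisconnectedNetworkError(
            f"{n_zero} zero modes found (expected <= 6): the network has floating fragments"
        )
    w, v = w[nonzero], _fix_signs(v[:, nonzero])
    mean = xyz.reshape(-1) if xyz is not None else np.zeros(h.shape[0])
    if isinstance(coords, SiteSet) and labels is None:
        labels = list(coords.labels)
    return ModeBasis(mean=mean, eigenvalues=w, eigenvectors=v, kind="anm",
                     labels=labels, metadata={"n_zero_modes": n_zero})


def anm(coords, params: AnmParameters | None = None) -> ModeBasis:
    """Convenience: Hessian construction + normal modes for a structure."""
    return anm_modes(anm_hessian(coords, params), coords=coords)


def overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute normalized dot product |a.b| / (|a||b|) in [0, 1]."""
    a = np.asarray(a, float).reshape(-1)
    b = np.asarray(b, float).reshape(-1)
    if a.size != b.size:
        raise ComparabilityError(f"vector lengths differ: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedOverlapError("overlap with a zero vector is undefined")
    return float(min(1.0, abs(a @ b) / (na * nb)))


def overlap_matrix(
    a: ModeBasis,
    b: ModeBasis | np.ndarray,
    k_a: int | None = None,
    k_b: int | None = None,
) -> OverlapMatrix:
    """Pairwise |overlap| between the first k_a modes of A and k_b modes of B.

    ``b`` may be a single 3N displacement vector, giving a one-column matrix.
    """
    k_a = k_a or a.n_modes
    va = a.eigenvectors[:, :k_a]
    if isinstance(b, ModeBasis):
        if a.labels is not None and b.labels is not None and a.labels != b.labels:
            raise ComparabilityError("mode bases carry different site labels")
        k_b = k_b or b.n_modes
        vb = b.eigenvectors[:, :k_b]
        col_kind = b.kind
    else:
        vb = np.asarray(b, float).reshape(-1, 1)
        nb = np.linalg.norm(vb)
        if nb == 0:
            raise UndefinedOverlapError("overlap with a zero vector is undefined")
        vb = vb / nb
        col_kind = "vec"
    if va.shape[0] != vb.shape[0]:
        raise ComparabilityError("mode vector lengths differ")
    return OverlapMatrix(values=np.abs(va.T @ vb), row_kind=a.kind, col_kind=col_kind)


def subspace_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of the singular values of the cross-projection between two
    orthonormal mode sets (columns); 1 means identical spans."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(np.sqrt(np.mean(s**2)))
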
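"""Essential dynamics of superposed ensembles.

Iterative mean-structure refinement, the 3N x 3N coordinate covariance,
PCA eigenmodes, signed mode projections (pe_1, pe_2, ...), and mode
extrapolation. The covariance uses unit masses (all sites are C-alpha)
and the population divisor 1/M; eigenvectors are sign-fixed so that each
vector's largest-magnitude component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ComparabilityError,
    ConvergenceError,
    InsufficientDataError,
    ValidationError,
)
from .geometry import kabsch_superpose, rmsd
from .structure_io import Ensemble, SiteSet, check_labels


@dataclass
class ModeBasis:
    """Mean coordinates plus sorted eigenpairs from PCA or ANM.

    ``eigenvalues`` are nm^2 for PCA (variances along each mode) and
    spring-energy curvatures for ANM. PCA modes are sorted descending by
    eigenvalue, ANM modes ascending after zero-mode removal.
    """

    mean: np.ndarray  # (3N,), nm
    eigenvalues: np.ndarray  # (K,)
    eigenvectors: np.ndarray  # (3N, K), orthonormal columns
    kind: str  # "pca" | "anm"
    labels: list[tuple[str, int]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).reshape(-1)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        self.eigenvectors = np.asarray(self.eigenvectors, float)
        if self.eigenvectors.shape[0] != self.mean.size:
            raise ValidationError("eigenvector length does not match mean coordinates")
        if self.eigenvectors.shape[1] != self.eigenvalues.size:
            raise ValidationError("eigenvalue/eigenvector count mismatch")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def mode(self, k: int) -> np.ndarray:
        """k-th mode vector, 1-based to match pe_1/pe_2 naming."""
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode index {k} outside 1..{self.n_modes}")
        return self.eigenvectors[:, k - 1]

    @property
    def mean_xyz(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)


@dataclass
class ProjectionTable:
    """Per-frame signed projections (nm) onto the first K basis modes."""

    values: np.ndarray  # (M, K)
    frame_indices: np.ndarray
    basis_kind: str = "pca"

    def pe(self, k: int) -> np.ndarray:
        return self.values[:, k - 1]

    def to_tsv(self, path: str | Path) -> None:
        k = self.values.shape[1]
        with open(path, "w") as fh:
            fh.write("frame\t" + "\t".join(f"pe{i}" for i in range(1, k + 1)) + "\n")
            for idx, row in zip(self.frame_indices, self.values):
                fh.write(f"{idx}\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def fit_frames(e: Ensemble, reference_xyz: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame onto ``reference_xyz``; returns (M, N, 3)."""
    out = np.empty_like(e.xyz)
    for i, frame in enumerate(e.xyz):
        tf, _ = kabsch_superpose(frame, reference_xyz)
        out[i] = tf.apply(frame)
    return out


def iterative_mean(
    e: Ensemble, tol: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, Ensemble]:
    """Converged average structure and the ensemble fitted to it.

    Alternates fitting all frames to the current mean with recomputing the
    mean, until successive means differ by less than ``tol`` (raw RMSD, nm).
    The returned mean is the exact arithmetic mean of the returned fitted
    frames, so downstream projections have exactly zero mean per mode.
    """
    if e.n_frames < 2:
        raise InsufficientDataError("iterative mean needs at least two frames")
    ref = e.xyz[0]
    last_change = np.inf
    for _ in range(max_iter):
        fitted = fit_frames(e, ref)
        new_mean = fitted.mean(axis=0)
        last_change = rmsd(new_mean, ref, fit=False)
        ref = new_mean
        if last_change < tol:
            fitted_e = Ensemble(list(e.labels), fitted, dict(e.provenance))
            return new_mean.reshape(-1), fitted_e
    raise ConvergenceError(
        f"mean structure did not converge in {max_iter} iterations (last change {last_change:.3g} nm)"
    )


def covariance(fitted: Ensemble, mean: np.ndarray) -> np.ndarray:
    """Population coordinate covariance C = (1/M) sum (x - mean)(x - mean)^T."""
    if fitted.n_frames < 2:
        raise InsufficientDataError("covariance needs at least two frames")
    x = fitted.frames - np.asarray(mean, float).reshape(-1)
    return x.T @ x / fitted.n_frames


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def pca_modes(
    c: np.ndarray,
    mean: np.ndarray | None = None,
    labels: list[tuple[str, int]] | None = None,
) -> ModeBasis:
    """Full eigendecomposition of a coordinate covariance matrix.

    Eigenvalues descending; eigenvector signs fixed by the
    largest-magnitude-component-positive rule.
    """
    c = np.asarray(c, float)
    scale = max(1.0, float(np.abs(c).max()))
    if c.ndim != 2 or c.shape[0] != c.shape[1] or np.abs(c - c.T).max() > 1e-10 * scale:
        raise ValidationError("covariance matrix must be symmetric")
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], _fix_signs(v[:, order])
    if mean is None:
        mean = np.zeros(c.shape[0])
    return ModeBasis(mean=mean, eigenvalues=w, eigenvectors=v, kind="pca", labels=labels)


def pca_from_ensemble(e: Ensemble, tol: float = 1e-6, max_iter: int = 100) -> tuple[ModeBasis, Ensemble]:
    """Convenience: iterative mean + covariance + PCA in one call."""
    mean, fitted = iterative_mean(e, tol=tol, max_iter=max_iter)
    basis = pca_modes(covariance(fitted, mean), mean=mean, labels=list(e.labels))
    return basis, fitted


def project(e: Ensemble, basis: ModeBasis, k: int | None = None) -> ProjectionTable:
    """Signed projections pe_k = (x_fitted - mean) . v_k for each frame (nm).

    Frames are Kabsch-fitted to the basis mean before projecting.
    """
    if basis.labels is not None:
        check_labels(e.labels, basis.labels)
    elif 3 * e.n_sites != basis.mean.size:
        raise ComparabilityError("ensemble size does not match basis")
    if k is None:
        k = min(basis.n_modes, 10)
    if k > basis.n_modes:
        raise IndexError(f"requested {k} modes, basis holds {basis.n_modes}")
    fitted = fit_frames(e, basis.mean_xyz)
    disp = fitted.reshape(e.n_frames, -1) - basis.mean
    values = disp @ basis.eigenvectors[:, :k]
    return ProjectionTable(values=values, frame_indices=np.arange(e.n_frames),
                           basis_kind=basis.kind)


def project_structure(s: SiteSet | np.ndarray, basis: ModeBasis, k: int | None = None) -> np.ndarray:
    """Projections of a single conformation (after fitting) onto the first k modes."""
    xyz = s.xyz if isinstance(s, SiteSet) else np.asarray(s, float).reshape(-1, 3)
    if isinstance(s, SiteSet) and basis.labels is not None:
        check_labels(s.labels, basis.labels)
    tf, _ = kabsch_superpose(xyz, basis.mean_xyz)
    disp = tf.apply(xyz).reshape(-1) - basis.mean
    return disp @ basis.eigenvectors[:, : (k or basis.n_modes)]


def extrapolate(basis: ModeBasis, k: int, amplitude: float) -> SiteSet:
    """Displace the mean along mode k: coords = mean + amplitude * v_k."""
    coords = basis.mean + amplitude * basis.mode(k)
    labels = basis.labels or [("A", i + 1) for i in range(coords.size // 3)]
    return SiteSet(labels=list(labels), xyz=coords.reshape(-1, 3))


def align_basis(basis: ModeBasis, reference_xyz: np.ndarray) -> ModeBasis:
    """Superpose a basis' mean onto reference coordinates and co-rotate its modes.

    A basis computed from an ensemble lives in that ensemble's arbitrary
    frame; comparing its eigenvectors with vectors defined at another
    structure (a template, a piston vector) requires expressing both in one
    frame. Eigenvalues and projections are invariant under this rotation.
    """
    reference_xyz = np.asarray(reference_xyz, float).reshape(-1, 3)
    tf, _ = kabsch_superpose(basis.mean_xyz, reference_xyz)
    mean = tf.apply(basis.mean_xyz).reshape(-1)
    n_modes = basis.n_modes
    vecs = basis.eigenvectors.reshape(-1, 3, n_modes)
    vecs = np.einsum("ij,njk->nik", tf.rotation, vecs).reshape(-1, n_modes)
    meta = dict(basis.metadata)
    meta["aligned"] = True
    return ModeBasis(mean=mean, eigenvalues=basis.eigenvalues.copy(), eigenvectors=vecs,
                     kind=basis.kind, labels=basis.labels, metadata=meta)


def orient_modes(basis: ModeBasis, references: dict[int, np.ndarray]) -> ModeBasis:
    """Flip mode signs so each listed mode has positive overlap with its reference.

    Used to pin the pe_2 < 0 = "downward alpha4 slide" convention by passing
    ``{2: -piston_vector}``; flips are recorded in the basis metadata.
    """
    vecs = basis.eigenvectors.copy()
    flips = []
    for k, ref in references.items():
        ref = np.asarray(ref, float).reshape(-1)
        if float(vecs[:, k - 1] @ ref) < 0:
            vecs[:, k - 1] = -vecs[:, k - 1]
            flips.append(k)
    meta = dict(basis.metadata)
    meta["sign_flips"] = flips
    return ModeBasis(mean=basis.mean, eigenvalues=basis.eigenvalues, eigenvectors=vecs,
                     kind=basis.kind, labels=basis.labels, metadata=meta)


def save_basis(basis: ModeBasis, path: str | Path, k: int | None = None) -> None:
    """Persist mean + eigenvalues + the first k eigenvectors as a TSV bundle."""
    k = k or basis.n_modes
    with open(path, "w") as fh:
        fh.write(f"# kind: {basis.kind}\n")
        fh.write("# eigenvalues: " + "\t".join(format(v, ".10g") for v in basis.eigenvalues[:k]) + "\n")
        if basis.labels is not None:
            fh.write("# labels: " + ",".join(f"{c}{r}" for c, r in basis.labels) + "\n")
        fh.write("coord\tmean\t" + "\t".join(f"v{i}" for i in range(1, k + 1)) + "\n")
        for i in range(basis.mean.size):
            row = [format(basis.mean[i], ".10g")]
            row += [format(basis.eigenvectors[i, j], ".10g") for j in range(k)]
            fh.write(f"{i}\t" + "\t".join(row) + "\n")


def load_basis(path: str | Path) -> ModeBasis:
    kind, eigenvalues, labels = "pca", None, None
    rows = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("# kind:"):
                kind = ln.split(":", 1)[1].strip()
            elif ln.startswith("# eigenvalues:"):
                eigenvalues = np.array([float(v) for v in ln.split(":", 1)[1].split()])
            elif ln.startswith("# labels:"):
                labels = []
                for tok in ln.split(":", 1)[1].strip().split(","):
                    labels.append((tok[0], int(tok[1:])))
            elif ln.startswith("#") or ln.startswith("coord\t"):
                continue
            else:
                rows.append([float(v) for v in ln.split("\t")[1:]])
    arr = np.asarray(rows, float)
    if eigenvalues is None:
        raise ValidationError(f"{path}: missing eigenvalue header")
    return ModeBasis(mean=arr[:, 0], eigenvalues=eigenvalues, eigenvectors=arr[:, 1:],
                     kind=kind, labels=labels)
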
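"""Piston vector construction and its projection spectrum over a mode basis.

The piston vector (PV) encodes the classical transmembrane-signaling
motion: the apo -> holo C-alpha displacement restricted to the alpha4
helix sites and normalized to unit length. Projecting the PV onto PCA or
ANM mode bases measures how much of each collective mode is piston-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble_modes import ModeBasis
from .errors import ComparabilityError, DegeneratePVError, SelectionError
from .geometry import kabsch_superpose
from .structure_io import SiteSet, alpha4_ranges, check_labels


@dataclass
class PistonVector:
    """Unit 3N displacement vector supported only on alpha4-helix sites."""

    vector: np.ndarray  # (3N,), unit norm
    mask: np.ndarray  # (N,) bool, True = alpha4 site
    labels: list[tuple[str, int]]
    raw_norm_nm: float  # masked displacement norm before normalization
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, float).reshape(-1)
        self.mask = np.asarray(self.mask, bool)
        if self.vector.size != 3 * self.mask.size:
            raise ComparabilityError("PV vector length does not match mask")


def sites_mask(
    labels: Sequence[tuple[str, int]],
    ranges: Mapping[str, Sequence[tuple[int, int]]],
) -> np.ndarray:
    """Boolean per-site mask for labels inside the per-chain ranges."""
    mask = np.zeros(len(labels), dtype=bool)
    for i, (chain, resnum) in enumerate(labels):
        for a, b in ranges.get(chain, ()):
            if a <= resnum <= b:
                mask[i] = True
                break
    if not mask.any():
        raise SelectionError("mask ranges select no sites")
    return mask


def build_pv(
    apo: SiteSet,
    holo: SiteSet,
    a4_ranges: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    fit: str = "auto",
    orient: str | None = "z-down",
) -> PistonVector:
    """Piston vector from an apo/holo structure pair.

    ``holo`` is first Kabsch-fitted to ``apo``; with ``fit="core"`` (the
    default resolution of ``"auto"`` whenever the alpha4 mask covers fewer
    than half the sites) the fit uses only non-alpha4 sites, so the static
    core defines the frame and the alpha4 motion is not absorbed into the
    superposition. The apo -> holo displacement is zeroed outside the mask
    and normalized. With ``orient="z-down"`` the sign is chosen so the mean
    z-component of the masked displacement is negative (the downward-slide
    convention); ``orient=None`` keeps the raw apo -> holo direction.
    """
    check_labels(apo.labels, holo.labels)
    if a4_ranges is None:
        a4_ranges = alpha4_ranges(sorted({c for c, _ in apo.labels}))
    mask = sites_mask(apo.labels, a4_ranges)
    if fit == "auto":
        fit = "core" if mask.mean() < 0.5 else "all"
    if fit == "core":
        core = ~mask
        if core.sum() < 3:
            fit = "all"
    if fit == "core":
        tf, _ = kabsch_superpose(holo.xyz[~mask], apo.xyz[~mask])
    elif fit == "all":
        tf, _ = kabsch_superpose(holo.xyz, apo.xyz)
    else:
        raise ValueError(f"unknown fit policy {fit!r}")
    disp = tf.apply(holo.xyz) - apo.xyz
    disp[~mask] = 0.0
    raw_norm = float(np.linalg.norm(disp))
    if raw_norm < 1e-12:
        raise DegeneratePVError("masked apo->holo displacement is zero")
    vec = disp / raw_norm
    flipped = False
    if orient == "z-down" and vec[mask, 2].mean() > 0:
        vec = -vec
        flipped = True
    return PistonVector(
        vector=vec.reshape(-1),
        mask=mask,
        labels=list(apo.labels),
        raw_norm_nm=raw_norm,
        provenance={"fit": fit, "orient": orient, "flipped": flipped,
                    "alpha4_ranges": {c: list(r) for c, r in a4_ranges.items()}},
    )


def pv_spectrum(pv: PistonVector, basis: ModeBasis, k: int | None = None) -> np.ndarray:
    """Signed projections PV . v_k for the first k basis modes.

    Squared entries sum to <= 1, with equality on a complete basis.
    """
    if basis.labels is not None:
        check_labels(pv.labels, basis.labels)
    elif pv.vector.size != basis.mean.size:
        raise ComparabilityError("PV length does not match basis")
    k = k or basis.n_modes
    return pv.vector @ basis.eigenvectors[:, :k]


def spectrum_to_tsv(spectrum: np.ndarray, eigenvalues: np.ndarray, path) -> None:
    """Machine-readable PV spectrum: mode index, eigenvalue, signed projection."""
    with open(path, "w") as fh:
        fh.write("mode\teigenvalue\tpv_projection\n")
        for i, (lam, p) in enumerate(zip(eigenvalues, spectrum), start=1):
            fh.write(f"{i}\t{lam:.10g}\t{p:.10g}\n")
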
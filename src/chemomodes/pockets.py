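"""Binding-pocket geometry along frames and mode extrapolations.

A homodimeric receptor has two symmetry-related pockets at the monomer
interface. Each pocket is spanned by three key C-alpha sites: two on one
monomer (e.g. Q152 on alpha4 and R64 on alpha1) and one on the other
monomer (R69'). Tracking the three pairwise distances of both pockets
along a collective mode exposes the anti-symmetric (negative-
cooperativity) signature: distances that open in the front pocket close
in the back pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensemble_modes import ModeBasis, extrapolate
from .errors import SelectionError, UndefinedScoreError
from .structure_io import Ensemble, SiteSet

PAIR_NAMES = ("d12", "d13", "d23")


@dataclass
class PocketSpec:
    """Key residues of the two interface pockets.

    ``res1`` and ``res2`` sit on a pocket's own monomer, ``res3_other`` on
    the opposite monomer. The front pocket is the one whose own residues
    lie on ``chains[0]``; the back pocket is its chain-swapped image.
    """

    res1: int = 152  # Q152, alpha4
    res2: int = 64   # R64, alpha1
    res3_other: int = 69  # R69', alpha1 of the other monomer
    chains: tuple[str, str] = ("A", "B")

    def pocket_labels(self, which: str) -> list[tuple[str, int]]:
        own, other = self.chains if which == "front" else self.chains[::-1]
        return [(own, self.res1), (own, self.res2), (other, self.res3_other)]


@dataclass
class PocketDistanceSet:
    """Distances d12, d13, d23 (nm) for front and back pockets per entry."""

    front: np.ndarray  # (M, 3)
    back: np.ndarray  # (M, 3)
    amplitudes: np.ndarray | None = None  # (M,) when measured along a mode
    spec: PocketSpec | None = None

    def to_tsv(self, path) -> None:
        cols = [f"{p}_front" for p in PAIR_NAMES] + [f"{p}_back" for p in PAIR_NAMES]
        first = "amplitude" if self.amplitudes is not None else "frame"
        idx = self.amplitudes if self.amplitudes is not None else np.arange(self.front.shape[0])
        with open(path, "w") as fh:
            fh.write(first + "\t" + "\t".join(cols) + "\n")
            for i, (a, f, b) in enumerate(zip(idx, self.front, self.back)):
                vals = list(f) + list(b)
                fh.write(format(a, ".10g") + "\t" + "\t".join(format(v, ".10g") for v in vals) + "\n")


def _site_index(labels: Sequence[tuple[str, int]], label: tuple[str, int]) -> int:
    try:
        return labels.index(label)
    except ValueError:
        raise SelectionError(f"pocket site {label} absent from the site set") from None


def _triple_distances(xyz: np.ndarray, idx: Sequence[int]) -> np.ndarray:
    p1, p2, p3 = (xyz[i] for i in idx)
    return np.array([
        np.linalg.norm(p1 - p2),
        np.linalg.norm(p1 - p3),
        np.linalg.norm(p2 - p3),
    ])


def pocket_distances(coords: SiteSet, spec: PocketSpec | None = None) -> PocketDistanceSet:
    """C-alpha pairwise distances of the three key residues for both pockets."""
    spec = spec or PocketSpec()
    idx_front = [_site_index(coords.labels, lab) for lab in spec.pocket_labels("front")]
    idx_back = [_site_index(coords.labels, lab) for lab in spec.pocket_labels("back")]
    return PocketDistanceSet(
        front=_triple_distances(coords.xyz, idx_front)[None, :],
        back=_triple_distances(coords.xyz, idx_back)[None, :],
        spec=spec,
    )


def distances_along_frames(e: Ensemble, spec: PocketSpec | None = None) -> PocketDistanceSet:
    """Pocket distances for every frame of an ensemble."""
    spec = spec or PocketSpec()
    idx_front = [_site_index(e.labels, lab) for lab in spec.pocket_labels("front")]
    idx_back = [_site_index(e.labels, lab) for lab in spec.pocket_labels("back")]
    front = np.vstack([_triple_distances(f, idx_front) for f in e.xyz])
    back = np.vstack([_triple_distances(f, idx_back) for f in e.xyz])
    return PocketDistanceSet(front=front, back=back, spec=spec)


def default_amplitude_grid() -> np.ndarray:
    """Extrapolation amplitudes -2 ... +2 nm in 0.1 nm steps."""
    return np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def distances_along_mode(
    basis: ModeBasis,
    k: int,
    amplitudes: np.ndarray | None = None,
    spec: PocketSpec | None = None,
) -> PocketDistanceSet:
    """Pocket distances of structures extrapolated along mode k."""
    spec = spec or PocketSpec()
    if amplitudes is None:
        amplitudes = default_amplitude_grid()
    amplitudes = np.asarray(amplitudes, float)
    if amplitudes.size == 0:
        raise UndefinedScoreError("amplitude grid is empty")
    front, back = [], []
    for a in amplitudes:
        s = extrapolate(basis, k, a)
        d = pocket_distances(s, spec)
        front.append(d.front[0])
        back.append(d.back[0])
    return PocketDistanceSet(front=np.vstack(front), back=np.vstack(back),
                             amplitudes=amplitudes, spec=spec)


def antisymmetry_score(series: PocketDistanceSet) -> dict[str, float]:
    """Pearson correlation between front and back distance deviations per pair.

    Deviations are taken from the entry at the amplitude closest to zero
    (or the first frame). Strongly negative scores are the anti-symmetric,
    negative-cooperativity signature: one pocket opens as the other closes.
    """
    if series.front.shape[0] < 3:
        raise UndefinedScoreError("need at least 3 points to score anti-symmetry")
    if series.amplitudes is not None:
        ref = int(np.argmin(np.abs(series.amplitudes)))
    else:
        ref = 0
    scores: dict[str, float] = {}
    for j, name in enumerate(PAIR_NAMES):
        df = series.front[:, j] - series.front[ref, j]
        db = series.back[:, j] - series.back[ref, j]
        if np.std(df) == 0 or np.std(db) == 0:
            raise UndefinedScoreError(f"zero-variance distance series for {name}")
        scores[name] = float(np.corrcoef(df, db)[0, 1])
    return scores
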
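"""Structure and ensemble I/O for C-alpha mode analysis.

Reads single- and multi-model PDB files (through :mod:`gemmi`), selects
C-alpha sites over configured helix residue ranges, and performs the
symmetric chain swap used to extend homodimer trajectories.

Internal units are nanometres everywhere; conversion from the PDB's
angstroms happens only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ComparabilityError,
    EmptyStructureError,
    InconsistentEnsembleError,
    PDBFormatError,
    SelectionError,
    SwapError,
)

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: Helix residue ranges (inclusive, 1-based) of the Tar periplasmic domain:
#: alpha1-alpha4 of each monomer.
TAR_HELIX_RANGES: tuple[tuple[int, int], ...] = (
    (44, 75),
    (89, 113),
    (118, 144),
    (146, 175),
)

#: The alpha4 helix range of Tar (the classical piston helix).
TAR_ALPHA4_RANGE: tuple[int, int] = (146, 175)


def tar_ranges(chains: Sequence[str] = ("A", "B")) -> dict[str, list[tuple[int, int]]]:
    """Default helix selection for a Tar periplasmic dimer on the given chains."""
    return {c: list(TAR_HELIX_RANGES) for c in chains}


def alpha4_ranges(chains: Sequence[str] = ("A", "B")) -> dict[str, list[tuple[int, int]]]:
    """Default alpha4 mask ranges (both monomers)."""
    return {c: [TAR_ALPHA4_RANGE] for c in chains}


@dataclass
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: np.ndarray  # (3,), nm


@dataclass
class Structure:
    """A single model's atoms, coordinates in nm."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class SiteSet:
    """Ordered, labeled C-alpha sites with an (N, 3) coordinate array in nm."""

    labels: list[tuple[str, int]]
    xyz: np.ndarray
    selection: dict | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(len(self.labels), 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in SiteSet")

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    @property
    def coords(self) -> np.ndarray:
        """Flattened 3N coordinate vector (nm)."""
        return self.xyz.reshape(-1)

    def with_xyz(self, xyz: np.ndarray) -> "SiteSet":
        return SiteSet(list(self.labels), np.asarray(xyz, float), self.selection)


@dataclass
class Ensemble:
    """M frames sharing one site ordering; coordinates (M, N, 3) in nm."""

    labels: list[tuple[str, int]]
    xyz: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim == 2:  # (M, 3N)
            self.xyz = self.xyz.reshape(self.xyz.shape[0], -1, 3)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != len(self.labels) or self.xyz.shape[2] != 3:
            raise InconsistentEnsembleError(
                f"frame array shape {self.xyz.shape} incompatible with {len(self.labels)} labels"
            )
        if self.xyz.shape[0] < 1:
            raise InconsistentEnsembleError("an ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_sites(self) -> int:
        return self.xyz.shape[1]

    @property
    def frames(self) -> np.ndarray:
        """(M, 3N) view of the coordinates."""
        return self.xyz.reshape(self.n_frames, -1)

    def frame(self, i: int) -> SiteSet:
        return SiteSet(list(self.labels), self.xyz[i].copy())


def check_labels(a_labels: Sequence[tuple[str, int]], b_labels: Sequence[tuple[str, int]]) -> None:
    """Raise ComparabilityError unless both label lists are identical."""
    if list(a_labels) != list(b_labels):
        raise ComparabilityError("site label lists differ; objects are not comparable")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _model_to_structure(model: gemmi.Model) -> Structure:
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=atom.name,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]) / ANGSTROM_PER_NM,
                    )
                )
    return Structure(atoms=atoms, model_id=model.num)


def read_pdb(path: str | Path, model_policy: str = "first") -> Structure | list[Structure]:
    """Read a PDB file; coordinates are converted from angstrom to nm.

    Parameters
    ----------
    path:
        PDB file with ATOM/MODEL records.
    model_policy:
        ``"first"`` returns a single :class:`Structure`; ``"all"`` a list.
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model policy {model_policy!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    models = [_model_to_structure(m) for m in st]
    models = [m for m in models if len(m) > 0]
    if not models:
        raise EmptyStructureError(f"no ATOM records read from {path}")
    if model_policy == "first":
        return models[0]
    return models


def write_pdb(structures: Structure | SiteSet | Sequence[Structure | SiteSet], path: str | Path) -> None:
    """Write one or more models to a PDB file (nm -> angstrom).

    ``SiteSet`` inputs are written as CA-only ALA traces, which round-trips
    through :func:`read_pdb` + :func:`select_calpha`.
    """
    if isinstance(structures, (Structure, SiteSet)):
        structures = [structures]
    st = gemmi.Structure()
    st.name = "chemomodes"
    for i, s in enumerate(structures, start=1):
        model = gemmi.Model(i)
        if isinstance(s, SiteSet):
            records = [
                AtomRecord(chain=c, resnum=r, resname="ALA", name="CA", xyz=s.xyz[j])
                for j, (c, r) in enumerate(s.labels)
            ]
        else:
            records = s.atoms
        chains: dict[str, gemmi.Chain] = {}
        for rec in records:
            if rec.chain not in chains:
                chains[rec.chain] = gemmi.Chain(rec.chain)
            ch = chains[rec.chain]
            if len(ch) == 0 or ch[len(ch) - 1].seqid.num != rec.resnum:
                res = gemmi.Residue()
                res.name = rec.resname
                res.seqid = gemmi.SeqId(rec.resnum, " ")
                res.het_flag = "A"
                ch.add_residue(res)
            res = ch[len(ch) - 1]
            atom = gemmi.Atom()
            atom.name = rec.name
            atom.element = gemmi.Element("C")
            x, y, z = np.asarray(rec.xyz, float) * ANGSTROM_PER_NM
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _normalize_ranges(
    ranges: Mapping[str, Sequence[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chain, rs in ranges.items():
        rs = [(int(a), int(b)) for a, b in rs]
        for a, b in rs:
            if b < a:
                raise SelectionError(f"range {a}-{b} on chain {chain} is reversed")
        out[str(chain)] = rs
    return out


def select_calpha(
    s: Structure, ranges: Mapping[str, Sequence[tuple[int, int]]]
) -> SiteSet:
    """Select CA atoms inside per-chain inclusive residue ranges.

    Missing residues inside a range are skipped with a warning and recorded
    in the returned selection spec; a chain named in ``ranges`` but absent
    from the structure raises :class:`SelectionError`.
    """
    ranges = _normalize_ranges(ranges)
    present: dict[tuple[str, int], np.ndarray] = {}
    chains_seen: set[str] = set()
    for atom in s.atoms:
        chains_seen.add(atom.chain)
        if atom.name == "CA":
            present.setdefault((atom.chain, atom.resnum), atom.xyz)
    labels: list[tuple[str, int]] = []
    coords: list[np.ndarray] = []
    missing: list[tuple[str, int]] = []
    for chain in sorted(ranges):
        if chain not in chains_seen:
            raise SelectionError(f"chain {chain!r} named in ranges is absent from the structure")
        for a, b in ranges[chain]:
            for resnum in range(a, b + 1):
                key = (chain, resnum)
                if key in present:
                    labels.append(key)
                    coords.append(present[key])
                else:
                    missing.append(key)
    if missing:
        logger.warning("select_calpha: %d residue(s) missing inside ranges: %s",
                       len(missing), missing[:10])
    if not labels:
        raise SelectionError("selection matched no CA atoms")
    return SiteSet(
        labels=labels,
        xyz=np.vstack(coords),
        selection={"ranges": ranges, "missing": missing},
    )


# ---------------------------------------------------------------------------
# Chain swap
# ---------------------------------------------------------------------------

def _swap_permutation(labels: Sequence[tuple[str, int]], chain_map: Mapping[str, str]) -> np.ndarray:
    chains = {c for c, _ in labels}
    if set(chain_map) != chains or set(chain_map.values()) != chains:
        raise SwapError(f"chain map {dict(chain_map)} is not a bijection over chains {sorted(chains)}")
    index = {lab: i for i, lab in enumerate(labels)}
    perm = np.empty(len(labels), dtype=int)
    for i, (chain, resnum) in enumerate(labels):
        # output site i carries the coordinates of the site whose mapped
        # label equals label i, i.e. the site (map^-1(chain), resnum)
        src = None
        for c_from, c_to in chain_map.items():
            if c_to == chain:
                src = (c_from, resnum)
                break
        if src not in index:
            raise SwapError(
                f"label {src} required by the swap is absent; chains are not homodimeric copies"
            )
        perm[i] = index[src]
    return perm


def swap_chains(obj: Ensemble | SiteSet, chain_map: Mapping[str, str] | None = None):
    """Relabel chains by a bijection and reorder coordinates accordingly.

    For an A/B homodimer the default map exchanges the two chains. The
    operation is an involution and preserves each frame's coordinate
    multiset.
    """
    labels = obj.labels
    if chain_map is None:
        chains = sorted({c for c, _ in labels})
        if len(chains) != 2:
            raise SwapError("default chain map requires exactly two chains")
        chain_map = {chains[0]: chains[1], chains[1]: chains[0]}
    perm = _swap_permutation(labels, chain_map)
    if isinstance(obj, SiteSet):
        return obj.with_xyz(obj.xyz[perm])
    swapped = Ensemble(list(labels), obj.xyz[:, perm, :].copy(), dict(obj.provenance))
    swapped.provenance["chain_swap"] = dict(chain_map)
    return swapped


def swap_vector(vec: np.ndarray, labels: Sequence[tuple[str, int]],
                chain_map: Mapping[str, str] | None = None) -> np.ndarray:
    """Apply the chain-swap site permutation to a 3N displacement vector."""
    if chain_map is None:
        chains = sorted({c for c, _ in labels})
        chain_map = {chains[0]: chains[1], chains[1]: chains[0]}
    perm = _swap_permutation(labels, chain_map)
    return np.asarray(vec, float).reshape(len(labels), 3)[perm].reshape(-1)


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

def read_ensemble(
    path: str | Path,
    ranges: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    fmt: str | None = None,
) -> Ensemble:
    """Read an ensemble from a multi-model PDB or a TSV coordinate table.

    For PDB input every model is passed through :func:`select_calpha` with
    ``ranges`` (default: Tar helix ranges on chains A/B); models must yield
    identical site lists.
    """
    path = Path(path)
    if fmt is None:
        fmt = "table" if path.suffix.lower() in (".tsv", ".txt", ".dat") else "pdb"
    if fmt == "table":
        return _read_ensemble_table(path)
    structures = read_pdb(path, model_policy="all")
    if ranges is None:
        ranges = tar_ranges()
    sitesets = []
    for s in structures:
        try:
            sitesets.append(select_calpha(s, ranges))
        except SelectionError as exc:
            raise InconsistentEnsembleError(f"model {s.model_id}: {exc}") from exc
    ref = sitesets[0]
    for s, st in zip(sitesets[1:], structures[1:]):
        if s.labels != ref.labels:
            raise InconsistentEnsembleError(
                f"model {st.model_id} site list differs from model {structures[0].model_id}"
            )
    xyz = np.stack([s.xyz for s in sitesets])
    return Ensemble(
        labels=list(ref.labels),
        xyz=xyz,
        provenance={"source": str(path), "format": "pdb", "selection": ref.selection},
    )


def _label_header(labels: Sequence[tuple[str, int]]) -> list[str]:
    cols = []
    for chain, resnum in labels:
        for ax in "xyz":
            cols.append(f"{chain}{resnum}:{ax}")
    return cols


def write_ensemble_table(e: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a TSV coordinate table (one frame per row, nm)."""
    header = "\t".join(_label_header(e.labels))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in e.frames:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def _read_ensemble_table(path: Path) -> Ensemble:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise InconsistentEnsembleError(f"{path} contains no data")
    cols = lines[0].split("\t")
    if len(cols) % 3 != 0:
        raise PDBFormatError(f"{path}: header column count {len(cols)} is not a multiple of 3")
    labels: list[tuple[str, int]] = []
    for col in cols[::3]:
        name, _, ax = col.rpartition(":")
        if ax != "x":
            raise PDBFormatError(f"{path}: malformed header column {col!r}")
        chain, num = name[0], int(name[1:])
        labels.append((chain, num))
    rows = []
    for i, ln in enumerate(lines[1:], start=1):
        vals = np.array([float(v) for v in ln.split("\t")])
        if vals.size != len(cols):
            raise InconsistentEnsembleError(f"{path}: row {i} has {vals.size} values, expected {len(cols)}")
        rows.append(vals)
    return Ensemble(labels=labels, xyz=np.vstack(rows),
                    provenance={"source": str(path), "format": "table"})
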
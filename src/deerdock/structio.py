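"""PDB coordinate I/O, rigid-domain containers and superposition primitives.

Only protein heavy atoms are retained: hydrogens, HETATM records and waters
never enter any downstream computation (clash checks, scattering, label
frames).  Residues are indexed by author residue number, coordinates are in
Angstrom throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "DomainStructure",
    "Transform",
    "read_pdb",
    "write_pdb",
    "superpose",
    "rmsd_after_superposition",
]

#: atoms counted as "main chain" / "backbone" (used for RMSD and clustering)
MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """One heavy atom of a protein residue."""

    name: str
    element: str
    coord: np.ndarray  # (3,) float, Angstrom
    residue_number: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError("element must be non-empty")


class DomainStructure:
    """A rigid protein domain: an ordered list of heavy atoms.

    Provides residue-level lookup by ``(chain_id, residue_number)`` and
    convenience coordinate extraction for superposition and clash checks.
    """

    def __init__(self, atoms: Sequence[AtomRecord], label: str = ""):
        if not atoms:
            raise ValueError("empty structure: no atoms")
        self.atoms: list[AtomRecord] = list(atoms)
        self.label = label
        self._index: dict[tuple[str, int], list[AtomRecord]] = {}
        for a in self.atoms:
            self._index.setdefault((a.chain_id, a.residue_number), []).append(a)

    # -- residue access -------------------------------------------------
    def residue(self, residue_number: int, chain_id: str | None = None) -> list[AtomRecord]:
        """Atoms of one residue.  With ``chain_id=None`` the first chain
        containing the residue number is used."""
        if chain_id is not None:
            key = (chain_id, residue_number)
            if key not in self._index:
                raise KeyError(f"residue {chain_id}/{residue_number} not found")
            return self._index[key]
        for (ch, num), atoms in self._index.items():
            if num == residue_number:
                return atoms
        raise KeyError(f"residue {residue_number} not found in any chain")

    def residue_atom(self, residue_number: int, atom_name: str,
                     chain_id: str | None = None) -> AtomRecord:
        for a in self.residue(residue_number, chain_id):
            if a.name == atom_name:
                return a
        raise KeyError(f"atom {atom_name} missing in residue {residue_number}")

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return list(self._index.keys())

    @property
    def n_residues(self) -> int:
        return len(self._index)

    # -- coordinates -----------------------------------------------------
    def coords(self, atom_names: Iterable[str] | None = None,
               residue_range: tuple[int, int] | None = None,
               chain_id: str | None = None) -> np.ndarray:
        """(n, 3) array of coordinates, optionally restricted by atom name,
        author residue-number range (inclusive) and chain."""
        names = set(atom_names) if atom_names is not None else None
        out = []
        for a in self.atoms:
            if names is not None and a.name not in names:
                continue
            if residue_range is not None and not (
                    residue_range[0] <= a.residue_number <= residue_range[1]):
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.append(a.coord)
        return np.asarray(out, dtype=float).reshape(-1, 3)

    def transformed(self, transform: "Transform") -> "DomainStructure":
        """Copy of the structure under a rigid motion."""
        moved = [
            AtomRecord(a.name, a.element, transform.apply(a.coord),
                       a.residue_number, a.residue_name, a.chain_id)
            for a in self.atoms
        ]
        return DomainStructure(moved, label=self.label)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Transform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rinv = self.rotation.T
        return Transform(rinv, -rinv @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self o other)(x) = self(other(x))."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# PDB reading / writing

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path, chain_filter: set[str] | None = None,
             label: str = "") -> DomainStructure:
    """Read heavy-atom ATOM records of a PDB file.

    Alternate locations: the first-listed conformer of each atom is kept
    (blank altloc always kept).  HETATM and waters are skipped; hydrogens
    are skipped.

    Parameters
    ----------
    chain_filter:
        If given, only atoms of these chain identifiers are loaded.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    seen: set[tuple[str, int, str]] = set()  # (chain, resnum, atom name)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or " "
            if chain_filter is not None and chain not in chain_filter:
                continue
            if resname in _WATER_NAMES:
                continue
            element = line[76:78].strip() or name[:1]
            if element.upper() == "H" or name.startswith(("H", "1H", "2H", "3H")):
                continue
            resnum = int(line[22:26])
            key = (chain, resnum, name)
            if key in seen:
                continue  # later altloc conformer of an atom already kept
            if altloc not in ("", "A"):
                # non-first altloc appearing before 'A'/blank would be kept by
                # file order; standard PDB lists 'A' first so this drops B, C...
                continue
            seen.add(key)
            coord = np.array([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])])
            atoms.append(AtomRecord(name, element, coord, resnum, resname, chain))
    if not atoms:
        raise ValueError(f"{path}: no ATOM records after filtering")
    return DomainStructure(atoms, label=label or path.stem)


def write_pdb(structure: DomainStructure, path: str | Path,
              model_number: int | None = None) -> None:
    """Write ATOM records with 3-decimal coordinates (standard PDB precision)."""
    with open(path, "w") as fh:
        fh.write(format_pdb(structure, model_number))
        fh.write("END\n")


def format_pdb(structure: DomainStructure, model_number: int | None = None) -> str:
    lines = []
    if model_number is not None:
        lines.append(f"MODEL     {model_number:4d}")
    for i, a in enumerate(structure.atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain_id}"
            f"{a.residue_number:4d}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}"
            f"{a.coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("TER")
    if model_number is not None:
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Superposition (Kabsch)

def superpose(reference: np.ndarray, moving: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Returns the optimal proper rigid transform T and the post-fit RMSD, so
    that ``T.apply(moving)`` best matches ``reference``.  Point sets must be
    equal length and correspondence-ordered, with at least 3 non-collinear
    points.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"correspondence error: shapes {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = ref - ref_c
    q = mov - mov_c
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    # degenerate geometry: all points collinear -> rank < 2
    if np.sum(s > 1e-10 * max(s[0], 1e-300)) < 2:
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mov_c
    transform = Transform(rot, trans)
    diff = transform.apply(mov) - ref
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return transform, rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two correspondence-ordered coordinate sets after optimal
    rigid superposition (symmetric in its arguments)."""
    _, rmsd = superpose(np.asarray(a), np.asarray(b))
    return rmsd


def rmsd_direct(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition (used for pose clustering,
    where the shared fixed-domain frame is meaningful)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("correspondence error")
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
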
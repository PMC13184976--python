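"""Conformer data model, multi-model structure I/O and geometric primitives.

A :class:`ConformerPool` is an ordered collection of conformers that share
one atom topology (same atoms, same order), the natural container for
ensemble fitting where every conformer contributes one column to a design
matrix.  Atoms are addressed by ``(res_index, atom_name)`` selectors with
1-based residue numbering.  All coordinates are in Angstrom, all angles in
degrees; dihedrals follow the IUPAC sign convention (clockwise positive
looking from the second to the third atom) on (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    FormatError,
    SelectionError,
    TopologyError,
)

Selector = tuple[int, str]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass
class Atom:
    """A single atom record.

    Attributes
    ----------
    name:
        Atom label, e.g. ``"CA"`` or ``"HA1"``.
    element:
        Element symbol (``"C"``, ``"Br"``, ...).
    res_index:
        1-based residue number.
    res_name:
        Three-letter residue code.
    xyz:
        Cartesian coordinates in Angstrom.
    """

    name: str
    element: str
    res_index: int
    res_name: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise FormatError(
                f"atom {self.res_index}:{self.name} has non-finite coordinates"
            )
        if not self.element:
            raise FormatError(f"atom {self.res_index}:{self.name} has empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.capitalize() in _HYDROGEN_ELEMENTS

    def key(self) -> Selector:
        return (self.res_index, self.name)


class Conformer:
    """One structural model: an ordered list of atoms plus free-form labels."""

    def __init__(self, id: str, atoms: Sequence[Atom], labels: Iterable[str] = ()):
        self.id = str(id)
        self.atoms: list[Atom] = list(atoms)
        self.labels: set[str] = set(labels)
        self._index: dict[Selector, int] = {}
        for i, a in enumerate(self.atoms):
            self._index[a.key()] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Conformer({self.id!r}, {len(self.atoms)} atoms, labels={sorted(self.labels)})"

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a fresh copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyError("coordinate array shape does not match atom count")
        for atom, xyz in zip(self.atoms, coords):
            atom.xyz = xyz

    def atom(self, sel: Selector) -> Atom:
        try:
            return self.atoms[self._index[(int(sel[0]), str(sel[1]))]]
        except KeyError:
            raise SelectionError(
                f"no atom {sel[1]!r} in residue {sel[0]} of conformer {self.id!r}"
            ) from None

    def has_atom(self, sel: Selector) -> bool:
        return (int(sel[0]), str(sel[1])) in self._index

    def position(self, sel: Selector) -> np.ndarray:
        return self.atom(sel).xyz

    def residue_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for a in self.atoms:
            out.setdefault(a.res_index, a.res_name)
        return out

    def copy(self, id: str | None = None) -> "Conformer":
        atoms = [
            Atom(a.name, a.element, a.res_index, a.res_name, a.xyz.copy())
            for a in self.atoms
        ]
        return Conformer(id if id is not None else self.id, atoms, set(self.labels))


class ConformerPool:
    """Ordered, topology-consistent collection of conformers."""

    def __init__(self, conformers: Sequence[Conformer]):
        if not conformers:
            raise TopologyError("a conformer pool must contain at least one conformer")
        self.conformers: list[Conformer] = list(conformers)
        self._check_topology()

    def _check_topology(self) -> None:
        ref = self.conformers[0]
        ref_sig = [(a.res_index, a.name) for a in ref.atoms]
        seen_ids = set()
        for c in self.conformers:
            if c.id in seen_ids:
                raise TopologyError(f"duplicate conformer id {c.id!r} in pool")
            seen_ids.add(c.id)
            if len(c) != len(ref):
                raise TopologyError(
                    f"conformer {c.id!r} has {len(c)} atoms, expected {len(ref)}"
                )
            sig = [(a.res_index, a.name) for a in c.atoms]
            if sig != ref_sig:
                raise TopologyError(
                    f"conformer {c.id!r} atom names/order differ from the first model"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    def ids(self) -> list[str]:
        return [c.id for c in self.conformers]

    def subset(self, indices: Sequence[int]) -> "ConformerPool":
        return ConformerPool([self.conformers[i] for i in indices])

    def extended(self, extra: Sequence[Conformer]) -> "ConformerPool":
        return ConformerPool(self.conformers + list(extra))


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def distance(c: Conformer, i: Selector, j: Selector) -> float:
    """Euclidean distance in Angstrom between two selected atoms."""
    return float(np.linalg.norm(c.position(i) - c.position(j)))


def angle(c: Conformer, a: Selector, b: Selector, c2: Selector) -> float:
    """Vertex angle at *b* in degrees, in [0, 180]."""
    return angle_points(c.position(a), c.position(b), c.position(c2))


def angle_points(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> float:
    v1 = np.asarray(pa, float) - pb
    v2 = np.asarray(pc, float) - pb
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("coincident atoms in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(c: Conformer, a: Selector, b: Selector, c2: Selector, d: Selector) -> float:
    """Torsion a-b-c2-d in degrees on (-180, 180], IUPAC sign convention."""
    return dihedral_points(
        c.position(a), c.position(b), c.position(c2), c.position(d)
    )


def dihedral_points(
    pa: np.ndarray, pb: np.ndarray, pc: np.ndarray, pd: np.ndarray
) -> float:
    b1 = np.asarray(pb, float) - pa
    b2 = np.asarray(pc, float) - pb
    b3 = np.asarray(pd, float) - pc
    n2 = np.linalg.norm(b2)
    if n2 < 1e-9:
        raise DegenerateGeometryError("zero-length central bond in dihedral")
    c1 = np.cross(b1, b2)
    c2v = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-9 or np.linalg.norm(c2v) < 1e-9:
        raise DegenerateGeometryError("collinear atoms in dihedral computation")
    x = float(np.dot(c1, c2v))
    y = float(np.dot(np.cross(c1, b2 / n2), c2v))
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def heavy_atom_rmsd(c1: Conformer, c2: Conformer, superpose: bool = True) -> float:
    """RMSD over non-hydrogen atoms; optionally Kabsch-minimized.

    Both conformers must share topology.  With ``superpose=True`` the
    deviation is minimized over rigid-body rotations and translations
    (Kabsch, via :class:`scipy.spatial.transform.Rotation`).
    """
    if len(c1) != len(c2) or any(
        a.key() != b.key() for a, b in zip(c1.atoms, c2.atoms)
    ):
        raise TopologyError("conformers do not share topology for RMSD")
    mask = np.array([not a.is_hydrogen for a in c1.atoms], dtype=bool)
    x = c1.coords[mask]
    y = c2.coords[mask]
    if x.shape[0] == 0:
        raise TopologyError("no heavy atoms to compare")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    if x.shape[0] < 3:
        raise TopologyError("need at least 3 heavy atoms to superpose")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, _ = Rotation.align_vectors(xc, yc)
    y_rot = rot.apply(yc)
    return float(np.sqrt(np.mean(np.sum((xc - y_rot) ** 2, axis=1))))


def backbone_phi(c: Conformer, res: int) -> float:
    """Backbone phi torsion C(res-1)-N(res)-CA(res)-C(res)."""
    return dihedral(c, (res - 1, "C"), (res, "N"), (res, "CA"), (res, "C"))


def backbone_psi(c: Conformer, res: int) -> float:
    """Backbone psi torsion N(res)-CA(res)-C(res)-N(res+1)."""
    return dihedral(c, (res, "N"), (res, "CA"), (res, "C"), (res + 1, "N"))


# ---------------------------------------------------------------------------
# file I/O: multi-model PDB (via gemmi) and concatenated-frame XYZ
# ---------------------------------------------------------------------------

def read_conformer_pool(path: str | Path, format: str | None = None) -> ConformerPool:
    """Read a conformer pool from a multi-model PDB or multi-frame XYZ file.

    ``format`` is ``"pdb"`` or ``"xyz"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise FormatError(f"unsupported structure format {fmt!r}")


def write_conformer_pool(
    pool: ConformerPool, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        _write_pdb(pool, path)
    elif fmt == "xyz":
        _write_xyz(pool, path)
    else:
        raise FormatError(f"unsupported structure format {fmt!r}")


def _read_pdb(path: Path) -> ConformerPool:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse PDB {path}: {exc}") from exc
    conformers = []
    for model in st:
        atoms = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = atom.element.name if atom.element else ""
                    if not element or element == "X":
                        element = _element_from_name(atom.name)
                    atoms.append(
                        Atom(
                            name=atom.name,
                            element=element,
                            res_index=residue.seqid.num,
                            res_name=residue.name.strip(),
                            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
        if atoms:
            conformers.append(Conformer(str(model.num), atoms))
    if not conformers:
        raise FormatError(f"no models found in {path}")
    return ConformerPool(conformers)


_TWO_LETTER_ELEMENTS = {"BR", "CL", "SE"}


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _write_pdb(pool: ConformerPool, path: Path) -> None:
    st = gemmi.Structure()
    st.name = "hairpinxb pool"
    for i, c in enumerate(pool, start=1):
        model = gemmi.Model(i)  # PDB MODEL records are numeric
        chain = gemmi.Chain("A")
        current_res = None
        residue = None
        for serial, a in enumerate(c.atoms, start=1):
            if current_res != a.res_index:
                if residue is not None:
                    chain.add_residue(residue)
                residue = gemmi.Residue()
                residue.name = a.res_name
                residue.seqid = gemmi.SeqId(a.res_index, " ")
                current_res = a.res_index
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.xyz)
            atom.serial = serial
            residue.add_atom(atom)
        if residue is not None:
            chain.add_residue(residue)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _read_xyz(path: Path) -> ConformerPool:
    """Concatenated-frame XYZ: repeated (natoms / comment / atom lines) blocks.

    XYZ carries no residue information, so atoms land in residue 1 with
    names ``<element><ordinal>``.
    """
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    conformers = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        atoms = []
        for j in range(natoms):
            idx = i + 2 + j  # header, comment, then atom lines
            lineno = idx + 1
            if idx >= len(lines):
                raise FormatError(f"{path}: truncated frame at line {lineno}")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: malformed atom line")
            try:
                xyz = np.array([float(p) for p in parts[1:4]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from None
            el = parts[0].capitalize()
            atoms.append(Atom(f"{el.upper()}{j + 1}", el, 1, "UNK", xyz))
        frame += 1
        conformers.append(Conformer(str(frame), atoms))
        i += 2 + natoms
    if not conformers:
        raise FormatError(f"no frames found in {path}")
    return ConformerPool(conformers)


def _write_xyz(pool: ConformerPool, path: Path) -> None:
    with open(path, "w") as fh:
        for c in pool:
            fh.write(f"{len(c)}\n{c.id}\n")
            for a in c.atoms:
                fh.write(
                    f"{a.element:<2s} {a.xyz[0]:12.6f} {a.xyz[1]:12.6f} {a.xyz[2]:12.6f}\n"
                )
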
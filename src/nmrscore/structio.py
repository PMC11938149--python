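"""Structure I/O, atom selection, rigid-body superposition and renumbering.

Structures are stored column-wise (one numpy array per atom attribute) with a
coordinate block of shape ``(n_conformers, n_atoms, 3)``; MODEL/ENDMDL blocks
of a multi-model PDB become conformers sharing one topology.  Parsing and
serialisation are delegated to :mod:`biotite`; this module adds validation
with useful error locations, altloc reduction, selection expressions and the
Kabsch superposition used throughout the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParseError, SelectionError, SuperpositionError

logger = logging.getLogger(__name__)

#: Atom names making up the backbone class in selection expressions.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single atom of one conformer."""

    serial: int
    name: str
    element: str
    residue_id: tuple[str, int, str]  # (chain id, residue number, insertion code)
    residue_name: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Structure:
    """A molecular structure with one or more conformers sharing a topology.

    Conformer indices are 1-based throughout the public API.
    """

    chain_ids: np.ndarray
    res_nums: np.ndarray
    icodes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    serials: np.ndarray
    hetero: np.ndarray
    coords: np.ndarray  # (n_conformers, n_atoms, 3)
    original_res_nums: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_conformers, n_atoms, 3)")
        n = self.coords.shape[1]
        for name in ("chain_ids", "res_nums", "icodes", "res_names",
                     "atom_names", "elements", "serials", "hetero"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} entries, expected {n}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(np.char.upper(self.elements.astype(str)), list(_HYDROGEN_ELEMENTS))

    def conformer_coords(self, conformer: int = 1) -> np.ndarray:
        """Coordinates of one conformer (1-based index)."""
        if not 1 <= conformer <= self.n_conformers:
            raise IndexError(
                f"conformer {conformer} out of range 1..{self.n_conformers}")
        return self.coords[conformer - 1]

    def atom(self, index: int, conformer: int = 1) -> Atom:
        return Atom(
            serial=int(self.serials[index]),
            name=str(self.atom_names[index]),
            element=str(self.elements[index]),
            residue_id=(str(self.chain_ids[index]), int(self.res_nums[index]),
                        str(self.icodes[index])),
            residue_name=str(self.res_names[index]),
            coords=self.conformer_coords(conformer)[index],
        )

    def residue_ids(self, indices: np.ndarray | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique residue identifiers over the given atom indices."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        seen: dict[tuple[str, int, str], None] = {}
        for i in idx:
            key = (str(self.chain_ids[i]), int(self.res_nums[i]), str(self.icodes[i]))
            seen.setdefault(key, None)
        return list(seen)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)


@dataclass(frozen=True)
class AtomSet:
    """An ordered subset of the atoms of one conformer of a :class:`Structure`."""

    structure: Structure
    conformer: int
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and (idx.min() < 0 or idx.max() >= self.structure.n_atoms):
            raise IndexError("atom indices out of bounds")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("atom indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.conformer_coords(self.conformer)[self.indices]


@dataclass(frozen=True)
class Superposition:
    """A rigid-body transform fitting a mobile set onto a reference."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Cheap pre-scan of a PDB file giving line-accurate errors.

    Checks that every ATOM/HETATM record is long enough and carries numeric
    coordinates, and that all MODEL blocks contain the same number of atom
    records.
    """
    model_counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    n_loose = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}: line {lineno}: truncated {rec} record")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric coordinate field")
                if in_model:
                    current += 1
                else:
                    n_loose += 1
            elif rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                in_model = False
                model_counts.append(current)
    if in_model:
        model_counts.append(current)
    if saw_model:
        counts = model_counts
        if not counts or counts[0] == 0:
            raise ParseError(f"{path}: no atom records found")
        for m, c in enumerate(counts, start=1):
            if c != counts[0]:
                raise ParseError(
                    f"{path}: model {m} has {c} atoms, expected {counts[0]}")
    elif n_loose == 0:
        raise ParseError(f"{path}: no atom records found")


def _from_biotite(atoms) -> Structure:
    """Convert a biotite AtomArray / AtomArrayStack to a :class:`Structure`."""
    import biotite.structure as struc

    if isinstance(atoms, struc.AtomArray):
        coords = atoms.coord[np.newaxis]
        first = atoms
    else:
        coords = atoms.coord
        first = atoms[0]
    n = first.array_length()
    serials = (first.atom_id if "atom_id" in first.get_annotation_categories()
               else np.arange(1, n + 1))
    return Structure(
        chain_ids=first.chain_id.astype(str),
        res_nums=first.res_id.astype(int),
        icodes=first.ins_code.astype(str),
        res_names=first.res_name.astype(str),
        atom_names=first.atom_name.astype(str),
        elements=first.element.astype(str),
        serials=np.asarray(serials, dtype=int),
        hetero=first.hetero.astype(bool),
        coords=np.asarray(coords, dtype=float),
    )


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    MODEL/ENDMDL blocks become conformers; hydrogens are retained.  For
    alternate locations only the highest-occupancy altloc is kept.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"`` or ``"mmcif"``; inferred from the suffix when ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")

    if format == "pdb":
        _validate_pdb_text(path)
        import biotite.structure.io.pdb as pdbio
        try:
            pfile = pdbio.PDBFile.read(str(path))
            try:
                atoms = pfile.get_structure(
                    model=None, altloc="occupancy", extra_fields=["atom_id"])
            except Exception:
                atoms = pfile.get_structure(
                    model=None, altloc="first", extra_fields=["atom_id"])
        except ParseError:
            raise
        except Exception as exc:  # biotite raises various error types
            raise ParseError(f"{path}: {exc}") from exc
    else:
        import biotite.structure.io.pdbx as pdbx
        try:
            cfile = pdbx.CIFFile.read(str(path))
            try:
                atoms = pdbx.get_structure(cfile, model=None, altloc="occupancy")
            except Exception:
                atoms = pdbx.get_structure(cfile, model=None, altloc="first")
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return _from_biotite(atoms)


def write_structure(structure: Structure, path: str | Path,
                    header_remarks: Sequence[str] = ()) -> None:
    """Write a structure as a (multi-model) PDB file.

    ``header_remarks`` lines are emitted as REMARK records before the first
    model, e.g. to record a generator seed.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = structure.n_atoms
    stack = struc.AtomArrayStack(structure.n_conformers, n)
    stack.coord[:] = structure.coords
    stack.chain_id = structure.chain_ids.astype("U4")
    stack.res_id = structure.res_nums.astype(int)
    stack.ins_code = structure.icodes.astype("U1")
    stack.res_name = structure.res_names.astype("U5")
    stack.atom_name = structure.atom_names.astype("U6")
    stack.element = structure.elements.astype("U2")
    stack.hetero = structure.hetero.astype(bool)
    pfile = pdbio.PDBFile()
    pfile.set_structure(stack)
    pfile.write(str(path))
    if header_remarks:
        body = Path(path).read_text()
        head = "".join(f"REMARK 300 {line}\n" for line in header_remarks)
        Path(path).write_text(head + body)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def select(structure: Structure, expr: str, conformer: int = 1) -> AtomSet:
    """Select atoms with a small expression grammar.

    Clauses are joined with ``and``:

    - ``chain A`` / ``chain A B`` — one or more chain ids
    - ``resi 11-90`` / ``resi 5 7 9-12`` — residue numbers/ranges
    - ``name CA CB`` — explicit atom names
    - ``backbone`` — N, CA, C, O
    - ``heavy`` — non-hydrogen atoms
    - ``noh`` — alias of ``heavy``; ``hydrogen`` — hydrogens only
    - ``all`` — no-op
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    clauses = [c.strip() for c in re.split(r"\band\b", expr) if c.strip()]
    if not clauses:
        raise SelectionError(f"empty selection expression: {expr!r}")
    for clause in clauses:
        tokens = clause.split()
        head, args = tokens[0].lower(), tokens[1:]
        if head == "chain":
            if not args:
                raise SelectionError(f"'chain' needs at least one id: {clause!r}")
            m = np.isin(structure.chain_ids.astype(str), args)
            if not m.any():
                logger.warning("selection %r matches no chains of %s",
                               clause, structure.chains())
            mask &= m
        elif head == "resi":
            if not args:
                raise SelectionError(f"'resi' needs residue numbers: {clause!r}")
            m = np.zeros(structure.n_atoms, dtype=bool)
            for token in args:
                g = _RANGE_RE.match(token)
                if not g:
                    raise SelectionError(f"bad residue range {token!r} in {clause!r}")
                lo = int(g.group(1))
                hi = int(g.group(2)) if g.group(2) is not None else lo
                m |= (structure.res_nums >= lo) & (structure.res_nums <= hi)
            mask &= m
        elif head == "name":
            if not args:
                raise SelectionError(f"'name' needs atom names: {clause!r}")
            mask &= np.isin(structure.atom_names.astype(str), args)
        elif head == "backbone":
            if args:
                raise SelectionError(f"'backbone' takes no arguments: {clause!r}")
            mask &= np.isin(structure.atom_names.astype(str), BACKBONE_ATOMS)
        elif head in ("heavy", "noh"):
            if args:
                raise SelectionError(f"{head!r} takes no arguments: {clause!r}")
            mask &= ~structure.is_hydrogen
        elif head == "hydrogen":
            mask &= structure.is_hydrogen
        elif head == "all":
            if args:
                raise SelectionError(f"'all' takes no arguments: {clause!r}")
        else:
            raise SelectionError(f"unknown selection keyword {head!r} in {expr!r}")
    return AtomSet(structure, conformer, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _paired_coords(mobile, reference) -> tuple[np.ndarray, np.ndarray]:
    x = mobile.coords if isinstance(mobile, AtomSet) else np.asarray(mobile, dtype=float)
    y = (reference.coords if isinstance(reference, AtomSet)
         else np.asarray(reference, dtype=float))
    if x.shape != y.shape:
        raise SuperpositionError(
            f"atom count mismatch: {x.shape[0]} vs {y.shape[0]}")
    return x, y


def superpose(mobile: AtomSet | np.ndarray,
              reference: AtomSet | np.ndarray) -> Superposition:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Atoms are paired by list order.  Reflections are excluded, so the
    returned rotation always has determinant +1.
    """
    x, y = _paired_coords(mobile, reference)
    if x.shape[0] < 3:
        raise SuperpositionError("need at least 3 atoms to superpose")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise SuperpositionError("need at least 3 non-collinear atoms")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_between(a: AtomSet | np.ndarray, b: AtomSet | np.ndarray,
                 fit: bool = False) -> float:
    """RMSD between two equally-sized atom sets, optionally after superposition."""
    if fit:
        return superpose(a, b).rmsd
    x, y = _paired_coords(a, b)
    if x.shape[0] == 0:
        raise SuperpositionError("empty atom sets")
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Renumbering
# ---------------------------------------------------------------------------

def renumber(structure: Structure, offsets: Mapping[str, int]) -> Structure:
    """Shift residue numbers per chain; originals are kept as metadata.

    Raises :class:`DataError` if the shift makes two residues of one chain
    collide (possible only in the presence of insertion codes).
    """
    from .errors import DataError

    for chain, off in offsets.items():
        if int(off) != off:
            raise DataError(f"offset for chain {chain!r} must be an integer")
    new_nums = structure.res_nums.copy()
    for chain, off in offsets.items():
        new_nums[structure.chain_ids.astype(str) == chain] += int(off)
    keys = set()
    for c, n, i in zip(structure.chain_ids, new_nums, structure.icodes):
        keys.add((str(c), int(n), str(i)))
    old_keys = {(str(c), int(n), str(i)) for c, n, i in
                zip(structure.chain_ids, structure.res_nums, structure.icodes)}
    if len(keys) != len(old_keys):
        raise DataError("renumbering collides with existing insertion codes")
    original = (structure.original_res_nums if structure.original_res_nums is not None
                else structure.res_nums.copy())
    return replace(structure, res_nums=new_nums, original_res_nums=original)
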
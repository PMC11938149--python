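"""Interface extraction, contact classification and surface-area computation.

Interface residues of a two-partner complex are those with any atom within a
distance cutoff (default 5 A, hydrogens included) of the partner.  Solvent
accessible surface areas use a deterministic Shrake-Rupley quadrature with a
golden-spiral point set; buried area is SASA(A) + SASA(B) - SASA(AB).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError
from .structio import Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Heavy elements considered polar for contact classification.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

_H_BOND_MAX = 1.3  # A; hydrogens inherit the class of the heavy atom this close

ResidueKey = tuple[str, int]  # (chain id, residue number)


@dataclass(frozen=True)
class InterfaceSet:
    """Interface residue sets of the two partners of a complex."""

    label_a: str
    label_b: str
    residues_a: frozenset[ResidueKey]
    residues_b: frozenset[ResidueKey]
    cutoff: float
    hydrogens_used: bool

    def numbers(self, side: str) -> frozenset[int]:
        """Residue numbers only (chain collapsed) of one side ('a' or 'b')."""
        residues = self.residues_a if side.lower() == "a" else self.residues_b
        return frozenset(num for _, num in residues)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("partner\tchain\tresidue\n")
            for label, residues in ((self.label_a, self.residues_a),
                                    (self.label_b, self.residues_b)):
                for chain, num in sorted(residues):
                    fh.write(f"{label}\t{chain}\t{num}\n")


@dataclass(frozen=True)
class ContactPair:
    """A contacting residue pair with its minimum interatomic distance."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float
    polarity: str  # polar | nonpolar


@dataclass
class SasaResult:
    """Shrake-Rupley solvent accessible surface areas."""

    atom_areas: np.ndarray  # per included atom, A^2 (0 for excluded atoms)
    residue_areas: dict[ResidueKey, float]
    total: float
    probe: float
    n_points: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _load_radius_table() -> tuple[dict[str, float], float]:
    raw = json.loads(
        resources.files("nmrscore.data").joinpath("vdw_radii.json").read_text())
    return {k.upper(): float(v) for k, v in raw["radii"].items()}, float(raw["default"])


_RADII, _RADIUS_DEFAULT = _load_radius_table()


def vdw_radius(element: str, default: float | None = None) -> float:
    return _RADII.get(element.upper(),
                      _RADIUS_DEFAULT if default is None else default)


def _chain_mask(s: Structure, chains: Sequence[str]) -> np.ndarray:
    return np.isin(s.chain_ids.astype(str), list(chains))


def _standard_mask(s: Structure, include_hetero: bool) -> np.ndarray:
    return np.ones(s.n_atoms, bool) if include_hetero else ~s.hetero


def _check_partner_chains(s: Structure, chains_a: Sequence[str],
                          chains_b: Sequence[str]) -> None:
    overlap = set(chains_a) & set(chains_b)
    if overlap:
        raise DataError(f"partner chain sets overlap: {sorted(overlap)}")
    present = set(s.chains())
    missing = (set(chains_a) | set(chains_b)) - present
    if missing:
        raise DataError(
            f"chains {sorted(missing)} not present (structure has {sorted(present)})")


def _atom_polar_classes(s: Structure, conformer: int) -> np.ndarray:
    """Per-atom polarity; hydrogens inherit their bonded heavy atom's class."""
    elements = np.char.upper(s.elements.astype(str))
    polar = np.isin(elements, list(POLAR_ELEMENTS))
    hydro = s.is_hydrogen
    if not hydro.any():
        return polar
    coords = s.conformer_coords(conformer)
    heavy_idx = np.flatnonzero(~hydro)
    tree = cKDTree(coords[heavy_idx])
    dist, nearest = tree.query(coords[hydro], k=1,
                               distance_upper_bound=_H_BOND_MAX)
    h_idx = np.flatnonzero(hydro)
    for pos, (d, j) in enumerate(zip(dist, nearest)):
        if np.isfinite(d):
            polar[h_idx[pos]] = polar[heavy_idx[j]]
    return polar


def _inter_chain_pairs(s: Structure, chains_a, chains_b, cutoff, include_h,
                       include_hetero, conformer):
    """Atom-index pairs (ia, ib) across the two partners within cutoff."""
    _check_partner_chains(s, chains_a, chains_b)
    base = _standard_mask(s, include_hetero)
    hydrogens_used = include_h
    if include_h and not s.is_hydrogen.any():
        logger.warning(
            "structure has no hydrogens; falling back to heavy atoms at the "
            "same %.1f A cutoff", cutoff)
        hydrogens_used = False
    if not include_h:
        base &= ~s.is_hydrogen
        hydrogens_used = False
    mask_a = base & _chain_mask(s, chains_a)
    mask_b = base & _chain_mask(s, chains_b)
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    coords = s.conformer_coords(conformer)
    pairs = []
    if idx_a.size and idx_b.size:
        tree_a = cKDTree(coords[idx_a])
        tree_b = cKDTree(coords[idx_b])
        for ia_local, blist in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
            for ib_local in blist:
                pairs.append((idx_a[ia_local], idx_b[ib_local]))
    return pairs, coords, hydrogens_used


def _residue_key(s: Structure, i: int) -> ResidueKey:
    return (str(s.chain_ids[i]), int(s.res_nums[i]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def interface_residues(s: Structure, chains_a: Sequence[str],
                       chains_b: Sequence[str], cutoff: float = DEFAULT_CUTOFF,
                       include_h: bool = True, include_hetero: bool = False,
                       conformer: int = 1,
                       label_a: str = "A", label_b: str = "B") -> InterfaceSet:
    """Residues of each partner with any atom within ``cutoff`` of the other.

    If ``include_h`` is set but the structure lacks hydrogens, heavy atoms
    are used at the unchanged cutoff and a warning is logged.
    """
    pairs, _, hydrogens_used = _inter_chain_pairs(
        s, chains_a, chains_b, cutoff, include_h, include_hetero, conformer)
    res_a = frozenset(_residue_key(s, ia) for ia, _ in pairs)
    res_b = frozenset(_residue_key(s, ib) for _, ib in pairs)
    return InterfaceSet(label_a=label_a, label_b=label_b,
                        residues_a=res_a, residues_b=res_b,
                        cutoff=cutoff, hydrogens_used=hydrogens_used)


def contact_pairs(s: Structure, chains_a: Sequence[str], chains_b: Sequence[str],
                  cutoff: float = DEFAULT_CUTOFF, include_h: bool = True,
                  include_hetero: bool = False,
                  conformer: int = 1) -> list[ContactPair]:
    """One record per contacting residue pair, with min distance and polarity.

    A pair is *polar* when at least one of its atom contacts within the
    cutoff has polar atoms (N/O/S, or hydrogens bonded to them) on both
    sides; otherwise *nonpolar*.
    """
    pairs, coords, _ = _inter_chain_pairs(
        s, chains_a, chains_b, cutoff, include_h, include_hetero, conformer)
    polar = _atom_polar_classes(s, conformer)
    best: dict[tuple[ResidueKey, ResidueKey], tuple[float, bool]] = {}
    for ia, ib in pairs:
        key = (_residue_key(s, ia), _residue_key(s, ib))
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        is_polar = bool(polar[ia] and polar[ib])
        if key in best:
            prev_d, prev_p = best[key]
            best[key] = (min(prev_d, d), prev_p or is_polar)
        else:
            best[key] = (d, is_polar)
    return [ContactPair(residue_a=ka, residue_b=kb, min_distance=d,
                        polarity="polar" if p else "nonpolar")
            for (ka, kb), (d, p) in sorted(best.items())]


def contact_pairs_to_tsv(pairs: Sequence[ContactPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_a\tres_a\tchain_b\tres_b\tmin_distance\tpolarity\n")
        for p in pairs:
            fh.write(f"{p.residue_a[0]}\t{p.residue_a[1]}\t{p.residue_b[0]}\t"
                     f"{p.residue_b[1]}\t{p.min_distance:.3f}\t{p.polarity}\n")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(s: Structure, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS, conformer: int = 1,
         include_hetero: bool = False, include_h: bool = False,
         radii: Mapping[str, float] | None = None,
         default_radius: float | None = None,
         atom_mask: np.ndarray | None = None) -> SasaResult:
    """Shrake-Rupley solvent accessible surface area.

    Heavy atoms only by default (hydrogens carry no area of their own in the
    standard protocol); deterministic given the point count.
    """
    include = _standard_mask(s, include_hetero)
    if not include_h:
        include &= ~s.is_hydrogen
    if atom_mask is not None:
        include &= np.asarray(atom_mask, bool)
    idx = np.flatnonzero(include)
    if idx.size == 0:
        raise DataError("no atoms to compute SASA on")
    coords = s.conformer_coords(conformer)[idx]
    table = _RADII if radii is None else {k.upper(): float(v) for k, v in radii.items()}
    rad = np.array([table.get(str(e).upper(),
                              _RADIUS_DEFAULT if default_radius is None else default_radius)
                    for e in s.elements[idx]])
    expanded = rad + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(s.n_atoms)
    for local_i in range(idx.size):
        center = coords[local_i]
        r_i = expanded[local_i]
        neigh = [j for j in tree.query_ball_point(center, r_i + expanded.max())
                 if j != local_i]
        surface = center + r_i * pts
        accessible = np.ones(n_points, bool)
        for j in neigh:
            d = np.linalg.norm(surface - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        areas[idx[local_i]] = (4.0 * np.pi * r_i ** 2
                               * accessible.sum() / n_points)
    residue_areas: dict[ResidueKey, float] = {}
    for i in idx:
        key = _residue_key(s, i)
        residue_areas[key] = residue_areas.get(key, 0.0) + float(areas[i])
    return SasaResult(atom_areas=areas, residue_areas=residue_areas,
                      total=float(areas.sum()), probe=probe, n_points=n_points)


def buried_area(s: Structure, chains_a: Sequence[str], chains_b: Sequence[str],
                probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
                conformer: int = 1, include_hetero: bool = False) -> float:
    """Buried area SASA(A) + SASA(B) - SASA(AB), chains kept in place."""
    _check_partner_chains(s, chains_a, chains_b)
    mask_a = _chain_mask(s, chains_a)
    mask_b = _chain_mask(s, chains_b)
    kwargs = dict(probe=probe, n_points=n_points, conformer=conformer,
                  include_hetero=include_hetero)
    sasa_a = sasa(s, atom_mask=mask_a, **kwargs).total
    sasa_b = sasa(s, atom_mask=mask_b, **kwargs).total
    sasa_ab = sasa(s, atom_mask=mask_a | mask_b, **kwargs).total
    return sasa_a + sasa_b - sasa_ab
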
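"""Trajectory analysis: contact frequencies, hydrogen bonds, RMSD, clustering.

A :class:`Trajectory` wraps a multi-conformer :class:`~nmrscore.structio.Structure`
whose conformers are the frames.  Frame indices are 1-based; analysis windows
default to all frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .errors import DataError
from .structio import Structure, read_structure, select, superpose

logger = logging.getLogger(__name__)

DEFAULT_HBOND_DIST = 3.0  # A, donor-acceptor
DEFAULT_HBOND_ANGLE = 20.0  # degrees of deviation from D-H...A linearity
_DONOR_H_MAX = 1.2  # A; bond inference distance for donor hydrogens

ResidueKey = tuple[str, int]


@dataclass
class Trajectory:
    """An ordered series of frames sharing one topology."""

    structure: Structure
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        if self.structure.n_conformers < 1:
            raise DataError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.structure.n_conformers

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` (1-based)."""
        return self.structure.conformer_coords(i)


@dataclass(frozen=True)
class ContactMap:
    """Per-residue-pair contact frequencies over an analysis window."""

    frequencies: dict[tuple[ResidueKey, ResidueKey], float]  # percent
    window: tuple[int, int]
    cutoff: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain_a\tres_a\tchain_b\tres_b\tfrequency\n")
            for (ka, kb), freq in sorted(self.frequencies.items()):
                fh.write(f"{ka[0]}\t{ka[1]}\t{kb[0]}\t{kb[1]}\t{freq:.2f}\n")


@dataclass(frozen=True)
class HBondRecord:
    """One donor-H...acceptor interaction aggregated over frames."""

    donor: int  # atom indices into the topology
    hydrogen: int
    acceptor: int
    mean_distance: float  # D-A, over frames where detected
    mean_deviation: float  # degrees from linearity, over frames where detected
    frequency: float  # percent of window frames


@dataclass(frozen=True)
class ClusterResult:
    """Hierarchical clustering of trajectory frames."""

    labels: np.ndarray  # per-frame cluster label (1-based frames -> labels[i-1])
    cluster_sizes: dict[int, int]
    representative_frame: int  # 1-based
    linkage: str
    threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "labels": [int(x) for x in self.labels],
            "cluster_sizes": {str(k): int(v) for k, v in self.cluster_sizes.items()},
            "representative_frame": self.representative_frame,
            "linkage": self.linkage,
            "threshold": self.threshold,
        }, indent=1))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_trajectory(source: str | Path, dt_ps: float | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a directory of PDB frames.

    Directory frames are ordered lexicographically by file name; an atom
    count mismatch is a hard error naming the offending frame.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise DataError(f"{source}: no PDB frames found")
        structures = [read_structure(p) for p in files]
        n0 = structures[0].n_atoms
        for k, st in enumerate(structures, start=1):
            if st.n_atoms != n0:
                raise DataError(
                    f"frame {k} ({files[k - 1].name}) has {st.n_atoms} atoms, "
                    f"expected {n0}")
        coords = np.concatenate([st.coords for st in structures], axis=0)
        base = structures[0]
        merged = Structure(
            chain_ids=base.chain_ids, res_nums=base.res_nums, icodes=base.icodes,
            res_names=base.res_names, atom_names=base.atom_names,
            elements=base.elements, serials=base.serials, hetero=base.hetero,
            coords=coords)
        return Trajectory(structure=merged, dt_ps=dt_ps)
    return Trajectory(structure=read_structure(source), dt_ps=dt_ps)


def _resolve_window(traj: Trajectory,
                    window: tuple[int, int] | None) -> tuple[int, int]:
    if window is None:
        return (1, traj.n_frames)
    lo, hi = int(window[0]), int(window[1])
    if not (1 <= lo <= hi <= traj.n_frames):
        raise DataError(
            f"window {window} outside frames 1..{traj.n_frames}")
    return (lo, hi)


def last_fraction_window(traj: Trajectory, fraction: float = 0.5) -> tuple[int, int]:
    """The last ``fraction`` of frames, e.g. the converged tail of a run."""
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    start = traj.n_frames - max(1, int(round(traj.n_frames * fraction))) + 1
    return (max(1, start), traj.n_frames)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_frequency(traj: Trajectory, chains_a: Sequence[str],
                      chains_b: Sequence[str], cutoff: float = 5.0,
                      window: tuple[int, int] | None = None,
                      include_h: bool = True) -> ContactMap:
    """Percent of window frames in which each residue pair has any-atom
    contact within ``cutoff``.  Pairs are unordered (A-side first) and
    counted once per frame."""
    lo, hi = _resolve_window(traj, window)
    s = traj.structure
    base = ~s.hetero
    if not include_h:
        base &= ~s.is_hydrogen
    mask_a = base & np.isin(s.chain_ids.astype(str), list(chains_a))
    mask_b = base & np.isin(s.chain_ids.astype(str), list(chains_b))
    if not mask_a.any() or not mask_b.any():
        raise DataError("one of the partner selections is empty")
    idx_a, idx_b = np.flatnonzero(mask_a), np.flatnonzero(mask_b)
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    n_frames = hi - lo + 1
    for f in range(lo, hi + 1):
        coords = traj.frame(f)
        tree_a = cKDTree(coords[idx_a])
        tree_b = cKDTree(coords[idx_b])
        seen: set[tuple[ResidueKey, ResidueKey]] = set()
        for ia_local, blist in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
            ia = idx_a[ia_local]
            ka = (str(s.chain_ids[ia]), int(s.res_nums[ia]))
            for ib_local in blist:
                ib = idx_b[ib_local]
                seen.add((ka, (str(s.chain_ids[ib]), int(s.res_nums[ib]))))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    freqs = {key: 100.0 * c / n_frames for key, c in counts.items()}
    return ContactMap(frequencies=freqs, window=(lo, hi), cutoff=cutoff)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donors_and_acceptors(s: Structure, mask: np.ndarray):
    """Donor (D, H) pairs and acceptor indices within ``mask``.

    Donors/acceptors are N or O heavy atoms; donor hydrogens are inferred by
    distance (H within 1.2 A of the heavy atom) from frame-1 geometry.
    """
    elements = np.char.upper(s.elements.astype(str))
    no_mask = mask & np.isin(elements, ["N", "O"])
    h_mask = mask & s.is_hydrogen
    coords = s.conformer_coords(1)
    donors: list[tuple[int, int]] = []
    if h_mask.any() and no_mask.any():
        no_idx = np.flatnonzero(no_mask)
        tree = cKDTree(coords[no_idx])
        for h in np.flatnonzero(h_mask):
            dist, j = tree.query(coords[h], k=1, distance_upper_bound=_DONOR_H_MAX)
            if np.isfinite(dist):
                donors.append((int(no_idx[j]), int(h)))
    acceptors = np.flatnonzero(no_mask)
    return donors, acceptors


def hbonds(traj: Trajectory, chains_a: Sequence[str], chains_b: Sequence[str],
           d_cut: float = DEFAULT_HBOND_DIST,
           ang_cut: float = DEFAULT_HBOND_ANGLE,
           window: tuple[int, int] | None = None) -> list[HBondRecord]:
    """Inter-chain hydrogen bonds detected per frame and aggregated.

    Per-frame criterion: donor-acceptor distance <= ``d_cut`` AND deviation
    of the D-H...A angle from linearity <= ``ang_cut`` degrees.  Requires
    explicit hydrogens.
    """
    s = traj.structure
    if not s.is_hydrogen.any():
        raise DataError(
            "hydrogen-bond analysis requires explicit hydrogens; protonate "
            "the structure first")
    lo, hi = _resolve_window(traj, window)
    base = ~s.hetero
    mask_a = base & np.isin(s.chain_ids.astype(str), list(chains_a))
    mask_b = base & np.isin(s.chain_ids.astype(str), list(chains_b))
    donors_a, acc_a = _donors_and_acceptors(s, mask_a)
    donors_b, acc_b = _donors_and_acceptors(s, mask_b)
    # candidate triples in both directions (donor on A -> acceptor on B, etc.)
    candidates = ([(d, h, a) for d, h in donors_a for a in acc_b]
                  + [(d, h, a) for d, h in donors_b for a in acc_a])
    stats: dict[tuple[int, int, int], list] = {}
    n_frames = hi - lo + 1
    for f in range(lo, hi + 1):
        coords = traj.frame(f)
        for d, h, a in candidates:
            da = float(np.linalg.norm(coords[d] - coords[a]))
            if da > d_cut:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
            deviation = 180.0 - np.degrees(np.arccos(cosang))
            if deviation > ang_cut:
                continue
            rec = stats.setdefault((d, h, a), [0, 0.0, 0.0])
            rec[0] += 1
            rec[1] += da
            rec[2] += deviation
    records = [
        HBondRecord(donor=d, hydrogen=h, acceptor=a,
                    mean_distance=tot_d / n, mean_deviation=tot_ang / n,
                    frequency=100.0 * n / n_frames)
        for (d, h, a), (n, tot_d, tot_ang) in sorted(stats.items())]
    return records


def hbonds_to_tsv(traj: Trajectory, records: Sequence[HBondRecord],
                  path: str | Path) -> None:
    s = traj.structure
    with open(path, "w") as fh:
        fh.write("donor\thydrogen\tacceptor\tmean_distance\tmean_deviation\tfrequency\n")
        for r in records:
            def tag(i: int) -> str:
                return (f"{s.chain_ids[i]}/{s.res_names[i]}{s.res_nums[i]}/"
                        f"{s.atom_names[i]}")
            fh.write(f"{tag(r.donor)}\t{tag(r.hydrogen)}\t{tag(r.acceptor)}\t"
                     f"{r.mean_distance:.3f}\t{r.mean_deviation:.2f}\t"
                     f"{r.frequency:.2f}\n")


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def ligand_rmsd_series(traj: Trajectory, receptor_sel: str, ligand_sel: str,
                       exclude: Sequence[tuple[int, int]] = (),
                       reference_frame: int = 1,
                       window: tuple[int, int] | None = None,
                       ) -> tuple[np.ndarray, float]:
    """Receptor-aligned ligand RMSD per frame, plus the window mean.

    Each frame is superposed onto the reference frame using the receptor
    selection; the RMSD is then computed over the ligand selection with the
    ``exclude`` residue ranges (e.g. flexible tails) removed.
    """
    s = traj.structure
    rec = select(s, receptor_sel)
    lig = select(s, ligand_sel)
    if len(rec) == 0:
        raise DataError("empty receptor selection")
    lig_idx = lig.indices
    for lo_r, hi_r in exclude:
        keep = ~((s.res_nums[lig_idx] >= lo_r) & (s.res_nums[lig_idx] <= hi_r))
        lig_idx = lig_idx[keep]
    if lig_idx.size == 0:
        raise DataError("ligand selection empty after tail exclusion")
    ref_coords = traj.frame(reference_frame)
    ref_rec = ref_coords[rec.indices]
    ref_lig = ref_coords[lig_idx]
    values = np.empty(traj.n_frames)
    for f in range(1, traj.n_frames + 1):
        coords = traj.frame(f)
        sup = superpose(coords[rec.indices], ref_rec)
        moved = sup.apply(coords[lig_idx])
        values[f - 1] = np.sqrt(np.mean(np.sum((moved - ref_lig) ** 2, axis=1)))
    lo, hi = _resolve_window(traj, window)
    return values, float(values[lo - 1:hi].mean())


def rmsd_series_to_tsv(values: np.ndarray, path: str | Path,
                       dt_ps: float | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("frame\ttime_ps\trmsd\n" if dt_ps else "frame\trmsd\n")
        for i, v in enumerate(values, start=1):
            if dt_ps:
                fh.write(f"{i}\t{(i - 1) * dt_ps:.1f}\t{v:.4f}\n")
            else:
                fh.write(f"{i}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_frames(traj: Trajectory, selection: str,
                   linkage: str = "average", threshold: float = 2.0,
                   align_sel: str | None = None) -> ClusterResult:
    """Agglomerative clustering of frames on a pairwise RMSD matrix.

    When ``align_sel`` is given, every frame is first superposed onto frame 1
    by that selection and RMSDs are computed in the common frame; otherwise
    each pair is best-fit on ``selection``.  The representative is the frame
    closest to the coordinate-wise mean of the most populated cluster (ties:
    lowest frame index; equally-populated clusters: the one containing the
    lowest frame index).
    """
    if threshold <= 0:
        raise DataError("threshold must be > 0")
    if traj.n_frames < 2:
        raise DataError("need at least 2 frames to cluster")
    s = traj.structure
    sel = select(s, selection)
    if len(sel) == 0:
        raise DataError("empty clustering selection")
    n = traj.n_frames
    if align_sel is not None:
        ref = traj.frame(1)
        align_idx = select(s, align_sel).indices
        coords = np.empty((n, len(sel), 3))
        for f in range(1, n + 1):
            fc = traj.frame(f)
            sup = superpose(fc[align_idx], ref[align_idx])
            coords[f - 1] = sup.apply(fc[sel.indices])
        diffs = coords[:, None, :, :] - coords[None, :, :, :]
        dmat = np.sqrt(np.mean(np.sum(diffs ** 2, axis=-1), axis=-1))
    else:
        frames = [traj.frame(f)[sel.indices] for f in range(1, n + 1)]
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = frames[i] - frames[j]
                raw = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
                if raw > 1e-9 and len(sel) >= 3:
                    try:
                        raw = superpose(frames[i], frames[j]).rmsd
                    except Exception:
                        pass
                dmat[i, j] = dmat[j, i] = raw
        coords = np.stack(frames)
    z = scipy_linkage(squareform(dmat, checks=False), method=linkage)
    labels = fcluster(z, t=threshold, criterion="distance")
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[int(lab)] = sizes.get(int(lab), 0) + 1
    max_size = max(sizes.values())
    # among equally populated clusters, take the one with the lowest frame index
    best_label = None
    for i, lab in enumerate(labels):
        if sizes[int(lab)] == max_size:
            best_label = int(lab)
            break
    members = np.flatnonzero(labels == best_label)
    mean_coords = coords[members].mean(axis=0)
    dists = np.sqrt(np.mean(
        np.sum((coords[members] - mean_coords) ** 2, axis=-1), axis=-1))
    rep = int(members[int(np.argmin(dists))]) + 1  # argmin takes first == lowest
    return ClusterResult(labels=labels, cluster_sizes=sizes,
                         representative_frame=rep, linkage=linkage,
                         threshold=threshold)
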
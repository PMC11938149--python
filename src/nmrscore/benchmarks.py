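"""Helpers for structure-comparison benchmarks on deposited entries.

These utilities operate on locally available PDB files (they perform no
network access): extraction of helix annotations from HELIX records,
backbone superposition of the first annotated helices of two structures,
and buried-area computation of a two-partner complex model.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError
from .interface import buried_area
from .structio import Structure, read_structure, select, superpose

logger = logging.getLogger(__name__)


def helix_ranges(path: str | Path) -> list[tuple[str, int, int]]:
    """(chain, start, end) of each HELIX record of a PDB file, in file order."""
    ranges = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("HELIX"):
                chain = line[19].strip()
                start = int(line[21:25])
                end = int(line[33:37])
                ranges.append((chain, start, end))
    return ranges


def _helix_backbone(structure: Structure, chain: str, start: int, end: int,
                    conformer: int = 1):
    return select(structure, f"chain {chain} and resi {start}-{end} and backbone",
                  conformer=conformer)


def paired_helix_rmsd(path_a: str | Path, path_b: str | Path,
                      n_helices: int = 2, chain_b: str | None = None,
                      conformer_a: int = 1,
                      ranges_a: Sequence[tuple[str, int, int]] | None = None,
                      ranges_b: Sequence[tuple[str, int, int]] | None = None,
                      ) -> float:
    """Backbone RMSD after superposing the first ``n_helices`` annotated
    helices of two structures.

    Helix ranges default to the files' HELIX records; explicit ranges
    override the annotation (the equivalence of helices between homologous
    structures is ultimately a user decision).  Each helix pair is truncated
    to the shorter member, dropping residues from the C-terminal end.
    """
    sa = read_structure(path_a)
    sb = read_structure(path_b)
    ra = list(ranges_a) if ranges_a is not None else helix_ranges(path_a)
    rb = list(ranges_b) if ranges_b is not None else helix_ranges(path_b)
    if chain_b is not None:
        rb = [r for r in rb if r[0] == chain_b]
    if len(ra) < n_helices or len(rb) < n_helices:
        raise DataError(
            f"need {n_helices} helices; found {len(ra)} and {len(rb)}")
    coords_a, coords_b = [], []
    for (ca, sa0, ea0), (cb, sb0, eb0) in zip(ra[:n_helices], rb[:n_helices]):
        length = min(ea0 - sa0, eb0 - sb0) + 1
        set_a = _helix_backbone(sa, ca, sa0, sa0 + length - 1, conformer_a)
        set_b = _helix_backbone(sb, cb, sb0, sb0 + length - 1)
        if len(set_a) != len(set_b):
            # uneven backbone completeness; truncate to the common length
            m = min(len(set_a), len(set_b))
            coords_a.append(set_a.coords[:m])
            coords_b.append(set_b.coords[:m])
        else:
            coords_a.append(set_a.coords)
            coords_b.append(set_b.coords)
    x = np.concatenate(coords_a)
    y = np.concatenate(coords_b)
    return superpose(x, y).rmsd


def model_buried_area(path: str | Path, probe: float = 1.4,
                      n_points: int = 960) -> float:
    """Buried area of a deposited two-chain complex model.

    The first annotated chain is partner A, all remaining chains partner B.
    """
    s = read_structure(path)
    chains = s.chains()
    if len(chains) < 2:
        raise DataError(f"{path}: need at least two chains, found {chains}")
    return buried_area(s, [chains[0]], chains[1:], probe=probe,
                       n_points=n_points)
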
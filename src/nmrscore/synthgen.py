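"""Deterministic synthetic fixtures with known ground truth.

Two idealized poly-alanine chains are placed so that a chosen number of
residue pairs are in contact (closest atoms well inside 4.5 A, arranged as an
ideal inter-chain hydrogen bond) while every other inter-chain residue pair
stays beyond 6 A.  Titration tables, jittered trajectories and relaxation
decays are derived from the same ground truth so downstream stages can be
verified against planted answers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DataError
from .structio import Structure, write_structure
from .cspkit import ShiftTable
from .trajanalysis import Trajectory

#: Spacing between consecutive residues along a chain (A).  Generous so that
#: only designed residue pairs can come within the contact cutoff.
RESIDUE_SPACING = 12.0

#: Inter-chain donor-acceptor distance of planted hydrogen bonds (A).
HBOND_DA = 2.9

_NONCONTACT_OFFSET = 30.0  # y displacement of non-contacting ligand residues

# local template: N, H, CA, CB, C, O with plausible bond lengths; the amide
# H points +y, the carbonyl O +y as well (flipped for the donor chain)
_TEMPLATE = {
    "N": np.array([-1.45, 0.0, 0.0]),
    "H": np.array([-1.45, 1.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "CB": np.array([0.0, 0.0, 1.52]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([1.52, 1.23, 0.0]),
}
_ELEMENTS = {"N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O"}

# x shift aligning the ligand amide N above the receptor carbonyl O
_DONOR_X_SHIFT = float(_TEMPLATE["O"][0] - _TEMPLATE["N"][0])
# y gap putting the donor N exactly HBOND_DA above the acceptor O
_CONTACT_GAP = float(_TEMPLATE["O"][1] + HBOND_DA)


@dataclass
class GroundTruth:
    """Planted answers that downstream stages must reproduce."""

    seed: int
    n_res_a: int
    n_res_b: int
    interface_a: frozenset[int] = frozenset()
    interface_b: frozenset[int] = frozenset()
    contacts: tuple[tuple[int, int], ...] = ()  # (res A, res B)
    hbonds: tuple[tuple[int, int], ...] = ()  # (donor res B, acceptor res A)
    perturbed_csp: frozenset[int] = frozenset()
    perturbed_broadened: frozenset[int] = frozenset()
    jitter_sigma: float = 0.0
    escape_at: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.seed,
            "n_res_a": self.n_res_a,
            "n_res_b": self.n_res_b,
            "interface_a": sorted(self.interface_a),
            "interface_b": sorted(self.interface_b),
            "contacts": [list(c) for c in self.contacts],
            "hbonds": [list(h) for h in self.hbonds],
            "perturbed_csp": sorted(self.perturbed_csp),
            "perturbed_broadened": sorted(self.perturbed_broadened),
            "jitter_sigma": self.jitter_sigma,
            "escape_at": self.escape_at,
        }, indent=1))


def _build_chain(chain_id: str, n_res: int, flip: bool,
                 x_offset: float, y_offset: float,
                 contact_residues: set[int]) -> dict:
    """Column arrays of one poly-alanine chain."""
    names, elements, chains, nums, coords = [], [], [], [], []
    for res in range(1, n_res + 1):
        x0 = x_offset + RESIDUE_SPACING * (res - 1)
        y0 = y_offset if res in contact_residues else y_offset + _NONCONTACT_OFFSET
        for name, local in _TEMPLATE.items():
            pos = local.copy()
            if flip:
                pos[1] = -pos[1]
            pos[0] += x0
            pos[1] += y0
            names.append(name)
            elements.append(_ELEMENTS[name])
            chains.append(chain_id)
            nums.append(res)
            coords.append(pos)
    return {"names": names, "elements": elements, "chains": chains,
            "nums": nums, "coords": coords}


def make_complex(n_res_a: int, n_res_b: int, n_contacts: int, seed: int = 0,
                 contact_offset: int = 0) -> tuple[Structure, GroundTruth]:
    """A two-chain poly-alanine complex with a designed interface.

    Exactly ``n_contacts`` residue pairs — chain A residue ``contact_offset+i``
    with chain B residue ``i`` — have atoms within the contact range (closest
    approach ~1.9 A, donor-acceptor 2.9 A); all other inter-chain residue
    pairs are separated by more than 6 A.  A seeded global rigid transform
    randomises the overall placement without changing internal distances.
    """
    if n_contacts < 0 or n_contacts > min(n_res_a, n_res_b):
        raise DataError(
            f"cannot place {n_contacts} contacts on chains of "
            f"{n_res_a} and {n_res_b} residues")
    if contact_offset < 0 or contact_offset + n_contacts > n_res_a:
        raise DataError(
            f"contact offset {contact_offset} pushes contacts past chain A")
    contacts_a = {contact_offset + i for i in range(1, n_contacts + 1)}
    contacts_b = set(range(1, n_contacts + 1))
    chain_a = _build_chain("A", n_res_a, flip=False, x_offset=0.0, y_offset=0.0,
                           contact_residues=set(range(1, n_res_a + 1)))
    chain_b = _build_chain(
        "B", n_res_b, flip=True,
        x_offset=_DONOR_X_SHIFT + RESIDUE_SPACING * contact_offset,
        y_offset=_CONTACT_GAP, contact_residues=contacts_b)

    names = chain_a["names"] + chain_b["names"]
    coords = np.array(chain_a["coords"] + chain_b["coords"])
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    coords = coords @ rot.T + trans

    n = len(names)
    structure = Structure(
        chain_ids=np.array(chain_a["chains"] + chain_b["chains"]),
        res_nums=np.array(chain_a["nums"] + chain_b["nums"], dtype=int),
        icodes=np.array([""] * n),
        res_names=np.array(["ALA"] * n),
        atom_names=np.array(names),
        elements=np.array(chain_a["elements"] + chain_b["elements"]),
        serials=np.arange(1, n + 1),
        hetero=np.zeros(n, dtype=bool),
        coords=coords[np.newaxis],
    )
    truth = GroundTruth(
        seed=seed, n_res_a=n_res_a, n_res_b=n_res_b,
        interface_a=frozenset(contacts_a), interface_b=frozenset(contacts_b),
        contacts=tuple((contact_offset + i, i) for i in range(1, n_contacts + 1)),
        hbonds=tuple((i, contact_offset + i) for i in range(1, n_contacts + 1)),
    )
    return structure, truth


def write_complex(structure: Structure, truth: GroundTruth,
                  path: str | Path) -> None:
    """Write the complex as PDB with the generator seed in the header."""
    write_structure(structure, path,
                    header_remarks=[f"nmrscore synthgen seed={truth.seed}"])


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def make_titration(truth: GroundTruth, effect: float, noise: float = 0.0,
                   broadened_fraction: float = 0.0, seed: int = 0,
                   partner: str = "a",
                   ) -> tuple[ShiftTable, ShiftTable, GroundTruth]:
    """Apo and holo shift tables with planted CSPs on the interface residues.

    Interface residues of the chosen partner receive a perturbation of
    magnitude ``effect`` (in combined-CSP units, split randomly between the
    1H and the 10x-scaled 15N dimension); all residues additionally receive
    Gaussian noise of scale ``noise`` per dimension.  A ``broadened_fraction``
    of the interface residues is removed from the holo table.
    """
    if effect <= 0:
        raise DataError("effect must be > 0")
    if not 0 <= broadened_fraction <= 1:
        raise DataError("broadened_fraction must be in [0, 1]")
    if noise < 0:
        raise DataError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    n_res = truth.n_res_a if partner.lower() == "a" else truth.n_res_b
    interface = sorted(truth.interface_a if partner.lower() == "a"
                       else truth.interface_b)
    residues = np.arange(1, n_res + 1)
    base_h = rng.uniform(7.0, 9.5, size=n_res)
    base_n = rng.uniform(105.0, 130.0, size=n_res)
    apo_df = pd.DataFrame({
        "residue": residues, "res_type": "ALA",
        "dH": base_h, "dN": base_n,
    })

    holo_h = base_h + rng.normal(0.0, noise, size=n_res) if noise else base_h.copy()
    holo_n = (base_n + rng.normal(0.0, 10.0 * noise, size=n_res)
              if noise else base_n.copy())
    n_broad = int(round(broadened_fraction * len(interface)))
    broadened = set(rng.choice(interface, size=n_broad, replace=False).tolist()
                    ) if n_broad else set()
    planted = set(interface) - broadened
    for res in planted:
        theta = rng.uniform(0.0, math.pi / 2.0)
        holo_h[res - 1] += effect * math.cos(theta)
        holo_n[res - 1] += 10.0 * effect * math.sin(theta)
    keep = ~np.isin(residues, sorted(broadened))
    holo_df = pd.DataFrame({
        "residue": residues[keep], "res_type": "ALA",
        "dH": holo_h[keep], "dN": holo_n[keep],
    })
    new_truth = replace(truth, perturbed_csp=frozenset(planted),
                        perturbed_broadened=frozenset(broadened))
    return (ShiftTable(label="apo", data=apo_df),
            ShiftTable(label="holo", data=holo_df), new_truth)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_trajectory(structure: Structure, truth: GroundTruth, n_frames: int,
                    jitter_sigma: float = 0.0, escape_at: int | None = None,
                    escape_vector: Sequence[float] = (0.0, 0.0, 40.0),
                    seed: int = 0) -> tuple[Trajectory, GroundTruth]:
    """Rigid-body-jittered frames around the complex.

    Every atom gets i.i.d. Gaussian jitter per frame.  From frame
    ``escape_at`` (1-based) onward, chain B is rigidly displaced by
    ``escape_vector``, breaking all planted contacts and hydrogen bonds.
    """
    if n_frames < 2:
        raise DataError("need at least 2 frames")
    if jitter_sigma < 0:
        raise DataError("jitter_sigma must be >= 0")
    if escape_at is not None and not 1 <= escape_at <= n_frames:
        raise DataError(f"escape_at {escape_at} outside 1..{n_frames}")
    rng = np.random.default_rng(seed)
    base = structure.conformer_coords(1)
    frames = np.empty((n_frames, structure.n_atoms, 3))
    ligand = structure.chain_ids.astype(str) == "B"
    vec = np.asarray(escape_vector, dtype=float)
    for f in range(n_frames):
        coords = base.copy()
        if jitter_sigma:
            coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
        if escape_at is not None and f + 1 >= escape_at:
            coords[ligand] += vec
        frames[f] = coords
    traj_structure = replace(structure, coords=frames)
    new_truth = replace(truth, jitter_sigma=jitter_sigma, escape_at=escape_at)
    return Trajectory(structure=traj_structure), new_truth


# ---------------------------------------------------------------------------
# relaxation decays
# ---------------------------------------------------------------------------

def make_decay(rate: float, i0: float, delays: Sequence[float],
               noise_frac: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Mono-exponential decay samples I(t) = i0 * exp(-rate t) * (1 + eps)."""
    if rate <= 0:
        raise DataError("rate must be > 0")
    t = np.asarray(delays, dtype=float)
    if np.any(t < 0):
        raise DataError("delays must be non-negative")
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-rate * t)
    eps = rng.normal(0.0, noise_frac, size=t.shape) if noise_frac else 0.0
    return pd.DataFrame({"delay": t, "intensity": clean * (1.0 + eps)})
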
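import numpy as np
import pandas as pd
import pytest

from nmrscore import cspkit, structio, synthgen


def build_structure(atoms, n_conformers=1):
    """Build a Structure from (chain, resnum, resname, atomname, element, xyz)."""
    n = len(atoms)
    coords = np.array([a[5] for a in atoms], dtype=float)
    return structio.Structure(
        chain_ids=np.array([a[0] for a in atoms]),
        res_nums=np.array([a[1] for a in atoms], dtype=int),
        icodes=np.array([""] * n),
        res_names=np.array([a[2] for a in atoms]),
        atom_names=np.array([a[3] for a in atoms]),
        elements=np.array([a[4] for a in atoms]),
        serials=np.arange(1, n + 1),
        hetero=np.zeros(n, dtype=bool),
        coords=np.repeat(coords[np.newaxis], n_conformers, axis=0),
    )


def shift_table(label, rows, **kwargs):
    """rows: list of (residue, res_type, dH, dN)."""
    df = pd.DataFrame(rows, columns=["residue", "res_type", "dH", "dN"])
    for key, values in kwargs.items():
        df[key] = values
    return cspkit.ShiftTable(label=label, data=df)


@pytest.fixture
def small_complex():
    return synthgen.make_complex(12, 10, 4, seed=7)


@pytest.fixture
def ten_residue_chain():
    atoms = []
    for res in range(1, 11):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
                              ("CB", "C"), ("HA", "H")):
            atoms.append(("A", res, "ALA", name, element,
                          (3.8 * res + 0.3 * len(atoms) % 2, 0.0, 0.0)))
    return build_structure(atoms)
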
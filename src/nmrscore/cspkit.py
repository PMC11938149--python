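"""Chemical-shift analysis: tables, CSPs, thresholds, restraints, relaxation.

The central quantity is the amide chemical shift perturbation

    ddelta = sqrt(ddeltaH**2 + (ddeltaN / alpha)**2)        (alpha = 10)

between an apo and a titrated (holo) state.  Peaks that are assigned in the
apo spectrum but vanish on titration are classified as *broadened* and carry
no ddelta; prolines carry no amide and are excluded throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

#: Default scaling applied to the 15N dimension of the CSP.
DEFAULT_ALPHA = 10.0

_REQUIRED_COLUMNS = ("residue", "res_type", "dH", "dN")

STATUS_SHIFTED = "shifted"
STATUS_BROADENED = "broadened"
STATUS_UNASSIGNED = "unassigned"
STATUS_NO_AMIDE = "no_amide"


@dataclass
class ShiftTable:
    """Per-residue amide shifts of one titration state.

    ``data`` columns: residue (int), res_type (3-letter code), dH (ppm),
    dN (ppm), intensity (optional), assigned (bool).
    """

    label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise DataError(f"shift table {self.label!r}: missing column {col!r}")
        if df["residue"].duplicated().any():
            dup = int(df.loc[df["residue"].duplicated(), "residue"].iloc[0])
            raise DataError(
                f"shift table {self.label!r}: duplicate residue {dup}")
        if "assigned" not in df.columns:
            df = df.assign(assigned=df["dH"].notna() & df["dN"].notna())
        else:
            df = df.assign(
                assigned=df["assigned"].astype(bool) & df["dH"].notna() & df["dN"].notna())
        if "intensity" not in df.columns:
            df = df.assign(intensity=np.nan)
        self.data = df.set_index("residue", drop=False).sort_index()

    @property
    def residues(self) -> set[int]:
        return set(self.data["residue"].astype(int))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class CspResult:
    """Per-residue CSP values and status flags."""

    data: pd.DataFrame  # columns: residue, res_type, delta, status
    alpha: float = DEFAULT_ALPHA

    def deltas(self) -> pd.Series:
        """Defined ddelta values (status == shifted), indexed by residue."""
        shifted = self.data[self.data["status"] == STATUS_SHIFTED]
        return shifted.set_index("residue")["delta"]

    def broadened(self) -> set[int]:
        return set(self.data.loc[self.data["status"] == STATUS_BROADENED, "residue"])

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "alpha": self.alpha,
            "rows": self.data.replace({np.nan: None}).to_dict(orient="records"),
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class PerturbedSet:
    """The set of NMR-perturbed residues (I_NMR) of one binding partner."""

    label: str
    residues: frozenset[int]
    sigma: float
    provenance: dict[int, str] = field(default_factory=dict)  # residue -> csp|broadened

    def __post_init__(self) -> None:
        self.residues = frozenset(int(r) for r in self.residues)
        bad = {r for r, p in self.provenance.items() if p not in ("csp", "broadened")}
        if bad:
            raise DataError(f"bad provenance flags for residues {sorted(bad)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "label": self.label,
            "sigma": self.sigma,
            "residues": sorted(self.residues),
            "provenance": {str(k): v for k, v in sorted(self.provenance.items())},
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PerturbedSet":
        raw = json.loads(Path(path).read_text())
        return cls(label=raw["label"], residues=frozenset(raw["residues"]),
                   sigma=float(raw["sigma"]),
                   provenance={int(k): v for k, v in raw.get("provenance", {}).items()})


@dataclass(frozen=True)
class RelaxationResult:
    """A mono-exponential decay fit I(t) = I0 * exp(-R t)."""

    rate: float
    i0: float
    rate_err: float
    valid: bool = True


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def read_shift_table(path: str | Path, format: str = "tsv",
                     label: str | None = None) -> ShiftTable:
    """Read a shift table from TSV/CSV or an NMR-STAR chemical-shift loop.

    The tabular schema requires columns ``residue``, ``res_type``, ``dH``,
    ``dN`` and accepts optional ``intensity`` and ``assigned``.  The
    NMR-STAR reader consumes the ``_Atom_chem_shift`` loop subset, pairing H
    and N rows per residue.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, comment="#")
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
        for col in ("dH", "dN"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.loc[coerced.isna() & df[col].notna(), col]
                if len(bad):
                    raise ParseError(
                        f"{path}: non-numeric {col} value {bad.iloc[0]!r}")
                df[col] = coerced
        return ShiftTable(label=label, data=df)
    if format in ("nmrstar", "nmrstar-subset", "star"):
        return _read_nmrstar(path, label)
    raise ValueError(f"unknown shift-table format {format!r}")


def _read_nmrstar(path: Path, label: str) -> ShiftTable:
    """Minimal NMR-STAR v3 chemical-shift loop reader (amide H/N subset)."""
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped == "loop_":
                in_loop, collecting = True, False
                tags, rows = [], []
                continue
            if in_loop and stripped.startswith("_"):
                tags.append(stripped.split(".")[-1] if "." in stripped else stripped[1:])
                continue
            if in_loop and stripped == "stop_":
                if {"Seq_ID", "Atom_ID", "Val"} <= set(tags):
                    break
                in_loop = False
                continue
            if in_loop and stripped and not stripped.startswith("#"):
                collecting = True
                rows.append(stripped.split())
    if not tags or not rows:
        raise ParseError(f"{path}: no _Atom_chem_shift loop found")
    if not {"Seq_ID", "Atom_ID", "Val"} <= set(tags):
        raise ParseError(f"{path}: chemical-shift loop lacks Seq_ID/Atom_ID/Val tags")
    idx = {t: i for i, t in enumerate(tags)}
    per_res: dict[int, dict] = {}
    for row in rows:
        if len(row) < len(tags):
            continue
        atom = row[idx["Atom_ID"]]
        if atom not in ("H", "HN", "N"):
            continue
        res = int(row[idx["Seq_ID"]])
        entry = per_res.setdefault(res, {"res_type": "UNK", "dH": np.nan, "dN": np.nan})
        if "Comp_ID" in idx:
            entry["res_type"] = row[idx["Comp_ID"]]
        try:
            val = float(row[idx["Val"]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric shift {row[idx['Val']]!r}") from exc
        entry["dN" if atom == "N" else "dH"] = val
    df = pd.DataFrame(
        [{"residue": r, **v} for r, v in sorted(per_res.items())],
        columns=["residue", "res_type", "dH", "dN"])
    return ShiftTable(label=label, data=df)


# ---------------------------------------------------------------------------
# CSP computation
# ---------------------------------------------------------------------------

def compute_csp(apo: ShiftTable, holo: ShiftTable,
                alpha: float = DEFAULT_ALPHA,
                intensity_floor: float | None = 0.15) -> CspResult:
    """Compute per-residue CSPs between an apo and a titrated state.

    A residue assigned in both states gets ``delta = sqrt(dH^2 + (dN/alpha)^2)``;
    assigned in apo but missing/unassigned in holo -> *broadened*; assigned in
    neither -> *unassigned*; prolines -> *no_amide*.  When both tables carry
    peak intensities, a holo/apo intensity ratio below ``intensity_floor``
    also flags the residue as broadened.
    """
    if alpha <= 0:
        raise DataError(f"alpha must be > 0, got {alpha}")
    residues = sorted(apo.residues | holo.residues)
    rows = []
    for res in residues:
        in_apo = res in apo.data.index
        in_holo = res in holo.data.index
        a = apo.data.loc[res] if in_apo else None
        h = holo.data.loc[res] if in_holo else None
        res_type = str((a if a is not None else h)["res_type"])
        if res_type.upper() in ("PRO", "P"):
            rows.append((res, res_type, np.nan, STATUS_NO_AMIDE))
            continue
        apo_ok = in_apo and bool(a["assigned"])
        holo_ok = in_holo and bool(h["assigned"])
        if apo_ok and holo_ok:
            if (intensity_floor is not None
                    and np.isfinite(a["intensity"]) and np.isfinite(h["intensity"])
                    and a["intensity"] > 0
                    and h["intensity"] / a["intensity"] < intensity_floor):
                rows.append((res, res_type, np.nan, STATUS_BROADENED))
                continue
            ddh = float(h["dH"]) - float(a["dH"])
            ddn = float(h["dN"]) - float(a["dN"])
            delta = math.sqrt(ddh ** 2 + (ddn / alpha) ** 2)
            rows.append((res, res_type, delta, STATUS_SHIFTED))
        elif apo_ok and not holo_ok:
            rows.append((res, res_type, np.nan, STATUS_BROADENED))
        else:
            rows.append((res, res_type, np.nan, STATUS_UNASSIGNED))
    df = pd.DataFrame(rows, columns=["residue", "res_type", "delta", "status"])
    return CspResult(data=df, alpha=alpha)


def significance_threshold(csp: CspResult, method: str = "trimmed_sd",
                           k_trim: float = 3.0,
                           value: float | None = None) -> float:
    """CSP significance threshold sigma (ppm).

    ``trimmed_sd``: iteratively compute the sample SD of the defined deltas,
    drop values above ``k_trim * SD`` and repeat to convergence; return the
    final SD.  ``fixed``: return the user-supplied ``value``.
    """
    if method == "fixed":
        if value is None:
            raise DataError("method='fixed' requires a value")
        return float(value)
    if method != "trimmed_sd":
        raise ValueError(f"unknown method {method!r}")
    deltas = csp.deltas().to_numpy(dtype=float)
    if deltas.size < 5:
        raise DataError(
            f"trimmed_sd needs >= 5 defined CSP values, got {deltas.size}")
    cur = deltas
    while True:
        sd = float(np.std(cur, ddof=1)) if cur.size > 1 else 0.0
        if sd == 0.0:
            return 0.0
        keep = cur <= k_trim * sd
        if keep.all():
            return sd
        if keep.sum() < 2:
            return sd
        cur = cur[keep]


def perturbed_set(csp: CspResult, sigma: float,
                  include_broadened: bool = True,
                  label: str = "") -> PerturbedSet:
    """Build I_NMR: residues with delta >= sigma, plus broadened residues."""
    if sigma < 0:
        raise DataError(f"sigma must be >= 0, got {sigma}")
    provenance: dict[int, str] = {}
    deltas = csp.deltas()
    for res, d in deltas.items():
        # delta == 0 is no perturbation even at a zero threshold
        if d >= sigma and d > 0:
            provenance[int(res)] = "csp"
    if include_broadened:
        for res in csp.broadened():
            provenance[int(res)] = "broadened"
    return PerturbedSet(label=label, residues=frozenset(provenance),
                        sigma=float(sigma), provenance=provenance)


# ---------------------------------------------------------------------------
# Restraint bookkeeping
# ---------------------------------------------------------------------------

RESTRAINT_CATEGORIES = ("intraresidue", "sequential", "medium", "long")


def classify_restraint(i: int, j: int) -> str:
    """Category of one distance restraint by sequence separation |i - j|."""
    sep = abs(int(i) - int(j))
    if sep == 0:
        return "intraresidue"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


def classify_restraints(pairs: Iterable[tuple[int, int]]) -> dict[str, int]:
    """Count restraints per sequence-separation category.

    Returns a dict with the four category counts plus ``total``.
    """
    counts = {c: 0 for c in RESTRAINT_CATEGORIES}
    for i, j in pairs:
        counts[classify_restraint(i, j)] += 1
    counts["total"] = sum(counts[c] for c in RESTRAINT_CATEGORIES)
    return counts


def restraint_total(category_counts: Mapping[str, int]) -> int:
    """Total restraints from per-category counts."""
    return sum(int(category_counts[c]) for c in RESTRAINT_CATEGORIES)


def assignment_completeness(n_assigned: int, n_total: int) -> int:
    """Backbone assignment completeness as a rounded integer percentage."""
    if n_total <= 0:
        raise DataError("total residue count must be positive")
    return round(100.0 * n_assigned / n_total)


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def fit_decay(delays: Sequence[float], intensities: Sequence[float],
              replicates: Sequence[tuple[float, float]] | None = None,
              ) -> RelaxationResult:
    """Fit I(t) = I0 * exp(-R t) by least squares.

    The rate's uncertainty comes from the scatter of replicate delays when
    any delay value occurs more than once (or via ``replicates``), otherwise
    from the fit covariance.  A non-decaying fit (R <= 0) is returned with
    ``valid=False``.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if replicates:
        rt, ry = zip(*replicates)
        t = np.concatenate([t, np.asarray(rt, dtype=float)])
        y = np.concatenate([y, np.asarray(ry, dtype=float)])
    if t.shape != y.shape:
        raise DataError("delays and intensities must have the same length")
    if np.unique(t).size < 3:
        raise DataError("need >= 3 distinct delays")
    if np.any(y <= 0):
        raise DataError("intensities must be positive")

    # noise estimate from replicate delays, if any
    sigma = None
    rep_vars = []
    for val in np.unique(t):
        grp = y[t == val]
        if grp.size > 1:
            rep_vars.append(np.var(grp, ddof=1))
    if rep_vars and np.mean(rep_vars) > 0:
        sigma = float(np.sqrt(np.mean(rep_vars)))

    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (math.exp(intercept), max(-slope, 1e-6))

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0,
            sigma=None if sigma is None else np.full_like(y, sigma),
            absolute_sigma=sigma is not None, maxfev=10000)
    except RuntimeError as exc:
        raise DataError(f"decay fit did not converge: {exc}") from exc
    i0, rate = float(popt[0]), float(popt[1])
    rate_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    if rate <= 0 or -slope <= 0:
        # refit without the positivity nudge to report the raw slope
        return RelaxationResult(rate=min(rate, -slope), i0=i0,
                                rate_err=rate_err, valid=False)
    return RelaxationResult(rate=rate, i0=i0, rate_err=rate_err, valid=True)


def hetnoe(sat: Mapping[int, float] | pd.Series,
           ref: Mapping[int, float] | pd.Series) -> pd.Series:
    """Per-residue heteronuclear NOE ratio sat/ref.

    Residues missing from either table are dropped (logged); a zero reference
    intensity is an error.
    """
    sat_s = pd.Series(dict(sat)) if not isinstance(sat, pd.Series) else sat
    ref_s = pd.Series(dict(ref)) if not isinstance(ref, pd.Series) else ref
    common = sat_s.index.intersection(ref_s.index)
    dropped = set(sat_s.index.symmetric_difference(ref_s.index))
    if dropped:
        logger.warning("hetNOE: residues %s missing from one table, dropped",
                       sorted(dropped))
    if (ref_s.loc[common] == 0).any():
        res = int(common[ref_s.loc[common] == 0][0])
        raise DataError(f"hetNOE: zero reference intensity at residue {res}")
    out = sat_s.loc[common] / ref_s.loc[common]
    out.index.name = "residue"
    return out.sort_index()
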
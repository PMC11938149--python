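"""Scoring of candidate complex models against NMR perturbed-residue sets.

Coverage C% is the fraction of a model's predicted interface residues that
are NMR-perturbed; error E% the fraction that are not.  Both share the same
denominator, so C + E = 100 exactly (computed on rationals).  Models are
ranked by the C/E ratio, with E = 0 treated as best-possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cspkit import PerturbedSet
from .errors import DataError
from .interface import DEFAULT_CUTOFF, InterfaceSet, interface_residues
from .structio import Structure


@dataclass(frozen=True)
class PartnerScore:
    """Coverage/error of one binding partner."""

    coverage: Fraction  # 0..1
    error: Fraction
    n_pred: int
    n_common: int
    n_wrong: int

    @property
    def c_pct(self) -> float:
        return float(100 * self.coverage)

    @property
    def e_pct(self) -> float:
        return float(100 * self.error)


@dataclass(frozen=True)
class ScoreCard:
    """Coverage/error summary of one model against the NMR perturbed sets."""

    model_id: str
    partners: Mapping[str, PartnerScore]
    combined: PartnerScore
    restricted: bool = False

    @property
    def c_pct(self) -> float:
        return self.combined.c_pct

    @property
    def e_pct(self) -> float:
        return self.combined.e_pct

    @property
    def ratio(self) -> float:
        """C/E ratio; +inf when E = 0."""
        if self.combined.error == 0:
            return float("inf")
        return float(self.combined.coverage / self.combined.error)

    def to_dict(self) -> dict:
        def block(p: PartnerScore) -> dict:
            return {"C_pct": round(p.c_pct, 1), "E_pct": round(p.e_pct, 1),
                    "n_pred": p.n_pred, "n_common": p.n_common, "n_wrong": p.n_wrong}
        return {
            "model_id": self.model_id,
            "partners": {k: block(v) for k, v in self.partners.items()},
            "combined": block(self.combined),
            "ratio": None if self.ratio == float("inf") else round(self.ratio, 3),
            "restricted": self.restricted,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class MutationPanel:
    """Loss-of-interaction mutations of one partner, by residue number."""

    label: str
    residues: tuple[int, ...]
    no_effect: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.residues + self.no_effect):
            raise DataError("mutation residue numbers must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "MutationPanel":
        raw = json.loads(Path(path).read_text())
        return cls(label=raw["label"], residues=tuple(raw["residues"]),
                   no_effect=tuple(raw.get("no_effect", ())))


# ---------------------------------------------------------------------------
# elementary scores
# ---------------------------------------------------------------------------

def _as_set(x: Iterable[int]) -> frozenset[int]:
    return frozenset(int(r) for r in x)


def coverage(i_pred: Iterable[int], i_nmr: Iterable[int]) -> float:
    """Interface coverage C% = 100 * |i_pred & i_nmr| / |i_pred|."""
    pred, nmr = _as_set(i_pred), _as_set(i_nmr)
    if not pred:
        raise DataError("coverage undefined for an empty predicted interface")
    return float(100 * Fraction(len(pred & nmr), len(pred)))


def error_pct(i_pred: Iterable[int], i_nmr: Iterable[int]) -> float:
    """Interface error E% = 100 * |i_pred - i_nmr| / |i_pred|."""
    pred, nmr = _as_set(i_pred), _as_set(i_nmr)
    if not pred:
        raise DataError("error undefined for an empty predicted interface")
    return float(100 * Fraction(len(pred - nmr), len(pred)))


def _partner_score(pred: frozenset, nmr: frozenset) -> PartnerScore:
    if not pred:
        raise DataError("empty predicted interface after restriction")
    common = pred & nmr
    return PartnerScore(coverage=Fraction(len(common), len(pred)),
                        error=Fraction(len(pred - nmr), len(pred)),
                        n_pred=len(pred), n_common=len(common),
                        n_wrong=len(pred - nmr))


# ---------------------------------------------------------------------------
# model scoring
# ---------------------------------------------------------------------------

def score_model(model: Structure,
                perturbed: Mapping[str, PerturbedSet],
                chains: Mapping[str, Sequence[str]],
                model_id: str = "model",
                cutoff: float = DEFAULT_CUTOFF,
                include_h: bool = True,
                restrict_to: Mapping[str, Iterable[int]] | None = None,
                conformer: int = 1) -> ScoreCard:
    """Score one complex model against per-partner NMR perturbed sets.

    ``perturbed`` and ``chains`` map the two partner labels to their
    :class:`PerturbedSet` and chain ids.  ``restrict_to`` optionally
    intersects each partner's predicted interface with a residue set (e.g.
    residues common to several modelling methods) before scoring.
    """
    labels = list(perturbed)
    if len(labels) != 2:
        raise DataError(f"need exactly 2 partners, got {labels}")
    la, lb = labels
    iface = interface_residues(model, chains[la], chains[lb], cutoff=cutoff,
                               include_h=include_h, conformer=conformer,
                               label_a=la, label_b=lb)
    preds = {la: frozenset(n for _, n in iface.residues_a),
             lb: frozenset(n for _, n in iface.residues_b)}
    restricted = False
    if restrict_to:
        for label, allowed in restrict_to.items():
            preds[label] = preds[label] & _as_set(allowed)
            restricted = True
    partner_scores = {
        label: _partner_score(preds[label], perturbed[label].residues)
        for label in labels}
    # combined score over the union of partners, keyed (label, residue) to
    # keep identically-numbered residues of the two partners distinct
    pred_union = frozenset((label, r) for label in labels for r in preds[label])
    nmr_union = frozenset((label, r) for label in labels
                          for r in perturbed[label].residues)
    combined = _partner_score(pred_union, nmr_union)
    return ScoreCard(model_id=model_id, partners=partner_scores,
                     combined=combined, restricted=restricted)


def rank_models(cards: Sequence[ScoreCard]) -> list[ScoreCard]:
    """Order score cards best-first by combined C/E ratio.

    Cards with E = 0 outrank every finite ratio and are ordered among
    themselves by C descending; ties break on model id (lexicographic), so
    the order is total and deterministic.
    """
    if not cards:
        raise DataError("need at least one score card")

    def key(card: ScoreCard):
        if card.combined.error == 0:
            return (0, -card.combined.coverage, card.model_id)
        return (1, -(card.combined.coverage / card.combined.error), card.model_id)

    return sorted(cards, key=key)


def mutation_concordance(iface: InterfaceSet, panel: MutationPanel,
                         side: str = "a") -> tuple[Fraction, list[tuple[int, bool]]]:
    """Fraction of loss-of-interaction mutations lying on the model interface.

    Returns the fraction plus a per-residue (residue, at_interface) listing.
    """
    if not panel.residues:
        raise DataError("empty mutation panel")
    interface_numbers = iface.numbers(side)
    table = [(r, r in interface_numbers) for r in panel.residues]
    hits = sum(1 for _, ok in table if ok)
    return Fraction(hits, len(panel.residues)), table
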
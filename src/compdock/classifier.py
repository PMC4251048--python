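"""Ligand typing from paired docking outcomes.

A ligand is docked against two rigid receptor conformations of the same
ligand-binding domain: one crystallised with an agonist bound (the
"agonist model") and one crystallised with an antagonist bound (the
"antagonist model").  Two readings of the paired outcome are provided:

* **SDM** (separate docking models): each model is consulted on its own.
  A ligand that docks to only one model is typed after that model; a
  ligand that docks to both carries no type information and is reported
  as *indeterminate*.

* **CDA** (competitive docking approach): the two models compete.  A
  ligand that docks to both is assigned the type whose model produced
  the more favorable score — winner take all.

Both callers share the trivial rows (no dock anywhere -> non-binder,
single-model dock -> that model's type) and differ only on the
both-docked row, which is where essentially all agonists land because
agonists are small enough to fit either binding pocket.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "AGONIST_MODEL",
    "ANTAGONIST_MODEL",
    "CALLS",
    "DockingOutcome",
    "LigandRecord",
    "TypeCall",
    "ConfusionSummary",
    "cda_call",
    "sdm_call",
    "evaluate",
    "run_batch",
    "InputError",
    "ReconciliationError",
]

AGONIST_MODEL = "agonist"
ANTAGONIST_MODEL = "antagonist"
MODELS = (AGONIST_MODEL, ANTAGONIST_MODEL)

#: every call the two modes can emit, in reporting order
CALLS = ("agonist", "antagonist", "non-binder", "indeterminate", "ambiguous")

TRUTHS = ("agonist", "antagonist", "decoy", "unknown")

Orientation = Literal["lower", "higher"]


class InputError(ValueError):
    """Malformed or inconsistent docking-outcome input."""


class ReconciliationError(ValueError):
    """Calls refer to ligands absent from the truth manifest."""


@dataclass(frozen=True)
class DockingOutcome:
    """One ligand's result against one receptor model.

    ``score`` is present iff ``docked``; its orientation (whether lower
    or higher means more favorable) is a property of the scoring
    function, not of the record, and is passed to the callers.
    """

    ligand_id: str
    model: str
    docked: bool
    score: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InputError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.docked:
            if self.score is None or not math.isfinite(self.score):
                raise InputError(
                    f"ligand {self.ligand_id!r}: docked outcome requires a finite score"
                )
        elif self.score is not None:
            raise InputError(
                f"ligand {self.ligand_id!r}: undocked outcome must not carry a score"
            )


@dataclass(frozen=True)
class LigandRecord:
    """Truth label for one ligand; ``set_tag`` records its collection."""

    ligand_id: str
    truth: str
    set_tag: str = ""

    def __post_init__(self) -> None:
        if self.truth not in TRUTHS:
            raise InputError(f"unknown truth label {self.truth!r}")


@dataclass(frozen=True)
class TypeCall:
    """A classification with the decision row that produced it.

    ``margin`` is the absolute score difference between the two models
    when both docked; ``winning_score`` the favored model's score.
    """

    ligand_id: str
    call: str
    basis: str
    winning_score: float | None = None
    margin: float | None = None


def _favored(ag_score: float, an_score: float, orientation: Orientation) -> int:
    """-1 if agonist model wins, +1 if antagonist model wins, 0 on tie."""
    if ag_score == an_score:
        return 0
    better_ag = ag_score < an_score if orientation == "lower" else ag_score > an_score
    return -1 if better_ag else 1


def _check_pair(ag: DockingOutcome, an: DockingOutcome) -> None:
    if ag.ligand_id != an.ligand_id:
        raise InputError(
            f"mismatched ligand ids: {ag.ligand_id!r} vs {an.ligand_id!r}"
        )
    if ag.model != AGONIST_MODEL or an.model != ANTAGONIST_MODEL:
        raise InputError(
            f"ligand {ag.ligand_id!r}: expected one outcome per model, "
            f"got ({ag.model!r}, {an.model!r})"
        )


def cda_call(
    ag: DockingOutcome,
    an: DockingOutcome,
    orientation: Orientation = "lower",
) -> TypeCall:
    """Competitive (winner-take-all) typing of one ligand.

    Decision table: neither model docked -> non-binder; one model docked
    -> that model's type; both docked -> the type whose model scored
    strictly more favorably.  An exact score tie is reported as
    *ambiguous* rather than forced to a type.
    """
    _check_pair(ag, an)
    lid = ag.ligand_id
    if not ag.docked and not an.docked:
        return TypeCall(lid, "non-binder", "docked-neither")
    if ag.docked and not an.docked:
        return TypeCall(lid, "agonist", "docked-agonist-model-only", ag.score)
    if an.docked and not ag.docked:
        return TypeCall(lid, "antagonist", "docked-antagonist-model-only", an.score)
    assert ag.score is not None and an.score is not None
    margin = abs(ag.score - an.score)
    win = _favored(ag.score, an.score, orientation)
    if win < 0:
        return TypeCall(lid, "agonist", "both-docked-agonist-score-favored", ag.score, margin)
    if win > 0:
        return TypeCall(lid, "antagonist", "both-docked-antagonist-score-favored", an.score, margin)
    return TypeCall(lid, "ambiguous", "both-docked-score-tie", ag.score, 0.0)


def sdm_call(
    ag: DockingOutcome,
    an: DockingOutcome,
    orientation: Orientation = "lower",
) -> TypeCall:
    """Separate-model typing: both-docked ligands are indeterminate.

    Identical to :func:`cda_call` on the no-dock and single-model rows;
    the scores are never compared.
    """
    _check_pair(ag, an)
    if ag.docked and an.docked:
        return TypeCall(ag.ligand_id, "indeterminate", "docked-both-models")
    return cda_call(ag, an, orientation)


@dataclass
class ConfusionSummary:
    """Truth-by-call counts with the derived accuracy figures.

    Accuracies cover agonist and antagonist truths only; decoys and
    unknowns are kept in ``counts`` but never enter an accuracy.  A call
    of non-binder, indeterminate or ambiguous is incorrect for any
    agonist/antagonist truth.  Percentages are stored at full precision;
    :meth:`summary` rounds to one decimal for reporting.
    """

    counts: pd.DataFrame  # index: truth, columns: call
    per_class_accuracy: Mapping[str, float] = field(default_factory=dict)  # percent
    overall_accuracy: float = float("nan")  # percent
    n_total: int = 0

    @property
    def n_evaluated(self) -> int:
        """Ligands with agonist/antagonist truth (the accuracy denominator)."""
        return int(
            self.counts.reindex(["agonist", "antagonist"], fill_value=0).to_numpy().sum()
        )

    def class_call_fraction(self, truth: str, call: str) -> float:
        """Percent of ``truth``-class ligands that received ``call``."""
        row = self.counts.loc[truth]
        total = int(row.sum())
        if total == 0:
            return float("nan")
        return 100.0 * int(row.get(call, 0)) / total

    def summary(self) -> str:
        lines = ["Confusion counts (rows: truth, columns: predicted call)", ""]
        lines.append(self.counts.to_string())
        lines.append("")
        for cls in ("agonist", "antagonist"):
            if cls in self.per_class_accuracy:
                lines.append(f"{cls} accuracy: {self.per_class_accuracy[cls]:.1f}%")
        lines.append(
            f"overall accuracy: {self.overall_accuracy:.1f}% "
            f"({int(round(self.overall_accuracy * self.n_evaluated / 100))} of {self.n_evaluated})"
        )
        return "\n".join(lines)


def evaluate(
    calls: Sequence[TypeCall],
    manifest: Sequence[LigandRecord],
) -> ConfusionSummary:
    """Score calls against a truth manifest.

    Every called ligand must appear in the manifest; unmatched ids raise
    :class:`ReconciliationError` listing them.  Accuracy for a class is
    correct calls over class size, times 100.
    """
    truth_by_id = {r.ligand_id: r.truth for r in manifest}
    if len(truth_by_id) != len(manifest):
        seen: set[str] = set()
        dups = sorted({r.ligand_id for r in manifest if r.ligand_id in seen or seen.add(r.ligand_id)})
        raise InputError(f"duplicate ligand ids in manifest: {dups}")
    missing = sorted({c.ligand_id for c in calls} - truth_by_id.keys())
    if missing:
        raise ReconciliationError(f"calls for ligands absent from manifest: {missing}")

    counts = pd.DataFrame(0, index=list(TRUTHS), columns=list(CALLS), dtype=int)
    for c in calls:
        counts.loc[truth_by_id[c.ligand_id], c.call] += 1
    counts = counts.loc[counts.sum(axis=1) > 0]  # drop empty truth rows

    per_class: dict[str, float] = {}
    correct = 0
    evaluated = 0
    for cls in ("agonist", "antagonist"):
        if cls not in counts.index:
            continue
        total = int(counts.loc[cls].sum())
        hit = int(counts.loc[cls, cls])
        per_class[cls] = 100.0 * hit / total if total else float("nan")
        correct += hit
        evaluated += total
    overall = 100.0 * correct / evaluated if evaluated else float("nan")
    return ConfusionSummary(
        counts=counts,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        n_total=len(calls),
    )


def _pair_outcomes(
    outcomes: Iterable[DockingOutcome],
) -> dict[str, dict[str, DockingOutcome]]:
    by_ligand: dict[str, dict[str, DockingOutcome]] = {}
    for o in outcomes:
        slot = by_ligand.setdefault(o.ligand_id, {})
        if o.model in slot:
            raise InputError(
                f"duplicate outcome for ligand {o.ligand_id!r}, model {o.model!r}"
            )
        slot[o.model] = o
    return by_ligand


def pair_for_ligand(
    ligand_id: str,
    per_model: Mapping[str, DockingOutcome],
) -> tuple[DockingOutcome, DockingOutcome]:
    """Complete a ligand's (agonist-model, antagonist-model) outcome pair.

    A missing model row means the docking engine produced no pose, i.e.
    a failed docking; it is filled in as ``docked=False`` with a warning.
    """
    pair = []
    for model in MODELS:
        if model in per_model:
            pair.append(per_model[model])
        else:
            warnings.warn(
                f"ligand {ligand_id!r}: no {model}-model row; treating as failed docking",
                stacklevel=3,
            )
            pair.append(DockingOutcome(ligand_id, model, docked=False))
    return pair[0], pair[1]


def run_batch(
    outcomes: Iterable[DockingOutcome],
    manifest: Sequence[LigandRecord],
    mode: Literal["sdm", "cda"],
    orientation: Orientation = "lower",
) -> tuple[list[TypeCall], ConfusionSummary]:
    """Classify every ligand in an outcome table and score the result.

    Ligands are processed in sorted id order; ligands present in the
    manifest but absent from the outcome table are treated as failing
    both models (non-binders).
    """
    if mode not in ("sdm", "cda"):
        raise InputError(f"unknown mode {mode!r}")
    caller = cda_call if mode == "cda" else sdm_call
    by_ligand = _pair_outcomes(outcomes)
    for rec in manifest:
        by_ligand.setdefault(rec.ligand_id, {})
    calls = []
    for lid in sorted(by_ligand):
        ag, an = pair_for_ligand(lid, by_ligand[lid])
        calls.append(caller(ag, an, orientation))
    return calls, evaluate(calls, manifest)
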
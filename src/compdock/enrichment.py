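"""Enrichment-factor evaluation of virtual screens.

A screening collection (true targets of one type plus decoys) is ranked
from the docking outcomes, and the enrichment factor

    EF = (TT_scr / n_scr) * (Nc / TTc)

is evaluated at cutoffs n_scr = ceil(fraction * Nc), where TT_scr is the
number of true targets among the top n_scr entries, Nc the collection
size and TTc the number of true targets in it.  EF is the fold
over-representation of targets in the screened head of the list; it is
bounded above by Nc/TTc (perfect retrieval) and equals 1 exactly at
fraction 1.  That upper bound makes some published EF_max claims
checkable without any scores: a value above Nc/TTc is arithmetically
impossible for the stated collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .classifier import (
    AGONIST_MODEL,
    ANTAGONIST_MODEL,
    DockingOutcome,
    InputError,
    LigandRecord,
    Orientation,
    cda_call,
    pair_for_ligand,
)

__all__ = [
    "ScreenEntry",
    "EFCurve",
    "rank_screen",
    "enrichment_factor",
    "ef_curve",
    "validate_ef_feasibility",
    "DEFAULT_FRACTIONS",
]

#: reporting cutoffs conventionally tabulated for this benchmark
DEFAULT_FRACTIONS = (0.01, 0.02, 0.03, 0.04, 0.05, 0.20)

FEASIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class ScreenEntry:
    """One ranked compound: tier first, then score orientation, then id."""

    ligand_id: str
    is_true_target: bool
    rank_score: float | None
    tier: int


def _oriented(score: float | None, orientation: Orientation) -> tuple[int, float]:
    # missing scores sort after any scored entry within the same tier
    if score is None:
        return (1, 0.0)
    return (0, score if orientation == "lower" else -score)


def rank_screen(
    outcomes: Iterable[DockingOutcome],
    manifest: Sequence[LigandRecord],
    mode: Literal["sdm", "cda"],
    screened_type: Literal["agonist", "antagonist"],
    orientation: Orientation = "lower",
) -> list[ScreenEntry]:
    """Order a screening collection for EF evaluation.

    SDM mode ranks by the screened model's score, with failed dockings
    last.  CDA mode ranks in three tiers: compounds competitively called
    as the screened type (by their winning score), then the remaining
    docked compounds (by screened-model score), then failures.  Ties
    within a tier break by ligand id, so rankings are deterministic.
    """
    if screened_type not in ("agonist", "antagonist"):
        raise InputError(f"unknown screened type {screened_type!r}")
    if mode not in ("sdm", "cda"):
        raise InputError(f"unknown mode {mode!r}")
    if not manifest:
        raise InputError("empty screening collection")

    by_ligand: dict[str, dict[str, DockingOutcome]] = {}
    for o in outcomes:
        slot = by_ligand.setdefault(o.ligand_id, {})
        if o.model in slot:
            raise InputError(f"duplicate outcome for {o.ligand_id!r}/{o.model!r}")
        slot[o.model] = o

    screened_model = AGONIST_MODEL if screened_type == "agonist" else ANTAGONIST_MODEL
    entries = []
    for rec in manifest:
        ag, an = pair_for_ligand(rec.ligand_id, by_ligand.get(rec.ligand_id, {}))
        own = ag if screened_model == AGONIST_MODEL else an
        is_target = rec.truth == screened_type
        if mode == "sdm":
            if own.docked:
                entries.append(ScreenEntry(rec.ligand_id, is_target, own.score, 1))
            else:
                entries.append(ScreenEntry(rec.ligand_id, is_target, None, 3))
        else:
            call = cda_call(ag, an, orientation)
            if call.call == screened_type:
                entries.append(
                    ScreenEntry(rec.ligand_id, is_target, call.winning_score, 1)
                )
            elif ag.docked or an.docked:
                entries.append(ScreenEntry(rec.ligand_id, is_target, own.score, 2))
            else:
                entries.append(ScreenEntry(rec.ligand_id, is_target, None, 3))
    entries.sort(
        key=lambda e: (e.tier, *_oriented(e.rank_score, orientation), e.ligand_id)
    )
    return entries


def _cutoff(fraction: float, nc: int) -> int:
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    return math.ceil(fraction * nc)


def enrichment_factor(ranking: Sequence[ScreenEntry], fraction: float) -> float:
    """EF at one screened fraction; cutoff is ceil(fraction * Nc)."""
    if not ranking:
        raise InputError("empty ranking")
    nc = len(ranking)
    ttc = sum(e.is_true_target for e in ranking)
    if ttc == 0:
        raise InputError("ranking contains no true targets")
    n_scr = _cutoff(fraction, nc)
    tt_scr = sum(e.is_true_target for e in ranking[:n_scr])
    return (tt_scr / n_scr) * (nc / ttc)


@dataclass
class EFCurve:
    """EF evaluated over a set of fractions, plus the scanned maximum.

    ``ef_max`` is the maximum of EF over every integer cutoff 1..Nc,
    not merely over the tabulated fractions; ``ef_max_fraction`` is the
    cutoff (as a fraction of Nc) where it is attained.
    """

    nc: int
    ttc: int
    points: list[tuple[float, int, int, float]]  # (fraction, n_scr, TT_scr, EF)
    ef_max: float
    ef_max_fraction: float

    @property
    def upper_bound(self) -> float:
        """Nc/TTc, the EF ceiling for this collection."""
        return self.nc / self.ttc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["fraction", "n_scr", "TT_scr", "EF"]
        )


def ef_curve(
    ranking: Sequence[ScreenEntry],
    fractions: Sequence[float] | None = None,
) -> EFCurve:
    """Tabulate EF at the given fractions and scan for EF_max."""
    if not ranking:
        raise InputError("empty ranking")
    nc = len(ranking)
    ttc = sum(e.is_true_target for e in ranking)
    if ttc == 0:
        raise InputError("ranking contains no true targets")
    if fractions is None:
        fractions = DEFAULT_FRACTIONS
    points = []
    for f in fractions:
        n_scr = _cutoff(f, nc)
        tt_scr = sum(e.is_true_target for e in ranking[:n_scr])
        points.append((f, n_scr, tt_scr, (tt_scr / n_scr) * (nc / ttc)))

    # ties resolve to the largest cutoff attaining the maximum, so a
    # perfect ranking reports its EF_max at fraction TTc/Nc
    ef_max, ef_max_n = 0.0, nc
    running_tt = 0
    for n_scr, entry in enumerate(ranking, start=1):
        running_tt += entry.is_true_target
        ef = (running_tt / n_scr) * (nc / ttc)
        if ef >= ef_max:
            ef_max, ef_max_n = ef, n_scr
    return EFCurve(nc, ttc, points, ef_max, ef_max_n / nc)


def validate_ef_feasibility(
    ef: float, nc: int, ttc: int
) -> Literal["feasible", "infeasible"]:
    """Check a claimed EF against the arithmetic ceiling Nc/TTc.

    Any EF above Nc/TTc (beyond a 1e-9 slack for printed rounding of
    the bound itself) cannot arise from the defining formula for the
    stated collection, whatever the underlying scores were.
    """
    if not (nc >= ttc >= 1):
        raise ValueError(f"require Nc >= TTc >= 1, got Nc={nc}, TTc={ttc}")
    return "infeasible" if ef > nc / ttc + FEASIBILITY_TOL else "feasible"
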
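"""Tabular and config I/O shared by the CLI and library.

Canonical tabular dialect: tab-delimited UTF-8 with a header row.
Score tables carry ``ligand_id, model, docked, score``; manifests carry
``ligand_id, truth, set_tag``.  Percentages are rounded to one decimal
only at this reporting layer; everything upstream is full precision.
All writers go through an atomic replace so partially written outputs
never appear under the final name.
"""

from __future__ import annotations

import csv
import dataclasses
import io as _io
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .classifier import (
    CALLS,
    MODELS,
    TRUTHS,
    ConfusionSummary,
    DockingOutcome,
    InputError,
    LigandRecord,
    TypeCall,
)
from .enrichment import DEFAULT_FRACTIONS, EFCurve
from .structures import DEFAULT_REGIONS, RmsdProfile

__all__ = [
    "read_score_table",
    "read_manifest",
    "read_calls",
    "write_score_table",
    "write_manifest",
    "write_calls",
    "write_summary",
    "write_ef_curve",
    "write_profile",
    "RunConfig",
    "load_config",
    "save_config",
    "TableFormatError",
]


class TableFormatError(ValueError):
    """Malformed TSV input; message names the offending line."""


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_rows(path: str | Path, required: Sequence[str]):
    """Yield (line_number, dict) for each data row; blank lines skipped."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in required if c not in header]
        if missing:
            raise TableFormatError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(required):
                raise TableFormatError(
                    f"{path}, line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, {c: row[i].strip() if i < len(row) else "" for c, i in idx.items()}


def read_score_table(path: str | Path) -> list[DockingOutcome]:
    """Read a docking-outcome TSV (ligand_id, model, docked, score)."""
    outcomes: list[DockingOutcome] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in _read_rows(path, ("ligand_id", "model", "docked", "score")):
        lid, model = row["ligand_id"], row["model"]
        if model not in MODELS:
            raise TableFormatError(
                f"{path}, line {lineno}: unknown model {model!r}; expected one of {MODELS}"
            )
        if (lid, model) in seen:
            raise TableFormatError(
                f"{path}, line {lineno}: duplicate (ligand, model) row ({lid!r}, {model!r})"
            )
        seen.add((lid, model))
        dtok = row["docked"].lower()
        if dtok in _TRUE:
            docked = True
        elif dtok in _FALSE:
            docked = False
        else:
            raise TableFormatError(
                f"{path}, line {lineno}: docked must be true/false/1/0, got {row['docked']!r}"
            )
        score: float | None = None
        if docked:
            try:
                score = float(row["score"])
            except ValueError:
                raise TableFormatError(
                    f"{path}, line {lineno}: docked row needs a numeric score, "
                    f"got {row['score']!r}"
                ) from None
            if not math.isfinite(score):
                raise TableFormatError(f"{path}, line {lineno}: non-finite score")
        elif row["score"]:
            raise TableFormatError(
                f"{path}, line {lineno}: undocked row must leave score empty"
            )
        try:
            outcomes.append(DockingOutcome(lid, model, docked, score))
        except InputError as exc:
            raise TableFormatError(f"{path}, line {lineno}: {exc}") from exc
    return outcomes


def read_manifest(path: str | Path) -> list[LigandRecord]:
    """Read a truth manifest TSV (ligand_id, truth[, set_tag])."""
    records: list[LigandRecord] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, ("ligand_id", "truth")):
        lid = row["ligand_id"]
        if lid in seen:
            raise TableFormatError(f"{path}, line {lineno}: duplicate ligand id {lid!r}")
        seen.add(lid)
        if row["truth"] not in TRUTHS:
            raise TableFormatError(
                f"{path}, line {lineno}: unknown truth {row['truth']!r}; "
                f"expected one of {TRUTHS}"
            )
        records.append(LigandRecord(lid, row["truth"], row.get("set_tag", "")))
    return records


def read_calls(path: str | Path) -> list[TypeCall]:
    """Read a calls TSV back (ligand_id, call at minimum)."""
    calls: list[TypeCall] = []
    for lineno, row in _read_rows(path, ("ligand_id", "call")):
        if row["call"] not in CALLS:
            raise TableFormatError(
                f"{path}, line {lineno}: unknown call {row['call']!r}"
            )
        calls.append(
            TypeCall(
                row["ligand_id"],
                row["call"],
                row.get("basis", ""),
                float(row["winning_score"]) if row.get("winning_score") else None,
                float(row["margin"]) if row.get("margin") else None,
            )
        )
    return calls


def _tsv(header: Sequence[str], rows: Iterable[Sequence]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(header)
    for row in rows:
        w.writerow(["" if v is None else v for v in row])
    return buf.getvalue()


def write_score_table(outcomes: Sequence[DockingOutcome], path: str | Path) -> None:
    _atomic_write(
        path,
        _tsv(
            ("ligand_id", "model", "docked", "score"),
            (
                (o.ligand_id, o.model, str(o.docked).lower(),
                 None if o.score is None else repr(o.score))
                for o in outcomes
            ),
        ),
    )


def write_manifest(manifest: Sequence[LigandRecord], path: str | Path) -> None:
    _atomic_write(
        path,
        _tsv(
            ("ligand_id", "truth", "set_tag"),
            ((r.ligand_id, r.truth, r.set_tag) for r in manifest),
        ),
    )


def write_calls(calls: Sequence[TypeCall], path: str | Path) -> None:
    _atomic_write(
        path,
        _tsv(
            ("ligand_id", "call", "basis", "winning_score", "margin"),
            (
                (c.ligand_id, c.call, c.basis,
                 None if c.winning_score is None else f"{c.winning_score:.6g}",
                 None if c.margin is None else f"{c.margin:.6g}")
                for c in calls
            ),
        ),
    )


def write_summary(summary: ConfusionSummary, path: str | Path) -> None:
    """Write both a machine-readable counts TSV and the text report."""
    path = Path(path)
    rows = []
    for truth in summary.counts.index:
        for call in summary.counts.columns:
            rows.append((truth, call, int(summary.counts.loc[truth, call])))
    _atomic_write(path.with_suffix(".tsv"), _tsv(("truth", "call", "count"), rows))
    _atomic_write(path.with_suffix(".txt"), summary.summary() + "\n")


def write_ef_curve(curve: EFCurve, path: str | Path) -> None:
    rows = [
        (f"{f:.6g}", n, tt, f"{ef:.6g}") for f, n, tt, ef in curve.points
    ]
    rows.append((f"{curve.ef_max_fraction:.6g}", "", "", f"{curve.ef_max:.6g}"))
    text = _tsv(("fraction", "n_scr", "TT_scr", "EF"), rows)
    text += f"# Nc={curve.nc}\tTTc={curve.ttc}\tEF_upper_bound={curve.upper_bound:.6g}\n"
    _atomic_write(path, text)


def write_profile(profile: RmsdProfile, path: str | Path) -> None:
    _atomic_write(
        path,
        _tsv(
            ("residue_number", "rmsd"),
            ((r, f"{v:.6g}") for r, v in sorted(profile.per_residue.items())),
        ),
    )


@dataclass
class RunConfig:
    """Run-level settings; YAML-serialisable, unknown keys rejected."""

    score_orientation: str = "lower"
    regions: tuple[tuple[int, int], ...] = DEFAULT_REGIONS
    ef_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    tie_policy: str = "ambiguous"
    output_dir: str = "."
    verbosity: str = "info"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.score_orientation not in ("lower", "higher"):
            raise ValueError(f"score_orientation must be lower|higher")
        if self.tie_policy != "ambiguous":
            raise ValueError("only the 'ambiguous' tie policy is implemented")
        self.regions = tuple(tuple(map(int, r)) for r in self.regions)
        self.ef_fractions = tuple(float(f) for f in self.ef_fractions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [list(r) for r in self.regions]
        d["ef_fractions"] = list(self.ef_fractions)
        return d


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {unknown}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    _atomic_write(path, yaml.safe_dump(cfg.to_dict(), sort_keys=True))
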
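"""Synthetic docking outcomes and coordinate pairs.

The docking engine behind the real study is commercial and its scores
were never published, so everything downstream (classification,
enrichment, structural analysis) is exercised here on synthetic inputs
with the same statistical structure:

* per-ligand score pairs whose class-dependent separation mirrors the
  competitive signal (a ligand's own-conformation model tends to score
  more favorably),
* size-dependent docking failure — a bulky antagonist cannot be
  accommodated by the closed agonist-conformation pocket and produces
  no pose there, which is the asymmetry that makes antagonists easier
  to type than agonists,
* decoys drawn from a less favorable score distribution,
* helix-like coordinate traces with perturbations confined to chosen
  residue regions, emulating the localized conformational differences
  between agonist- and antagonist-bound receptor forms.

Fixture tables reproducing the published confusion-table outcome
patterns (which are public, unlike the scores) are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    AGONIST_MODEL,
    ANTAGONIST_MODEL,
    DockingOutcome,
    LigandRecord,
)
from .structures import AtomRecord, StructureModel

__all__ = [
    "ScoreSimConfig",
    "StructureSimConfig",
    "simulate_scores",
    "simulate_structures",
    "emit_fixture_tables",
    "FIXTURE_NAMES",
]


def _default_means() -> dict[tuple[str, str], float]:
    # own-conformation model scores ~1.2 units more favorable on average
    return {
        ("agonist", AGONIST_MODEL): -9.5,
        ("agonist", ANTAGONIST_MODEL): -8.3,
        ("antagonist", AGONIST_MODEL): -7.8,
        ("antagonist", ANTAGONIST_MODEL): -9.5,
        ("decoy", AGONIST_MODEL): -6.5,
        ("decoy", ANTAGONIST_MODEL): -6.5,
    }


def _default_sds() -> dict[tuple[str, str], float]:
    return {k: 0.8 for k in _default_means()}


@dataclass
class ScoreSimConfig:
    """Conditions for the score simulator.

    Defaults emulate the crystallographic benchmark set: 47 agonists and
    19 antagonists, no decoys, with most antagonists too bulky for the
    agonist-conformation pocket.  Scores are Gaussian per class x model
    with lower = more favorable.
    """

    n_agonists: int = 47
    n_antagonists: int = 19
    n_decoys: int = 0
    score_means: dict[tuple[str, str], float] = field(default_factory=_default_means)
    score_sds: dict[tuple[str, str], float] = field(default_factory=_default_sds)
    bulky_fraction: float = 0.85
    p_fail_agonist_model_if_bulky: float = 1.0
    p_fail_baseline: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_agonists, self.n_antagonists, self.n_decoys):
            if n < 0:
                raise ValueError("ligand counts must be non-negative")
        for p in (
            self.bulky_fraction,
            self.p_fail_agonist_model_if_bulky,
            self.p_fail_baseline,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        for k, sd in self.score_sds.items():
            if sd <= 0:
                raise ValueError(f"score sd must be positive, got {sd} for {k}")


def simulate_scores(
    cfg: ScoreSimConfig,
) -> tuple[list[DockingOutcome], list[LigandRecord]]:
    """Draw a docking-outcome table and matching truth manifest.

    Reproducible: the same config (including seed) yields identical
    output.  Failed dockings are emitted as explicit ``docked=False``
    rows for both models, as a real outcome table would record them.
    """
    import warnings

    if cfg.n_agonists + cfg.n_antagonists + cfg.n_decoys == 0:
        warnings.warn("all ligand counts are zero; output is empty", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    outcomes: list[DockingOutcome] = []
    manifest: list[LigandRecord] = []

    groups = (
        ("agonist", cfg.n_agonists, "sim-agonist"),
        ("antagonist", cfg.n_antagonists, "sim-antagonist"),
        ("decoy", cfg.n_decoys, "sim-decoy"),
    )
    for truth, count, tag in groups:
        for i in range(count):
            lid = f"{tag}-{i + 1:04d}"
            manifest.append(LigandRecord(lid, truth, tag))
            bulky = truth == "antagonist" and rng.random() < cfg.bulky_fraction
            for model in (AGONIST_MODEL, ANTAGONIST_MODEL):
                p_fail = cfg.p_fail_baseline
                if bulky and model == AGONIST_MODEL:
                    p_fail = max(p_fail, cfg.p_fail_agonist_model_if_bulky)
                if rng.random() < p_fail:
                    outcomes.append(DockingOutcome(lid, model, docked=False))
                else:
                    score = rng.normal(
                        cfg.score_means[(truth, model)],
                        cfg.score_sds[(truth, model)],
                    )
                    outcomes.append(DockingOutcome(lid, model, True, float(score)))
    return outcomes, manifest


@dataclass
class StructureSimConfig:
    """Conditions for the coordinate-pair simulator.

    A helix-like trace of ``n_residues`` residues starting at author
    number ``residue_start`` is generated; the partner copy is perturbed
    (isotropic Gaussian, ``perturbation_sd`` Å) only inside
    ``perturbation_regions`` and optionally rigidly displaced.  Defaults
    span residues 300-559 so the receptor's discriminating regions
    (338-340 and 532-548) exist in the trace.
    """

    n_residues: int = 260
    atoms_per_residue: int = 5
    residue_start: int = 300
    perturbation_regions: tuple[tuple[int, int], ...] = ((532, 548),)
    perturbation_sd: float = 1.0
    rigid_transform: str = "random"  # "random" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if not (1 <= self.atoms_per_residue <= 9):
            raise ValueError("atoms_per_residue must be in 1..9")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be >= 0")
        if self.rigid_transform not in ("random", "none"):
            raise ValueError(f"rigid_transform must be 'random' or 'none'")
        lo_ok = self.residue_start
        hi_ok = self.residue_start + self.n_residues - 1
        for lo, hi in self.perturbation_regions:
            if lo > hi or lo < lo_ok or hi > hi_ok:
                raise ValueError(
                    f"perturbation region {lo}-{hi} outside residue range "
                    f"{lo_ok}-{hi_ok}"
                )


_ATOM_NAMES = ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "CZ")

# local offsets (Å) of each atom from its residue's CA anchor; chosen to
# be non-collinear so superposition is always well conditioned
_LOCAL_OFFSETS = np.array(
    [
        [-1.2, 0.6, -0.8],  # N
        [0.0, 0.0, 0.0],  # CA
        [1.3, 0.4, 0.6],  # C
        [2.1, 1.3, 0.4],  # O
        [-0.4, -1.4, 0.6],  # CB
        [-0.9, -2.6, 0.1],  # CG
        [-1.5, -3.7, 0.9],  # CD
        [-2.2, -4.8, 0.3],  # CE
        [-2.8, -5.9, 1.1],  # CZ
    ]
)


def _helix_trace(cfg: StructureSimConfig) -> list[AtomRecord]:
    """Ideal-helix CA spiral (2.3 Å radius, 1.5 Å rise, 100°/residue)."""
    atoms = []
    names = _ATOM_NAMES[: cfg.atoms_per_residue]
    offsets = _LOCAL_OFFSETS[: cfg.atoms_per_residue]
    for i in range(cfg.n_residues):
        theta = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        for name, off in zip(names, offsets):
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    residue_number=cfg.residue_start + i,
                    insertion_code="",
                    residue_name="ALA",
                    chain_id="A",
                    position=ca + rot @ off,
                )
            )
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_structures(
    cfg: StructureSimConfig,
) -> tuple[StructureModel, StructureModel]:
    """Generate a reference trace and a locally perturbed partner."""
    rng = np.random.default_rng(cfg.seed)
    base_atoms = _helix_trace(cfg)
    ref = StructureModel("SIM-REF", base_atoms, {"reported_ligand_type": "apo"})

    in_region = {
        a.residue_number
        for a in base_atoms
        if any(lo <= a.residue_number <= hi for lo, hi in cfg.perturbation_regions)
    }
    rot = _random_rotation(rng) if cfg.rigid_transform == "random" else np.eye(3)
    trans = rng.uniform(-20, 20, size=3) if cfg.rigid_transform == "random" else np.zeros(3)
    alt_atoms = []
    for a in base_atoms:
        pos = a.position.copy()
        if a.residue_number in in_region and cfg.perturbation_sd > 0:
            pos = pos + rng.normal(0.0, cfg.perturbation_sd, size=3)
        pos = rot @ pos + trans
        alt_atoms.append(
            AtomRecord(
                atom_name=a.atom_name,
                residue_number=a.residue_number,
                insertion_code=a.insertion_code,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                position=pos,
            )
        )
    alt = StructureModel("SIM-ALT", alt_atoms, {"reported_ligand_type": "apo"})
    return ref, alt


# ---------------------------------------------------------------------------
# fixture outcome tables
#
# The published confusion tables fix, for each benchmark set, how many
# ligands of each truth class fell into each docking-outcome row and, for
# the both-docked ligands, how the score comparison resolved.  The actual
# scores are unpublished; the fixtures below use arbitrary well-separated
# score values that force exactly the published win/loss splits.

FIXTURE_NAMES = ("table3", "table4", "table5", "table6")

# (truth, count, pattern); pattern: both_ag = both docked agonist-model wins,
# both_an = both docked antagonist-model wins, an_only, none
_CRYSTALLOGRAPHIC = (
    ("agonist", 35, "both_ag"),
    ("agonist", 8, "both_an"),
    ("agonist", 4, "an_only"),
    ("antagonist", 1, "both_ag"),
    ("antagonist", 1, "both_an"),
    ("antagonist", 17, "an_only"),
)
_DUD = (
    ("agonist", 47, "both_ag"),
    ("agonist", 19, "both_an"),
    ("agonist", 1, "an_only"),
    ("antagonist", 1, "both_ag"),
    ("antagonist", 2, "both_an"),
    ("antagonist", 34, "an_only"),
    ("antagonist", 2, "none"),
)


def _build_fixture(
    spec: tuple, tag: str
) -> tuple[list[DockingOutcome], list[LigandRecord]]:
    outcomes: list[DockingOutcome] = []
    manifest: list[LigandRecord] = []
    counters: dict[str, int] = {}
    for truth, count, pattern in spec:
        for _ in range(count):
            idx = counters.get(truth, 0) + 1
            counters[truth] = idx
            lid = f"{tag}-{truth[:3]}-{idx:03d}"
            manifest.append(LigandRecord(lid, truth, tag))
            jitter = 0.01 * idx  # distinct scores, never a tie
            if pattern == "both_ag":
                outcomes.append(DockingOutcome(lid, AGONIST_MODEL, True, -10.0 - jitter))
                outcomes.append(DockingOutcome(lid, ANTAGONIST_MODEL, True, -9.0 - jitter))
            elif pattern == "both_an":
                outcomes.append(DockingOutcome(lid, AGONIST_MODEL, True, -9.0 - jitter))
                outcomes.append(DockingOutcome(lid, ANTAGONIST_MODEL, True, -10.0 - jitter))
            elif pattern == "an_only":
                outcomes.append(DockingOutcome(lid, AGONIST_MODEL, False))
                outcomes.append(DockingOutcome(lid, ANTAGONIST_MODEL, True, -9.5 - jitter))
            elif pattern == "none":
                outcomes.append(DockingOutcome(lid, AGONIST_MODEL, False))
                outcomes.append(DockingOutcome(lid, ANTAGONIST_MODEL, False))
            else:  # pragma: no cover
                raise AssertionError(pattern)
    return outcomes, manifest


def emit_fixture_tables(
    name: str,
) -> tuple[list[DockingOutcome], list[LigandRecord]]:
    """Deterministic outcome table reproducing a published pattern.

    ``table3``/``table4`` share the crystallographic-set pattern (the
    two published tables are the SDM and CDA readings of the same
    docking run); ``table5``/``table6`` share the benchmark-binder
    pattern.  Feed the result to ``run_batch`` with the matching mode.
    """
    if name in ("table3", "table4"):
        return _build_fixture(_CRYSTALLOGRAPHIC, "xtal")
    if name in ("table5", "table6"):
        return _build_fixture(_DUD, "dud")
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
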
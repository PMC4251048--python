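"""Receptor-conformation analysis of ligand-binding-domain monomers.

Nuclear-receptor ligand-binding domains adopt distinct shapes depending
on whether an agonist or an antagonist is bound: in the antagonist form
the C-terminal helix (H12) is displaced from the co-regulator groove.
This module parses single-chain monomers from PDB files, superposes
pairs by least squares (Kabsch), and resolves the deviation into
backbone / all-atom / per-residue / region RMSDs.  For the estrogen
receptor α the discriminating regions are the loop connecting helices 2
and 3 (residues 338-340) and the stretch from the end of helix 11
through helix 12 (residues 532-548), in author numbering.

RMSD over n matched atom pairs (V_i, W_i) is

    RMSD = sqrt( (1/n) * sum_i |V_i - W_i|^2 )

computed after a single rigid-body superposition; region and
per-residue values reuse that one fit rather than re-fitting locally,
so they measure genuine local deviation in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "BACKBONE_ATOMS",
    "DEFAULT_REGIONS",
    "AtomRecord",
    "StructureModel",
    "AtomSelection",
    "MatchedPairs",
    "SuperpositionResult",
    "RmsdProfile",
    "ConformationCall",
    "read_structure",
    "match_atoms",
    "kabsch_superpose",
    "rmsd",
    "region_rmsd",
    "per_residue_profile",
    "classify_conformation",
    "select_reference_structures",
    "FormatError",
    "ChainNotFoundError",
    "InsufficientOverlapError",
    "DegenerateGeometryError",
    "SelectionError",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: conformation-discriminating regions, ERα author numbering, inclusive
DEFAULT_REGIONS = ((338, 340), (532, 548))


class FormatError(ValueError):
    """Unparseable PDB content."""


class ChainNotFoundError(KeyError):
    """Requested chain absent from the file."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 matched atoms between two structures."""


class DegenerateGeometryError(ValueError):
    """Coincident or collinear coordinates; superposition underdetermined."""


class SelectionError(ValueError):
    """No candidate structure survives the reference-selection filters."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    residue_number: int
    insertion_code: str
    residue_name: str
    chain_id: str
    position: np.ndarray  # (3,) Å
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy out of [0,1]: {self.occupancy}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.residue_number, self.insertion_code, self.atom_name)


@dataclass
class StructureModel:
    """One single-chain monomer with author residue numbering.

    ``metadata`` carries what reference selection needs: resolution (Å),
    whether the entry is mutated/modified, the bound ligand's id and its
    reported pharmacological type (agonist/antagonist/unknown/apo).
    """

    structure_id: str
    atoms: list[AtomRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        chains = {a.chain_id for a in self.atoms}
        if len(chains) > 1:
            raise ValueError(f"{self.structure_id}: atoms span chains {sorted(chains)}")
        seen: set[tuple[int, str, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"{self.structure_id}: duplicate atom {a.key}")
            seen.add(a.key)

    @property
    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})


@dataclass(frozen=True)
class AtomSelection:
    """Residue ranges (inclusive, author numbering) and an atom set.

    ``residue_ranges=None`` means all residues; ``atom_set`` is either
    ``"backbone"`` (N, CA, C, O) or ``"all"`` (all heavy atoms).
    """

    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_set: str = "backbone"

    def __post_init__(self) -> None:
        if self.atom_set not in ("backbone", "all"):
            raise ValueError(f"atom_set must be 'backbone' or 'all', got {self.atom_set!r}")
        if self.residue_ranges is not None:
            rr = tuple(tuple(map(int, r)) for r in self.residue_ranges)
            for lo, hi in rr:
                if lo > hi:
                    raise ValueError(f"empty residue interval {lo}-{hi}")
            object.__setattr__(self, "residue_ranges", rr)

    def admits(self, atom: AtomRecord) -> bool:
        if self.atom_set == "backbone" and atom.atom_name not in BACKBONE_ATOMS:
            return False
        if self.residue_ranges is None:
            return True
        return any(lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges)


ALL_BACKBONE = AtomSelection(None, "backbone")
ALL_ATOMS = AtomSelection(None, "all")


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform x -> x @ rotation.T + translation and its RMSD."""

    rotation: np.ndarray  # (3,3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MatchedPairs:
    """Paired coordinates of atoms shared by two structures."""

    keys: tuple[tuple[int, str, str], ...]
    coords_a: np.ndarray  # (n, 3)
    coords_b: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class RmsdProfile:
    """Per-residue RMSD (Å) in a common superposition frame."""

    per_residue: dict[int, float]
    selection: AtomSelection


@dataclass(frozen=True)
class ConformationCall:
    structure_id: str
    rmsd_to_agonist_ref: float
    rmsd_to_antagonist_ref: float
    call: str  # agonist-like | antagonist-like | equidistant


_WATER_NAMES = {"HOH", "DOD", "WAT"}

#: pharmacological type of well-characterised ERα ligands by PDB het code
KNOWN_LIGAND_TYPES = {
    "EST": "agonist",  # estradiol (e.g. 1GWR)
    "OHT": "antagonist",  # 4-hydroxytamoxifen (e.g. 3ERT)
    "RAL": "antagonist",  # raloxifene
    "DES": "agonist",  # diethylstilbestrol
    "GEN": "agonist",  # genistein
}


def _is_hydrogen(atom: gemmi.Atom) -> bool:
    return bool(atom.element.is_hydrogen)


def read_structure(
    pdb_text: str,
    chain: str | None = None,
    structure_id: str | None = None,
) -> StructureModel:
    """Parse one monomer chain from PDB-format text.

    The first model is used.  If ``chain`` is omitted, the first chain
    containing polymer (ATOM) residues is taken.  Alternate locations
    are resolved to the highest-occupancy conformer (ties keep altloc
    "A"); hydrogens and hetero atoms are dropped from the atom list, but
    the identity of the first non-water hetero residue on the chain is
    recorded as the bound ligand in ``metadata``.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB content: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB content contains no model")
    model = st[0]

    def chain_has_polymer(ch: gemmi.Chain) -> bool:
        return any(res.het_flag == "A" for res in ch)

    picked = None
    if chain is None:
        for ch in model:
            if chain_has_polymer(ch):
                picked = ch
                break
        if picked is None and len(model) > 0:
            picked = model[0]
        if picked is None:
            raise FormatError("PDB content contains no chains")
    else:
        for ch in model:
            if ch.name == chain:
                picked = ch
                break
        if picked is None:
            raise ChainNotFoundError(
                f"chain {chain!r} not found; available: {[c.name for c in model]}"
            )

    atoms: list[AtomRecord] = []
    ligand_id = None
    for res in picked:
        if res.het_flag != "A":
            if res.name not in _WATER_NAMES and ligand_id is None:
                ligand_id = res.name
            continue
        # altloc groups within the residue, keyed by atom name
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            if _is_hydrogen(atom):
                continue
            by_name.setdefault(atom.name, []).append(atom)
        for name, group in by_name.items():
            best = max(
                group,
                key=lambda a: (a.occ, 1 if (a.altloc or "A") == "A" else 0),
            )
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    chain_id=picked.name,
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    altloc=best.altloc or "",
                    occupancy=min(max(best.occ, 0.0), 1.0),
                )
            )

    sid = structure_id or (st.name.strip() if st.name else "") or "UNKNOWN"
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    meta = {
        "resolution": resolution,
        "has_mutation": None,
        "ligand_id": ligand_id,
        "reported_ligand_type": (
            KNOWN_LIGAND_TYPES.get(ligand_id, "unknown") if ligand_id else "apo"
        ),
    }
    return StructureModel(structure_id=sid, atoms=atoms, metadata=meta)


def match_atoms(
    a: StructureModel,
    b: StructureModel,
    sel: AtomSelection = ALL_BACKBONE,
) -> MatchedPairs:
    """Pair atoms shared by two structures under a selection.

    Matching is by (residue number, insertion code, atom name) —
    strict intersection, no gap imputation — ordered by residue then
    atom name so output is deterministic.
    """
    if not a.atoms or not b.atoms:
        raise InsufficientOverlapError("cannot match atoms of an empty structure")
    map_a = {x.key: x for x in a.atoms if sel.admits(x)}
    map_b = {x.key: x for x in b.atoms if sel.admits(x)}
    shared = sorted(map_a.keys() & map_b.keys())
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} matched atoms between "
            f"{a.structure_id} and {b.structure_id} under selection {sel}"
        )
    va = np.array([map_a[k].position for k in shared])
    vb = np.array([map_b[k].position for k in shared])
    return MatchedPairs(tuple(shared), va, vb)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinates, in Å."""
    va = np.asarray(coords_a, dtype=float)
    vb = np.asarray(coords_b, dtype=float)
    if va.shape != vb.shape or va.ndim != 2 or va.shape[1] != 3:
        raise ValueError(f"paired (n,3) arrays required, got {va.shape} vs {vb.shape}")
    if va.shape[0] == 0:
        raise ValueError("rmsd of zero atom pairs is undefined")
    return float(np.sqrt(np.mean(np.sum((va - vb) ** 2, axis=1))))


def kabsch_superpose(pairs: MatchedPairs) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Classic SVD solution: center both point sets, take the SVD of the
    covariance, and correct an improper rotation through the sign of
    the determinant so the result is a pure rotation.  Raises
    :class:`DegenerateGeometryError` when the points are coincident or
    collinear, where the optimal rotation is not unique.
    """
    va, vb = pairs.coords_a, pairs.coords_b
    n = va.shape[0]
    if n < 3:
        raise InsufficientOverlapError(f"need >=3 pairs, got {n}")
    ca, cb = va.mean(axis=0), vb.mean(axis=0)
    a0, b0 = va - ca, vb - cb
    # rank of either centered set < 2 => collinear/coincident
    for centered in (a0, b0):
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                "coordinates are collinear or coincident; rotation underdetermined"
            )
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    fitted = va @ rot.T + trans
    return SuperpositionResult(rot, trans, rmsd(fitted, vb), n)


def region_rmsd(
    a: StructureModel,
    b: StructureModel,
    regions: Sequence[tuple[int, int]] | None = None,
    superpose_on: AtomSelection = ALL_BACKBONE,
    sel_atom_set: str = "all",
) -> dict[tuple[int, int], float]:
    """RMSD per residue region after one global superposition.

    The fit is computed once on ``superpose_on`` and applied unchanged
    to every region, so region values reflect local deviation in the
    shared frame.  Regions with no matched atoms are omitted from the
    result rather than reported as zero.
    """
    if regions is None:
        regions = DEFAULT_REGIONS
    sup = kabsch_superpose(match_atoms(a, b, superpose_on))
    out: dict[tuple[int, int], float] = {}
    for lo, hi in regions:
        sel = AtomSelection(((lo, hi),), sel_atom_set)
        try:
            pairs = match_atoms(a, b, sel)
        except InsufficientOverlapError:
            # below the generic 3-atom floor: accept any nonzero overlap
            pairs = _match_lenient(a, b, sel)
            if pairs is None:
                continue
        out[(int(lo), int(hi))] = rmsd(sup.apply(pairs.coords_a), pairs.coords_b)
    return out


def _match_lenient(
    a: StructureModel, b: StructureModel, sel: AtomSelection
) -> MatchedPairs | None:
    map_a = {x.key: x for x in a.atoms if sel.admits(x)}
    map_b = {x.key: x for x in b.atoms if sel.admits(x)}
    shared = sorted(map_a.keys() & map_b.keys())
    if not shared:
        return None
    return MatchedPairs(
        tuple(shared),
        np.array([map_a[k].position for k in shared]),
        np.array([map_b[k].position for k in shared]),
    )


def per_residue_profile(
    a: StructureModel,
    b: StructureModel,
    sel: AtomSelection = ALL_ATOMS,
    superpose_on: AtomSelection = ALL_BACKBONE,
) -> RmsdProfile:
    """RMSD of each shared residue after one global superposition.

    Note the mean of per-residue values generally differs from the
    global RMSD (root-mean-square does not average linearly unless all
    residues contribute equal atom counts).
    """
    sup = kabsch_superpose(match_atoms(a, b, superpose_on))
    pairs = _match_lenient(a, b, sel)
    if pairs is None:
        raise InsufficientOverlapError("no shared atoms under profile selection")
    moved = sup.apply(pairs.coords_a)
    profile: dict[int, float] = {}
    residues = np.array([k[0] for k in pairs.keys])
    for resnum in np.unique(residues):
        mask = residues == resnum
        profile[int(resnum)] = rmsd(moved[mask], pairs.coords_b[mask])
    return RmsdProfile(profile, sel)


def classify_conformation(
    s: StructureModel,
    agonist_ref: StructureModel,
    antagonist_ref: StructureModel,
    sel: AtomSelection = ALL_BACKBONE,
) -> ConformationCall:
    """Nearest-reference conformation call.

    The query is superposed independently onto each reference and the
    smaller RMSD wins strictly; an exact tie is reported as
    "equidistant" rather than forced to a label.
    """
    r_ag = kabsch_superpose(match_atoms(s, agonist_ref, sel)).rmsd
    r_an = kabsch_superpose(match_atoms(s, antagonist_ref, sel)).rmsd
    if r_ag < r_an:
        call = "agonist-like"
    elif r_an < r_ag:
        call = "antagonist-like"
    else:
        call = "equidistant"
    return ConformationCall(s.structure_id, r_ag, r_an, call)


def select_reference_structures(
    candidates: Iterable[StructureModel | Mapping],
    type: str,
) -> list:
    """Rank candidate reference structures for one ligand type.

    Keeps entries whose reported bound-ligand type matches, excluding
    mutated/modified entries and unknown-ligand entries, then sorts by
    resolution ascending (best first) with structure id as the
    deterministic tie-break.
    """
    if type not in ("agonist", "antagonist"):
        raise ValueError(f"type must be 'agonist' or 'antagonist', got {type!r}")

    def meta(c):
        if isinstance(c, StructureModel):
            return c.structure_id, c.metadata
        return c["structure_id"], c

    kept = []
    for cand in candidates:
        sid, m = meta(cand)
        if m.get("reported_ligand_type") != type:
            continue
        if m.get("has_mutation"):
            continue
        if m.get("resolution") is None:
            continue
        kept.append((float(m["resolution"]), sid, cand))
    if not kept:
        raise SelectionError(f"no usable {type}-bound candidate structures")
    kept.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in kept]
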
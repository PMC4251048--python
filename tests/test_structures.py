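"""Parsing, superposition and RMSD analysis of monomer structures."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from compdock.structures import (
    ALL_ATOMS,
    ALL_BACKBONE,
    AtomSelection,
    ChainNotFoundError,
    DegenerateGeometryError,
    FormatError,
    InsufficientOverlapError,
    MatchedPairs,
    SelectionError,
    classify_conformation,
    kabsch_superpose,
    match_atoms,
    per_residue_profile,
    read_structure,
    region_rmsd,
    rmsd,
    select_reference_structures,
)

from conftest import make_structure, random_rotation


def atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ",
              record="ATOM", element=" C"):
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f} 20.00          {element}\n"
    )


class TestReadStructure:
    def test_minimal_two_residue_parse(self):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0)
            + atom_line(2, "CA", "GLY", "A", 2, 4.0, 5.0, 6.0)
            + "END\n"
        )
        model = read_structure(text, structure_id="MINI")
        assert len(model.atoms) == 2
        assert model.atoms[0].position == pytest.approx([1.0, 2.0, 3.0])
        assert model.residue_numbers == [1, 2]

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.60, altloc="A")
            + atom_line(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.40, altloc="B")
            + atom_line(3, "CA", "ALA", "A", 2, 1.0, 0.0, 0.0)
            + "END\n"
        )
        model = read_structure(text)
        ca1 = [a for a in model.atoms if a.residue_number == 1]
        assert len(ca1) == 1
        assert ca1[0].position == pytest.approx([0.0, 0.0, 0.0])
        assert ca1[0].occupancy == pytest.approx(0.60)

    def test_altloc_tie_prefers_a(self):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.50, altloc="B")
            + atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.50, altloc="A")
            + "END\n"
        )
        model = read_structure(text)
        assert model.atoms[0].altloc == "A"

    def test_hydrogens_excluded(self):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, "H", "ALA", "A", 1, 0.5, 0.5, 0.5, element=" H")
            + "END\n"
        )
        assert [a.atom_name for a in read_structure(text).atoms] == ["CA"]

    def test_hetero_ligand_recorded_not_in_atoms(self):
        # estradiol (EST) on the same chain: excluded from atoms, typed agonist
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, "C1", "EST", "A", 900, 5.0, 5.0, 5.0, record="HETATM")
            + atom_line(3, "O", "HOH", "A", 901, 8.0, 8.0, 8.0, record="HETATM",
                        element=" O")
            + "END\n"
        )
        model = read_structure(text)
        assert len(model.atoms) == 1
        assert model.metadata["ligand_id"] == "EST"
        assert model.metadata["reported_ligand_type"] == "agonist"

    def test_requested_chain_absent(self):
        text = atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0) + "END\n"
        with pytest.raises(ChainNotFoundError):
            read_structure(text, chain="B")

    def test_unparseable_input_raises_format_error(self):
        with pytest.raises(FormatError):
            read_structure("ATOM      1  CA  ALA A   1      not a coordinate\n")


class TestMatchAtoms:
    def test_identical_backbone_pairs_four_per_residue(self, toy_backbone):
        pairs = match_atoms(toy_backbone, toy_backbone, ALL_BACKBONE)
        assert len(pairs) == 4 * 5
        assert np.allclose(pairs.coords_a, pairs.coords_b)

    def test_missing_residue_excluded_entirely(self, toy_backbone):
        trimmed = make_structure(
            "B",
            {
                r: {a.atom_name: tuple(a.position) for a in toy_backbone.atoms
                    if a.residue_number == r}
                for r in (1, 2, 4, 5)
            },
        )
        pairs = match_atoms(toy_backbone, trimmed, ALL_BACKBONE)
        assert len(pairs) == 16
        assert all(k[0] != 3 for k in pairs.keys)

    def test_atom_name_mismatch_dropped_by_enumeration(self):
        # exhaustive enumeration: A has {N,CA} x 5, B has {N,CA} x 5 except
        # residue 3 where CA is renamed CB -> intersection is 9 atoms
        res_a = {i: {"N": (i, 0, 0), "CA": (i, 1, 0.2 * i)} for i in range(1, 6)}
        res_b = {i: dict(res_a[i]) for i in range(1, 6)}
        res_b[3] = {"N": res_a[3]["N"], "CB": res_a[3]["CA"]}
        a, b = make_structure("A", res_a), make_structure("B", res_b)
        expected = sum(
            1 for i in range(1, 6) for name in res_a[i] if name in res_b[i]
        )
        pairs = match_atoms(a, b, ALL_ATOMS)
        assert len(pairs) == expected == 9

    def test_insufficient_overlap(self):
        a = make_structure("A", {1: {"CA": (0, 0, 0)}, 2: {"CA": (1, 0, 0)}})
        b = make_structure("B", {1: {"CA": (0, 0, 0)}, 9: {"CA": (1, 0, 0)}})
        with pytest.raises(InsufficientOverlapError):
            match_atoms(a, b, ALL_ATOMS)


class TestRmsd:
    def test_identical_points_zero(self):
        x = np.arange(12.0).reshape(4, 3)
        assert rmsd(x, x) == 0.0

    def test_single_pair_three_angstrom(self):
        assert rmsd([[0.0, 0.0, 0.0]], [[0.0, 3.0, 0.0]]) == pytest.approx(3.0)

    def test_hand_computed_three_pairs(self):
        # squared deviations 1, 1, 4 -> sqrt(6/3) = sqrt(2)
        a = [[0, 0, 0], [1, 0, 0], [0, 2, 0]]
        b = [[0, 0, 1], [1, 1, 0], [0, 2, 2]]
        assert rmsd(a, b) == pytest.approx(1.4142135623730951, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.empty((0, 3)), np.empty((0, 3)))

    def test_invariance_under_common_rigid_transform(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        base = rmsd(a, b)
        for seed in range(5):
            r = random_rotation(np.random.default_rng(seed))
            t = np.random.default_rng(seed + 100).uniform(-50, 50, 3)
            assert rmsd(a @ r.T + t, b @ r.T + t) == pytest.approx(base, abs=1e-8)


def _pairs(a: np.ndarray, b: np.ndarray) -> MatchedPairs:
    keys = tuple((i, "", "CA") for i in range(len(a)))
    return MatchedPairs(keys, np.asarray(a, float), np.asarray(b, float))


def numeric_min_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over rotations numerically."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def objective(angles):
        r = Rotation.from_euler("xyz", angles).as_matrix()
        return rmsd(a0 @ r.T, b0)

    best = np.inf
    for start in ([0, 0, 0], [1, 2, 3], [3, 1, 0.5], [-2, 0.5, 2.5]):
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets_identity_rotation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 3))
        sup = kabsch_superpose(_pairs(a, a))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_random_transform(self):
        rng = np.random.default_rng(11)
        a = rng.normal(scale=5.0, size=(30, 3))
        r = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        b = a @ r.T + t
        sup = kabsch_superpose(_pairs(a, b))
        assert sup.rmsd < 1e-8
        assert np.allclose(sup.rotation, r, atol=1e-8)
        assert np.allclose(sup.translation, t, atol=1e-6)
        # recovered transform inverts the applied one
        assert np.allclose(sup.apply(a), b, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(3)
        sup = kabsch_superpose(_pairs(rng.normal(size=(10, 3)),
                                      rng.normal(size=(10, 3))))
        rtr = sup.rotation.T @ sup.rotation
        assert np.linalg.norm(rtr - np.eye(3)) < 1e-8
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_perturbed_four_points_match_numeric_oracle(self):
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        b = a.copy()
        b[2] += [0.4, -0.3, 0.5]  # one perturbed point
        got = kabsch_superpose(_pairs(a, b)).rmsd
        assert got == pytest.approx(numeric_min_rmsd(a, b), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_least_squares_optimality_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.5, size=(6, 3))
        sup = kabsch_superpose(_pairs(a, b))
        assert sup.rmsd <= rmsd(a, b) + 1e-12
        assert sup.rmsd == pytest.approx(numeric_min_rmsd(a, b), abs=1e-5)
        # agrees with the scipy implementation of the same problem
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_collinear_input_rejected(self):
        a = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(_pairs(a, a))


def perturbed_copy(model, region, sd, seed):
    rng = np.random.default_rng(seed)
    residues = {}
    for a in model.atoms:
        pos = np.array(a.position)
        if region[0] <= a.residue_number <= region[1]:
            pos = pos + rng.normal(scale=sd, size=3)
        residues.setdefault(a.residue_number, {})[a.atom_name] = tuple(pos)
    return make_structure(model.structure_id + "-P", residues)


@pytest.fixture
def numbered_helix():
    """Backbone spanning author numbers 330-560 (helical trace)."""
    residues = {}
    for i, resnum in enumerate(range(330, 561)):
        theta = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        residues[resnum] = {
            "N": tuple(ca + [-1.2, 0.6, -0.8]),
            "CA": tuple(ca),
            "C": tuple(ca + [1.3, 0.4, 0.6]),
            "O": tuple(ca + [2.1, 1.3, 0.4]),
        }
    return make_structure("HELIX", residues)


class TestRegionRmsd:
    def test_identical_structures_all_zero(self, numbered_helix):
        out = region_rmsd(numbered_helix, numbered_helix)
        assert set(out) == {(338, 340), (532, 548)}
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in out.values())

    def test_perturbation_localized_to_late_region(self, numbered_helix):
        other = perturbed_copy(numbered_helix, (532, 548), sd=1.5, seed=5)
        out = region_rmsd(numbered_helix, other)
        assert out[(532, 548)] > 10 * out[(338, 340)]

    def test_default_regions(self, numbered_helix):
        assert set(region_rmsd(numbered_helix, numbered_helix).keys()) == {
            (338, 340),
            (532, 548),
        }

    def test_absent_region_omitted_not_zero(self, numbered_helix):
        out = region_rmsd(numbered_helix, numbered_helix, regions=[(1, 5), (338, 340)])
        assert (1, 5) not in out
        assert (338, 340) in out

    def test_union_is_weighted_rms_of_parts(self, numbered_helix):
        other = perturbed_copy(numbered_helix, (340, 560), sd=0.8, seed=9)
        parts = region_rmsd(numbered_helix, other, regions=[(338, 340), (532, 548)])
        a, b = parts[(338, 340)], parts[(532, 548)]
        # weighted RMS identity: regions contribute 3 and 17 residues x 4 atoms
        n1, n2 = 3 * 4, 17 * 4
        sup = kabsch_superpose(match_atoms(numbered_helix, other))
        sel = AtomSelection(((338, 340), (532, 548)), "all")
        pairs = match_atoms(numbered_helix, other, sel)
        got = rmsd(sup.apply(pairs.coords_a), pairs.coords_b)
        expected = np.sqrt((n1 * a**2 + n2 * b**2) / (n1 + n2))
        assert got == pytest.approx(expected, abs=1e-10)


class TestPerResidueProfile:
    def test_identical_structures_zero_profile(self, numbered_helix):
        prof = per_residue_profile(numbered_helix, numbered_helix)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in prof.per_residue.values())

    def test_profile_peaks_at_perturbed_residue(self, numbered_helix):
        other = perturbed_copy(numbered_helix, (540, 540), sd=2.0, seed=13)
        prof = per_residue_profile(numbered_helix, other)
        assert max(prof.per_residue, key=prof.per_residue.get) == 540

    def test_rms_of_profile_equals_global_with_equal_atom_counts(self, numbered_helix):
        # every residue contributes exactly 4 backbone atoms, so the
        # root-mean-square of per-residue values recovers the global RMSD
        other = perturbed_copy(numbered_helix, (330, 560), sd=0.5, seed=17)
        prof = per_residue_profile(numbered_helix, other, sel=ALL_BACKBONE)
        sup = kabsch_superpose(match_atoms(numbered_helix, other))
        vals = np.array(list(prof.per_residue.values()))
        assert np.sqrt(np.mean(vals**2)) == pytest.approx(sup.rmsd, abs=1e-10)
        # the plain mean underestimates it (Jensen), documented inequality
        assert vals.mean() <= sup.rmsd + 1e-12


class TestClassifyConformation:
    def test_references_classify_as_themselves(self, numbered_helix):
        other = perturbed_copy(numbered_helix, (532, 548), sd=2.0, seed=19)
        assert classify_conformation(numbered_helix, numbered_helix, other).call == "agonist-like"
        assert classify_conformation(other, numbered_helix, other).call == "antagonist-like"

    def test_self_comparison_zero_rmsd(self, numbered_helix):
        other = perturbed_copy(numbered_helix, (532, 548), sd=2.0, seed=19)
        call = classify_conformation(numbered_helix, numbered_helix, other)
        assert call.rmsd_to_agonist_ref == pytest.approx(0.0, abs=1e-10)

    def test_interpolated_structure_calls_nearest(self, numbered_helix):
        anta = perturbed_copy(numbered_helix, (532, 548), sd=2.0, seed=23)
        residues = {}
        pos_a = {a.key: a.position for a in numbered_helix.atoms}
        for a in anta.atoms:
            mix = 0.1 * pos_a[a.key] + 0.9 * a.position  # 90% toward antagonist
            residues.setdefault(a.residue_number, {})[a.atom_name] = tuple(mix)
        query = make_structure("Q", residues)
        assert classify_conformation(query, numbered_helix, anta).call == "antagonist-like"

    def test_exact_tie_is_equidistant(self, numbered_helix):
        call = classify_conformation(numbered_helix, numbered_helix, numbered_helix)
        assert call.call == "equidistant"


class TestSelectReferenceStructures:
    CANDS = [
        {"structure_id": "1GWR", "resolution": 2.4, "has_mutation": False,
         "reported_ligand_type": "agonist"},
        {"structure_id": "MUTA", "resolution": 1.8, "has_mutation": True,
         "reported_ligand_type": "agonist"},
        {"structure_id": "3ERT", "resolution": 1.9, "has_mutation": False,
         "reported_ligand_type": "antagonist"},
        {"structure_id": "XLOW", "resolution": 2.6, "has_mutation": False,
         "reported_ligand_type": "antagonist"},
        {"structure_id": "UNKN", "resolution": 1.0, "has_mutation": False,
         "reported_ligand_type": "unknown"},
    ]

    def test_mutant_excluded_despite_better_resolution(self):
        ranked = select_reference_structures(self.CANDS, "agonist")
        assert [c["structure_id"] for c in ranked] == ["1GWR"]

    def test_antagonists_sorted_by_resolution(self):
        ranked = select_reference_structures(self.CANDS, "antagonist")
        assert [c["structure_id"] for c in ranked] == ["3ERT", "XLOW"]

    def test_single_candidate_returned_unchanged(self):
        ranked = select_reference_structures([self.CANDS[0]], "agonist")
        assert ranked == [self.CANDS[0]]

    def test_empty_after_filtering_raises(self):
        with pytest.raises(SelectionError):
            select_reference_structures([self.CANDS[1]], "agonist")
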
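import numpy as np
import pytest
from scipy import stats

from conftest import audit_molecule, audit_uniform, make_structures
from xtalgen.cells import CellLengths
from xtalgen.errors import ConfigurationError, DomainError
from xtalgen.oblique import vectors_from_lengths
from xtalgen.placement import (
    Atom,
    ContentBudget,
    CrystalStructure,
    ElementFrequencyTable,
    PlacementRules,
    ShortfallWarning,
    assign_adps,
    grow_artificial_molecule,
    make_equal_atom,
    place_uniform,
    populate_special_positions,
    sample_budget,
    sample_sphere_point,
)
from xtalgen.symmetry import SPECIAL, p1bar_group


def cube_structure(edge: float = 10.0) -> CrystalStructure:
    return CrystalStructure.from_vectors(
        vectors_from_lengths(CellLengths(edge, edge, edge)), p1bar_group()
    )


class TestBudget:
    def test_forced_v_atom(self):
        rng = np.random.default_rng(0)
        b = sample_budget(800.0, p1bar_group(), rng, v_atom_range=(10.0, 10.0))
        assert b.n_nonh == 40  # round(800 / (2 * 10))

    def test_forced_hydrogen_fraction(self):
        rng = np.random.default_rng(0)
        b = sample_budget(
            800.0, p1bar_group(), rng, v_atom_range=(10.0, 10.0), x_h_range=(0.5, 0.5)
        )
        assert b.n_h == 40  # x/(1-x) = 1

    def test_zero_hydrogen(self):
        rng = np.random.default_rng(0)
        b = sample_budget(800.0, p1bar_group(), rng, x_h_range=(0.0, 0.0))
        assert b.n_h == 0

    def test_floor_at_one(self):
        rng = np.random.default_rng(0)
        b = sample_budget(5.0, p1bar_group(), rng, v_atom_range=(22.0, 22.0))
        assert b.n_nonh == 1

    def test_invalid_volume(self):
        with pytest.raises(DomainError):
            sample_budget(0.0, p1bar_group(), np.random.default_rng(0))


class TestFrequencyTable:
    def test_default_loads(self, freq_table):
        assert abs(sum(freq_table.general.values()) - 1.0) < 1e-9
        assert abs(sum(freq_table.special.values()) - 1.0) < 1e-9
        assert "H" not in freq_table.general
        assert freq_table.radius("C") == 0.76  # Cordero sp3 value

    def test_cno_shares(self, freq_table):
        general_cno = sum(freq_table.general[e] for e in "CNO")
        special_cno = sum(freq_table.special[e] for e in "CNO")
        assert general_cno == pytest.approx(0.89, abs=1e-9)
        assert special_cno == pytest.approx(0.49, abs=1e-9)

    def test_bad_table_rejected(self, freq_table):
        with pytest.raises(ConfigurationError):
            ElementFrequencyTable(
                general={"C": 0.5}, special=freq_table.special, radii=freq_table.radii
            )
        with pytest.raises(ConfigurationError):
            ElementFrequencyTable(
                general={"H": 1.0}, special=freq_table.special, radii=freq_table.radii
            )

    def test_unknown_radius(self, freq_table):
        with pytest.raises(ConfigurationError):
            freq_table.radius("Xx")


class TestSpherePoint:
    def test_exact_radius(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = sample_sphere_point(np.array([1.0, -2.0, 3.0]), 1.5, rng)
            assert np.linalg.norm(p - [1.0, -2.0, 3.0]) == pytest.approx(1.5, abs=1e-12)

    def test_zero_mean_direction(self):
        rng = np.random.default_rng(2)
        n = 200_000
        pts = np.array([sample_sphere_point(np.zeros(3), 1.0, rng) for _ in range(n)])
        sigma = 1.0 / np.sqrt(3 * n)  # per-axis s.d. of the mean (E[z^2] = 1/3)
        assert np.all(np.abs(pts.mean(axis=0)) < 4 * sigma)

    def test_hatbox_z_uniform(self):
        # Archimedes: z-coordinate uniform on [-r, r]
        rng = np.random.default_rng(3)
        z = np.array(
            [sample_sphere_point(np.zeros(3), 2.0, rng)[2] for _ in range(300_000)]
        )
        ks = stats.kstest(z, stats.uniform(loc=-2.0, scale=4.0).cdf).statistic
        assert ks < 0.005

    def test_bad_radius(self):
        with pytest.raises(DomainError):
            sample_sphere_point(np.zeros(3), 0.0, np.random.default_rng(0))


class TestPlaceUniform:
    def test_contact_rule_audit(self, uniform_structures):
        rules = PlacementRules()
        for s in uniform_structures:
            assert audit_uniform(s, rules.d_min_contact) == 0

    def test_impossible_dmin_places_at_most_one(self, freq_table):
        rng = np.random.default_rng(4)
        s = cube_structure(4.0)
        budget = ContentBudget(v_atom=10.0, x_h=0.0, n_nonh=5, n_h=0)
        rules = PlacementRules(d_min_contact=50.0)
        with pytest.warns(ShortfallWarning):
            place_uniform(s, budget, rules, freq_table, rng)
        assert len(s.atoms) <= 1

    def test_minimum_one_atom(self, freq_table):
        rng = np.random.default_rng(5)
        s = cube_structure()
        budget = ContentBudget(v_atom=22.0, x_h=0.0, n_nonh=1, n_h=0)
        place_uniform(s, budget, rules=PlacementRules(), table=freq_table, rng=rng)
        assert sum(1 for a in s.atoms if a.element != "H") == 1

    def test_hydrogen_count_exact_without_shortfall(self, uniform_structures):
        for s in uniform_structures:
            r = s.report
            if r.shortfall == 0:
                n_h = sum(1 for a in s.atoms if a.element == "H")
                assert n_h == r.requested_h

    def test_element_frequencies_converge(self, uniform_structures, freq_table):
        observed: dict[str, int] = {}
        for s in uniform_structures:
            for a in s.atoms:
                if a.element != "H" and a.site.kind != SPECIAL:
                    observed[a.element] = observed.get(a.element, 0) + 1
        n = sum(observed.values())
        # merge rare elements so every expected count is >= 5
        main = [e for e, p in freq_table.general.items() if p * n >= 5]
        obs = [observed.get(e, 0) for e in main] + [
            sum(c for e, c in observed.items() if e not in main)
        ]
        exp = [freq_table.general[e] * n for e in main]
        exp.append(n - sum(exp))
        chi2 = stats.chisquare(obs, exp)
        assert chi2.pvalue > 0.01


class TestGrowMolecule:
    def test_contact_dichotomy_audit(self, molecule_structures, freq_table):
        rules = PlacementRules()
        low, high = rules.bond_window
        for s in molecule_structures:
            assert audit_molecule(s, freq_table, low, high, rules.nonbond_factor) == 0

    def test_connectivity(self, molecule_structures, freq_table):
        # every non-special atom has >= 1 neighbor inside its bond window
        from conftest import brute_force_pair_distances

        for s in molecule_structures:
            if sum(1 for a in s.atoms if a.site.kind != SPECIAL) < 2:
                continue
            d, ei, ej = brute_force_pair_distances(s)
            rsum = np.array(
                [freq_table.radius(a) + freq_table.radius(b) for a, b in zip(ei, ej)]
            )
            bonded = (d >= 0.9 * rsum * (1 - 1e-9)) & (d <= 1.1 * rsum * (1 + 1e-9))
            # count bonded partners per expanded image via the oracle pairs
            # (at least the grown parent bond must show up for the asym atom
            # or its inversion mate)
            frac_bonded = bonded.mean()
            assert bonded.sum() >= len([a for a in s.atoms if a.site.kind != SPECIAL]) - 1
            assert frac_bonded > 0.0

    def test_cc_bond_lengths_within_window(self):
        # Cordero C radius 0.76: window U(0.9*1.52, 1.1*1.52) = [1.368, 1.672]
        table = ElementFrequencyTable(
            general={"C": 1.0},
            special={"C": 1.0},
            radii={"C": 0.76, "H": 0.31},
        )
        rng = np.random.default_rng(6)
        s = cube_structure(10.0)
        budget = ContentBudget(v_atom=12.0, x_h=0.0, n_nonh=20, n_h=0)
        grow_artificial_molecule(s, budget, PlacementRules(), table, rng)
        d, ei, ej = __import__("conftest").brute_force_pair_distances(s)
        bonded = d[(d >= 1.368 - 1e-9) & (d <= 1.672 + 1e-9)]
        others = d[(d < 1.368 - 1e-9) | (d > 1.672 + 1e-9)]
        assert len(bonded) >= len(s.atoms) - 1
        assert np.all(others >= 1.5 * 1.52 * (1 - 1e-9))

    def test_hydrogens_last_and_bonded_to_heavy(self, molecule_structures):
        for s in molecule_structures:
            elements = [a.element for a in s.atoms]
            if "H" in elements:
                first_h = elements.index("H")
                assert all(e == "H" for e in elements[first_h:])


class TestSpecialPositions:
    def test_populate(self, freq_table):
        rng = np.random.default_rng(7)
        s = cube_structure()
        populate_special_positions(s, [0, 2], freq_table, rng)
        assert len(s.atoms) == 2
        assert all(a.site.kind == SPECIAL for a in s.atoms)
        assert np.allclose(s.atoms[1].frac, [0.0, 0.5, 0.0])

    def test_specials_count_against_budget(self, freq_table):
        rng = np.random.default_rng(8)
        s = cube_structure()
        populate_special_positions(s, [0, 1], freq_table, rng)
        budget = ContentBudget(v_atom=10.0, x_h=0.0, n_nonh=5, n_h=0)
        place_uniform(s, budget, PlacementRules(), freq_table, rng)
        assert sum(1 for a in s.atoms if a.element != "H") <= 5


class TestAdps:
    def test_zero_deviation_shares_structure_u(self):
        rng = np.random.default_rng(9)
        atoms = [Atom("C", np.zeros(3)) for _ in range(10)]
        assign_adps(atoms, rng, dev_range=(0.0, 0.0))
        assert len({a.u_iso for a in atoms}) == 1

    def test_default_interval(self):
        rng = np.random.default_rng(10)
        atoms = [Atom("C", np.zeros(3)) for _ in range(5000)]
        assign_adps(atoms, rng)
        u = np.array([a.u_iso for a in atoms])
        assert u.min() >= 0.005 and u.max() <= 0.105

    def test_clamp(self):
        rng = np.random.default_rng(11)
        atoms = [Atom("C", np.zeros(3))]
        assign_adps(atoms, rng, u_range=(0.001, 0.001), dev_range=(-0.005, -0.005))
        assert atoms[0].u_iso == 0.001


class TestEqualAtom:
    def test_replaces_all(self, molecule_structures):
        import copy

        s = copy.deepcopy(molecule_structures[0])
        coords_before = [a.frac.copy() for a in s.atoms]
        make_equal_atom(s)
        assert {a.element for a in s.atoms} == {"C"}
        for before, atom in zip(coords_before, s.atoms):
            assert np.array_equal(before, atom.frac)

    def test_idempotent(self, molecule_structures):
        import copy

        s = copy.deepcopy(molecule_structures[0])
        once = [a.element for a in make_equal_atom(s).atoms]
        twice = [a.element for a in make_equal_atom(s).atoms]
        assert once == twice


class TestRules:
    def test_invalid_windows(self):
        with pytest.raises(ConfigurationError):
            PlacementRules(bond_window=(1.1, 0.9))
        with pytest.raises(ConfigurationError):
            PlacementRules(nonbond_factor=1.0)
        with pytest.raises(ConfigurationError):
            PlacementRules(max_coord_retries=0)
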
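import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paranmr.io import SSPrediction
from paranmr.pre import PREMeasurement
from paranmr.restraints import (
    PRE_FORCE_CONSTANT,
    PRE_FORCE_CONSTANT_KJ_NM2,
    FlatBottomRestraint,
    ReplicaLadder,
    RestraintCollection,
    build_pre_collections,
    build_ss_restraints,
    collection_energy,
    flat_bottom_energy,
    ladder_scale,
    restraint_energy_force,
    select_active,
)


def make_restraint(lower=10.0, upper=20.0, k=PRE_FORCE_CONSTANT, switch=3.0):
    return FlatBottomRestraint(
        "L1C", ("protein", 1), lower, upper, k, linear_switch=switch
    )


class TestFlatBottom:
    def test_zero_inside_flat_region(self):
        r = make_restraint()
        for d in (10.0, 12.5, 20.0):
            assert restraint_energy_force(r, d) == (0.0, 0.0)

    def test_unit_violation_energy(self):
        # k = 2.5 kJ/mol/Å^2 (the 250 kJ/mol/nm^2 default), 1 Å violation
        assert PRE_FORCE_CONSTANT == PRE_FORCE_CONSTANT_KJ_NM2 / 100.0
        e, f = restraint_energy_force(make_restraint(), 21.0)
        assert e == pytest.approx(0.5 * 2.5 * 1.0**2) == pytest.approx(1.25)
        assert f == pytest.approx(2.5)

    def test_c1_continuity_at_linear_switch(self):
        r = make_restraint()
        d = 20.0 + 3.0
        e_quad, f_quad = flat_bottom_energy(d - 1e-13, 10, 20, 2.5, 3.0)
        e_lin, f_lin = flat_bottom_energy(d + 1e-13, 10, 20, 2.5, 3.0)
        assert e_quad == pytest.approx(e_lin, abs=1e-10)
        assert f_quad == pytest.approx(f_lin, abs=1e-10)

    def test_linear_branch_has_constant_slope(self):
        e1, f1 = flat_bottom_energy(25.0, 10, 20, 2.5, 3.0)
        e2, f2 = flat_bottom_energy(27.0, 10, 20, 2.5, 3.0)
        assert f1 == f2 == pytest.approx(2.5 * 3.0)
        assert e2 - e1 == pytest.approx(2 * 2.5 * 3.0)

    def test_pure_quadratic_mode(self):
        e, f = flat_bottom_energy(30.0, 10, 20, 2.5, None)
        assert e == pytest.approx(0.5 * 2.5 * 100.0)
        assert f == pytest.approx(2.5 * 10.0)

    def test_lower_side_mirrored_with_negative_slope(self):
        e, f = flat_bottom_energy(8.0, 10, 20, 2.5, 3.0)
        assert e == pytest.approx(0.5 * 2.5 * 4.0)
        assert f == pytest.approx(-2.5 * 2.0)

    @settings(deadline=None, derandomize=True)
    @given(d=st.floats(0.0, 40.0))
    def test_force_is_negative_gradient(self, d):
        eps = 1e-6
        e_p, _ = flat_bottom_energy(d + eps, 10, 20, 2.5, 3.0)
        e_m, _ = flat_bottom_energy(max(0.0, d - eps), 10, 20, 2.5, 3.0)
        _, dE = flat_bottom_energy(d, 10, 20, 2.5, 3.0)
        num = (e_p - e_m) / (eps + min(eps, d))
        assert dE == pytest.approx(num, abs=1e-4)


class TestSelection:
    def test_default_fraction_selects_90_of_100(self, rng):
        coll = RestraintCollection([make_restraint() for _ in range(100)], 0.9)
        energies = rng.permutation(100).astype(float)
        active = select_active(coll, energies)
        assert len(active) == 90
        # the 10 largest energies are exactly the ones left out
        assert set(np.argsort(energies)[-10:]) == set(range(100)) - set(active)

    def test_full_fraction_keeps_everything(self):
        coll = RestraintCollection([make_restraint()] * 7, 1.0)
        assert len(select_active(coll, np.arange(7.0))) == 7

    def test_ties_break_by_ascending_index(self):
        coll = RestraintCollection([make_restraint()] * 10, 0.9)
        active = select_active(coll, np.zeros(10))
        assert list(active) == list(range(9))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            RestraintCollection([], 0.9).n_active
            select_active(RestraintCollection([], 0.9), [])

    def test_ceil_guarantee_on_awkward_sizes(self):
        # ceil(0.9*30) must be 27, not a float artifact away
        assert RestraintCollection([make_restraint()] * 30, 0.9).n_active == 27
        assert RestraintCollection([make_restraint()] * 7, 0.9).n_active == 7
        assert RestraintCollection([make_restraint()] * 104, 0.95).n_active == 99


class TestCollectionEnergy:
    def test_nine_of_ten_satisfied_is_free(self):
        coll = RestraintCollection([make_restraint()] * 10, 0.9)
        energies = [0.0] * 9 + [12.0]
        assert collection_energy(coll, energies) == 0.0

    def test_eight_of_ten_pays_least_violated_member(self):
        coll = RestraintCollection([make_restraint()] * 10, 0.9)
        energies = [0.0] * 8 + [3.0, 12.0]
        assert collection_energy(coll, energies) == 3.0

    def test_all_satisfied_is_exactly_zero(self):
        coll = RestraintCollection([make_restraint()] * 10, 0.9)
        assert collection_energy(coll, np.zeros(10)) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(3, 12),
        f=st.floats(0.3, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_matches_subset_enumeration_oracle(self, n, f, seed):
        rng = np.random.default_rng(seed)
        energies = rng.exponential(2.0, size=n)
        coll = RestraintCollection([make_restraint()] * n, f)
        m = coll.n_active
        brute = min(
            sum(energies[i] for i in subset)
            for subset in itertools.combinations(range(n), m)
        )
        assert collection_energy(coll, energies) == pytest.approx(brute, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariant_for_distinct_energies(self, seed):
        rng = np.random.default_rng(seed)
        energies = rng.permutation(12).astype(float)
        coll = RestraintCollection([make_restraint()] * 12, 0.75)
        e0 = collection_energy(coll, energies)
        perm = rng.permutation(12)
        assert collection_energy(coll, energies[perm]) == pytest.approx(e0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_energy_non_increasing_as_fraction_decreases(self, seed):
        rng = np.random.default_rng(seed)
        energies = rng.exponential(1.0, size=15)
        fractions = [1.0, 0.9, 0.7, 0.5, 0.3]
        values = [
            collection_energy(RestraintCollection([make_restraint()] * 15, f), energies)
            for f in fractions
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def make_measurements(n_sites=10, with_all_classes=True):
    ms = []
    for s in range(n_sites):
        site = f"L{s}C"
        ms.append(PREMeasurement(site, "protein", 1, "broadened", "broadened"))
        if with_all_classes:
            ms.append(PREMeasurement(site, "protein", 2, 30.0, 15.0))
            ms.append(PREMeasurement(site, "protein", 3, 1.0, 25.0))
    return ms


class TestBuilders:
    def test_by_site_and_class_gives_thirty_collections(self):
        colls = build_pre_collections(make_measurements(), "by_site_and_class")
        assert len(colls) == 30
        assert all(c.active_fraction == 0.9 for c in colls)

    def test_single_scheme_gives_one_collection(self):
        colls = build_pre_collections(make_measurements(), "single")
        assert len(colls) == 1
        assert len(colls[0]) == 30

    def test_missing_class_pair_is_omitted(self):
        ms = make_measurements()
        ms = [
            m for m in ms if not (m.label_site == "L0C" and m.dclass == "long")
        ]
        assert len(build_pre_collections(ms, "by_site_and_class")) == 29

    def test_restraint_bounds_follow_classification(self):
        colls = build_pre_collections(make_measurements(), "by_site_and_class")
        for coll in colls:
            for r in coll.restraints:
                if r.dclass == "short":
                    assert (r.lower, r.upper) == (0.0, 17.0)
                elif r.dclass == "medium":
                    assert (r.lower, r.upper) == (10.0, 20.0)
                else:
                    assert r.lower == 15.0 and math.isinf(r.upper)


class TestSSFragments:
    def test_uniform_helix_yields_window_per_start(self):
        coll = build_ss_restraints(SSPrediction("protein", "HHHHHHH"))
        assert len(coll) == 3  # windows starting at residues 1, 2, 3
        assert all(g.ss_class == "helix" for g in coll.restraints)
        assert coll.active_fraction == 0.95

    def test_four_of_five_qualifies(self):
        coll = build_ss_restraints(SSPrediction("protein", "HHLHH"))
        assert len(coll) == 1

    def test_three_of_five_does_not_qualify(self):
        with pytest.warns(UserWarning):
            coll = build_ss_restraints(SSPrediction("protein", "HHLLH"))
        assert len(coll) == 0

    def test_extended_windows_use_extended_templates(self):
        coll = build_ss_restraints(SSPrediction("protein", "EEEEE"))
        (group,) = coll.restraints
        assert group.ss_class == "extended"
        assert all(t.target_deg in (-135.0, 135.0) for t in group.torsions)

    def test_too_short_prediction_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            coll = build_ss_restraints(SSPrediction("protein", "HHH"))
        assert len(coll) == 0

    def test_fragment_contents(self):
        coll = build_ss_restraints(SSPrediction("protein", "HHHHHH"))
        group = coll.restraints[0]
        assert list(group.residues) == [1, 2, 3, 4, 5]
        assert len(group.torsions) == 10  # phi+psi per residue
        assert [d[:2] for d in group.ca_distances] == [(1, 4), (2, 5)]


class TestLadder:
    def test_bottom_and_top_of_ladder(self):
        ladder = ReplicaLadder(n_replicas=8, t_min=300.0, t_max=500.0, alpha_min=0.0)
        assert ladder_scale(ladder, 0) == (300.0, 1.0)
        t_top, a_top = ladder_scale(ladder, 7)
        assert t_top == pytest.approx(500.0)
        assert a_top == 0.0

    def test_geometric_temperature_ratio_constant(self):
        ladder = ReplicaLadder(n_replicas=6, t_min=290.0, t_max=510.0)
        ratios = [
            ladder.temperature(i + 1) / ladder.temperature(i) for i in range(5)
        ]
        assert all(r == pytest.approx(ratios[0], rel=1e-12) for r in ratios)

    def test_alpha_non_increasing(self):
        ladder = ReplicaLadder(n_replicas=8, alpha_min=0.2)
        alphas = [ladder.alpha(i) for i in range(8)]
        assert alphas[0] == 1.0 and alphas[-1] == pytest.approx(0.2)
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))

    def test_out_of_range_replica_rejected(self):
        ladder = ReplicaLadder(n_replicas=4)
        with pytest.raises(IndexError):
            ladder.temperature(4)
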
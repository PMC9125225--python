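"""Reservoir structure, generator assembly, units, and compatibility."""

import numpy as np
import pytest

import unitflow as uf
from unitflow.errors import IndependenceError

FLIP = np.array([[-1.0, 1.0], [1.0, -1.0]])


def two_bit_space():
    return uf.JointSpace([uf.Coordinate("1", 2), uf.Coordinate("2", 2)])


def flip_reservoir(name, coord, rate=1.0):
    return uf.Reservoir(name, {coord}, {coord}, uf.ConstantRates(rate * FLIP))


def two_flip_system(r1=1.0, r2=1.0):
    return uf.CompositeSystem(two_bit_space(), [
        flip_reservoir("f1", "1", r1), flip_reservoir("f2", "2", r2)
    ])


class TestValidateReservoir:
    def test_valid_bit_flip(self):
        sp = two_bit_space()
        assert uf.validate_reservoir(flip_reservoir("f", "1"), sp) == []

    def test_moves_non_puppet(self):
        # full matrix that swaps both bits although only "1" is declared puppet
        sp = two_bit_space()
        M = np.zeros((4, 4))
        M[sp.index((1, 1)), sp.index((0, 0))] = 1.0
        M[sp.index((0, 0)), sp.index((1, 1))] = 1.0
        np.fill_diagonal(M, -M.sum(axis=0))
        res = uf.Reservoir("bad", {"1"}, {"1"}, uf.ConstantRates(M),
                           full_matrix=True)
        v = uf.validate_reservoir(res, sp)
        assert any("non-puppet" in msg for msg in v)

    def test_non_leader_dependence(self):
        # rates for coordinate 1 secretly depend on coordinate 3, which is
        # not in the declared leader set {1, 2}
        sp = uf.JointSpace([uf.Coordinate(n, 2) for n in "123"])
        M = np.zeros((8, 8))
        for x2 in (0, 1):
            for x3 in (0, 1):
                rate = 1.0 + x3  # illegal x3 dependence
                a = sp.index((0, x2, x3))
                b = sp.index((1, x2, x3))
                M[b, a] += rate
                M[a, b] += rate
        np.fill_diagonal(M, 0.0)
        np.fill_diagonal(M, -M.sum(axis=0))
        res = uf.Reservoir("bad", {"1"}, {"1", "2"}, uf.ConstantRates(M),
                           full_matrix=True)
        v = uf.validate_reservoir(res, sp)
        assert any("non-leader" in msg for msg in v)
        # exhaustive confirmation that the dependence is real
        assert M[sp.index((1, 0, 0)), sp.index((0, 0, 0))] != \
            M[sp.index((1, 0, 1)), sp.index((0, 0, 1))]

    def test_column_sum_violation(self):
        sp = two_bit_space()
        bad = uf.Reservoir("bad", {"1"}, {"1"},
                           uf.ConstantRates(np.array([[-1.0, 1.0],
                                                      [1.0, -0.5]])))
        v = uf.validate_reservoir(bad, sp)
        assert any("column sums" in msg for msg in v)

    def test_leader_must_contain_puppet(self):
        with pytest.raises(ValueError, match="leader"):
            uf.Reservoir("r", {"1", "2"}, {"1"}, uf.ConstantRates(np.eye(2)))


class TestClosures:
    def test_fig1_reservoirs_affecting(self, fig1):
        sys = fig1.system
        nu3 = sys.reservoirs_affecting({"3"})
        assert len(nu3) == 1
        assert nu3[0].puppets == frozenset({"3"})
        assert sys.leader_closure({"3"}) == frozenset({"3"})

    def test_fig1_leader_closure_of_memory(self, fig1):
        # the memory subsystem 1 reads receptor 2
        assert fig1.system.leader_closure({"1"}) == frozenset({"1", "2"})

    def test_full_set_closures(self, fig1):
        names = set(fig1.system.space.names)
        assert fig1.system.leader_closure(names) == names
        assert fig1.system.puppet_closure(names) == names

    def test_containment_chain(self, walker):
        # A ⊆ P(A) ⊆ L(A) for every coordinate set
        sys = walker.system
        for a in [{"1"}, {"A"}, {"1", "B"}, {"3"}]:
            p = sys.puppet_closure(a)
            l = sys.leader_closure(a)
            assert frozenset(a) <= p <= l

    def test_unknown_name(self, fig1):
        with pytest.raises(KeyError):
            fig1.system.reservoirs_affecting({"nope"})


class TestGlobalRate:
    def test_single_reservoir_equals_embedding(self):
        sp = two_bit_space()
        res = flip_reservoir("f", "1", 2.5)
        sys = uf.CompositeSystem(sp, [res, flip_reservoir("g", "2", 0.0 + 1e-12)],
                                 )
        K = res.embedded(0.0, sp)
        np.testing.assert_allclose(
            sys.global_rate(0.0), K + sys.reservoirs[1].embedded(0.0, sp),
            atol=1e-15)

    def test_two_flip_kronecker_sum(self):
        # independent flips at rates r1, r2: single-flip entries are exactly
        # r1 or r2, double-flip entries are zero
        r1, r2 = 0.7, 1.3
        sys = two_flip_system(r1, r2)
        sp = sys.space
        K = sys.global_rate(0.0)
        expected = np.kron(r1 * FLIP, np.eye(2)) + np.kron(np.eye(2), r2 * FLIP)
        np.testing.assert_allclose(K, expected, atol=1e-14)
        assert K[sp.index((1, 1)), sp.index((0, 0))] == 0.0

    def test_column_sums_zero_random_systems(self, rng):
        names = ["1", "2", "3"]
        sp = uf.JointSpace([uf.Coordinate(n, 2) for n in names])
        for seed in range(30):
            st = uf.random_height2_structure(names, rng)
            sys = uf.random_unit_system(st, sp, seed=seed)
            K = sys.global_rate(0.0)
            np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-10)
            off = K - np.diag(np.diag(K))
            assert off.min() >= -1e-12


class TestUnits:
    def test_full_set_always_a_unit(self, fig1):
        assert fig1.system.is_unit(fig1.system.space.names)

    def test_fig1_membership(self, fig1):
        sys = fig1.system
        assert sys.is_unit({"3"})
        assert sys.is_unit({"1", "2", "3"})
        assert sys.is_unit({"3", "4"})
        assert not sys.is_unit({"2"})
        assert not sys.is_unit({"1"})
        assert not sys.is_unit({"4"})

    def test_marginal_rate_failure_carries_witness(self, fig1):
        with pytest.raises(IndependenceError) as exc:
            fig1.system.marginal_rate({"2"}, 0.0)
        assert exc.value.discrepancy > 1e-10
        assert len(exc.value.witness) == 2

    def test_marginal_rate_of_autonomous_unit(self, fig1):
        sys = fig1.system
        M = sys.marginal_rate({"3"}, 0.0)
        res3 = sys.reservoirs_affecting({"3"})[0]
        np.testing.assert_allclose(M, res3.protocol.at(0.0), atol=1e-12)

    def test_union_of_units_is_a_unit(self, rng):
        names = ["1", "2", "3", "4"]
        sp = uf.JointSpace([uf.Coordinate(n, 2) for n in names])
        for seed in range(10):
            st = uf.random_height2_structure(names, rng)
            sys = uf.random_unit_system(st, sp, seed=seed)
            units = list(st.units)
            for i in range(len(units)):
                for j in range(i + 1, len(units)):
                    assert sys.is_unit(units[i] | units[j])

    def test_intersection_of_units_is_a_unit(self, rng):
        names = ["1", "2", "3", "4"]
        sp = uf.JointSpace([uf.Coordinate(n, 2) for n in names])
        found = 0
        for seed in range(40):
            st = uf.random_height2_structure(names, rng)
            sys = uf.random_unit_system(st, sp, seed=seed)
            for a in st.units:
                for b in st.units:
                    inter = a & b
                    if inter and inter != a and inter != b:
                        found += 1
                        assert sys.is_unit(inter)
        assert found > 0


class TestMultipartite:
    def test_fig1_is_mpp(self, fig1):
        assert fig1.system.is_multipartite()

    def test_double_flip_is_not_mpp(self):
        sp = two_bit_space()
        sub = sp.subspace({"1", "2"})
        T = np.zeros((4, 4))
        T[sub.index((1, 1)), sub.index((0, 0))] = 1.0
        T[sub.index((0, 0)), sub.index((1, 1))] = 1.0
        np.fill_diagonal(T, -T.sum(axis=0))
        res = uf.Reservoir("both", {"1", "2"}, {"1", "2"}, uf.ConstantRates(T))
        sys = uf.CompositeSystem(sp, [res])
        assert not sys.is_multipartite()

    def test_walker_is_not_mpp(self, walker):
        assert not walker.system.is_multipartite()


class TestCompatibility:
    def test_identity_case(self, fig1):
        sys = fig1.system
        K = sys.marginal_rate({"3"}, 0.0)
        sp3 = sys.space.subspace({"3"})
        ok, resid = uf.check_rate_compatibility(K, K, {"3"}, sp3)
        assert ok and resid < 1e-12

    def test_nested_units(self, fig1):
        sys = fig1.system
        omega = {"3", "4"}
        K_omega = sys.marginal_rate(omega, 0.0)
        K_alpha = sys.marginal_rate({"3"}, 0.0)
        ok, resid = uf.check_rate_compatibility(
            K_alpha, K_omega, {"3"}, sys.space.subspace(omega))
        assert ok and resid < 1e-10

    def test_perturbation_detected(self, fig1):
        sys = fig1.system
        omega = {"3", "4"}
        K_omega = sys.marginal_rate(omega, 0.0).copy()
        K_alpha = sys.marginal_rate({"3"}, 0.0)
        K_omega[0, 1] += 1e-3
        ok, resid = uf.check_rate_compatibility(
            K_alpha, K_omega, {"3"}, sys.space.subspace(omega))
        assert not ok and resid > 1e-4


class TestSubsystem:
    def test_unit_generator_is_sum_of_its_reservoirs(self, fig1):
        # for a tight structure, the unit generator equals the sum of the
        # ν(ω) reservoir matrices restricted to the unit, entrywise
        sys = fig1.system
        for unit in fig1.structure:
            sub = sys.subsystem(unit)
            np.testing.assert_allclose(
                sys.marginal_rate(unit, 0.0), sub.global_rate(0.0), atol=1e-10
            )

    def test_non_tight_refused(self, walker):
        with pytest.raises(ValueError, match="tight"):
            walker.system.subsystem({"1"})

    def test_duplicate_puppet_sets_need_flag(self):
        sp = two_bit_space()
        r1 = flip_reservoir("f1", "1", 1.0)
        r2 = flip_reservoir("f2", "1", 2.0)
        r3 = flip_reservoir("f3", "2", 1.0)
        with pytest.raises(ValueError, match="puppet set"):
            uf.CompositeSystem(sp, [r1, r2, r3])
        sys = uf.CompositeSystem(sp, [r1, r2, r3],
                                 allow_duplicate_puppets=True)
        assert sys.is_unit({"1"})
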
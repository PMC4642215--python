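"""First-sector (C^3) feasibility, constructive solver, and unification."""

import numpy as np
import pytest

from qconj import (
    GeneratorConfig,
    RepresentabilityError,
    construct_representation,
    feasibility_interval,
    first_sector_compatibility,
    representable,
    sample_dataset,
    unify,
    verify_representation,
)
from qconj.first_sector import FirstSectorRepresentation, SolverParameters

from conftest import triplet
from oracles import first_sector_search


class TestFeasibilityInterval:
    def test_skateboard_interval(self):
        iv = feasibility_interval(0.28, 0.84)
        assert iv.ave == pytest.approx(0.56)
        assert iv.dev == pytest.approx(np.sqrt(0.72 * 0.16))
        assert iv.lo == pytest.approx(0.56 - 0.33941125, abs=1e-6)
        assert iv.contains(0.34)

    def test_degenerate_point_interval(self):
        iv = feasibility_interval(1.0, 0.49)
        assert iv.dev == 0.0
        assert iv.lo == iv.hi == pytest.approx(0.745)
        assert iv.contains(0.745) and not iv.contains(0.78)

    def test_all_zero(self):
        iv = feasibility_interval(0.0, 0.0)
        assert iv.lo == iv.hi == 0.0

    def test_half_width_bounded(self, rng):
        for _ in range(200):
            mu_a, mu_b = rng.uniform(0, 1, 2)
            iv = feasibility_interval(mu_a, mu_b)
            assert 0.0 <= iv.dev <= 0.5 + 1e-12


class TestConstructRepresentation:
    def test_filing_cabinet_rank2(self, filing_cabinet):
        rep = construct_representation(filing_cabinet)
        assert rep.params.branch == "rank2"
        assert max(verify_representation(rep).values()) < 1e-10
        assert rep.membership_ab() == pytest.approx(0.53, abs=1e-12)

    def test_all_ones_rank3(self):
        rep = construct_representation(triplet(1.0, 1.0, 1.0))
        assert rep.params.branch == "rank3"
        assert np.allclose(rep.projector, np.eye(3))
        assert max(verify_representation(rep).values()) < 1e-12

    def test_all_zeros_rank0(self):
        rep = construct_representation(triplet(0.0, 0.0, 0.0))
        assert rep.params.branch == "rank0"
        assert np.allclose(rep.projector, 0)
        assert max(verify_representation(rep).values()) == 0.0

    def test_infeasible_triplet_rejected_with_interval(self, heated_waterbed):
        with pytest.raises(RepresentabilityError) as exc:
            construct_representation(heated_waterbed)
        assert exc.value.detail["lo"] == pytest.approx(0.745)
        assert exc.value.detail["hi"] == pytest.approx(0.745)

    def test_rank1_branch_for_low_mass(self):
        rep = construct_representation(triplet(0.3, 0.4, 0.2))
        assert rep.params.branch == "rank1"
        assert max(verify_representation(rep).values()) < 1e-10

    def test_rank1_used_at_exact_unit_sum(self):
        rep = construct_representation(triplet(0.4, 0.6, 0.5))
        assert rep.params.branch == "rank1"
        assert max(verify_representation(rep).values()) < 1e-10

    def test_deterministic(self):
        t = triplet(0.31, 0.52, 0.47)
        r1 = construct_representation(t)
        r2 = construct_representation(t)
        assert np.array_equal(r1.state_a, r2.state_a)
        assert np.array_equal(r1.state_b, r2.state_b)
        assert r1.params == r2.params

    @pytest.mark.parametrize("regime", ["classical", "overextended_representable"])
    def test_random_feasible_triplets_have_tiny_residuals(self, regime):
        ds = sample_dataset(GeneratorConfig(regime=regime, count=60, seed=11))
        for t in ds:
            if not representable(t):
                continue  # classical regime can fall outside the interval
            rep = construct_representation(t)
            assert max(verify_representation(rep).values()) < 1e-10

    def test_boundary_interference_extremes(self):
        iv = feasibility_interval(0.3, 0.2)
        for mu_ab in (iv.lo, iv.hi):
            rep = construct_representation(triplet(0.3, 0.2, mu_ab))
            assert max(verify_representation(rep).values()) < 1e-10


class TestVerifyRepresentation:
    def test_flags_hand_built_orthogonality_violation(self):
        t = triplet(0.5, 0.5, 0.5)
        a = np.array([1.0, 0.0, 0.0], dtype=complex)
        b = np.array([0.7, np.sqrt(1 - 0.49), 0.0], dtype=complex)  # <a|b> = 0.7
        m = np.diag([1.0 + 0j, 0, 0])
        bad = FirstSectorRepresentation(
            a, b, m, SolverParameters("rank1", 0.5, 0.5, 0, 0, 0), t
        )
        res = verify_representation(bad)
        assert res["orthogonality"] == pytest.approx(0.7)

    def test_degenerate_rank0_residuals_vanish(self):
        rep = construct_representation(triplet(0.0, 0.0, 0.0))
        assert all(v == 0.0 for v in verify_representation(rep).values())


class TestTheorem1Oracle:
    """Closed-form interval vs randomized numerical search, small grid.

    (The full >=500-triplet grid lives in the acceptance suite.)
    """

    def test_agreement_on_random_grid(self, rng):
        for _ in range(30):
            mu_a, mu_b, mu_ab = rng.uniform(0, 1, 3)
            predicted = feasibility_interval(mu_a, mu_b).contains(mu_ab)
            found = first_sector_search(mu_a, mu_b, mu_ab, rng, starts=4)
            assert predicted == found, (mu_a, mu_b, mu_ab)


class TestUnify:
    def test_worked_pair_shares_canonical_states(self, filing_cabinet, skateboard):
        model = unify([construct_representation(t) for t in (filing_cabinet, skateboard)])
        assert np.allclose(model.state_a, [1, 0, 0])
        assert np.allclose(model.state_b, [0, 1, 0])
        mu_a, mu_b, mu_ab = model.membership(0)
        assert mu_a == pytest.approx(0.97, abs=1e-10)
        assert mu_b == pytest.approx(0.31, abs=1e-10)
        assert mu_ab == pytest.approx(0.53, abs=1e-10)

    def test_canonical_rep_maps_with_identity(self):
        rep = construct_representation(triplet(0.0, 0.0, 0.0))  # states e1, e2
        model = unify([rep])
        assert np.allclose(model.unitaries[0], np.eye(3), atol=1e-12)
        assert np.allclose(model.projectors[0], rep.projector)

    def test_unitaries_are_unitary_and_projectors_valid(self, rng):
        ds = sample_dataset(
            GeneratorConfig(regime="overextended_representable", count=10, seed=5)
        )
        model = unify([construct_representation(t) for t in ds])
        from qconj.linalg import as_projector, is_unitary

        for u, m in zip(model.unitaries, model.projectors):
            assert is_unitary(u)
            as_projector(m)

    def test_membership_preserved_for_random_datasets(self):
        """Unification preserves all 3k expectations (unitary invariance)."""
        ds = sample_dataset(
            GeneratorConfig(regime="overextended_representable", count=25, seed=9)
        )
        model = unify([construct_representation(t) for t in ds])
        for i, t in enumerate(ds):
            mu_a, mu_b, mu_ab = model.membership(i)
            assert mu_a == pytest.approx(t.mu_a, abs=1e-10)
            assert mu_b == pytest.approx(t.mu_b, abs=1e-10)
            assert mu_ab == pytest.approx(t.mu_ab, abs=1e-10)

    def test_unification_preserves_pairwise_inner_products(self, rng):
        ds = sample_dataset(GeneratorConfig(regime="classical", count=6, seed=13))
        reps = [construct_representation(t) for t in ds if representable(t)]
        model = unify(reps)
        for i, rep in enumerate(reps):
            u = model.unitaries[i]
            before = np.vdot(rep.state_a, rep.projector @ rep.state_b)
            after = np.vdot(u @ rep.state_a, model.projectors[i] @ (u @ rep.state_b))
            assert abs(before - after) < 1e-12

    def test_identical_triplets_commute(self, sailboat):
        reps = [
            construct_representation(triplet(*sailboat.weights, name=f"p{i}"))
            for i in range(3)
        ]
        model = unify(reps)
        for i in range(3):
            for j in range(3):
                r = first_sector_compatibility(model, i, j)
                assert r.max_magnitude < 1e-12
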
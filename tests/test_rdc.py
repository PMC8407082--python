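import math

import numpy as np
import pytest
from scipy.optimize import minimize

from paranmr.geometry import rotation_about_axis
from paranmr.io import RDCRecord
from paranmr.rdc import (
    AlignmentTensor,
    RDCRestraintConfig,
    back_calculate_all,
    back_calculate_rdc,
    bond_vectors,
    design_matrix,
    fit_tensor_svd,
    q_factor,
    rdc_restraint_energy,
)

TENSOR = AlignmentTensor(4.0, -9.0, 3.0, -2.0, 1.5)


def records_for(structure, chain="protein"):
    return [RDCRecord(chain, r, 0.0) for r in structure.residues(chain)]


class TestTensor:
    def test_matrix_is_symmetric_traceless(self):
        m = TENSOR.matrix
        assert np.allclose(m, m.T)
        assert np.trace(m) == pytest.approx(0.0, abs=1e-12)

    def test_vector_round_trip(self):
        assert AlignmentTensor.from_vector(TENSOR.as_vector()) == TENSOR

    def test_from_matrix_rejects_trace(self):
        with pytest.raises(ValueError, match="traceless"):
            AlignmentTensor.from_matrix(np.eye(3))


class TestBackCalculation:
    def test_bond_along_z_reads_a_zz(self, helix10):
        # synthetic two-atom frame: u = z
        diag = AlignmentTensor(2.0, -5.0, 0.0, 0.0, 0.0)
        u = np.array([[0.0, 0.0, 1.0]])
        d = design_matrix(u) @ diag.as_vector()
        assert d[0] == pytest.approx(diag.a_zz) == pytest.approx(3.0)

    def test_null_tensor_gives_zero_everywhere(self, helix10):
        zero = AlignmentTensor(0, 0, 0, 0, 0)
        recs = records_for(helix10)
        assert np.allclose(back_calculate_all(helix10, zero, recs), 0.0)

    def test_matches_explicit_matrix_contraction(self, helix10, rng):
        recs = records_for(helix10)
        u = bond_vectors(helix10, recs)
        via_design = back_calculate_all(helix10, TENSOR, recs)
        explicit = np.array([ui @ TENSOR.matrix @ ui for ui in u])
        assert np.allclose(via_design, explicit, atol=1e-12)
        one = back_calculate_rdc(helix10, TENSOR, recs[3])
        assert one == pytest.approx(explicit[3], rel=1e-12)

    def test_joint_rotation_leaves_couplings_unchanged(self, helix10, rng):
        recs = records_for(helix10)
        d0 = back_calculate_all(helix10, TENSOR, recs)
        R = rotation_about_axis(rng.normal(size=3), 0.9)
        rotated = helix10.with_coords(helix10.coords @ R.T)
        d1 = back_calculate_all(rotated, TENSOR.rotated(R), recs)
        assert np.allclose(d0, d1, atol=1e-9)


class TestFit:
    def test_noise_free_exact_recovery(self, two_lobe):
        structure, _ = two_lobe
        recs = [
            RDCRecord(r.chain_id, r.residue_index, d)
            for r, d in zip(
                records_for(structure),
                back_calculate_all(structure, TENSOR, records_for(structure)),
            )
        ]
        fitted, residuals = fit_tensor_svd(structure, recs)
        assert np.allclose(fitted.as_vector(), TENSOR.as_vector(), atol=1e-8)
        d_obs = np.array([r.D_obs for r in recs])
        assert q_factor(d_obs, back_calculate_all(structure, fitted, recs)) == (
            pytest.approx(0.0, abs=1e-10)
        )
        assert np.allclose(residuals, 0.0, atol=1e-10)

    def test_underdetermined_system_rejected(self, helix10):
        with pytest.raises(ValueError, match="at least 5"):
            fit_tensor_svd(helix10, records_for(helix10)[:4])

    def test_noisy_component_error_matches_linear_model_covariance(self, two_lobe):
        # Monte Carlo over replicates: the empirical component RMSE must
        # match sigma^2 (A^T A)^-1 from ordinary least-squares theory
        structure, _ = two_lobe
        base = records_for(structure)[:60]
        u = bond_vectors(structure, base)
        A = design_matrix(u)
        d_true = A @ TENSOR.as_vector()
        sigma = 1.0
        cov = sigma**2 * np.linalg.inv(A.T @ A)
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(200):
            noisy = [
                RDCRecord(r.chain_id, r.residue_index, d + rng.normal(0, sigma))
                for r, d in zip(base, d_true)
            ]
            fitted, _ = fit_tensor_svd(structure, noisy)
            errs.append(fitted.as_vector() - TENSOR.as_vector())
        emp = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.allclose(emp, np.sqrt(np.diag(cov)), rtol=0.25)


class TestRestraintEnergy:
    def config(self):
        return RDCRestraintConfig()

    def test_within_tolerance_is_free(self, helix10):
        recs = records_for(helix10)
        d_calc = back_calculate_all(helix10, TENSOR, recs)
        shifted = [
            RDCRecord(r.chain_id, r.residue_index, d + 1.0)
            for r, d in zip(recs, d_calc)
        ]
        e, grads, tgrad = rdc_restraint_energy(helix10, TENSOR, shifted, self.config())
        assert e == 0.0
        assert not grads
        assert np.allclose(tgrad, 0.0)

    def test_single_violation_hand_arithmetic(self, helix10):
        recs = records_for(helix10)
        d_calc = back_calculate_all(helix10, TENSOR, recs)
        shifted = [RDCRecord(recs[0].chain_id, recs[0].residue_index, d_calc[0] - 2.5)]
        e, _, _ = rdc_restraint_energy(helix10, TENSOR, shifted, self.config())
        # deviation 2.5 Hz, 1.5 Hz flat bottom, k=0.5 -> 0.5*0.5*1^2
        assert e == pytest.approx(0.25, rel=1e-12)

    def test_gradients_match_central_differences(self, helix10, rng):
        recs = records_for(helix10)
        d_calc = back_calculate_all(helix10, TENSOR, recs)
        obs = [
            RDCRecord(r.chain_id, r.residue_index, d + rng.normal(0, 3.0))
            for r, d in zip(recs, d_calc)
        ]
        cfg = self.config()
        e0, grads, tgrad = rdc_restraint_energy(helix10, TENSOR, obs, cfg)
        assert e0 > 0
        eps = 1e-6
        # tensor components
        v = TENSOR.as_vector()
        for k in range(5):
            vp, vm = v.copy(), v.copy()
            vp[k] += eps
            vm[k] -= eps
            ep, _, _ = rdc_restraint_energy(helix10, vp, obs, cfg)
            em, _, _ = rdc_restraint_energy(helix10, vm, obs, cfg)
            assert tgrad[k] == pytest.approx((ep - em) / (2 * eps), rel=1e-5, abs=1e-7)
        # atoms
        for key, g in list(grads.items())[:4]:
            idx = helix10.index_of(*key)
            for k in range(3):
                cp = helix10.coords.copy()
                cp[idx, k] += eps
                ep, _, _ = rdc_restraint_energy(helix10.with_coords(cp), TENSOR, obs, cfg)
                cp[idx, k] -= 2 * eps
                em, _, _ = rdc_restraint_energy(helix10.with_coords(cp), TENSOR, obs, cfg)
                assert g[k] == pytest.approx((ep - em) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_zero_tolerance_minimum_recovers_svd_fit(self, two_lobe):
        # with tol=0 and fixed structure, minimizing the restraint energy
        # over the tensor DOF must land on the least-squares solution
        structure, _ = two_lobe
        recs = records_for(structure)
        d_calc = back_calculate_all(structure, TENSOR, recs)
        rng = np.random.default_rng(5)
        obs = [
            RDCRecord(r.chain_id, r.residue_index, d + rng.normal(0, 1.0))
            for r, d in zip(recs, d_calc)
        ]
        svd_fit, _ = fit_tensor_svd(structure, obs)
        cfg = RDCRestraintConfig(tolerance=0.0, k_rdc=0.5)

        def fun(v):
            e, _, g = rdc_restraint_energy(structure, v, obs, cfg)
            return e, g

        res = minimize(fun, np.zeros(5), jac=True, method="L-BFGS-B", tol=1e-14)
        assert np.allclose(res.x, svd_fit.as_vector(), atol=1e-6)

    def test_energy_invariant_under_record_order(self, helix10, rng):
        recs = records_for(helix10)
        d_calc = back_calculate_all(helix10, TENSOR, recs)
        obs = [
            RDCRecord(r.chain_id, r.residue_index, d + rng.normal(0, 3.0))
            for r, d in zip(recs, d_calc)
        ]
        e0, _, _ = rdc_restraint_energy(helix10, TENSOR, obs, self.config())
        perm = list(rng.permutation(len(obs)))
        e1, _, _ = rdc_restraint_energy(
            helix10, TENSOR, [obs[i] for i in perm], self.config()
        )
        assert e1 == pytest.approx(e0, rel=1e-12)


class TestQFactor:
    def test_perfect_agreement(self):
        assert q_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_null_prediction_gives_one(self):
        assert q_factor([1.0, -2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_three_element_hand_case(self):
        # rms(obs-calc) = sqrt((1+4+4)/3), rms(obs) = sqrt((4+9+36)/3)
        obs, calc = [2.0, -3.0, 6.0], [1.0, -1.0, 4.0]
        assert q_factor(obs, calc) == pytest.approx(math.sqrt(9 / 3) / math.sqrt(49 / 3))

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            q_factor([0.0, 0.0], [1.0, 2.0])
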
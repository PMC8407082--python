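import math
from dataclasses import replace

import numpy as np
import pytest

from paranmr import io
from paranmr.geometry import rotation_about_axis
from paranmr.pre import measurements_from_intensities
from paranmr.rdc import fit_tensor_svd, q_factor, back_calculate_all
from paranmr.spinlabels import place_virtual_site
from paranmr.synthetic import (
    default_scenario,
    make_helix,
    make_two_helix_toy,
    make_two_lobe_toy,
    simulate_all_pre,
    simulate_pre_experiment,
    simulate_rdc,
    simulate_ss,
    two_helix_scenario,
)


class TestStructures:
    def test_helix_ca_spacing_is_alpha_helical(self, helix10):
        ca = np.array([helix10.xyz("protein", r, "CA") for r in range(1, 11)])
        d13 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        assert np.all((5.0 <= d13) & (d13 <= 5.5))

    def test_helix_amides_roughly_parallel_to_axis(self, helix10):
        ca = np.array([helix10.xyz("protein", r, "CA") for r in range(1, 11)])
        axis = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
        angles = []
        for r in range(1, 11):
            nh = helix10.xyz("protein", r, "H") - helix10.xyz("protein", r, "N")
            nh /= np.linalg.norm(nh)
            angles.append(math.degrees(math.acos(abs(float(nh @ axis)))))
        assert np.mean(angles) < 20.0

    def test_minimum_helix_length_enforced(self):
        with pytest.raises(ValueError):
            make_helix(3)

    def test_two_helix_toy_is_compact(self):
        structure, ss = make_two_helix_toy()
        assert ss.count("H") == 20 and len(ss) == 24
        ca = np.array(
            [structure.xyz("protein", r, "CA") for r in structure.residues("protein")]
        )
        h1, h2 = ca[:10], ca[14:]
        gap = np.linalg.norm(
            h1[:, None, :] - h2[None, :, :], axis=-1
        ).min()
        assert 4.0 < gap < 8.0  # packed, not clashing

    def test_two_lobe_toy_has_docked_peptide(self, two_lobe):
        structure, ss = two_lobe
        assert set(structure.chain_ids) == {"protein", "peptide"}
        assert set(ss) == {"protein", "peptide"}
        assert len(ss["protein"]) == len(structure.residues("protein"))
        pca = np.array(
            [structure.xyz("protein", r, "CA") for r in structure.residues("protein")]
        )
        qca = np.array(
            [structure.xyz("peptide", r, "CA") for r in structure.residues("peptide")]
        )
        gap = np.linalg.norm(pca[:, None] - qca[None, :], axis=-1).min()
        assert 4.0 < gap < 8.0


class TestPREForwardModel:
    def test_noise_free_recovery_of_ensemble_averaged_distance(self):
        # zero jitter + zero noise: the pipeline-recovered distance equals
        # the point distance exactly (the r^-6 average is over one point)
        sc = replace(
            two_helix_scenario(seed=1), label_jitter_sd=0.0, intensity_noise_sd=0.0
        )
        site = sc.label_sites[0]
        records = simulate_pre_experiment(sc, site.site_name)
        ms = measurements_from_intensities(records, sc.conditions)
        pos = place_virtual_site(sc.structure, site)
        checked = 0
        for m in ms:
            if isinstance(m.distance, str):
                continue
            truth = np.linalg.norm(
                pos - sc.structure.xyz(m.chain_id, m.residue_index, "H")
            )
            assert m.distance == pytest.approx(truth, abs=1e-6)
            checked += 1
        assert checked > 3

    def test_jittered_recovery_matches_r6_average_truth(self):
        # with label jitter but no intensity noise the recovered distance is
        # the <r^-6>^(-1/6) ensemble average over the label cloud
        sc = replace(two_helix_scenario(seed=2), intensity_noise_sd=0.0)
        site = sc.label_sites[0]
        records = simulate_pre_experiment(sc, site.site_name)
        ms = measurements_from_intensities(records, sc.conditions)
        rng = np.random.default_rng([sc.seed, 0])
        pos = place_virtual_site(sc.structure, site)
        cloud = pos + rng.normal(0.0, sc.label_jitter_sd, size=(sc.n_jitter_draws, 3))
        for m in ms:
            if isinstance(m.distance, str):
                continue
            h = sc.structure.xyz(m.chain_id, m.residue_index, "H")
            r6avg = float(np.mean(np.linalg.norm(cloud - h, axis=1) ** -6.0)) ** (
                -1 / 6
            )
            assert m.distance == pytest.approx(r6avg, abs=1e-6)

    def test_close_residues_emitted_as_broadened(self):
        sc = replace(
            two_helix_scenario(seed=1), label_jitter_sd=0.0, intensity_noise_sd=0.0
        )
        site = sc.label_sites[0]
        pos = place_virtual_site(sc.structure, site)
        records = simulate_pre_experiment(sc, site.site_name)
        for rec in records:
            truth = float(
                np.linalg.norm(pos - sc.structure.xyz(rec.chain_id, rec.residue_index, "H"))
            )
            if truth < 6.0:
                assert rec.broadened

    def test_unlabeled_peptide_sites_omit_peptide_rows(self):
        sc = default_scenario(seed=0)
        labelled = sorted(sc.peptide_labeled_sites)
        unlabelled = [
            s.site_name for s in sc.label_sites if s.site_name not in labelled
        ]
        assert len(labelled) == 4 and len(sc.label_sites) == 10
        with_pep = simulate_pre_experiment(sc, labelled[0])
        without = simulate_pre_experiment(sc, unlabelled[0])
        assert any(r.chain_id == "peptide" for r in with_pep)
        assert not any(r.chain_id == "peptide" for r in without)

    def test_reproducible_under_same_seed(self):
        a = simulate_all_pre(two_helix_scenario(seed=9))
        b = simulate_all_pre(two_helix_scenario(seed=9))
        assert a == b


class TestRDCForwardModel:
    def test_noise_free_recovery_of_true_tensor(self):
        sc = replace(default_scenario(seed=4), rdc_noise_sd=0.0)
        records = simulate_rdc(sc)
        fitted, _ = fit_tensor_svd(sc.structure, records)
        assert np.allclose(
            fitted.as_vector(), sc.true_tensor.as_vector(), atol=1e-8
        )

    def test_noisy_q_factor_scales_with_noise(self):
        # truth-tensor back-calculation across replicates: Q ~ sd/rms(D_obs)
        qs, expected = [], []
        for seed in range(200):
            sc = replace(default_scenario(seed=seed), rdc_noise_sd=1.0)
            records = simulate_rdc(sc)
            d_obs = np.array([r.D_obs for r in records])
            d_true = back_calculate_all(sc.structure, sc.true_tensor, records)
            qs.append(q_factor(d_obs, d_true))
            expected.append(1.0 / math.sqrt(float(np.mean(d_obs**2))))
        assert np.mean(qs) == pytest.approx(np.mean(expected), rel=0.05)

    def test_covariant_under_joint_rotation_of_truth(self, rng):
        sc = replace(two_helix_scenario(seed=6), rdc_noise_sd=0.0)
        R = rotation_about_axis(rng.normal(size=3), 0.8)
        rotated = replace(
            sc,
            structure=sc.structure.with_coords(sc.structure.coords @ R.T),
            true_tensor=sc.true_tensor.rotated(R),
        )
        d0 = [r.D_obs for r in simulate_rdc(sc)]
        d1 = [r.D_obs for r in simulate_rdc(rotated)]
        assert np.allclose(d0, d1, atol=1e-9)


class TestClosure:
    def test_every_emitted_table_parses_through_the_readers(self, tmp_path):
        sc = default_scenario(seed=0)
        intensity = io.write_intensity_table(simulate_all_pre(sc))
        assert io.read_intensity_table(intensity)
        rdc = io.write_rdc_table(simulate_rdc(sc))
        assert io.read_rdc_table(rdc)
        ss = io.write_ss_prediction(simulate_ss(sc))
        lengths = {c: len(sc.structure.residues(c)) for c in sc.structure.chain_ids}
        assert io.read_ss_prediction(ss, chain_lengths=lengths)
        pdb = io.write_structure(sc.structure)
        assert len(io.read_structure(pdb, io.DEFAULT_CHAIN_NAMES)) == len(sc.structure)

    def test_noise_free_restraints_contain_ground_truth(self):
        # end-to-end closure: noise-free scenario -> simulated tables ->
        # distances -> restraints whose flat regions hold the true distances
        from paranmr.pipeline import measurements_from_scenario
        from paranmr.restraints import build_pre_collections

        sc = replace(
            two_helix_scenario(seed=1), label_jitter_sd=0.0, intensity_noise_sd=0.0
        )
        ms = measurements_from_scenario(sc)
        collections = build_pre_collections(ms)
        positions = {
            s.site_name: place_virtual_site(sc.structure, s) for s in sc.label_sites
        }
        for coll in collections:
            for r in coll.restraints:
                d = float(
                    np.linalg.norm(
                        positions[r.site_a]
                        - sc.structure.xyz(r.site_b[0], r.site_b[1], "H")
                    )
                )
                assert r.lower <= d <= r.upper, (r, d)
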
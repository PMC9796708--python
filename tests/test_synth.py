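"""Ground-truth structure and statistical properties of synthetic cohorts."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import kinectome as kc
from conftest import build_kinectomes, edge_vectors
from kinectome import modularity as mod
from kinectome.synth import (
    _RIGIDITY_PHASES,
    _RIGIDITY_WEIGHTS,
    _TEMPLATE_PROFILES,
    CohortSpec,
)


class TestSpecValidation:
    def test_mode_defaults(self):
        healthy = CohortSpec(n_subjects=3, mode="healthy")
        assert healthy.asymmetry == 0.0
        assert healthy.trunk_coupling == 0.0
        assert healthy.between_subject_ap_var_inflation == 1.0
        assert healthy.dysregulation == 1.0
        sick = CohortSpec(n_subjects=3, mode="parkinsonian")
        assert sick.asymmetry == 0.25
        assert sick.trunk_coupling == 0.3
        assert sick.between_subject_ap_var_inflation == 2.0
        assert sick.dysregulation == 1.5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            CohortSpec(n_subjects=3, mode="ataxic")
        with pytest.raises(ValueError, match="subjects"):
            CohortSpec(n_subjects=1)
        with pytest.raises(ValueError, match="frames"):
            CohortSpec(n_subjects=3, cycle_duration=0.2)
        with pytest.raises(ValueError, match=">= 0"):
            CohortSpec(n_subjects=3, signature_scale=-0.1)

    def test_frame_count(self):
        spec = CohortSpec(n_subjects=2)
        assert spec.n_frames == 264  # 120 fps x 1.1 s x 2 cycles


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = CohortSpec(n_subjects=5, mode="healthy", seed=3)
        t1, s1 = kc.generate_cohort(spec)
        t2, s2 = kc.generate_cohort(CohortSpec(n_subjects=5, seed=3))
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.positions, b.positions)
        assert s1.equals(s2)

    def test_different_seeds_differ(self):
        t1, _ = kc.generate_cohort(CohortSpec(n_subjects=3, seed=1))
        t2, _ = kc.generate_cohort(CohortSpec(n_subjects=3, seed=2))
        assert not np.allclose(t1[0].positions, t2[0].positions)


class TestPlantedTruth:
    def test_healthy_couplings_zero(self):
        truth = kc.planted_truth(CohortSpec(n_subjects=6, mode="healthy"))
        np.testing.assert_array_equal(truth["couplings"], 0.0)

    def test_parkinsonian_coupling_sampling(self):
        spec = CohortSpec(n_subjects=200, mode="parkinsonian", seed=8)
        truth = kc.planted_truth(spec)
        se = spec.coupling_sd / np.sqrt(spec.n_subjects)
        # clipping at zero biases the mean up slightly; allow for it
        assert abs(truth["couplings"].mean() - spec.trunk_coupling) < 3 * se + 0.02

    def test_template_communities_three_modules_per_axis(self):
        truth = kc.planted_truth(CohortSpec(n_subjects=3))
        for axis in ("ML", "AP", "V"):
            labels = truth["communities"][axis]
            assert len(labels) == 21
            assert set(labels) == {0, 1, 2}

    def test_healthy_template_amplitudes_bilaterally_symmetric(self):
        spec = CohortSpec(n_subjects=3, mode="healthy")
        truth = kc.planted_truth(spec)
        amps = truth["template_amplitudes"]
        ms = spec.marker_set
        for left, right in ms.homologous_pairs():
            np.testing.assert_array_equal(
                amps[ms.index(left)], amps[ms.index(right)]
            )

    def test_truth_consistent_with_cohort(self):
        spec = CohortSpec(n_subjects=8, mode="parkinsonian", seed=21)
        truth = kc.planted_truth(spec)
        _, subjects = kc.generate_cohort(spec)
        np.testing.assert_allclose(
            subjects["motor_score"].to_numpy(), truth["motor_scores"]
        )


class TestRigidityDrive:
    def test_orthogonal_to_module_latents(self):
        # per axis, the drive must have zero inner product with each module
        # waveform so trunk-limb coupling cannot leak into module structure
        for axis, profile in _TEMPLATE_PROFILES.items():
            weights, phases = profile["weights"], profile["phases"]
            rphi = _RIGIDITY_PHASES[axis]
            for m in range(3):
                overlap = (
                    _RIGIDITY_WEIGHTS * weights[m] * np.cos(rphi - phases[m])
                ).sum()
                assert abs(overlap) < 1e-8, (axis, m)


class TestCohortStructure:
    def test_two_trials_per_subject_and_metadata(self):
        trials, subjects = kc.generate_cohort(
            CohortSpec(n_subjects=4, mode="parkinsonian", seed=5)
        )
        assert len(trials) == 8
        pairs = kc.validate_session(trials, subjects)
        assert len(pairs) == 4
        assert (subjects["group"] == "PD").all()
        assert (subjects["motor_score"] >= 0).all()

    def test_healthy_module_recovery_ml(self, healthy_cohort):
        pairs, _ = healthy_cohort
        spec = CohortSpec(n_subjects=10, mode="healthy", seed=11)
        truth = kc.planted_truth(spec)
        parts = [
            mod.louvain(mod.to_adjacency(k), seed=3)
            for q in ("acceleration", "jerk")
            for k in build_kinectomes(pairs, q, "ML")
        ]
        group = mod.group_communities(mod.allegiance(parts), seed=4)
        assert adjusted_rand_score(
            truth["communities"]["ML"], group.community_id
        ) == pytest.approx(1.0)

    def test_homologous_leg_markers_share_community(self, healthy_cohort):
        pairs, _ = healthy_cohort
        parts = [
            mod.louvain(mod.to_adjacency(k), seed=3)
            for k in build_kinectomes(pairs, "acceleration", "ML")
        ]
        group = mod.group_communities(mod.allegiance(parts), seed=4)
        ms = kc.default_marker_set()
        for left, right in ms.homologous_pairs():
            if ms.anatomical_group[right] in ("leg", "foot"):
                assert (
                    group.community_id[ms.index(left)]
                    == group.community_id[ms.index(right)]
                ), (left, right)

    def test_disease_mode_inflates_ap_acceleration_variability(
        self, healthy_cohort, pd_cohort
    ):
        hc_pairs, _ = healthy_cohort
        pd_pairs, _ = pd_cohort
        iu = np.triu_indices(21, k=1)
        sd_hc = kc.group_edge_stats(
            build_kinectomes(hc_pairs, "acceleration", "AP"), "sd"
        )[iu].mean()
        sd_pd = kc.group_edge_stats(
            build_kinectomes(pd_pairs, "acceleration", "AP"), "sd"
        )[iu].mean()
        assert sd_pd > sd_hc

    def test_identifiability_degrades_without_signature(self):
        # signature off + strong trial variation: IR collapses toward chance
        strong = CohortSpec(n_subjects=10, mode="healthy", seed=7,
                            signature_scale=0.0, trial_noise_scale=0.3)
        weak = CohortSpec(n_subjects=10, mode="healthy", seed=7)
        irs = []
        for spec in (weak, strong):
            pairs = kc.validate_session(*kc.generate_cohort(spec))
            test, retest = edge_vectors(pairs, "jerk", "AP")
            scores = kc.fingerprint_scores(
                kc.identifiability_matrix(test, retest)
            )
            irs.append(scores.ir)
        assert irs[0] > irs[1]
        assert irs[1] < 0.5

    def test_ir_monotone_in_trial_noise(self):
        irs = []
        for noise in (0.05, 0.4, 1.2):
            spec = CohortSpec(n_subjects=10, mode="healthy", seed=9,
                              signature_scale=0.05, trial_noise_scale=noise)
            pairs = kc.validate_session(*kc.generate_cohort(spec))
            test, retest = edge_vectors(pairs, "jerk", "ML")
            irs.append(
                kc.fingerprint_scores(
                    kc.identifiability_matrix(test, retest)
                ).ir
            )
        assert irs[0] >= irs[1] >= irs[2]
        assert irs[0] > irs[2]
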
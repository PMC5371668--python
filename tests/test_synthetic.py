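"""Ground-truth generator behavior: exact type mixtures, ODE fidelity,
multinomial sampling, and trial fold-change structure."""

import numpy as np
import pytest

from glvnet.models import GLVModel, TrialDesign
from glvnet.synthetic import (
    counts_from_profile,
    expected_trial_composition,
    generate_trial,
    sample_interaction_matrix,
    sample_planted_matrix,
    simulate_glv,
)


def _pair_type(a, i, j):
    si, sj = np.sign(a[i, j]), np.sign(a[j, i])
    return {
        (1, 1): "mutual",
        (-1, -1): "competitive",
        (1, 0): "commensal",
        (0, 1): "commensal",
        (-1, 0): "amensal",
        (0, -1): "amensal",
        (0, 0): "none",
    }[(si, sj)]


class TestSampleInteractionMatrix:
    def test_all_mutual_mixture_gives_positive_offdiagonal_pairs(self):
        m = sample_interaction_matrix(6, {"mutual": 1.0}, seed=0)
        off = m.interactions[~np.eye(6, dtype=bool)]
        assert (off > 0).all()

    def test_same_seed_reproduces_model(self):
        kw = dict(
            n_taxa=8,
            type_mixture={"mutual": 0.5, "amensal": 0.5},
            seed=42,
        )
        m1, m2 = sample_interaction_matrix(**kw), sample_interaction_matrix(**kw)
        np.testing.assert_array_equal(m1.interactions, m2.interactions)
        np.testing.assert_array_equal(m1.growth_rates, m2.growth_rates)

    def test_requested_type_counts_realized_exactly(self):
        # brute-force count of pair types on the output matrix
        mix = {"mutual": 0.25, "competitive": 0.25, "commensal": 0.25, "amensal": 0.25}
        m = sample_interaction_matrix(10, mix, seed=5)
        a = m.interactions
        counts = {}
        for i in range(10):
            for j in range(i + 1, 10):
                t = _pair_type(a, i, j)
                counts[t] = counts.get(t, 0) + 1
        # 45 pairs, proportions 0.25 each -> largest-remainder gives 12/11/11/11
        assert sorted(counts.values()) == [11, 11, 11, 12]
        assert set(counts) == set(mix)

    def test_diagonal_strictly_negative(self):
        m = sample_interaction_matrix(5, {"none": 1.0}, seed=1)
        assert (np.diag(m.interactions) < 0).all()

    @pytest.mark.parametrize(
        "mixture", [{"mutual": 0.7}, {"mutual": -0.2, "none": 1.2}, {"weird": 1.0}]
    )
    def test_invalid_mixture_rejected(self, mixture):
        with pytest.raises(ValueError):
            sample_interaction_matrix(4, mixture, seed=0)


class TestSimulateGLV:
    def test_single_taxon_fixed_point_is_constant(self):
        m = GLVModel(["x"], np.array([0.5]), np.array([[-0.5]]))
        prof = simulate_glv(m, np.array([1.0]), np.linspace(0, 5, 11), renormalize=False)
        np.testing.assert_allclose(prof.abundances, 1.0, atol=1e-6)

    def test_interior_equilibrium_is_invariant(self):
        model, _, x_star = sample_planted_matrix(seed=3)
        times = np.linspace(0, 10, 21)
        prof = simulate_glv(model, x_star, times, noise_sd=0.0, renormalize=False)
        np.testing.assert_allclose(
            prof.abundances, np.tile(x_star[:, None], (1, len(times))), atol=1e-6
        )

    def test_noise_free_run_is_deterministic(self, five_taxon_model):
        x0 = np.full(5, 0.2)
        t = np.linspace(0, 3, 13)
        p1 = simulate_glv(five_taxon_model, x0, t, noise_sd=0.0, seed=1)
        p2 = simulate_glv(five_taxon_model, x0, t, noise_sd=0.0, seed=99)
        np.testing.assert_array_equal(p1.abundances, p2.abundances)

    def test_matches_fine_step_euler_oracle(self, two_taxon_model):
        """Adaptive integration agrees with an independent brute-force
        Euler integrator at a very fine step."""
        x0 = np.array([0.4, 0.6])
        times = np.linspace(0, 2, 9)
        prof = simulate_glv(two_taxon_model, x0, times, renormalize=False)

        b, a = two_taxon_model.growth_rates, two_taxon_model.interactions
        h = 1e-5
        x = x0.copy()
        oracle = [x0.copy()]
        for k in range(len(times) - 1):
            n_steps = int(round((times[k + 1] - times[k]) / h))
            for _ in range(n_steps):
                x = x + h * x * (b + a @ x)
            oracle.append(x.copy())
        oracle = np.array(oracle).T
        np.testing.assert_allclose(prof.abundances, oracle, rtol=1e-4)

    def test_normalized_columns_sum_to_one(self, five_taxon_model):
        prof = simulate_glv(
            five_taxon_model, np.full(5, 0.2), np.linspace(0, 3, 7),
            noise_sd=0.1, seed=2,
        )
        np.testing.assert_allclose(prof.abundances.sum(axis=0), 1.0, atol=1e-12)

    def test_divergent_trajectory_raises_with_time(self):
        # runaway mutualism overwhelms self-limitation
        m = GLVModel(
            ["a", "b"],
            np.array([1.0, 1.0]),
            np.array([[-0.01, 5.0], [5.0, -0.01]]),
        )
        with pytest.raises(RuntimeError, match="t="):
            simulate_glv(m, np.array([1.0, 1.0]), np.linspace(0, 20, 21))

    def test_process_noise_same_seed_identical(self, five_taxon_model):
        kw = dict(
            x0=np.full(5, 0.2), times=np.linspace(0, 3, 13),
            noise_sd=0.1, seed=11, noise_mode="process",
        )
        p1 = simulate_glv(five_taxon_model, **kw)
        p2 = simulate_glv(five_taxon_model, **kw)
        np.testing.assert_array_equal(p1.abundances, p2.abundances)


class TestCountsFromProfile:
    def test_columns_sum_to_depth(self, dense_profile):
        t = counts_from_profile(dense_profile, depth=1234, seed=0)
        assert (t.counts.sum(axis=0) == 1234).all()

    def test_even_split_within_three_sigma(self):
        import pandas as pd

        props = pd.DataFrame({"s": [0.5, 0.5]}, index=["a", "b"])
        t = counts_from_profile(props, depth=10**6, seed=4)
        sigma = np.sqrt(10**6 * 0.25)
        assert abs(t.counts.loc["a", "s"] - 5 * 10**5) < 3 * sigma

    def test_zero_probability_taxon_never_sampled(self):
        import pandas as pd

        props = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 0.0]}, index=["a", "b"])
        t = counts_from_profile(props, depth=5000, seed=1)
        assert (t.counts.loc["b"] == 0).all()


class TestGenerateTrial:
    def _model(self):
        # P rare (like the administered probiotic), strong edge P -> Q
        a = np.array(
            [
                [-1.0, 0.0, 0.0],
                [1.0, -1.0, 0.0],
                [0.0, 0.0, -1.0],
            ]
        )
        return GLVModel(["P", "Q", "R"], np.array([0.5, 0.5, 0.5]), a)

    def test_control_group_matches_baseline_composition(self):
        model = self._model()
        baseline = np.array([0.005, 0.4, 0.595])
        design = TrialDesign(groups=["G1", "G5"], administered={"G1": ["P"], "G5": []},
                             n_per_group=4, boost=15.0)
        tables = generate_trial(model, baseline, design, seed=0, depth=200000,
                                animal_sd=0.01)
        rel = tables["G5"].counts / tables["G5"].counts.sum(axis=0)
        np.testing.assert_allclose(rel.mean(axis=1), baseline, atol=0.01)

    def test_no_coupling_limit_only_administered_changes(self):
        a = np.diag([-1.0, -1.0, -1.0])
        model = GLVModel(["P", "Q", "R"], np.array([0.5, 0.5, 0.5]), a)
        baseline = np.array([0.01, 0.5, 0.49])
        expected = expected_trial_composition(model, baseline, ["P"], boost=10.0)
        # only P moved (before renormalization)
        np.testing.assert_allclose(expected[1:], baseline[1:], rtol=1e-12)
        assert expected[0] == pytest.approx(0.1)
        # observed fold change of P vs control ~ boost (P is rare)
        fc = (expected[0] / expected.sum()) / baseline[0]
        assert fc == pytest.approx(10.0, rel=0.1)

    def test_partner_response_matches_hand_propagation(self):
        model = self._model()
        baseline = np.array([0.005, 0.08, 0.915])
        boost, dt = 15.0, 14.0
        expected = expected_trial_composition(model, baseline, ["P"], boost, dt)
        # hand evaluation: Q's drive is a_QP * (P_boosted - P_baseline)
        drive_q = 1.0 * (baseline[0] * boost - baseline[0])
        hand_q = baseline[1] * np.exp(dt * drive_q)
        assert expected[1] == pytest.approx(hand_q, rel=1e-12)
        # relative fold change of Q clears the relevance threshold
        fc_q = (expected[1] / expected.sum()) / baseline[1]
        assert fc_q > 2.0

    def test_unknown_genus_lists_valid_labels(self):
        model = self._model()
        design = TrialDesign(groups=["G1", "G5"],
                             administered={"G1": ["Zzz"], "G5": []})
        with pytest.raises(KeyError, match="valid labels"):
            generate_trial(model, np.array([0.2, 0.4, 0.4]), design)


class TestPlantedMatrix:
    def test_planted_magnitudes_dominate_background(self):
        model, planted, _ = sample_planted_matrix(seed=2)
        idx = {t: i for i, t in enumerate(model.taxa)}
        planted_cells = set()
        for a, b, _t in planted:
            planted_cells |= {(idx[b], idx[a]), (idx[a], idx[b])}
        mat = model.interactions
        off = [
            abs(mat[i, j])
            for i in range(10)
            for j in range(10)
            if i != j and (i, j) not in planted_cells and mat[i, j] != 0
        ]
        weakest_planted = min(abs(mat[i, j]) for i, j in planted_cells)
        assert weakest_planted >= 5 * max(off)

    def test_equilibrium_is_locally_stable(self):
        model, _, x_star = sample_planted_matrix(seed=9)
        jac = np.diag(x_star) @ model.interactions
        assert np.linalg.eigvals(jac).real.max() < 0
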
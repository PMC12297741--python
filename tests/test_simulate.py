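"""Samplers against exact enumeration, determinism, and model invariants."""

import numpy as np
import pandas as pd
import pytest

from lonenet import (
    dichotomize,
    enumerate_ising_moments,
    reverse_score,
    sample_ggm_data,
    sample_ising,
    sample_likert_cls,
    sample_moderated_data,
)
from lonenet.params import GroundTruthGGM, IsingParameters, ModeratedTruth

from conftest import random_ising


def single_node(tau: float) -> IsingParameters:
    return IsingParameters(["X"], [tau], [[0.0]])


class TestIsingSampler:
    @pytest.mark.parametrize(
        "tau,expected", [(0.0, 0.5), (np.log(3), 0.75)], ids=["symmetric", "logit3"]
    )
    def test_single_node_activation(self, tau, expected):
        data = sample_ising(single_node(tau), 10_000, seed=1)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(data["X"].mean() - expected) < 3 * se

    def test_two_node_moments(self):
        # exhaustive weights 1,1,1,2 over the 4 states give E[X1]=0.6, E[X1X2]=0.4
        params = IsingParameters(
            ["A", "B"], [0.0, 0.0], [[0.0, np.log(2)], [np.log(2), 0.0]]
        )
        mom = enumerate_ising_moments(params)
        assert mom["node_means"][0] == pytest.approx(0.6, abs=1e-12)
        assert mom["pair_means"][0, 1] == pytest.approx(0.4, abs=1e-12)
        assert mom["expected_sum"] == pytest.approx(1.2, abs=1e-12)
        data = sample_ising(params, 20_000, seed=2)
        assert data["A"].mean() == pytest.approx(0.6, abs=0.015)
        assert (data["A"] * data["B"]).mean() == pytest.approx(0.4, abs=0.015)

    def test_independent_nodes_factorize(self, rng):
        from scipy.special import expit

        tau = rng.uniform(-2, 2, 4)
        params = IsingParameters(list("WXYZ"), tau, np.zeros((4, 4)))
        mom = enumerate_ising_moments(params)
        np.testing.assert_allclose(mom["node_means"], expit(tau), atol=1e-12)
        np.testing.assert_allclose(
            mom["pair_means"][0, 1], expit(tau[0]) * expit(tau[1]), atol=1e-12
        )

    def test_enumeration_refuses_large_networks(self):
        params = IsingParameters(
            [f"S{i}" for i in range(21)], np.zeros(21), np.zeros((21, 21))
        )
        with pytest.raises(ValueError, match="enumeration"):
            enumerate_ising_moments(params)

    def test_sampler_within_monte_carlo_error_of_oracle(self, rng):
        n = 2000
        hits = 0
        n_sets = 15
        for k in range(n_sets):
            params = random_ising(rng, int(rng.integers(2, 5)))
            mom = enumerate_ising_moments(params)
            scores = sample_ising(params, n, seed=100 + k).sum(axis=1)
            se = scores.std(ddof=1) / np.sqrt(n)
            hits += abs(scores.mean() - mom["expected_sum"]) <= 3 * se
        assert hits >= 0.9 * n_sets

    def test_seed_determinism(self, rng):
        params = random_ising(rng, 4)
        a = sample_ising(params, 200, seed=7)
        b = sample_ising(params, 200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_asymmetric_omega_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            IsingParameters(["A", "B"], [0, 0], [[0, 0.5], [0.2, 0]])

    def test_fkg_monotonicity_of_thresholds(self):
        # with omega >= 0, raising any tau_i never lowers any E[X_j]
        omega = np.array([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]])
        for i in range(3):
            for t in np.linspace(-1, 1, 5):
                base = IsingParameters(list("ABC"), [-0.5, 0.0, 0.5], omega)
                tau_hi = base.tau.copy()
                tau_hi[i] = t + 0.3
                tau_lo = base.tau.copy()
                tau_lo[i] = t
                hi = enumerate_ising_moments(IsingParameters(base.labels, tau_hi, omega))
                lo = enumerate_ising_moments(IsingParameters(base.labels, tau_lo, omega))
                assert np.all(hi["node_means"] >= lo["node_means"] - 1e-12)


class TestGGMSampler:
    def test_two_node_partial_correlation(self):
        truth = GroundTruthGGM(["A", "B"], [[2.0, -1.0], [-1.0, 2.0]])
        assert truth.pcor[0, 1] == pytest.approx(0.5)
        data = sample_ggm_data(truth, 50_000, seed=3)
        assert data.corr().iloc[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_identity_precision_uncorrelated(self):
        truth = GroundTruthGGM(list("ABCD"), np.eye(4))
        data = sample_ggm_data(truth, 5000, seed=4)
        off = data.corr().to_numpy()[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 4 / np.sqrt(5000))

    def test_chain_nonadjacent_partials_vanish(self):
        K = np.eye(5)
        for i in range(4):
            K[i, i + 1] = K[i + 1, i] = -0.4
        truth = GroundTruthGGM(list("ABCDE"), K)
        data = sample_ggm_data(truth, 40_000, seed=5)
        Khat = np.linalg.inv(data.cov().to_numpy())
        d = np.sqrt(np.diag(Khat))
        pcor = -Khat / np.outer(d, d)
        assert abs(pcor[0, 2]) < 0.02 and abs(pcor[0, 4]) < 0.02
        assert pcor[0, 1] == pytest.approx(truth.pcor[0, 1], abs=0.02)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            GroundTruthGGM(["A", "B"], [[1.0, 2.0], [2.0, 1.0]])

    def test_seed_determinism(self):
        truth = GroundTruthGGM(["A", "B"], [[2.0, -1.0], [-1.0, 2.0]])
        pd.testing.assert_frame_equal(
            sample_ggm_data(truth, 50, seed=6), sample_ggm_data(truth, 50, seed=6)
        )


class TestModeratedSampler:
    @staticmethod
    def moderated_pair(m: float = -0.2) -> ModeratedTruth:
        p = 4
        w0 = np.zeros((p, p))
        w0[0, 1] = w0[1, 0] = 0.3
        mm = np.zeros((p, p))
        mm[0, 1] = mm[1, 0] = m
        return ModeratedTruth([f"D{i}" for i in range(p)], w0, mm)

    def test_negative_moderation_weakens_with_moderator(self):
        truth = self.moderated_pair(-0.2)
        data, s = sample_moderated_data(truth, 20_000, seed=7)
        q = s.quantile([1 / 3, 2 / 3]).to_numpy()
        r = [
            data.loc[mask, ["D0", "D1"]].corr().iloc[0, 1]
            for mask in (s <= q[0], (s > q[0]) & (s <= q[1]), s > q[1])
        ]
        assert r[0] > r[1] > r[2]

    def test_zero_moderation_matches_static_model(self):
        truth = self.moderated_pair(0.0)
        data, s = sample_moderated_data(truth, 20_000, seed=8)
        q = s.quantile([1 / 3, 2 / 3]).to_numpy()
        r = [
            data.loc[mask, ["D0", "D1"]].corr().iloc[0, 1]
            for mask in (s <= q[0], s > q[1])
        ]
        assert abs(r[0] - r[1]) < 0.04
        static = GroundTruthGGM(truth.labels, truth.conditional_precision(0.0))
        ref = sample_ggm_data(static, 20_000, seed=8)
        assert data["D0"].corr(data["D1"]) == pytest.approx(
            ref["D0"].corr(ref["D1"]), abs=0.03
        )

    def test_constant_moderator_gives_base_weights(self):
        truth = ModeratedTruth(
            ["A", "B"],
            [[0, 0.3], [0.3, 0]],
            [[0, -0.1], [-0.1, 0]],
            moderator_sd=0.0,
        )
        _, s = sample_moderated_data(truth, 100, seed=9)
        assert np.all(s == 0.0)
        np.testing.assert_allclose(truth.conditional_weights(0.0), truth.base_weights)

    def test_non_pd_reports_offending_moderator(self):
        truth = ModeratedTruth(
            ["A", "B"],
            [[0, 0.5], [0.5, 0]],
            [[0, 0.4], [0.4, 0]],
            moderator_truncation=None,
        )
        with pytest.raises(ValueError, match="moderator value"):
            sample_moderated_data(truth, 2000, seed=10)


class TestLikertEmission:
    def test_round_trip_recovers_latent_states(self, rng):
        truth = random_ising(rng, 5)
        survey, latent = sample_likert_cls(
            truth, 400, seed=11, reverse_keyed={"S2", "S4"}, return_latent=True
        )
        recovered = dichotomize(reverse_score(survey))
        assert recovered.astype("int64").equals(latent)

    def test_extreme_thresholds_give_absent_responses(self):
        truth = IsingParameters(list("AB"), [-10.0, -10.0], np.zeros((2, 2)))
        survey = sample_likert_cls(truth, 300, seed=12)
        assert set(survey.responses.stack().unique()) <= {1, 2}

    def test_empty_survey_keeps_schema(self, rng):
        truth = random_ising(rng, 3)
        survey = sample_likert_cls(truth, 0, seed=13, reverse_keyed={"S1"})
        assert survey.items == truth.labels and survey.n_participants == 0
        assert survey.reverse_keyed == {"S1"}
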
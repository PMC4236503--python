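import numpy as np
import pytest

import saturascreen as ss
from saturascreen.subst_models import (ModelParameterError,
                                       category_rates_and_weights,
                                       transition_probabilities_batch)


def jc_prob_same(d):
    return 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)


class TestGenerator:
    def test_jc_offdiagonals(self, jc):
        Q = ss.build_generator(jc)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_hky_kappa1_equals_f81(self):
        freqs = [0.4, 0.1, 0.2, 0.3]
        hky = ss.SubstitutionModel.hky(freqs, kappa=1.0)
        f81 = ss.SubstitutionModel(np.asarray(freqs))
        assert np.allclose(ss.build_generator(hky), ss.build_generator(f81))

    def test_detailed_balance_random_gtr(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            f = rng.dirichlet(np.ones(4) * 5)
            r = rng.gamma(2.0, 1.0, 6)
            m = ss.SubstitutionModel.gtr(f, r)
            Q = ss.build_generator(m)
            flux = f[:, None] * Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_substitution_rate(self, gtr):
        Q = ss.build_generator(gtr)
        mu = -(gtr.base_frequencies * np.diag(Q)).sum()
        assert mu == pytest.approx(1.0, abs=1e-12)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ModelParameterError):
            ss.SubstitutionModel(np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ModelParameterError):
            ss.SubstitutionModel(np.array([0.5, 0.3, 0.3, 0.3]))


class TestTransitionProbabilities:
    def test_zero_distance_identity(self, gtr):
        assert np.allclose(ss.transition_probabilities(gtr, 0.0), np.eye(4))

    def test_long_distance_reaches_stationarity(self, jc, gtr):
        for m in (jc, gtr):
            P = ss.transition_probabilities(m, 500.0)
            assert np.allclose(P, np.tile(m.base_frequencies, (4, 1)),
                               atol=1e-10)

    def test_jc_closed_form_at_075(self, jc):
        P = ss.transition_probabilities(jc, 0.75)
        off = 0.25 * (1 - np.exp(-1.0))
        assert P[0, 1] == pytest.approx(off, abs=1e-12)
        assert P[0, 0] == pytest.approx(jc_prob_same(0.75), abs=1e-12)

    @pytest.mark.parametrize("d", [0.01, 0.1, 0.5, 1.0, 3.0])
    def test_jc_closed_form_grid(self, jc, d):
        P = ss.transition_probabilities(jc, d)
        assert np.allclose(np.diag(P), jc_prob_same(d), atol=1e-10)
        assert np.allclose(P[~np.eye(4, dtype=bool)],
                           (1 - jc_prob_same(d)) / 3.0, atol=1e-10)

    @pytest.mark.parametrize("d", [0.05, 0.3, 1.2])
    def test_k80_closed_form(self, d):
        kappa = 5.0
        m = ss.SubstitutionModel.k80(kappa)
        P = ss.transition_probabilities(m, d)
        # normalized K80: per-target transversion rate 1/(kappa+2), so the
        # closed form uses beta = 2/(kappa+2) and alpha = kappa*beta
        beta = 2.0 / (kappa + 2.0)
        alpha = kappa * beta
        p_tv = 0.25 - 0.25 * np.exp(-2.0 * beta * d)
        p_ts = (0.25 + 0.25 * np.exp(-2.0 * beta * d)
                - 0.5 * np.exp(-(alpha + beta) * d))
        # A->G is a transition; A->C and A->T are transversions
        assert P[0, 2] == pytest.approx(p_ts, abs=1e-10)
        assert P[0, 1] == pytest.approx(p_tv, abs=1e-10)
        assert P[0, 3] == pytest.approx(p_tv, abs=1e-10)

    def test_chapman_kolmogorov(self, gtr):
        a, b = 0.23, 0.41
        Pa = ss.transition_probabilities(gtr, a)
        Pb = ss.transition_probabilities(gtr, b)
        Pab = ss.transition_probabilities(gtr, a + b)
        assert np.allclose(Pa @ Pb, Pab, atol=1e-8)

    def test_stationarity(self, gtr):
        pi = gtr.base_frequencies
        for d in [0.1, 1.0, 10.0]:
            assert np.allclose(pi @ ss.transition_probabilities(gtr, d), pi,
                               atol=1e-10)

    def test_rows_sum_to_one(self, gtr):
        for d in [0.0, 0.2, 2.0]:
            P = ss.transition_probabilities(gtr, d)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0.0 and P.max() <= 1.0

    def test_negative_distance_rejected(self, jc):
        with pytest.raises(ValueError):
            ss.transition_probabilities(jc, -0.1)

    def test_batch_matches_scalar(self, gtr):
        d = np.array([0.0, 0.15, 0.9, 4.0])
        batch = transition_probabilities_batch(gtr, d)
        for k, dk in enumerate(d):
            assert np.allclose(batch[k],
                               ss.transition_probabilities(gtr, dk),
                               atol=1e-12)


class TestRateHeterogeneity:
    @pytest.mark.parametrize("shape", [0.1, 0.5, 1.0, 5.0, 50.0])
    def test_discrete_gamma_mean_one(self, shape):
        rates = ss.discrete_gamma_rates(shape, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(rates) > 0).all()

    def test_invariant_mixture(self):
        m = ss.SubstitutionModel(gamma_shape=0.5, p_invariant=0.2)
        rates, weights = category_rates_and_weights(m)
        assert rates[0] == 0.0 and weights[0] == pytest.approx(0.2)
        assert weights.sum() == pytest.approx(1.0)
        assert (rates * weights).sum() == pytest.approx(1.0, abs=1e-12)

    def test_from_config(self):
        m = ss.SubstitutionModel.from_config(
            {"model": "GTR", "freqs": [0.3, 0.2, 0.3, 0.2],
             "rates": [1, 2, 1, 1, 3, 1], "gamma_shape": 0.5, "ncat": 4})
        assert m.gamma_shape == 0.5
        with pytest.raises(ModelParameterError):
            ss.SubstitutionModel.from_config({"model": "CODON"})
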
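import numpy as np
import pytest

import saturascreen as ss
from saturascreen._felsenstein import brute_force_site_log_likelihood
from saturascreen.site_rates import (AT_LOWER, CONVERGED, UNINFORMATIVE,
                                     empirical_frequencies)
from conftest import random_chronogram


class TestSiteLogLikelihood:
    def test_rate_zero_constant_column_is_log_pi(self, four_taxon_chronogram,
                                                 gtr):
        col = {t: "G" for t in "ABCD"}
        ll = ss.site_log_likelihood(col, four_taxon_chronogram, gtr, 0.0)
        assert ll == pytest.approx(np.log(gtr.base_frequencies[2]), abs=1e-9)

    def test_all_gap_column_probability_one(self, four_taxon_chronogram, gtr):
        col = {t: "-" for t in "ABCD"}
        ll = ss.site_log_likelihood(col, four_taxon_chronogram, gtr, 0.3)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_taxon_mismatch_reported(self, four_taxon_chronogram, gtr):
        with pytest.raises(ValueError, match="match"):
            ss.site_log_likelihood({"A": "A", "B": "C", "C": "G", "X": "T"},
                                   four_taxon_chronogram, gtr, 0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_enumeration_random_trees(self, seed, gtr):
        """Pruning likelihoods equal the exhaustive ancestral-state sum on
        random 4-6 taxon trees, including ambiguity codes and gaps."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        ch = random_chronogram(rng, n)
        states = list("ACGT") + ["R", "N", "-"]
        col = {t: states[rng.integers(0, len(states))] for t in ch.taxa}
        rate = float(rng.uniform(0.02, 0.8))
        a = ss.site_log_likelihood(col, ch, gtr, rate)
        b = brute_force_site_log_likelihood(col, ch, gtr, rate)
        assert a == pytest.approx(b, abs=1e-10)

    def test_invariant_under_taxon_reordering(self, four_taxon_chronogram,
                                              gtr):
        col = {"A": "A", "B": "C", "C": "G", "D": "T"}
        ll1 = ss.site_log_likelihood(col, four_taxon_chronogram, gtr, 0.2)
        col2 = dict(reversed(list(col.items())))
        ll2 = ss.site_log_likelihood(col2, four_taxon_chronogram, gtr, 0.2)
        assert ll1 == pytest.approx(ll2, abs=1e-12)


class TestEstimateSiteRates:
    def test_constant_columns_hit_lower_bound(self, small_chronogram, jc):
        aln = ss.Alignment(small_chronogram.taxa,
                           np.full((12, 5), "A", dtype="<U1"))
        sr = ss.estimate_site_rates(aln, small_chronogram, jc)
        assert (sr.rates == sr.bounds[0]).all()
        assert (sr.flags == AT_LOWER).all()

    def test_duplicate_columns_identical_estimates(self, small_chronogram,
                                                   gtr):
        rng = np.random.default_rng(0)
        rates = np.full(30, 0.01)
        aln = ss.simulate_alignment(small_chronogram, gtr, rates, 3)
        dup = ss.Alignment(aln.taxa, np.hstack([aln.data, aln.data[:, :1]]))
        sr = ss.estimate_site_rates(dup, small_chronogram, gtr)
        assert sr.rates[-1] == sr.rates[0]
        assert len(sr) == dup.length

    def test_mostly_missing_column_flagged_uninformative(
            self, small_chronogram, gtr):
        data = np.full((12, 1), "-", dtype="<U1")
        data[0, 0] = "A"
        data[1, 0] = "C"
        aln = ss.Alignment(small_chronogram.taxa, data)
        sr = ss.estimate_site_rates(aln, small_chronogram, gtr)
        assert sr.flags[0] == UNINFORMATIVE

    def test_local_optimum_certificate(self, small_chronogram, gtr):
        """The profile log-likelihood at the returned rate beats nearby
        rates, certifying a local maximum."""
        aln = ss.simulate_alignment(small_chronogram, gtr,
                                    np.full(40, 0.008), 11)
        sr = ss.estimate_site_rates(aln, small_chronogram, gtr, tol=1e-8)
        ok = sr.flags == CONVERGED
        assert ok.sum() >= 20
        from saturascreen._felsenstein import LikelihoodEngine
        engine = LikelihoodEngine(aln, small_chronogram, gtr)
        for factor in (1 - 1e-4, 1 + 1e-4):
            ll = engine.loglik_per_site(sr.rates * factor)
            assert (ll[ok] <= sr.log_likelihoods[ok] + 1e-9).all()

    def test_median_recovery_replicate_columns(self):
        """Across 500 replicate columns simulated at 0.005 subs/site/Ma on a
        20-taxon, root-age-390 chronogram, the median estimate lands within
        20% of truth."""
        cfg = ss.SimulationConfig(n_taxa=20, root_age=390.0, seed=17)
        tree = ss.simulate_chronogram(cfg)
        model = ss.SubstitutionModel.gtr([0.3, 0.2, 0.3, 0.2],
                                         [1, 4, 1, 1, 4, 1])
        aln = ss.simulate_alignment(tree, model, np.full(500, 0.005), 17)
        sr = ss.estimate_site_rates(aln, tree, model, tol=1e-6)
        med = np.median(sr.rates)
        assert 0.004 < med < 0.006

    def test_rate_scales_inversely_with_time_units(self, small_chronogram,
                                                   gtr):
        aln = ss.simulate_alignment(small_chronogram, gtr,
                                    np.full(25, 0.01), 23)
        sr1 = ss.estimate_site_rates(aln, small_chronogram, gtr, tol=1e-8)
        scaled = small_chronogram.scaled(3.0)
        sr2 = ss.estimate_site_rates(aln, scaled, gtr, tol=1e-8)
        ok = (sr1.flags == CONVERGED) & (sr2.flags == CONVERGED)
        assert ok.any()
        assert np.allclose(sr2.rates[ok] * 3.0, sr1.rates[ok], rtol=1e-5)

    def test_output_length_and_wrapper(self, four_taxon_chronogram, gtr):
        col = {"A": "A", "B": "A", "C": "G", "D": "G"}
        rate, ll, flag = ss.estimate_site_rate(col, four_taxon_chronogram,
                                               gtr)
        assert rate > 0 and np.isfinite(ll)
        assert flag in (CONVERGED, AT_LOWER)


class TestEmpiricalFrequencies:
    def test_ambiguity_split_and_missing_ignored(self):
        aln = ss.Alignment.from_strings({"A": "AR-", "B": "C?N"})
        f = empirical_frequencies(aln, pseudocount=0.0)
        # A=1 + R gives A+G each 0.5; C=1
        assert f[0] == pytest.approx(1.5 / 3.0)
        assert f[1] == pytest.approx(1.0 / 3.0)
        assert f[2] == pytest.approx(0.5 / 3.0)
        assert f.sum() == pytest.approx(1.0)
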
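"""NB GLM engine, testability filters, FDR estimation, result classification."""
import warnings

import numpy as np
import pandas as pd
import pytest

from bindqtl.assoc import (
    AssociationResult,
    TestableSite,
    associate,
    bh_qvalues,
    classify_results,
    estimate_fdr,
    fit_nb_genotype,
    select_testable,
    storey_pi0,
    storey_qvalues,
)
from bindqtl.genotyping import MISSING, SnpCall
from bindqtl.nbglm import fit_nbglm, nb_loglik


def make_site(y, g, rep=None, site="s1", snp="p1"):
    y = np.asarray(y, float)
    g = np.asarray(g)
    if rep is None:
        rep = np.array(["r1"] * len(y))
    return TestableSite(site, snp, y, g, np.asarray(rep),
                        np.array([f"m{i}" for i in range(len(y))]))


def sim_site(rng, beta=0.0, n_samples=12, depth=50.0, theta=10.0):
    g = rng.choice([0, 1, 2], size=n_samples, p=[0.25, 0.5, 0.25]).repeat(2)
    rep = np.tile(["r1", "r2"], n_samples)
    mu = depth * np.exp(beta * g) * np.where(rep == "r1", 1.0, 0.8)
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    return make_site(y, g, rep)


class TestNbGlm:
    def test_matches_statsmodels_mle(self, rng):
        """Plain joint-MLE route reproduces statsmodels NegativeBinomial."""
        from statsmodels.discrete.discrete_model import NegativeBinomial
        for _ in range(5):
            ts = sim_site(rng, beta=0.3)
            X = np.column_stack([np.ones(len(ts.counts)),
                                 ts.genotype.astype(float),
                                 (ts.replicate == "r2").astype(float)])
            f = fit_nbglm(ts.counts, X, cr_adjust=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = NegativeBinomial(ts.counts, X).fit(disp=0)
            assert np.allclose(f.beta, m.params[:-1], atol=1e-4)
            assert f.theta == pytest.approx(1.0 / m.params[-1], rel=1e-2)
            # expected vs observed information: a few percent on the SEs
            assert np.allclose(f.se, m.bse[:-1], rtol=6e-2)

    def test_loglik_formula_against_scipy(self, rng):
        from scipy import stats
        y = rng.negative_binomial(5, 0.4, size=30).astype(float)
        mu = np.full_like(y, 5 * 0.6 / 0.4)
        ll = nb_loglik(y, mu, 5.0)
        oracle = stats.nbinom.logpmf(y, 5, 5 / (5 + mu)).sum()
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_fixed_theta_path(self, rng):
        ts = sim_site(rng)
        X = np.column_stack([np.ones(len(ts.counts)), ts.genotype.astype(float)])
        f = fit_nbglm(ts.counts, X, theta=10.0)
        assert f.theta == 10.0 and f.converged


class TestFitNbGenotype:
    def test_identical_counts_no_signal(self):
        y = np.full(24, 40.0)
        g = np.array([0] * 8 + [1] * 8 + [2] * 8)
        r = fit_nb_genotype(make_site(y, g))
        assert abs(r.slope) < 1e-6
        assert r.wald_p > 0.9

    def test_coding_involution(self, rng):
        """Swapping allele labels negates the slope, preserves p exactly."""
        ts = sim_site(rng, beta=0.4)
        r1 = fit_nb_genotype(ts, theta=10.0)
        flipped = make_site(ts.counts, 2 - ts.genotype, ts.replicate)
        r2 = fit_nb_genotype(flipped, theta=10.0)
        assert r2.slope == pytest.approx(-r1.slope, abs=1e-6)
        assert r2.wald_p == pytest.approx(r1.wald_p, abs=1e-9)
        assert {r1.higher_occupancy_allele, r2.higher_occupancy_allele} == {"A", "B"}

    def test_sign_recovery_two_fold_homozygote(self, rng):
        """Spec scenario: 2-fold homozygote effect, depth 50, theta 10,
        24 points -> coefficient sign correct in >99% of sites."""
        correct = sum(fit_nb_genotype(sim_site(rng, beta=np.log(2) / 2)).slope > 0
                      for _ in range(300))
        assert correct / 300 > 0.99

    def test_dominance_wins_aic_majority(self, rng):
        """Exact-dominance data prefer a dominant collapsing by AIC."""
        wins = 0
        n = 150
        for _ in range(n):
            g = rng.choice([0, 1, 2], size=12, p=[0.25, 0.5, 0.25]).repeat(2)
            rep = np.tile(["r1", "r2"], 12)
            mu = 50.0 * np.exp(np.log(2.5) * (g >= 1)) * np.where(rep == "r1", 1, 0.8)
            y = rng.negative_binomial(10, 10 / (10 + mu)).astype(float)
            r = fit_nb_genotype(make_site(y, g, rep))
            wins += r.model == "dominantB"
        assert wins / n > 0.5

    def test_r2_and_het_signal_populated(self, rng):
        r = fit_nb_genotype(sim_site(rng, beta=0.5))
        assert 0.0 <= r.r2 <= 1.0
        assert r.het_signal > 0


class TestSelectTestable:
    def call(self, genotypes, snp="p1", failed=()):
        return SnpCall(snp_id=snp, allele_a="A", allele_b="C", quality=60.0,
                       genotypes=genotypes, filters_failed=list(failed))

    def counts_df(self, site="s1", samples=None, reps=("r1", "r2")):
        samples = samples or [f"m{i}" for i in range(12)]
        rows = [(site, m, r, 40) for m in samples for r in reps]
        return pd.DataFrame(rows, columns=["site_id", "sample", "replicate",
                                           "count"])

    def test_balanced_classes_testable(self):
        gts = {f"m{i}": [0] * 5 + [1] * 4 + [2] * 3 for i in range(12)}
        gts = {f"m{i}": ([0] * 5 + [1] * 4 + [2] * 3)[i] for i in range(12)}
        ts, ledger = select_testable(self.counts_df(), [self.call(gts)],
                                     {"p1": "s1"})
        assert len(ts) == 1 and ledger.empty

    def test_class_minimum_violated(self):
        gts = {f"m{i}": ([0] * 10 + [1, 2])[i] for i in range(12)}
        ts, ledger = select_testable(self.counts_df(), [self.call(gts)],
                                     {"p1": "s1"})
        assert not ts
        assert ledger.iloc[0]["reason"] == "genotype-class minimum"

    def test_coverage_in_five_samples_excluded(self):
        gts = {f"m{i}": (0 if i < 3 else 2 if i < 5 else MISSING)
               for i in range(12)}
        ts, ledger = select_testable(self.counts_df(), [self.call(gts)],
                                     {"p1": "s1"})
        assert not ts and ledger.iloc[0]["reason"] == "coverage"

    def test_mappability_fail_excluded(self):
        gts = {f"m{i}": ([0] * 5 + [1] * 4 + [2] * 3)[i] for i in range(12)}
        ts, ledger = select_testable(self.counts_df(), [self.call(gts)],
                                     {"p1": "s1"}, mappability_pass={"s1": False})
        assert not ts and ledger.iloc[0]["reason"] == "mappability"

    def test_multi_snp_prefers_more_data_points(self):
        gts_full = {f"m{i}": ([0] * 5 + [1] * 4 + [2] * 3)[i] for i in range(12)}
        gts_part = dict(gts_full)
        gts_part["m0"] = MISSING
        ts, _ = select_testable(
            self.counts_df(),
            [self.call(gts_full, "p1"), self.call(gts_part, "p2")],
            {"p1": "s1", "p2": "s1"})
        assert len(ts) == 1 and ts[0].snp_id == "p1"


class TestFdr:
    def test_all_ones(self):
        assert np.all(estimate_fdr([1.0, 1.0, 1.0], "bh") == 1.0)
        assert np.all(estimate_fdr([1.0, 1.0, 1.0], "storey") == 1.0)

    def test_bh_hand_example(self):
        q = estimate_fdr([0.001, 0.02, 0.9], "bh")
        assert np.allclose(q, [0.003, 0.03, 0.9])

    def test_storey_pi0_on_uniform_null(self, rng):
        p = rng.random(10000)
        assert 0.9 <= storey_pi0(p) <= 1.1

    def test_qvalues_monotone_in_p(self, rng):
        p = np.concatenate([rng.random(500) ** 3, rng.random(500)])
        for method in ("bh", "storey"):
            q = estimate_fdr(p, method)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_storey_equals_bh_when_pi0_forced_one(self, rng):
        p = rng.random(200)
        assert np.allclose(storey_qvalues(p, pi0=1.0), bh_qvalues(p))

    def test_empty_input(self):
        assert estimate_fdr([], "bh").size == 0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            estimate_fdr([0.5], "bonferroni")


class TestClassify:
    def test_concordance_flags(self, core_pwm):
        from bindqtl.motifs import MotifMatch
        m = MotifMatch(site_id="s1", offset=0, strand="+", score=20.0,
                       pvalue=1e-5, model_id="core", start=60, width=14,
                       core_start=60)
        # consensus base at column 0 is C; SNP C->T, higher occupancy C
        res = [AssociationResult(site_id="s1", snp_id="p1", model="additive",
                                 slope=-1.0, wald_p=1e-6, q=1e-5,
                                 higher_occupancy_allele="A")]
        summary = classify_results(res, {"s1": m}, {"p1": (60, "C", "T")},
                                   {"core": core_pwm}, fdr=0.01)
        assert res[0].contact_region is True
        assert res[0].favored_matches_observed is True
        assert summary["allele_concordance"] == 1.0
        # flip the observed direction -> discordant
        res[0].higher_occupancy_allele = "B"
        summary = classify_results(res, {"s1": m}, {"p1": (60, "C", "T")},
                                   {"core": core_pwm}, fdr=0.01)
        assert summary["allele_concordance"] == 0.0


class TestAssociateEndToEnd:
    def test_multi_candidate_resolved_to_one_per_site(self, rng):
        sites = [sim_site(rng, beta=0.0) for _ in range(3)]
        sites[1] = make_site(sites[0].counts, sites[0].genotype,
                             sites[0].replicate, site="s1", snp="pB")
        sites[0].position_ambiguous = sites[1].position_ambiguous = True
        res = associate(sites, moderate_dispersion=False)
        assert len({r.site_id for r in res}) == len(res)

    def test_q_attached_and_finite(self, rng):
        res = associate([sim_site(rng) for _ in range(50)],
                        moderate_dispersion=False)
        assert all(np.isfinite(r.q) for r in res if r.converged)
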
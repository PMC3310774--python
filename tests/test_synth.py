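"""Synthetic study generator: pedigree, sites, counts, pileups, conservation."""
import numpy as np
import pytest

from bindqtl.motifs import CORE_WIDTH, build_pwm, default_core_pwm
from bindqtl.synth import (
    MemberSpec,
    PedigreeError,
    PedigreeSpec,
    SimConfig,
    emit_conservation,
    generate_sites,
    generate_study,
    genotype_matrix,
    occupancy,
    simulate_counts,
    simulate_pedigree,
    simulate_pileups,
)
from bindqtl.genotyping import mendelian_consistent


class TestPedigreeSpec:
    def test_default_is_12_members(self, pedigree_spec):
        assert len(pedigree_spec.members) == 12
        pedigree_spec.validate()

    def test_wrong_founder_count_rejected(self):
        bad = PedigreeSpec(tuple([MemberSpec("a", "M"), MemberSpec("b", "F")]))
        with pytest.raises(PedigreeError):
            bad.validate()

    def test_stray_child_named_in_error(self, pedigree_spec):
        members = pedigree_spec.members + (MemberSpec("x", "M", "c1", "c2"),)
        with pytest.raises(PedigreeError, match="x"):
            PedigreeSpec(members).validate()


class TestSimulatePedigree:
    def test_no_recombination_gives_whole_chromosome_blocks(self, pedigree_spec):
        cfg = SimConfig(seed=1, n_sites=50, recomb_rate=0.0,
                        site_genetic_spacing=None)
        ped = simulate_pedigree(pedigree_spec, cfg)
        # a single IBD value per pair across every site
        assert all(np.unique(ped.ibd[:, p]).size == 1
                   for p in range(ped.ibd.shape[1]))

    def test_ibd_values_are_half_integers(self, small_study):
        assert set(np.unique(small_study.pedigree.ibd)) <= {0.0, 0.5, 1.0}

    def test_free_recombination_mean_ibd_half(self, pedigree_spec):
        cfg = SimConfig(seed=2, n_sites=10000, site_genetic_spacing=10.0)
        ped = simulate_pedigree(pedigree_spec, cfg)
        # full sibs: E[IBD]=0.5, Var[IBD]=1/8 per site
        mean = ped.ibd.mean()
        se = np.sqrt(1 / 8 / ped.ibd.size)  # optimistic (pairs correlate)
        assert abs(mean - 0.5) < 30 * se    # loose but directional

    def test_ibd_consistent_with_labels(self, small_study):
        ped = small_study.pedigree
        for pi, (a, b) in enumerate(ped.sib_pairs):
            la = ped.labels[ped.index(a)]
            lb = ped.labels[ped.index(b)]
            recomputed = ((la[:, 0] == lb[:, 0]).astype(float)
                          + (la[:, 1] == lb[:, 1])) / 2
            assert np.array_equal(recomputed, ped.ibd[:, pi])

    def test_fifteen_sib_pairs(self, small_study):
        assert len(small_study.pedigree.sib_pairs) == 15

    def test_mendelian_consistency_exact(self, small_study):
        """Generated genotypes never violate transmission, at any site."""
        study = small_study
        for j in range(min(200, study.genotypes.shape[1])):
            gts = {m: int(study.genotypes[i, j])
                   for i, m in enumerate(study.samples)}
            ok, bad = mendelian_consistent(gts, study.pedigree.spec)
            assert ok, bad

    def test_ibd_uncertainty_injection(self, pedigree_spec):
        cfg = SimConfig(seed=3, n_sites=200, ibd_uncertainty_rate=0.3)
        ped = simulate_pedigree(pedigree_spec, cfg)
        frac = (ped.ibd_uncertainty > 0.05).mean()
        assert 0.2 < frac < 0.4


class TestGenerateSites:
    def test_snp_rate_one_plants_everywhere(self):
        cfg = SimConfig(seed=4, n_sites=100, snp_rate=1.0, extra_snp_rate=0.0)
        _, sites, snps = generate_sites(cfg)
        assert len({s.site_id for s in snps}) == 100

    def test_uniform_snp_placement_contact_fraction(self):
        """Uniform placement puts ~44/134 of SNPs in the contact region."""
        cfg = SimConfig(seed=5, n_sites=6000, snp_rate=1.0, extra_snp_rate=0.5)
        _, sites, snps = generate_sites(cfg)
        core_start = sites[0].core_start
        n = len(snps)
        def rel(s):
            site = sites[s.site_index]
            p = s.window_pos - core_start
            return (CORE_WIDTH - 1 - p) if site.strand == "-" else p
        inside = sum(-20 <= rel(s) <= 23 for s in snps)
        expect = 44 / 134
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(inside / n - expect) < 4 * se

    def test_degenerate_column_sampled_uniformly(self):
        f = default_core_pwm().freqs.copy()
        f[6] = 0.25
        pwm = build_pwm(f)
        cfg = SimConfig(seed=6, n_sites=4000, snp_rate=0.0)
        _, sites, _ = generate_sites(cfg, pwm)
        col = []
        for s in sites:
            core = s.seq[s.core_start:s.core_start + CORE_WIDTH]
            if s.strand == "-":
                from bindqtl._util import revcomp_str
                core = revcomp_str(core)
            col.append(core[6])
        counts = np.array([col.count(b) for b in "ACGT"]) / len(col)
        assert np.all(np.abs(counts - 0.25) < 4 * np.sqrt(0.25 * 0.75 / len(col)))

    def test_founder_allele_frequency_recovered(self):
        cfg = SimConfig(seed=7, n_sites=6000, snp_rate=1.0)
        spec = PedigreeSpec.default()
        ped = simulate_pedigree(spec, cfg)
        _, sites, snps = generate_sites(cfg)
        freq = np.mean([s.hap_has_alt.mean() for s in snps])
        se = np.sqrt(0.25 / (8 * len(snps)))
        assert abs(freq - 0.5) < 3 * se


class TestSimulateCounts:
    def test_silent_snp_allele_fraction_half(self, small_study):
        """Flank (zero-delta) SNPs split heterozygote reads 50:50."""
        study = small_study
        silent = {s.snp_id for s in study.snps
                  if s.rel_occ_diff == 0.0}
        sub = study.allele_counts[study.allele_counts["snp_id"].isin(silent)]
        tot = sub["reads_a"].sum() + sub["reads_b"].sum()
        frac = sub["reads_b"].sum() / tot
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / tot)

    def test_step_function_limit_heterozygote(self):
        # slope -> 0 makes occupancy a step: het expected count = depth/2
        p = occupancy(np.array([20.0, 5.0]), 14.0, 0.0)
        assert p[0] == 1.0 and p[1] == 0.0

    def test_nb_moment_check(self, pedigree_spec):
        """Sample variance of null counts matches mu + mu^2/theta."""
        cfg = SimConfig(seed=8, n_sites=2000, snp_rate=0.0, dispersion=10.0,
                        batch_factors=(1.0,), single_replicate_sample=None)
        ped = simulate_pedigree(pedigree_spec, cfg)
        _, sites, snps = generate_sites(cfg)
        counts, _, site_mu, _ = simulate_counts(cfg, ped, sites, snps,
                                                default_core_pwm())
        df = counts.merge(
            counts.groupby("site_id")["count"].agg(["mean", "var"]),
            left_on="site_id", right_index=True)
        # pool sites with similar expected mean: compare pooled var to theory
        mu = site_mu.mean(axis=1)
        sel = (mu > 20) & (mu < 60)
        got = df[df["site_id"].isin(np.array([s.site_id for s in sites])[sel])]
        piv = got.groupby("site_id")["count"].agg(["mean", "var"])
        theory = piv["mean"] + piv["mean"] ** 2 / 10.0
        ratio = piv["var"].sum() / theory.sum()
        assert 0.9 < ratio < 1.1

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(dispersion=0.0).validate()

    def test_occupancy_monotone_in_score(self):
        s = np.linspace(0, 30, 50)
        p = occupancy(s, 14.0, 1.5)
        assert np.all(np.diff(p) > 0)

    def test_effect_labels_follow_occupancy_threshold(self, small_study):
        for snp in small_study.snps:
            expect = "functional" if snp.rel_occ_diff > small_study.cfg.truth_threshold \
                else "silent"
            assert snp.effect_label == expect


class TestSimulatePileups:
    def test_error_free_pileups_match_genotypes(self, pedigree_spec):
        cfg = SimConfig(seed=9, n_sites=60, base_error=0.0)
        ped = simulate_pedigree(pedigree_spec, cfg)
        _, sites, snps = generate_sites(cfg)
        g = genotype_matrix(ped, snps)
        piles = simulate_pileups(cfg, ped, snps, g)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for _, row in piles.iterrows():
            j = next(k for k, s in enumerate(snps) if s.snp_id == row["snp_id"])
            mi = ped.member_ids.index(row["sample"])
            counts = np.array([row[f"n{b}"] for b in "ACGT"])
            alt = counts[base_idx[snps[j].alt]]
            if counts.sum() == 0:
                continue
            frac = alt / counts.sum()
            gt = g[mi, j]
            if gt == 0:
                assert frac == 0.0
            elif gt == 2:
                assert frac == 1.0

    def test_homozygote_error_rate(self, pedigree_spec):
        """base_error=0.01: non-matching reads ~ depth * error."""
        cfg = SimConfig(seed=10, n_sites=400, base_error=0.01, pileup_depth=50,
                        snp_rate=1.0)
        ped = simulate_pedigree(pedigree_spec, cfg)
        _, sites, snps = generate_sites(cfg)
        g = genotype_matrix(ped, snps)
        piles = simulate_pileups(cfg, ped, snps, g)
        snp_by_id = {s.snp_id: (k, s) for k, s in enumerate(snps)}
        mism = total = 0
        for _, row in piles.iterrows():
            k, s = snp_by_id[row["snp_id"]]
            mi = ped.member_ids.index(row["sample"])
            if g[mi, k] != 0:
                continue
            counts = np.array([row[f"n{b}"] for b in "ACGT"])
            ref = "ACGT".index(s.ref)
            mism += counts.sum() - counts[ref]
            total += counts.sum()
        rate = mism / total
        assert abs(rate - 0.01) < 4 * np.sqrt(0.01 * 0.99 / total)


class TestConservation:
    def test_noise_free_rank_order_matches_information(self, pedigree_spec):
        cfg = SimConfig(seed=12, n_sites=5, snp_rate=0.0)
        _, sites, _ = generate_sites(cfg)
        pwm = default_core_pwm()
        track = emit_conservation(cfg, sites, pwm, noise_sd=0.0)
        ic = pwm.information_content()
        for i, site in enumerate(sites):
            core = track[i, site.core_start:site.core_start + CORE_WIDTH]
            prof = ic if site.strand == "+" else ic[::-1]
            assert np.allclose(core, prof)
            # flanks carry no signal
            assert np.allclose(track[i, :site.core_start], 0.0)

    def test_large_noise_destroys_correlation(self, pedigree_spec):
        cfg = SimConfig(seed=13, n_sites=400, snp_rate=0.0)
        _, sites, _ = generate_sites(cfg)
        pwm = default_core_pwm()
        ic = pwm.information_content()
        for sd, bound in ((0.1, 0.9), (50.0, 0.2)):
            track = emit_conservation(cfg, sites, pwm, noise_sd=sd)
            cors = []
            for i, site in enumerate(sites):
                core = track[i, site.core_start:site.core_start + CORE_WIDTH]
                prof = ic if site.strand == "+" else ic[::-1]
                cors.append(np.corrcoef(core, prof)[0, 1])
            mean_cor = np.nanmean(cors)
            assert (mean_cor > bound) if sd < 1 else (mean_cor < bound)


class TestDeterminism:
    def test_same_seed_same_study(self):
        a = generate_study(SimConfig(seed=21, n_sites=30))
        b = generate_study(SimConfig(seed=21, n_sites=30))
        assert a.genome == b.genome
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.counts.equals(b.counts)
        assert a.pileups.equals(b.pileups)

    def test_different_substreams_are_independent(self):
        # changing pileup parameters must not perturb counts
        a = generate_study(SimConfig(seed=22, n_sites=30, pileup_depth=10))
        b = generate_study(SimConfig(seed=22, n_sites=30, pileup_depth=60))
        assert a.counts.equals(b.counts)
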
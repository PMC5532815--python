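"""Paired allelic model: filters, fit symmetry, CIs, BH, read assignment."""

import numpy as np
import pysam
import pytest
from scipy.stats import chi2

from editvar import (AsedObservation, DataError, EditingSite, HetSnpAssignment,
                     SimConfig, UntestableError, assign_reads_to_alleles,
                     bh_fdr, filter_ased_observations, fit_ased_model,
                     phi_confidence_interval, simulate_ased_counts)
from editvar.ased import ased_scan


def obs(e1, u1, e2, u2, rid="r"):
    return AsedObservation(rid, e1, u1, e2, u2)


class TestFilters:
    def test_zero_allele_coverage_dropped(self):
        kept = filter_ased_observations(
            [obs(5, 5, 0, 0)] + [obs(5, 5, 4, 6, f"k{i}") for i in range(3)])
        assert len(kept) == 3

    def test_pooled_phi_below_one_percent_dropped(self):
        low = obs(1, 99, 0, 100)       # pooled Phi = 0.005
        kept = filter_ased_observations(
            [low] + [obs(5, 45, 5, 45, f"k{i}") for i in range(3)])
        assert low not in kept

    def test_pooled_phi_boundary_inclusive(self):
        edge = obs(1, 99, 1, 99)       # pooled Phi = 0.01 exactly
        kept = filter_ased_observations(
            [edge] + [obs(5, 45, 5, 45, f"k{i}") for i in range(2)])
        assert edge in kept

    def test_fewer_than_three_replicates_not_analyzable(self):
        assert filter_ased_observations([obs(5, 5, 4, 6, "a"),
                                         obs(5, 5, 4, 6, "b")]) is None


class TestFit:
    def test_symmetric_counts_give_null_fit(self):
        sym = [obs(6, 44, 6, 44, f"k{i}") for i in range(5)]
        fit = fit_ased_model(sym, compute_ci=False)
        assert abs(fit.delta_hat) < 1e-3
        assert fit.lrt_stat < 1e-4
        assert fit.p_value > 0.99

    def test_label_swap_antisymmetry(self):
        for s in (1, 2, 3):
            cfg = SimConfig(delta=1.5, alpha0=-2.0, coverage_mean=60, seed=s)
            o = simulate_ased_counts(cfg, 8)
            f1 = fit_ased_model(o, compute_ci=False)
            f2 = fit_ased_model([x.swapped() for x in o], compute_ci=False)
            assert f1.delta_hat == pytest.approx(-f2.delta_hat, abs=2e-3)
            assert f1.p_value == pytest.approx(f2.p_value, rel=1e-2, abs=1e-8)

    def test_recovers_planted_delta(self):
        est, hits = [], 0
        for s in range(30):
            cfg = SimConfig(delta=2.0, alpha0=-3.0, coverage_mean=50, seed=900 + s)
            fit = fit_ased_model(simulate_ased_counts(cfg, 10), compute_ci=False)
            est.append(fit.delta_hat)
            hits += fit.p_value < 0.05
        assert abs(np.median(est) - 2.0) < 0.2
        assert hits >= 27              # the vast majority detected

    def test_reports_mean_allelic_phi_and_cis(self):
        o = [obs(10, 40, 25, 25, f"k{i}") for i in range(4)]
        fit = fit_ased_model(o)
        assert fit.phi_allele1_mean == pytest.approx(0.2)
        assert fit.phi_allele2_mean == pytest.approx(0.5)
        assert len(fit.ci_allele1) == 4
        lo, hi = fit.ci_allele1[0]
        assert lo < 0.2 < hi

    def test_too_few_replicates(self):
        with pytest.raises(UntestableError):
            fit_ased_model([obs(1, 1, 1, 1)] * 2)


class TestPhiConfidenceInterval:
    def test_boundary_mles(self):
        lo, hi = phi_confidence_interval(0, 10)
        assert lo == 0.0 and 0 < hi < 1
        lo, hi = phi_confidence_interval(10, 10)
        assert hi == 1.0 and 0 < lo < 1

    def test_symmetric_about_half(self):
        lo, hi = phi_confidence_interval(5, 10)
        assert lo < 0.5 < hi
        assert lo == pytest.approx(1 - hi, abs=1e-9)

    def test_matches_grid_scan(self):
        # oracle: 1e-4-resolution scan of the likelihood-ratio condition
        for y, n in [(2, 20), (7, 30), (1, 100), (45, 50)]:
            grid = np.linspace(1e-7, 1 - 1e-7, 2_000_001)
            ll = y * np.log(grid) + (n - y) * np.log1p(-grid)
            phat = y / n
            llhat = y * np.log(phat) + (n - y) * np.log1p(-phat)
            inside = grid[2 * (llhat - ll) <= chi2.ppf(0.95, 1)]
            lo, hi = phi_confidence_interval(y, n)
            assert lo == pytest.approx(inside[0], abs=1e-4)
            assert hi == pytest.approx(inside[-1], abs=1e-4)

    def test_zero_total_undefined(self):
        with pytest.raises(DataError):
            phi_confidence_interval(0, 0)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(5)
        n, p = 30, 0.3
        draws = rng.binomial(n, p, 600)
        cover = np.mean([(lambda c: c[0] <= p <= c[1])(
            phi_confidence_interval(int(y), n)) for y in draws])
        assert 0.90 <= cover <= 0.99


class TestBhFdr:
    def test_extremes(self):
        assert bh_fdr([1e-9] * 6).all()
        assert not bh_fdr([1.0] * 6).any()

    def test_hand_computed_step_up(self):
        # sorted p vs q*i/m: 0.001<=0.025, 0.02<=0.05, 0.04<=0.075, 0.9>0.1
        flags = bh_fdr([0.001, 0.02, 0.04, 0.9], q=0.10)
        assert flags.tolist() == [True, True, True, False]


class TestReadAssignment:
    def _bam(self, bam_builder):
        # editing site chr1:1001 (+), het SNP chr1:991 C/T; reads are 30-mers
        # starting at pos0=980: SNP at read offset 10, site at offset 20
        def read(snp_base, site_base):
            return "A" * 10 + snp_base + "A" * 9 + site_base + "A" * 9

        reads = []
        tally = {("C", "G"): 3, ("C", "A"): 2, ("T", "G"): 1, ("T", "A"): 4}
        k = 0
        for (sb, eb), cnt in tally.items():
            for _ in range(cnt):
                reads.append((f"r{k}", 980, read(sb, eb)))
                k += 1
        reads.append(("other", 980, read("G", "G")))   # neither allele
        reads.append(("short", 980, "A" * 10 + "C"))   # covers SNP only
        return bam_builder(reads, name="ased.bam"), tally

    def test_counts_equal_hand_tally(self, bam_builder):
        bam, tally = self._bam(bam_builder)
        site = EditingSite("chr1", 1001, "+")
        asg = HetSnpAssignment("chr1", 991, "C", "T", site=site)
        with pysam.AlignmentFile(bam) as af:
            o = assign_reads_to_alleles(af, asg)
        assert (o.edited_allele1, o.unedited_allele1) == (3, 2)
        assert (o.edited_allele2, o.unedited_allele2) == (1, 4)

    def test_conflicting_het_snps_discard_read(self, bam_builder):
        # second het SNP at offset 15 (chr1:996); one read has a haplotype-
        # inconsistent combination and must be dropped
        def read(b1, b2, eb):
            return "A" * 10 + b1 + "A" * 4 + b2 + "A" * 4 + eb + "A" * 9

        reads = [("ok1", 980, read("C", "G", "G")),
                 ("ok2", 980, read("T", "A", "G")),
                 ("conflict", 980, read("C", "A", "G"))]
        bam = bam_builder(reads, name="conflict.bam")
        site = EditingSite("chr1", 1001, "+")
        asg = HetSnpAssignment("chr1", 991, "C", "T", site=site)
        other = HetSnpAssignment("chr1", 996, "G", "A", site=site)
        with pysam.AlignmentFile(bam) as af:
            o = assign_reads_to_alleles(af, asg, other_het_snps=[other])
        assert (o.edited_allele1, o.edited_allele2) == (1, 1)

    def test_homozygous_assignment_rejected(self):
        with pytest.raises(DataError):
            HetSnpAssignment("chr1", 10, "C", "C")

    def test_ag_snp_flagged(self):
        assert HetSnpAssignment("chr1", 10, "A", "G").is_ag_snp
        assert HetSnpAssignment("chr1", 10, "T", "C").is_ag_snp
        assert not HetSnpAssignment("chr1", 10, "C", "G").is_ag_snp


def test_ased_scan_flags_planted_shift():
    rng = np.random.default_rng(77)
    data = {}
    for i in range(12):
        delta = 2.0 if i < 3 else 0.0
        cfg = SimConfig(delta=delta, alpha0=-2.5, coverage_mean=50, seed=0)
        data[f"site{i}"] = simulate_ased_counts(cfg, 10, rng=rng)
    res = ased_scan(data, q=0.10)
    called = set(res.loc[res.significant, "key"])
    assert {"site0", "site1", "site2"} <= called
    assert res.loc[res.status == "ok", "p_value"].notna().all()


def test_ased_scan_reports_unanalyzable():
    data = {"thin": [obs(3, 3, 2, 4, "a"), obs(3, 3, 2, 4, "b")],
            "good": [obs(5, 45, 20, 30, f"k{i}") for i in range(5)]}
    res = ased_scan(data)
    assert res.set_index("key").loc["thin", "status"] == "filtered"
    assert res.set_index("key").loc["good", "status"] == "ok"
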
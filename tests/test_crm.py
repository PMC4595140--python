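"""CRM validation: expected ratios, chi-square forms, the Near HGT driver."""
import math

import numpy as np
import pytest

from nearhgt.crm import (
    chi_square_pvalue,
    chi_square_stat,
    chi_square_two_cell,
    crm_from_distances,
    crm_single_test,
    expected_distance,
    expected_ratio,
    near_hgt,
)
from nearhgt.distances import OrthologAlignment, gene_distance, jc_to_hamming
from nearhgt.errors import CRMTestSkipped
from nearhgt.synteny import Genome


class TestExpectedRatio:
    def test_worked_example_value(self):
        assert expected_ratio(0.583, 0.541) == pytest.approx(1.077, abs=1e-3)

    def test_equal_distances_give_unity(self):
        assert expected_ratio(0.3, 0.3) == 1.0

    def test_scale_invariance(self):
        assert expected_ratio(0.583, 0.541) == pytest.approx(
            expected_ratio(5.83, 5.41)
        )

    def test_uninformative_witness_skipped(self):
        with pytest.raises(CRMTestSkipped):
            expected_ratio(0.5, 0.0)
        with pytest.raises(CRMTestSkipped):
            expected_ratio(math.inf, 0.5)


class TestExpectedDistance:
    def test_worked_example_value(self):
        assert expected_distance(1.077, 0.0237) == pytest.approx(0.0255, abs=5e-5)

    def test_unit_ratio_is_identity(self):
        assert expected_distance(1.0, 0.042) == 0.042

    def test_zero_witness_distance(self):
        assert expected_distance(1.3, 0.0) == 0.0


class TestChiSquare:
    def test_worked_example_statistic(self):
        # the printed hamming conversions feed the printed statistic
        assert chi_square_stat(1472, 0.00795, 0.02507) == pytest.approx(
            17.65, abs=0.01
        )

    def test_zero_when_observed_equals_expected(self):
        assert chi_square_stat(100, 0.2, 0.2) == 0.0

    def test_two_cell_oracle(self):
        # sum the two (O-E)^2/E cells explicitly
        l, o, e = 100, 0.10, 0.20
        cells = (l * o - l * e) ** 2 / (l * e) + (
            (l * (1 - o) - l * (1 - e)) ** 2 / (l * (1 - e))
        )
        assert chi_square_stat(l, o, e) == pytest.approx(cells, rel=1e-12)

    def test_closed_form_equals_two_cell_form_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            l = int(rng.integers(1, 10000))
            h_exp = rng.uniform(0.01, 0.99)
            h_obs = rng.uniform(0.0, 0.99)
            a = chi_square_stat(l, h_obs, h_exp)
            b = chi_square_two_cell(l, h_obs, h_exp)
            assert abs(a - b) <= 1e-9 * max(a, 1e-30)

    def test_invariant_under_complementing_both_fractions(self):
        assert chi_square_stat(321, 0.1, 0.3) == pytest.approx(
            chi_square_stat(321, 0.9, 0.7)
        )

    def test_degenerate_expectation_rejected(self):
        with pytest.raises(ValueError):
            chi_square_stat(100, 0.1, 0.0)

    def test_pvalue_against_normal_tail_oracle(self):
        # upper tail of chi2(1) equals erfc(sqrt(x/2)) = 2(1 - Phi(sqrt(x)))
        for stat in (0.5, 3.841, 17.65):
            assert chi_square_pvalue(stat) == pytest.approx(
                math.erfc(math.sqrt(stat / 2)), rel=1e-9
            )
        assert chi_square_pvalue(0.0) == 1.0
        assert chi_square_pvalue(3.841) == pytest.approx(0.05, abs=1e-3)
        assert chi_square_pvalue(17.65) == pytest.approx(2.7e-5, rel=0.05)


class TestCRMFromDistances:
    def test_worked_example_end_to_end(self):
        rec = crm_from_distances(0.0080, 0.0237, 0.583, 0.541, 1472)
        assert rec.rho == pytest.approx(1.077, abs=1e-3)
        assert rec.d_exp == pytest.approx(0.0255, abs=5e-5)
        assert rec.h_obs == pytest.approx(0.00795, abs=1e-5)
        assert rec.h_exp == pytest.approx(0.02507, abs=5e-5)
        assert rec.chi2 == pytest.approx(17.65, abs=0.08)
        assert rec.p <= 0.01
        assert rec.direction == "shorter"

    def test_composition_matches_hand_assembled_pipeline(self):
        d_h_s, d_w_s, d_h_r, d_w_r, l = 0.05, 0.03, 0.4, 0.5, 500
        rec = crm_from_distances(d_h_s, d_w_s, d_h_r, d_w_r, l)
        rho = expected_ratio(d_h_r, d_w_r)
        d_exp = expected_distance(rho, d_w_s)
        stat = chi_square_stat(l, jc_to_hamming(d_h_s), jc_to_hamming(d_exp))
        assert rec.chi2 == pytest.approx(stat, rel=1e-12)
        assert rec.p == pytest.approx(chi_square_pvalue(stat), rel=1e-12)
        assert rec.direction == "longer"

    def test_observed_equal_to_expected_is_null(self):
        rec = crm_from_distances(0.03, 0.03, 0.5, 0.5, 1000)
        assert rec.chi2 == 0.0 and rec.p == 1.0

    def test_jc_scale_uses_uncorrected_distances(self):
        rec = crm_from_distances(0.05, 0.03, 0.4, 0.5, 500, scale="jc")
        d_exp = 0.4 / 0.5 * 0.03
        assert rec.chi2 == pytest.approx(
            500 * (0.05 - d_exp) ** 2 / (d_exp * (1 - d_exp))
        )

    def test_saturated_expectation_skipped(self):
        with pytest.raises(CRMTestSkipped):
            crm_from_distances(0.01, 0.5, 30.0, 0.5, 100)

    def test_bonferroni_correction_monotone(self):
        rec = crm_from_distances(0.0080, 0.0237, 0.583, 0.541, 1472)
        assert rec.corrected(1).p_corrected == rec.p
        assert rec.corrected(10).p_corrected == pytest.approx(10 * rec.p)
        assert rec.corrected(10**9).p_corrected == 1.0
        assert rec.corrected(5).p_corrected >= rec.p


class TestCRMSingleTest:
    def make_alignments(self, rng, length=300):
        seqs = {}
        orgs = ["s1", "s2", "r1", "r2"]
        base = rng.choice(list("ACGT"), size=length)
        for o in orgs:
            mut = base.copy()
            n_mut = {"s1": 2, "s2": 4, "r1": 60, "r2": 0}[o]
            pos = rng.choice(length, size=n_mut, replace=False)
            for p in pos:
                mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
            seqs[o] = "".join(mut)
        return OrthologAlignment("gh", seqs), OrthologAlignment("gw", dict(seqs))

    def test_matches_distance_level_composition(self):
        rng = np.random.default_rng(3)
        g_h, g_w = self.make_alignments(rng)
        rec = crm_single_test(g_h, g_w, "s1", "s2", "r1", "r2")
        expect = crm_from_distances(
            gene_distance(g_h, "s1", "s2").jc,
            gene_distance(g_w, "s1", "s2").jc,
            gene_distance(g_h, "r1", "r2").jc,
            gene_distance(g_w, "r1", "r2").jc,
            g_h.length,
        )
        assert rec.chi2 == pytest.approx(expect.chi2)
        assert rec.gene == "gh" and rec.witness == "gw"

    def test_missing_organism_reported_as_skip(self):
        aln = OrthologAlignment("g", {"s1": "ACGT", "s2": "ACGT"})
        with pytest.raises(CRMTestSkipped, match="missing organisms"):
            crm_single_test(aln, aln, "s1", "s2", "r1", "r2")


class TestNearHGTDriver:
    def test_identical_genomes_yield_empty_report(self):
        genes = tuple(f"g{i}" for i in range(30))
        g1, g2 = Genome("A", genes), Genome("B", genes)
        report = near_hgt([g1, g2], ["R1", "R2"], {}, k=5)
        assert report.summaries == [] and report.putative_genes == set()

    def test_eight_strains_enumerate_28_pairs(self):
        genes = tuple(f"g{i}" for i in range(30))
        strains = [Genome(f"S{i}", genes) for i in range(8)]
        report = near_hgt(strains, ["R1", "R2"], {}, k=5)
        assert len(report.profiles) == 28

    def test_implanted_transfer_recovered(self, transfer_fixture):
        fx = transfer_fixture
        report = near_hgt(fx.strains, fx.references, fx.alignments, k=10)
        truth = fx.transfers[0]
        assert report.putative_genes == {truth.gene}
        involved = [
            s for s in report.summaries if s.gene == truth.gene and s.putative_hgt
        ]
        assert any(
            set(s.strain_pair) == {truth.donor, truth.recipient} for s in involved
        )
        for s in involved:
            assert s.recipient == truth.recipient
            assert s.best_p_corrected <= 0.01

    def test_null_fixture_reports_nothing(self, null_fixture):
        fx = null_fixture
        report = near_hgt(fx.strains, fx.references, fx.alignments, k=10)
        assert report.putative_genes == set()

    def test_transferred_pair_direction_is_shorter(self, transfer_fixture):
        fx = transfer_fixture
        report = near_hgt(fx.strains, fx.references, fx.alignments, k=10)
        truth = fx.transfers[0]
        pair_summary = [
            s
            for s in report.summaries
            if set(s.strain_pair) == {truth.donor, truth.recipient}
            and s.gene == truth.gene
        ]
        assert pair_summary and pair_summary[0].direction == "shorter"
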
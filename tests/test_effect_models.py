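"""2x2 construction, Woolf log odds ratios and the HWE chi-square."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpmeta as sm
from snpmeta.effect_models import ContingencyTable
from snpmeta.study_io import Design, StudyRecord


def _record(gc, gn, n1=None, n0=None):
    return StudyRecord(
        study_id="s", year=2000, ethnicity="X", design=Design.POPULATION,
        n_cases=n1 if n1 is not None else sum(gc),
        n_controls=n0 if n0 is not None else sum(gn),
        genotype_counts_cases=gc, genotype_counts_controls=gn,
    )


class TestAlleleTable:
    def test_reconstruction_from_reported_frequencies(self):
        # 191 cases / 114 controls at frequencies 0.49 / 0.37
        t = sm.allele_table_from_maf(191, 114, 0.49, 0.37)
        assert (t.a, t.b, t.c, t.d) == (187, 195, 84, 144)
        assert not t.correction_applied

    def test_symmetric_input_gives_unit_odds_ratio(self):
        t = sm.allele_table_from_maf(100, 100, 0.5, 0.5)
        assert (t.a, t.b, t.c, t.d) == (100, 100, 100, 100)
        assert sm.log_odds_ratio(t).log_or == 0.0

    def test_zero_cell_triggers_correction_in_all_cells(self):
        t = sm.allele_table_from_maf(10, 10, 0.0, 0.1)
        assert t.correction_applied
        assert (t.a, t.b, t.c, t.d) == (0.5, 20.5, 2.5, 18.5)

    def test_arm_totals_conserved(self):
        for maf in (0.05, 0.37, 0.4999, 0.73):
            t = sm.allele_table_from_maf(123, 457, maf, maf)
            assert not t.correction_applied
            assert t.a + t.b == 2 * 123 and t.c + t.d == 2 * 457

    def test_zero_arm_rejected(self):
        with pytest.raises(ValueError):
            sm.allele_table_from_maf(0, 10, 0.3, 0.3)


class TestGenotypeTable:
    CASES = (30, 50, 20)
    CONTROLS = (40, 45, 15)

    @pytest.mark.parametrize("model,cells", [
        ("dominant", (70, 30, 60, 40)),
        ("recessive", (20, 80, 15, 85)),
        ("heterozygous", (50, 30, 45, 40)),
        ("homozygous", (20, 30, 15, 40)),
        ("allele", (90, 110, 75, 125)),
    ])
    def test_model_contrasts(self, model, cells):
        t = sm.genotype_table(_record(self.CASES, self.CONTROLS), model)
        assert (t.a, t.b, t.c, t.d) == cells

    def test_absent_counts_name_the_study(self):
        rec = StudyRecord("Hani", 1998, "X", Design.POPULATION, 10, 10, 0.3, 0.3)
        with pytest.raises(ValueError, match="Hani"):
            sm.genotype_table(rec, "dominant")

    def test_genotype_vs_maf_reconstruction_agree(self):
        """Allele table from genotype counts matches the table rebuilt from
        the genotype-implied frequency, up to rounding (log OR within 0.02)."""
        rec = _record(self.CASES, self.CONTROLS)
        direct = sm.log_odds_ratio(sm.genotype_table(rec, "allele"))
        maf1 = (50 + 2 * 20) / 200
        maf0 = (45 + 2 * 15) / 200
        rebuilt = sm.log_odds_ratio(sm.allele_table_from_maf(100, 100, maf1, maf0))
        assert abs(direct.log_or - rebuilt.log_or) <= 0.02


class TestLogOddsRatio:
    def test_woolf_arithmetic(self):
        est = sm.log_odds_ratio(ContingencyTable(187, 195, 84, 144))
        assert est.log_or == pytest.approx(math.log((187 * 144) / (195 * 84)))
        assert est.odds_ratio == pytest.approx(1.644, abs=5e-4)
        assert est.variance == pytest.approx(1/187 + 1/195 + 1/84 + 1/144)
        assert est.variance == pytest.approx(0.0293, abs=5e-5)

    def test_balanced_table(self):
        est = sm.log_odds_ratio(ContingencyTable(100, 100, 100, 100))
        assert est.log_or == 0.0 and est.variance == pytest.approx(0.04)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_case_control_transposition_negates(self, cells):
        a, b, c, d = cells
        est = sm.log_odds_ratio(ContingencyTable(a, b, c, d))
        flipped = sm.log_odds_ratio(ContingencyTable(c, d, a, b))
        assert flipped.log_or == pytest.approx(-est.log_or)
        assert flipped.variance == pytest.approx(est.variance)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_doubling_all_cells_preserves_odds_ratio(self, cells):
        a, b, c, d = cells
        est = sm.log_odds_ratio(ContingencyTable(a, b, c, d))
        doubled = sm.log_odds_ratio(ContingencyTable(2*a, 2*b, 2*c, 2*d))
        assert doubled.log_or == pytest.approx(est.log_or)


class TestHwe:
    @pytest.mark.parametrize("triple,chi2,p", [
        ((25, 50, 25), 0.0, 1.0),          # exact equilibrium
        ((0, 0, 50), 0.0, 1.0),            # monomorphic, fits trivially
        ((50, 0, 0), 0.0, 1.0),
    ])
    def test_degenerate_cases(self, triple, chi2, p):
        got = sm.hwe_chi2(triple)
        assert got == (chi2, p)

    def test_heterozygote_deficit(self):
        # allele freq 0.5 -> expected (25, 50, 25); chi2 = 25/25+100/50+25/25
        chi2, p = sm.hwe_chi2((30, 40, 30))
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_matches_expected_count_oracle_exhaustively(self):
        """Agrees with an independently coded expected-count computation on
        every genotype triple with total <= 30."""
        from scipy.stats import chi2 as chi2_dist

        def oracle(ee, ek, kk):
            n = ee + ek + kk
            k_alleles = ek + 2 * kk
            if k_alleles == 0 or k_alleles == 2 * n:
                return 0.0, 1.0
            p = k_alleles / (2 * n)
            exp = [n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p * p]
            stat = sum((o - e) ** 2 / e for o, e in zip((ee, ek, kk), exp))
            return stat, float(chi2_dist.sf(stat, 1))

        for total in range(1, 31):
            for ee in range(total + 1):
                for ek in range(total - ee + 1):
                    kk = total - ee - ek
                    got = sm.hwe_chi2((ee, ek, kk))
                    want = oracle(ee, ek, kk)
                    assert got[0] == pytest.approx(want[0], abs=1e-12)
                    assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sm.hwe_chi2((0, 0, 0))


def test_fixture_allele_estimates_cover_case_control_rows(table1, allele_ests):
    assert len(allele_ests) == 47
    assert all(e.model == "allele" for e in allele_ests)
    # the family-only row contributes no case-control estimate
    assert "Altshuler" not in {e.study_id for e in allele_ests}
    assert "Gloyn 2003" in {e.study_id for e in allele_ests}
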
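"""Isotope-pattern and MIDA kernel tests against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midaflux import constants, mida
from midaflux.errors import DegenerateEnrichmentError, ValidationError

from .conftest import random_composition
from .oracles import (
    brute_convolve,
    brute_label_pattern_enumerate,
    brute_natural_pattern,
    normalize,
)

PALMITATE = mida.ElementalComposition(C=16, H=32, O=2)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("G", mida.ElementalComposition(C=2, H=5, N=1, O=2)),
            ("GG", mida.ElementalComposition(C=4, H=8, N=2, O=3)),
        ],
    )
    def test_unmodified(self, seq, expected):
        assert mida.composition_from_peptide(seq, fixed_mods={}) == expected

    def test_carbamidomethyl_cysteine(self):
        # C + A + K free amino acids minus 2 waters plus C2H3NO, summed by hand
        expected = mida.ElementalComposition(C=14, H=27, N=5, O=5, S=1)
        assert mida.composition_from_peptide("CAK") == expected

    @pytest.mark.parametrize("seq", ["PEPTIDEK", "ACDEFGHIKLMNPQRSTVWY", "MK"])
    def test_against_pyteomics(self, seq):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        ours = mida.composition_from_peptide(seq, fixed_mods={})
        ref = pyteomics_mass.Composition(sequence=seq)
        for elem in constants.ELEMENTS:
            assert getattr(ours, elem) == ref.get(elem, 0)

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            mida.composition_from_peptide("GGXG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            mida.composition_from_peptide("")


class TestSiteCount:
    def test_additivity(self):
        table = {"A": 4.0, "G": 2.06}
        assert mida.label_site_count("A", table) == 4.0
        assert mida.label_site_count("AA", table) == 8.0
        assert mida.label_site_count("AG", table) == pytest.approx(6.06)

    def test_missing_residue_named(self):
        with pytest.raises(ValidationError, match="'W'"):
            mida.label_site_count("AW", {"A": 4.0})

    def test_default_table_covers_all_residues(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert mida.label_site_count(seq) > 0


class TestNaturalDistribution:
    def test_single_carbon(self):
        d = mida.natural_isotope_distribution(mida.ElementalComposition(C=1), 4)
        assert d[0] == pytest.approx(0.9893, abs=1e-4)
        assert d[1] == pytest.approx(0.0107, abs=1e-4)

    def test_single_hydrogen(self):
        d = mida.natural_isotope_distribution(mida.ElementalComposition(H=1), 4)
        assert d[1] == pytest.approx(0.000115, abs=1e-5)

    def test_rejects_single_channel(self):
        with pytest.raises(ValidationError):
            mida.natural_isotope_distribution(PALMITATE, 1)

    @pytest.mark.parametrize("channels", [4, 6])
    def test_matches_bruteforce_oracle(self, rng, channels):
        for _ in range(20):
            comp = random_composition(rng)
            ours = mida.natural_isotope_distribution(comp, channels).abundances
            ref = normalize(brute_natural_pattern(comp, channels))
            assert np.max(np.abs(ours - ref)) <= 1e-10

    def test_distribution_invariants(self, rng):
        for _ in range(20):
            comp = random_composition(rng)
            d = mida.natural_isotope_distribution(comp, 4)
            assert abs(d.abundances.sum() - 1) <= 1e-9
            assert np.all(d.abundances >= 0)


class TestEnrichedDistribution:
    def test_p_zero_equals_natural(self):
        lp = mida.LabelParameters(p=0.0, n=10)
        nat = mida.natural_isotope_distribution(PALMITATE, 4)
        enr = mida.enriched_distribution(PALMITATE, lp, 4)
        assert np.allclose(nat.abundances, enr.abundances, atol=0)

    def test_isotope_free_binomial(self, monkeypatch):
        """With an idealized mono-isotopic element table, the enriched MID is
        exactly Binomial(n, p)."""
        ideal = {e: np.array([1.0]) for e in constants.ELEMENTS}
        monkeypatch.setattr(constants, "isotope_abundances", lambda path=None: ideal)
        lp = mida.LabelParameters(p=0.05, n=1)
        d = mida.enriched_distribution(PALMITATE, lp, 4)
        assert d[0] == pytest.approx(0.95, abs=1e-12)
        assert d[1] == pytest.approx(0.05, abs=1e-12)

    def test_matches_site_enumeration_oracle(self, rng):
        """Convolution route equals exhaustive enumeration over all 2^10
        site-labeling outcomes convolved with the natural pattern."""
        comp = mida.composition_from_peptide("ALANINEK", fixed_mods={})
        lp = mida.LabelParameters(p=0.05, n=10)
        ours = mida.enriched_distribution(comp, lp, 4).abundances
        nat = brute_natural_pattern(comp, 4)
        lab = brute_label_pattern_enumerate(10, 0.05, 4)
        ref = normalize(brute_convolve(nat, lab, 4))
        assert np.max(np.abs(ours - np.array(ref))) <= 1e-10

    def test_noninteger_n_interpolates(self):
        comp = PALMITATE
        p = 0.05
        lo = mida.enriched_distribution(comp, mida.LabelParameters(p=p, n=4), 3)
        hi = mida.enriched_distribution(comp, mida.LabelParameters(p=p, n=5), 3)
        mid = mida.enriched_distribution(comp, mida.LabelParameters(p=p, n=4.25), 3)
        expected = 0.75 * lo.abundances + 0.25 * hi.abundances
        assert np.allclose(mid.abundances, expected, atol=1e-12)

    @given(
        p=st.floats(0.01, 0.15),
        n=st.integers(1, 30),
    )
    @settings(max_examples=30)
    def test_m0_depletion_monotone_in_p_and_n(self, p, n):
        lp = mida.LabelParameters(p=p, n=n)
        em = mida.theoretical_max_em(PALMITATE, lp, 0)
        em_more_p = mida.theoretical_max_em(
            PALMITATE, mida.LabelParameters(p=min(p + 0.01, 0.2), n=n), 0
        )
        em_more_n = mida.theoretical_max_em(PALMITATE, mida.LabelParameters(p=p, n=n + 1), 0)
        assert em < 0
        assert abs(em_more_p) > abs(em)
        assert abs(em_more_n) > abs(em)


class TestExcessAndFraction:
    def test_excess_identity_and_subtraction(self):
        nat = mida.natural_isotope_distribution(PALMITATE, 3)
        assert mida.excess_enrichment(nat, nat, 0) == 0.0
        a = mida.MassIsotopomerDistribution(np.array([0.60, 0.30, 0.10]))
        b = mida.MassIsotopomerDistribution(np.array([0.65, 0.25, 0.10]))
        assert mida.excess_enrichment(a, b, 0) == pytest.approx(-0.05)

    def test_channel_out_of_range(self):
        nat = mida.natural_isotope_distribution(PALMITATE, 3)
        with pytest.raises(ValidationError):
            mida.excess_enrichment(nat, nat, 5)

    def test_emmax_consistency_with_enriched(self):
        lp = mida.LabelParameters(p=0.05, n=22)
        nat = mida.natural_isotope_distribution(PALMITATE, 3)
        enr = mida.enriched_distribution(PALMITATE, lp, 3)
        em = mida.excess_enrichment(enr, nat, 0)
        assert em == pytest.approx(
            mida.theoretical_max_em(PALMITATE, lp, 0, channels=3), abs=1e-12
        )

    def test_emmax_palmitate_matches_sitewise_oracle(self):
        from .oracles import brute_label_pattern_sitewise

        lp = mida.LabelParameters(p=0.05, n=22)
        channels = 3
        nat_raw = brute_natural_pattern(PALMITATE, channels)
        lab = brute_label_pattern_sitewise(22, 0.05, channels)
        enr = normalize(brute_convolve(nat_raw, lab, channels))
        ref = enr[0] - normalize(nat_raw)[0]
        assert mida.theoretical_max_em(PALMITATE, lp, 0, channels=3) == pytest.approx(
            ref, abs=1e-10
        )

    def test_emmax_degenerate_at_p_zero(self):
        assert mida.theoretical_max_em(PALMITATE, mida.LabelParameters(p=0, n=22), 0) == 0.0
        with pytest.raises(DegenerateEnrichmentError):
            mida.fractional_synthesis(0.01, 0.0)

    @given(alpha=st.floats(0.0, 1.0))
    @settings(max_examples=30)
    def test_mixture_linearity(self, alpha):
        lp = mida.LabelParameters(p=0.05, n=22)
        nat = mida.natural_isotope_distribution(PALMITATE, 3)
        enr = mida.enriched_distribution(PALMITATE, lp, 3)
        measured = nat.mix(enr, alpha)
        em = mida.excess_enrichment(measured, nat, 0)
        est = mida.fractional_synthesis(
            em, mida.theoretical_max_em(PALMITATE, lp, 0, channels=3)
        )
        assert est.f == pytest.approx(alpha, abs=1e-9)

    @pytest.mark.parametrize(
        "raw,f,flag",
        [
            (0.0, 0.0, "ok"),
            (1.0, 1.0, "ok"),
            (-0.01, 0.0, "clamped_low"),
            (1.03, 1.0, "clamped_high"),
            (-0.5, math.nan, "failed"),
            (1.2, math.nan, "failed"),
        ],
    )
    def test_clamping_rules(self, raw, f, flag):
        est = mida.fractional_synthesis(raw * -0.2, -0.2)
        assert est.flag == flag
        if math.isnan(f):
            assert math.isnan(est.f)
        else:
            assert est.f == pytest.approx(f)


class TestKinetics:
    def test_examples(self):
        assert mida.rate_constant(0.0, 5.0) == 0.0
        assert mida.rate_constant(0.5, 1.0) == pytest.approx(math.log(2))
        assert mida.rate_constant(1 - math.exp(-0.3 * 2), 2.0) == pytest.approx(0.3)

    @given(k=st.floats(1e-3, 5.0), t=st.floats(0.25, 3.0))
    @settings(max_examples=50)
    def test_roundtrip(self, k, t):
        f = 1 - math.exp(-k * t)
        assert mida.rate_constant(f, t) == pytest.approx(k, rel=1e-9)

    def test_rejections(self):
        with pytest.raises(ValidationError):
            mida.rate_constant(1.0, 1.0)
        with pytest.raises(ValidationError):
            mida.rate_constant(0.5, 0.0)

    def test_kinetics_result_consistency(self):
        r = mida.KineticsResult.from_k(0.7, 2.0)
        assert r.f == pytest.approx(1 - math.exp(-1.4))
        with pytest.raises(ValidationError):
            mida.KineticsResult(f=0.5, k=0.1, t=1.0)
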
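"""Peptide-to-protein FSR pipeline: recovery, filtering, statistics."""

import numpy as np
import pandas as pd
import pytest

from midaflux import mida, proteome, simulate
from midaflux.errors import ValidationError


def _forward_measurement(seq: str, f: float, p: float) -> proteome.PeptideMeasurement:
    comp = mida.composition_from_peptide(seq)
    n = mida.label_site_count(seq)
    base = mida.natural_isotope_distribution(comp, 4)
    enr = mida.enriched_distribution(comp, mida.LabelParameters(p=p, n=n), 4)
    return proteome.PeptideMeasurement(
        sequence=seq, accession="P1", sample="s1", group="g", time_h=24.0,
        abundances=base.mix(enr, f).abundances,
    )


class TestPeptideFSR:
    def test_noiseless_inverse(self):
        m = _forward_measurement("GASPVTLCK", f=0.4, p=0.05)
        est = proteome.peptide_fsr(m, p=0.05)
        assert est.f == pytest.approx(0.4, abs=1e-9)

    def test_natural_pattern_gives_zero(self):
        m = _forward_measurement("GASPVTLCK", f=0.0, p=0.05)
        assert proteome.peptide_fsr(m, p=0.05).f == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_p_rejected(self):
        m = _forward_measurement("GASPVTLCK", f=0.4, p=0.05)
        with pytest.raises(ValidationError):
            proteome.peptide_fsr(m, p=0.0)

    def test_quality_gate_on_abundance_sum(self):
        with pytest.raises(ValidationError, match="quality gate"):
            proteome.PeptideMeasurement(
                sequence="GK", accession="P1", sample="s", group="g",
                time_h=24.0, abundances=np.array([0.3, 0.1, 0.05, 0.05]),
            )

    def test_noisy_recovery_500_peptides(self):
        """Median |f̂ - f| < 0.03 at instrument-level noise (SD 0.003)."""
        spec = simulate.ProteomeSpec(
            n_proteins=30, animals_per_group=3, time_points_h=(24.0,),
            noise=simulate.NoiseModel(sd=0.003),
        )
        peps, truth = simulate.simulate_proteome(spec, seed=42)
        assert len(peps) >= 500
        out = proteome.peptide_fsr_table(peps, 0.05)
        merged = out.merge(
            truth[["accession", "group", "time_h", "f"]],
            on=["accession", "group", "time_h"], suffixes=("_est", "_true"),
        )
        err = (merged["f_est"] - merged["f_true"]).abs()
        assert err.median() < 0.03


class TestAggregateProtein:
    def _pep_table(self, rows):
        return pd.DataFrame(
            rows, columns=["accession", "sample", "group", "time_h", "f",
                           "quality_flag", "sequence"]
        )

    def test_mean_and_filter(self):
        t = self._pep_table(
            [("A", "s1", "g", 24.0, f, "ok", f"SEQ{i}") for i, f in
             enumerate([0.2, 0.3, 0.4])]
            + [("B", "s1", "g", 24.0, 0.5, "ok", "SEQX")]
        )
        out = proteome.aggregate_protein(t)
        assert list(out["accession"]) == ["A"]  # B has 1 peptide -> excluded
        assert out["f"].iloc[0] == pytest.approx(0.3)
        assert out["n_peptides"].iloc[0] == 3

    def test_failed_peptides_do_not_count(self):
        t = self._pep_table(
            [("A", "s1", "g", 24.0, 0.2, "ok", "S1"),
             ("A", "s1", "g", 24.0, np.nan, "failed", "S2")]
        )
        assert proteome.aggregate_protein(t).empty

    def test_idempotent_under_refilter(self):
        t = self._pep_table(
            [("A", "s1", "g", 24.0, f, "ok", f"S{i}") for i, f in
             enumerate([0.1, 0.2, 0.3, 0.4])]
        )
        once = proteome.aggregate_protein(t)
        refiltered = once[once["n_peptides"] >= 2].reset_index(drop=True)
        pd.testing.assert_frame_equal(once, refiltered)

    def test_k_matches_f_and_time(self):
        t = self._pep_table(
            [("A", "s1", "g", 24.0, 0.5, "ok", "S1"), ("A", "s1", "g", 24.0, 0.5, "ok", "S2")]
        )
        out = proteome.aggregate_protein(t)
        assert out["k"].iloc[0] == pytest.approx(np.log(2))  # f=0.5 in 1 day


class TestGroupCompare:
    def _proteins(self, treated_f, control_f, acc="A", t=24.0):
        rows = [
            {"accession": acc, "sample": f"t{i}", "group": "tm", "time_h": t, "f": f}
            for i, f in enumerate(treated_f)
        ] + [
            {"accession": acc, "sample": f"c{i}", "group": "ctrl", "time_h": t, "f": f}
            for i, f in enumerate(control_f)
        ]
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        res = proteome.group_compare(
            self._proteins([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]), "tm", "ctrl"
        )
        row = res.table.iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["log2_ratio"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_twofold_ratio(self):
        res = proteome.group_compare(
            self._proteins([0.4, 0.4, 0.4], [0.2, 0.2, 0.2]), "tm", "ctrl"
        )
        assert res.table["ratio"].iloc[0] == pytest.approx(2.0)

    def test_one_sided_detection_reported(self):
        df = self._proteins([0.4, 0.4], [0.2, 0.2])
        df = pd.concat(
            [df, pd.DataFrame([{"accession": "B", "sample": "t0", "group": "tm",
                                "time_h": 24.0, "f": 0.5}])]
        )
        res = proteome.group_compare(df, "tm", "ctrl")
        assert res.n_omitted == 1
        assert list(res.one_sided["accession"]) == ["B"]

    def test_null_type1_calibration(self, rng):
        """Welch test false-positive rate ~5% on null protein comparisons."""
        n_prot, n_animals = 400, 5
        rows = []
        for i in range(n_prot):
            for g in ("tm", "ctrl"):
                for a in range(n_animals):
                    rows.append(
                        {"accession": f"P{i}", "sample": f"{g}{a}", "group": g,
                         "time_h": 24.0, "f": 0.3 + rng.normal(0, 0.01)}
                    )
        res = proteome.group_compare(pd.DataFrame(rows), "tm", "ctrl")
        rate = (res.table["p_value"] < 0.05).mean()
        # 3-sigma binomial band around 0.05 at 400 trials
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_prot)


class TestPathwaySummary:
    def _comparisons(self, ratios_p, t=24.0):
        return pd.DataFrame(
            [{"accession": acc, "time_h": t, "log2_ratio": r, "p_value": p}
             for acc, r, p in ratios_p]
        )

    def test_hand_computed_weighted_mean(self):
        comps = self._comparisons(
            [("A", 0.0, 0.01), ("B", 1.0, 0.01)]
            + [(f"X{i}", -1.0, 0.01) for i in range(3)]
        )
        counts = {"A": 1, "B": 3, "X0": 1, "X1": 1, "X2": 1}
        mapping = pd.DataFrame(
            {"accession": ["A", "B", "X0", "X1", "X2"], "pathway": ["pw"] * 5}
        )
        out = proteome.kegg_pathway_summary(comps, counts, mapping, min_proteins=5)
        # weights 1,3,1,1,1 on ratios 0,1,-1,-1,-1 -> (0+3-3)/7 = 0
        assert out["weighted_log2_ratio"].iloc[0] == pytest.approx(0.0)
        # two-protein check from first principles: {0,1} with counts {1,3} -> 0.75
        out2 = proteome.kegg_pathway_summary(
            comps.iloc[:2], counts, mapping.iloc[:2], min_proteins=2
        )
        assert out2["weighted_log2_ratio"].iloc[0] == pytest.approx(0.75)

    def test_min_proteins_filter(self):
        comps = self._comparisons([(f"P{i}", -1.0, 0.01) for i in range(4)])
        mapping = pd.DataFrame(
            {"accession": [f"P{i}" for i in range(4)], "pathway": ["pw"] * 4}
        )
        out = proteome.kegg_pathway_summary(
            comps, {f"P{i}": 1 for i in range(4)}, mapping, min_proteins=5
        )
        assert out.empty

    def test_nonsignificant_excluded(self):
        comps = self._comparisons(
            [(f"P{i}", -1.0, 0.01) for i in range(5)] + [("Q", 5.0, 0.9)]
        )
        mapping = pd.DataFrame(
            {"accession": [f"P{i}" for i in range(5)] + ["Q"], "pathway": ["pw"] * 6}
        )
        out = proteome.kegg_pathway_summary(
            comps, {a: 1 for a in mapping["accession"]}, mapping
        )
        assert out["weighted_log2_ratio"].iloc[0] == pytest.approx(-1.0)
        assert out["n_proteins"].iloc[0] == 5

    def test_invariant_to_duplicates_and_order(self):
        comps = self._comparisons([(f"P{i}", float(i), 0.01) for i in range(6)])
        mapping = pd.DataFrame(
            {"accession": [f"P{i}" for i in range(6)], "pathway": ["pw"] * 6}
        )
        counts = {f"P{i}": i + 1 for i in range(6)}
        a = proteome.kegg_pathway_summary(comps, counts, mapping)
        b = proteome.kegg_pathway_summary(
            pd.concat([comps.iloc[::-1], comps]), counts,
            pd.concat([mapping, mapping]),
        )
        pd.testing.assert_frame_equal(a, b)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValidationError):
            proteome.kegg_pathway_summary(
                self._comparisons([("A", 0.0, 0.01)]), {"A": 1}, pd.DataFrame()
            )


class TestConcordance:
    def test_identical_and_negated(self):
        v = pd.Series({"g1": 1.0, "g2": -0.5, "g3": 2.0, "g4": 0.1})
        rep = proteome.mrna_fsr_concordance(v, v)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.sign_agreement == 1.0
        rep_neg = proteome.mrna_fsr_concordance(v, -v)
        assert rep_neg.spearman_rho == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        with pytest.raises(ValidationError):
            proteome.mrna_fsr_concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 1.0})

    def test_constructed_sign_agreement(self, rng):
        """80% concordant genes by construction -> sign agreement ~0.80."""
        n = 200
        mrna = rng.normal(0, 1, n)
        fsr = np.abs(rng.normal(0, 1, n)) * np.sign(mrna)
        flip = rng.choice(n, size=40, replace=False)
        fsr[flip] *= -1
        genes = [f"g{i}" for i in range(n)]
        rep = proteome.mrna_fsr_concordance(
            dict(zip(genes, mrna)), dict(zip(genes, fsr))
        )
        assert rep.sign_agreement == pytest.approx(0.80, abs=1e-9)
        assert rep.n_shared == n

    def test_divergent_genes_listed(self):
        mrna = {"g1": 1.0, "g2": -1.0, "g3": 0.2, "g4": 1.5}
        fsr = {"g1": 1.2, "g2": 1.0, "g3": -0.1, "g4": -2.0}
        rep = proteome.mrna_fsr_concordance(mrna, fsr)
        assert set(rep.divergent["gene"]) == {"g2", "g4"}
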
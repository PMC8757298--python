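"""Tests for enrichment, colocalization, correlations, DE, and diet ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from outbredqtl import (
    ContingencyTable2x2,
    colocalize,
    correlation_structure,
    differential_expression,
    fisher_association,
    founder_enrichment,
    interaction_anova,
    percent_difference,
)
from outbredqtl.architecture import allele_diet_ranking
from outbredqtl.peaks import QtlPeak, SupportInterval
from outbredqtl.scan import FounderEffectVector


def _peak(pheno, chrom, pos, lo, hi, qclass="cis", fclass="mrna", effects=None):
    fx = None
    if effects is not None:
        fx = FounderEffectVector(pheno, "m", np.asarray(effects, float), 0.0)
    return QtlPeak(
        pheno, fclass, "additive", chrom, "m", pos, 10.0, 5.0,
        SupportInterval(chrom, lo, hi), qclass, 0.3, founder_effects=fx,
    )


class TestFisher:
    def test_correlation_mapping_table_odds_ratio(self):
        # mapping-status x known-interaction counts among significant
        # miRNA-mRNA correlations
        res = fisher_association(ContingencyTable2x2(706, 540225, 1199, 866105))
        assert round(res.odds_ratio, 2) == 0.94
        assert res.p_value > 0.05

    def test_de_eqtl_table_odds_ratio(self):
        res = fisher_association(ContingencyTable2x2(4045, 1410, 4612, 1303))
        assert round(res.odds_ratio, 2) == 0.81
        assert res.p_value < 0.001

    def test_symmetric_table(self):
        res = fisher_association(ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_odds_ratio_closed_form(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 1000, size=4)
            res = fisher_association(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert res.odds_ratio == pytest.approx((a * d) / (b * c), abs=1e-12)

    def test_zero_denominator_flagged_infinite(self):
        res = fisher_association(ContingencyTable2x2(5, 0, 3, 7))
        assert np.isinf(res.odds_ratio)
        assert 0.0 <= res.p_value <= 1.0

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestFounderEnrichment:
    def test_centered_rows_sum_to_zero(self, rng):
        eff = rng.normal(size=(30, 8))
        res = founder_enrichment(eff)
        np.testing.assert_allclose(res.scaled_effects.sum(axis=1), 0.0, atol=1e-10)

    def test_null_calibration(self):
        # i.i.d. founder effects: Kruskal-Wallis significant in about 5%
        # of panels
        gen = np.random.default_rng(0)
        hits = 0
        n_panels = 200
        for _ in range(n_panels):
            res = founder_enrichment(gen.normal(size=(40, 8)))
            hits += res.kruskal_p < 0.05
        assert abs(hits / n_panels - 0.05) <= 0.05

    def test_planted_wild_enrichment_recovered(self):
        gen = np.random.default_rng(1)
        for _ in range(3):
            eff = gen.normal(size=(80, 8))
            eff[:, 5] *= 3.0  # CAST/EiJ
            eff[:, 6] *= 3.0  # PWK/PhJ
            res = founder_enrichment(eff)
            flagged = set(res.enriched_founders())
            assert flagged == {"CAST/EiJ", "PWK/PhJ"}

    def test_too_few_peaks_rejected(self, rng):
        with pytest.raises(ValueError):
            founder_enrichment(rng.normal(size=(1, 8)))


class TestColocalize:
    def test_overlap_arithmetic(self):
        e = _peak("g1", "1", 12.0, 10.0, 20.0)
        m = _peak("mir1", "1", 17.0, 15.0, 25.0, fclass="mirna")
        pairs = colocalize([e], [m])
        assert len(pairs) == 1
        assert pairs[0].distance_mb == pytest.approx(5.0)

    def test_different_chromosomes_no_pair(self):
        e = _peak("g1", "1", 12.0, 10.0, 20.0)
        m = _peak("mir1", "2", 12.0, 10.0, 20.0, fclass="mirna")
        assert colocalize([e], [m]) == []

    def test_identical_peak_distance_zero(self):
        e = _peak("g1", "3", 42.0, 40.0, 44.0)
        m = _peak("mir1", "3", 42.0, 41.0, 43.0, fclass="mirna")
        assert colocalize([e], [m])[0].distance_mb == 0.0

    def test_matches_brute_force_on_random_peaks(self, rng):
        eqtl = [
            _peak(f"g{i}", str(rng.integers(1, 4)), 0, *sorted(rng.uniform(0, 100, 2)))
            for i in range(40)
        ]
        mir = [
            _peak(
                f"mir{i}", str(rng.integers(1, 4)), 0,
                *sorted(rng.uniform(0, 100, 2)), fclass="mirna",
            )
            for i in range(20)
        ]
        got = {(p.mirqtl.phenotype, p.eqtl.phenotype) for p in colocalize(eqtl, mir)}
        brute = set()
        for m in mir:
            for e in eqtl:
                if m.chrom == e.chrom and (
                    max(m.interval.lower_mb, e.interval.lower_mb)
                    <= min(m.interval.upper_mb, e.interval.upper_mb)
                ):
                    brute.add((m.phenotype, e.phenotype))
        assert got == brute


class TestCorrelationStructure:
    def _panels(self, rng, n_mir=5, n_mrna=8, n=60):
        ind = [f"i{k}" for k in range(n)]
        mir = pd.DataFrame(
            rng.normal(size=(n_mir, n)),
            index=[f"mir{i}" for i in range(n_mir)],
            columns=ind,
        )
        mrna = pd.DataFrame(
            rng.normal(size=(n_mrna, n)),
            index=[f"g{i}" for i in range(n_mrna)],
            columns=ind,
        )
        return mir, mrna

    def test_monotone_function_gives_rho_one(self, rng):
        mir, mrna = self._panels(rng)
        mrna.loc["g0"] = np.exp(mir.loc["mir0"])  # strictly increasing
        cats = pd.Series("no-eqtl", index=mrna.index)
        out = correlation_structure(mir, mrna, cats)
        rec = out.records.query("mirna == 'mir0' and mrna == 'g0'")
        assert rec["rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_spearman(self, rng):
        mir, mrna = self._panels(rng, n=25)
        cats = pd.Series("no-eqtl", index=mrna.index)
        out = correlation_structure(mir, mrna, cats)
        for _, row in out.records.sample(10, random_state=0).iterrows():
            rho, p = stats.spearmanr(
                mir.loc[row["mirna"]], mrna.loc[row["mrna"]]
            )
            assert row["rho"] == pytest.approx(rho, abs=1e-12)
            assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_bh_matches_brute_force_oracle(self, rng):
        mir, mrna = self._panels(rng)
        cats = pd.Series("no-eqtl", index=mrna.index)
        out = correlation_structure(mir, mrna, cats, alpha=0.4)
        p = out.records["p"].to_numpy()
        # independent BH: largest k with p_(k) <= k/m * alpha
        order = np.argsort(p)
        m = len(p)
        thresh = 0.4 * (np.arange(1, m + 1) / m)
        passing = np.flatnonzero(np.sort(p) <= thresh)
        n_sig_oracle = 0 if len(passing) == 0 else passing.max() + 1
        assert out.n_significant == n_sig_oracle

    def test_fdr_controlled_on_independent_noise(self):
        gen = np.random.default_rng(3)
        ind = [f"i{k}" for k in range(100)]
        mir = pd.DataFrame(
            gen.normal(size=(50, 100)),
            index=[f"mir{i}" for i in range(50)], columns=ind,
        )
        mrna = pd.DataFrame(
            gen.normal(size=(50, 100)),
            index=[f"g{i}" for i in range(50)], columns=ind,
        )
        cats = pd.Series("no-eqtl", index=mrna.index)
        out = correlation_structure(mir, mrna, cats)
        assert out.n_significant / len(out.records) <= 0.05

    def test_known_interactions_flagged(self, rng):
        mir, mrna = self._panels(rng)
        catalog = pd.DataFrame({"mirna": ["mir1"], "target": ["g2"]})
        cats = pd.Series("no-eqtl", index=mrna.index)
        out = correlation_structure(mir, mrna, cats, interaction_catalog=catalog)
        rec = out.records.query("mirna == 'mir1' and mrna == 'g2'")
        assert rec["known_interaction"].iloc[0]
        assert out.records["known_interaction"].sum() == 1

    def test_too_few_shared_individuals(self, rng):
        mir, mrna = self._panels(rng, n=4)
        mrna.columns = ["i0", "i1", "x1", "x2"]
        with pytest.raises(ValueError, match="shared"):
            correlation_structure(mir, mrna, pd.Series("no-eqtl", index=mrna.index))

    def test_bh_adjusted_never_below_raw(self, rng):
        mir, mrna = self._panels(rng)
        out = correlation_structure(
            mir, mrna, pd.Series("no-eqtl", index=mrna.index)
        )
        assert (out.records["p_bh"] >= out.records["p"] - 1e-15).all()


class TestDifferentialExpression:
    def _panel(self, rng, n_feat=30, n=60, shift_idx=(), shift=0.0):
        ind = [f"i{k}" for k in range(n)]
        diets = pd.Series(
            ["HFCA"] * (n // 2) + ["HP"] * (n - n // 2), index=ind
        )
        vals = rng.normal(loc=8.0, size=(n_feat, n))
        for i in shift_idx:
            vals[i, : n // 2] += shift
        values = pd.DataFrame(
            vals, index=[f"g{i}" for i in range(n_feat)], columns=ind
        )
        fclass = pd.Series("mrna", index=values.index)
        return values, fclass, diets

    def test_floor_in_exactly_quarter_of_samples_passes(self, rng):
        values, fclass, diets = self._panel(rng, n_feat=1, n=40)
        values.iloc[0] = 3.0  # below the floor everywhere
        values.iloc[0, :10] = 4.0  # at the floor in exactly 25%
        table = differential_expression(values, fclass, diets)
        assert "g0" in table.index

    def test_below_prevalence_excluded(self, rng):
        values, fclass, diets = self._panel(rng, n_feat=1, n=40)
        values.iloc[0] = 3.0
        values.iloc[0, :9] = 4.0  # only 22.5%
        table = differential_expression(values, fclass, diets)
        assert "g0" not in table.index

    def test_null_labels_nothing_significant(self):
        gen = np.random.default_rng(5)
        values, fclass, diets = self._panel(gen, n_feat=100, n=80)
        table = differential_expression(values, fclass, diets)
        assert table["significant"].mean() <= 0.02

    def test_planted_shift_recovered_with_high_sensitivity(self):
        gen = np.random.default_rng(6)
        shifted = tuple(range(30))  # 30% of 100 features
        values, fclass, diets = self._panel(
            gen, n_feat=100, n=200, shift_idx=shifted, shift=2.0
        )
        table = differential_expression(values, fclass, diets)
        hits = table.loc[[f"g{i}" for i in shifted], "significant"].mean()
        assert hits >= 0.9

    def test_one_group_raises(self, rng):
        values, fclass, diets = self._panel(rng)
        diets[:] = "HFCA"
        with pytest.raises(ValueError):
            differential_expression(values, fclass, diets)

    def test_mirna_filter_uses_rpmmm_floor(self, rng):
        values, fclass, diets = self._panel(rng, n_feat=2, n=40)
        fclass[:] = "mirna"
        values.iloc[0] = 60.0  # above 50 RPMMM everywhere
        values.iloc[1] = 10.0  # below everywhere
        table = differential_expression(values, fclass, diets)
        assert "g0" in table.index and "g1" not in table.index


class TestDietInteraction:
    def test_identical_effects_score_zero(self):
        eff = np.array([1.0, -1.0, 0.5, 0, 0, 0, 0, -0.5])
        assert np.abs(percent_difference(eff, eff)).sum() == 0.0

    def test_single_founder_doubling_contributes_100(self):
        hp = np.array([1.0, 0.5, -0.5, 0.3, -0.3, 0.8, -0.8, -1.0])
        hfca = hp.copy()
        hfca[0] = 2.0  # +1.0 -> +2.0
        pct = percent_difference(hfca, hp)
        assert pct[0] == pytest.approx(100.0)
        assert np.abs(pct[1:]).max() == 0.0

    def test_score_invariant_to_common_rescaling(self, rng):
        hp = rng.normal(size=8)
        hfca = rng.normal(size=8)
        s1 = np.abs(percent_difference(hfca, hp)).sum()
        s2 = np.abs(percent_difference(3.7 * hfca, 3.7 * hp)).sum()
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_interaction_anova_null_uniform_p(self, small_dataset):
        geno, panel, _ = small_dataset
        diet = panel.diet_indicator()
        gen = np.random.default_rng(7)
        dosages = geno.dosages(geno.markers.index[3])
        ps = [
            interaction_anova(dosages, gen.standard_normal(geno.n_individuals), diet)
            for _ in range(100)
        ]
        # roughly uniform: nominal 5% level hit in 5% +/- a few
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) <= 0.07

    def test_interaction_anova_detects_planted_interaction(self, small_dataset):
        geno, panel, _ = small_dataset
        diet = panel.diet_indicator()
        dosages = geno.dosages(geno.markers.index[3])
        b = np.array([0, 0, 0, 0, 2.0, 0, 0, 0])  # NZO only in HFCA
        gen = np.random.default_rng(8)
        y = (dosages @ b) * diet + 0.3 * gen.standard_normal(geno.n_individuals)
        assert interaction_anova(dosages, y, diet) < 1e-6

    def test_ranking_requires_concordant_diet_peaks(self, small_dataset):
        geno, panel, _ = small_dataset
        diet = panel.diet_indicator()
        dosages = geno.dosages(geno.markers.index[3])
        b = np.array([0, 0, 0, 0, 2.0, 0, 0, 0])
        gen = np.random.default_rng(9)
        y = (dosages @ b) * diet + 0.3 * gen.standard_normal(geno.n_individuals)
        pid = str(panel.values.index[0])
        expr = pd.DataFrame([y], index=[pid], columns=panel.values.columns)
        ipeak = _peak(pid, "1", 10.0, 5.0, 15.0, effects=b)
        ipeak.marker = geno.markers.index[3]
        h = _peak(pid, "1", 10.0, 5.0, 15.0, effects=2 * b)
        q = _peak(pid, "1", 11.0, 6.0, 16.0, effects=b)
        records = allele_diet_ranking(
            [ipeak], [h], [q], expr, geno, panel.covariates["diet"]
        )
        assert len(records) == 1
        assert records[0].divergence_score > 0
        # no HP peak -> excluded
        records2 = allele_diet_ranking(
            [ipeak], [h], [], expr, geno, panel.covariates["diet"]
        )
        assert records2 == []
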
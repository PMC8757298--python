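"""Tests for kinship, REML variance components, LOD scans and BLUPs."""

import numpy as np
import pandas as pd
import pytest

from outbredqtl import (
    AlleleProbabilityTensor,
    ScanContext,
    SimulationConfig,
    blup_effects,
    estimate_heritability,
    fit_null,
    loco_kinship,
    overall_kinship,
    scan,
    simulate_dataset,
)
from outbredqtl.data import N_FOUNDERS


def _random_geno(rng, n=10, markers_per_chrom=(4, 3), hard=False):
    chroms = []
    names = []
    for c, m in enumerate(markers_per_chrom, start=1):
        for j in range(m):
            names.append(f"c{c}_m{j + 1}")
            chroms.append((str(c), float(j)))
    markers = pd.DataFrame(
        {"chrom": [c for c, _ in chroms], "pos_mb": [p for _, p in chroms]},
        index=pd.Index(names, name="marker"),
    )
    M = len(names)
    if hard:
        labels = rng.integers(0, N_FOUNDERS, size=(n, 2, M))
        probs = (np.eye(N_FOUNDERS)[labels]).mean(axis=1)
    else:
        raw = rng.random((n, M, N_FOUNDERS))
        probs = raw / raw.sum(axis=2, keepdims=True)
    return AlleleProbabilityTensor(probs, [f"i{k}" for k in range(n)], markers)


class TestKinship:
    def test_matches_brute_force_triple_loop(self, rng):
        geno = _random_geno(rng, n=8)
        K = overall_kinship(geno)
        n, M, F = geno.probs.shape
        brute = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                for m in range(M):
                    brute[i, j] += geno.probs[i, m] @ geno.probs[j, m]
        brute /= M
        assert np.abs(K - brute).max() < 1e-10

    def test_identical_individuals_have_self_similarity(self, rng):
        geno = _random_geno(rng, n=4)
        geno.probs[1] = geno.probs[0]
        K = overall_kinship(geno)
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_orthogonal_homozygotes(self):
        # two individuals, one marker, hard probabilities on different founders
        probs = np.zeros((2, 1, 8))
        probs[0, 0, 0] = 1.0
        probs[1, 0, 5] = 1.0
        markers = pd.DataFrame(
            {"chrom": ["1"], "pos_mb": [0.0]}, index=pd.Index(["m1"], name="marker")
        )
        geno = AlleleProbabilityTensor(probs, ["a", "b"], markers)
        K = overall_kinship(geno)
        assert K[0, 0] == pytest.approx(1.0)
        assert K[0, 1] == pytest.approx(0.0)

    def test_loco_excludes_focal_chromosome(self, rng):
        geno = _random_geno(rng, n=12, markers_per_chrom=(5, 6))
        ks = loco_kinship(geno)
        # recompute chromosome-2-only kinship by brute force: LOCO for chrom 1
        idx = geno.chrom_indices("2")
        flat = geno.probs[:, idx, :].reshape(12, -1)
        np.testing.assert_allclose(ks.loco["1"], flat @ flat.T / len(idx), atol=1e-12)

    def test_single_chromosome_warns_and_zeroes(self, rng):
        geno = _random_geno(rng, markers_per_chrom=(5,))
        with pytest.warns(UserWarning, match="single-chromosome"):
            ks = loco_kinship(geno)
        assert not ks.loco["1"].any()

    def test_psd_and_symmetric(self, small_kinship):
        ev = np.linalg.eigvalsh(small_kinship.full)
        assert ev.min() > -1e-10
        np.testing.assert_allclose(small_kinship.full, small_kinship.full.T)


class TestFitNull:
    def test_zero_kinship_gives_residual_variance(self, rng):
        n = 80
        y = rng.standard_normal(n)
        vc = fit_null(y, None, np.zeros((n, n)))
        assert vc.sigma_g == 0.0
        assert vc.sigma_e == pytest.approx(
            ((y - y.mean()) ** 2).sum() / (n - 1), rel=1e-8
        )

    def test_collinear_design_names_columns(self, rng):
        n = 30
        x = rng.standard_normal(n)
        cov = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="dup"):
            fit_null(rng.standard_normal(n), cov, np.eye(n), ["keep", "dup"])

    def test_null_trait_ratio_near_zero(self):
        cfg = SimulationConfig(
            n_individuals=300,
            chromosomes=(("1", 100.0, 30), ("2", 100.0, 30)),
            n_mrna=1,
            n_mirna=0,
            seed=31,
        )
        geno, _, _ = simulate_dataset(cfg)
        K = overall_kinship(geno)
        gen = np.random.default_rng(0)
        ratios = [
            fit_null(gen.standard_normal(300), None, K).h2 for _ in range(20)
        ]
        assert np.median(ratios) < 0.1

    def test_pure_polygenic_ratio_near_one(self):
        cfg = SimulationConfig(
            n_individuals=300,
            chromosomes=(("1", 100.0, 30), ("2", 100.0, 30)),
            n_mrna=1,
            n_mirna=0,
            seed=37,
        )
        geno, _, _ = simulate_dataset(cfg)
        K = overall_kinship(geno)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(300))
        gen = np.random.default_rng(1)
        ratios = [
            fit_null(L @ gen.standard_normal(300), None, K).h2 for _ in range(20)
        ]
        assert np.median(ratios) > 0.9


class TestScan:
    def test_matches_haley_knott_closed_form(self, rng):
        # kinship off: LOD must equal (n/2) log10(RSS0/RSS1) from a
        # two-line least-squares oracle (n=12 keeps designs unsaturated)
        for _ in range(10):
            n = 12
            geno = _random_geno(rng, n=n, markers_per_chrom=(3, 2), hard=True)
            y = rng.standard_normal(n)
            res = scan(geno, y, kinship=None)
            for m, marker in enumerate(geno.markers.index):
                X0 = np.ones((n, 1))
                X1 = geno.probs[:, m, :]
                r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
                r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
                lod = (n / 2) * np.log10((r0 @ r0) / (r1 @ r1))
                assert res.lod.iloc[m, 0] == pytest.approx(lod, abs=1e-8)

    def test_diallelic_hand_example(self):
        # n=8, one marker where founders split into two alleles; the LOD has
        # a two-group closed form
        probs = np.zeros((8, 1, 8))
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        probs[np.arange(8), 0, group * 5] = 1.0  # founders A vs CAST
        markers = pd.DataFrame(
            {"chrom": ["1"], "pos_mb": [0.0]}, index=pd.Index(["m1"], name="marker")
        )
        geno = AlleleProbabilityTensor(
            probs, [f"i{k}" for k in range(8)], markers
        )
        y = np.array([1.0, 2.0, 1.5, 2.5, 4.0, 5.0, 4.5, 5.5])
        res = scan(geno, y, kinship=None)
        rss0 = ((y - y.mean()) ** 2).sum()
        rss1 = sum(((y[group == g] - y[group == g].mean()) ** 2).sum() for g in (0, 1))
        assert res.lod.iloc[0, 0] == pytest.approx(4 * np.log10(rss0 / rss1), abs=1e-10)

    def test_constant_phenotype_warns_lod_zero(self, small_dataset, small_kinship):
        geno, _, _ = small_dataset
        with pytest.warns(UserWarning, match="constant"):
            res = scan(geno, np.ones(geno.n_individuals), kinship=small_kinship)
        assert (res.lod.to_numpy() == 0).all()

    def test_lod_nonnegative_and_finite(self, small_dataset, small_kinship):
        geno, panel, _ = small_dataset
        res = scan(
            geno,
            panel.values.iloc[:5],
            covariates=panel.diet_indicator(),
            kinship=small_kinship,
        )
        arr = res.lod.to_numpy()
        assert np.isfinite(arr).all()
        assert (arr >= 0).all()

    def test_interactive_lod_at_least_additive(self, small_dataset, small_kinship):
        # interactive full model nests the additive full model against the
        # same covariates-only null, so its LOD can only be larger
        geno, panel, _ = small_dataset
        diet = panel.diet_indicator()
        y = panel.values.iloc[3].to_numpy(float)
        add = scan(geno, y, covariates=diet, kinship=small_kinship, model="additive")
        inter = scan(
            geno, y, covariates=diet, kinship=small_kinship,
            model="interactive", interactive=diet,
        )
        assert (
            inter.lod.to_numpy() >= add.lod.to_numpy() - 1e-6
        ).all()

    def test_planted_qtl_recovered_at_marker(self):
        cfg = SimulationConfig(
            n_individuals=200,
            chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
            n_mrna=1,
            n_mirna=0,
            seed=41,
        )
        geno, _, _ = simulate_dataset(cfg)
        ks = loco_kinship(geno)
        ctx = ScanContext(geno, kinship=ks)
        marker = geno.markers.index[20]
        target = geno.marker_index(marker)
        eff = np.array([1.5, -1.5, 0, 0, 0, 0, 0, 0])  # strong biallelic contrast
        gen = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            g = geno.dosages(marker) @ eff
            g = (g - g.mean()) / g.std()
            y = g + gen.standard_normal(200)  # QTL explains half the variance
            lod, _ = ctx.scan_phenotype(y)
            hits += abs(int(np.argmax(lod)) - target) <= 1
        assert hits >= 18

    def test_deterministic(self, small_dataset, small_kinship):
        geno, panel, _ = small_dataset
        y = panel.values.iloc[0].to_numpy(float)
        a = scan(geno, y, kinship=small_kinship).lod
        b = scan(geno, y, kinship=small_kinship).lod
        pd.testing.assert_frame_equal(a, b)

    def test_loco_makes_lod_invariant_to_same_chrom_marker_shuffle(
        self, small_dataset
    ):
        geno, panel, _ = small_dataset
        y = panel.values.iloc[1].to_numpy(float)
        idx1 = geno.chrom_indices("1")
        shuffled = geno.probs.copy()
        gen = np.random.default_rng(3)
        shuffled[:, idx1, :] = shuffled[:, gen.permutation(idx1), :]
        geno2 = AlleleProbabilityTensor(
            shuffled, geno.individuals, geno.markers
        )
        # kinship built from the shuffled tensor: chromosome 1 LOCO kinship
        # ignores chromosome 1 markers entirely
        k1 = loco_kinship(geno)
        k2 = loco_kinship(geno2)
        lod1 = scan(geno, y, kinship=k1).lod.to_numpy()[idx1]
        lod2 = scan(geno, y, kinship=k2).lod.to_numpy()[idx1]
        np.testing.assert_allclose(lod1, lod2, atol=1e-9)


class TestBlup:
    def test_null_coefficients_calibrated_and_match_slow_oracle(self):
        # Under a genotype-independent trait the BLUP coefficients are
        # typically near zero (median max |coef| < 0.1 SD over replicates)
        # and in every replicate equal those of an independent slow REML
        # implementation that works with the explicit covariance
        # V = I + gamma Z Z'.
        cfg = SimulationConfig(
            n_individuals=300,
            chromosomes=(("1", 100.0, 20), ("2", 100.0, 20)),
            n_mrna=1,
            n_mirna=0,
            seed=43,
        )
        geno, _, _ = simulate_dataset(cfg)
        marker = geno.markers.index[5]
        Z = geno.dosages(marker)
        n = 300
        X = np.ones((n, 1))

        def slow_blup(y):
            from scipy.optimize import minimize_scalar

            def neg2(log_g):
                V = np.eye(n) + np.exp(log_g) * (Z @ Z.T)
                Vi = np.linalg.inv(V)
                XVX = X.T @ Vi @ X
                b = np.linalg.solve(XVX, X.T @ Vi @ y)
                r = y - X @ b
                _, ldV = np.linalg.slogdet(V)
                _, ldX = np.linalg.slogdet(XVX)
                return (n - 1) * np.log(r @ Vi @ r) + ldV + ldX

            res = minimize_scalar(
                neg2, bounds=(-14, 14), method="bounded",
                options={"xatol": 1e-10},
            )
            g = 0.0 if neg2(-30.0) <= res.fun else float(np.exp(res.x))
            if g == 0.0:
                return np.zeros(8)
            V = np.eye(n) + g * (Z @ Z.T)
            Vi = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            return g * Z.T @ Vi @ (y - X @ b)

        gen = np.random.default_rng(4)
        maxima = []
        for _ in range(10):
            y = gen.standard_normal(n)
            fx = blup_effects(geno, marker, y)
            np.testing.assert_allclose(fx.effects, slow_blup(y), atol=2e-4)
            maxima.append(np.abs(fx.effects).max() / y.std())
        assert np.median(maxima) < 0.1

    def test_planted_effect_ranks_first_noise_free(self, small_dataset):
        geno, _, _ = small_dataset
        marker = geno.markers.index[8]
        eff = np.zeros(8)
        eff[5] = 1.0  # CAST only
        y = geno.dosages(marker) @ eff
        fx = blup_effects(geno, marker, y)
        assert np.argmax(fx.effects) == 5
        assert fx.effects[5] > 0
        assert np.all(fx.effects[5] > np.delete(fx.effects, 5))

    def test_shrinkage_relative_to_ols(self, small_dataset, small_kinship, rng):
        # BLUP founder coefficients never exceed the (min-norm) least-squares
        # solution in L2 norm on the identical whitened design
        geno, panel, _ = small_dataset
        for i in range(5):
            marker = geno.markers.index[rng.integers(geno.n_markers)]
            y = rng.standard_normal(geno.n_individuals)
            chrom = geno.markers.loc[marker, "chrom"]
            fx = blup_effects(geno, marker, y, None, small_kinship.loco[chrom])
            # oracle: whitened min-norm OLS of the residualized dosage block
            from outbredqtl.scan import _eigendecompose, _null_design, _reml_h2

            K = small_kinship.loco[chrom]
            s, U = _eigendecompose(K)
            X = _null_design(len(y), None)
            h2, _ = _reml_h2(U.T @ y, U.T @ X, s)
            d = 1.0 / np.sqrt(h2 * s + (1 - h2))
            yw = (U.T @ y) * d
            Xw = (U.T @ X) * d[:, None]
            Zw = (U.T @ geno.dosages(marker)) * d[:, None]
            Q, _ = np.linalg.qr(Xw)
            y_res = yw - Q @ (Q.T @ yw)
            Z_res = Zw - Q @ (Q.T @ Zw)
            u_ols = np.linalg.pinv(Z_res) @ y_res
            assert np.linalg.norm(fx.effects) <= np.linalg.norm(u_ols) + 1e-10

    def test_underrepresented_founders_raise(self):
        probs = np.zeros((10, 2, 8))
        probs[:, :, 3] = 1.0  # single founder everywhere
        markers = pd.DataFrame(
            {"chrom": ["1", "1"], "pos_mb": [0.0, 1.0]},
            index=pd.Index(["m1", "m2"], name="marker"),
        )
        geno = AlleleProbabilityTensor(
            probs, [f"i{k}" for k in range(10)], markers
        )
        with pytest.raises(ValueError, match="fewer than 2 founders"):
            blup_effects(geno, "m1", np.arange(10.0))


class TestHeritability:
    def test_bounded_in_unit_interval(self, small_dataset, small_kinship):
        geno, panel, _ = small_dataset
        for i in range(5):
            est = estimate_heritability(
                panel.values.iloc[i].to_numpy(float),
                small_kinship.full,
                panel.diet_indicator(),
            )
            assert 0.0 <= est.h2 <= 1.0

    def test_pure_noise_low_pure_polygenic_high(self, small_kinship):
        n = small_kinship.n
        L = np.linalg.cholesky(small_kinship.full + 1e-8 * np.eye(n))
        gen = np.random.default_rng(5)
        noise = [
            estimate_heritability(gen.standard_normal(n), small_kinship.full).h2
            for _ in range(10)
        ]
        poly = [
            estimate_heritability(
                L @ gen.standard_normal(n), small_kinship.full
            ).h2
            for _ in range(10)
        ]
        assert np.median(noise) < 0.15
        assert np.median(poly) > 0.85
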
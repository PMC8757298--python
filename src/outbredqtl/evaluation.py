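"""Reproducibility studies: calibration and recovery runs of the pipeline.

Each function here sets up a seeded synthetic study, runs the package end to
end on it, and returns the measured quantity: printed-table association
statistics, least-squares oracle agreement of the mixed-model scan,
agreement of the two-stage permutation screen with exhaustive permutation,
type-I error of per-phenotype thresholds, recovery of planted heritability,
cis/trans classes, wild-derived founder enrichment and diet interactions,
and support-interval coverage.  Study sizes are desk scale (hundreds of
individuals and phenotypes, two chromosomes) so a full run finishes in
minutes on one CPU; every random draw descends from the single seed
argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import (
    ContingencyTable2x2,
    allele_diet_ranking,
    fisher_association,
    founder_enrichment,
)
from .data import AlleleProbabilityTensor, ExpressionPanel, N_FOUNDERS
from .kinship import loco_kinship
from .peaks import (
    QtlPeak,
    characterize_phenotype,
    find_peaks,
    support_interval,
)
from .permute import (
    PermutationConfig,
    exhaustive_significant,
    permutation_null,
    threshold_from_null,
    two_stage_screen,
)
from .scan import ScanContext, blup_effects, estimate_heritability, scan
from .simulate import (
    GroundTruth,
    PlantedQtl,
    SimulationConfig,
    assign_diets,
    mosaics_to_alleleprobs,
    simulate_expression,
    simulate_mosaics,
)

#: Contingency tables printed in the source study.  Mapping-status x
#: validated-interaction counts among significant miRNA-mRNA correlations,
#: and differential-expression x eQTL-status counts for mRNA.
CORRELATION_MAPPING_TABLE = (706, 540225, 1199, 866105)
DE_EQTL_TABLE = (4045, 1410, 4612, 1303)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream])
    )


def fisher_printed_tables() -> dict[str, float]:
    """Association statistics on the study's printed 2x2 tables."""
    t_corr = fisher_association(ContingencyTable2x2(*CORRELATION_MAPPING_TABLE))
    t_de = fisher_association(ContingencyTable2x2(*DE_EQTL_TABLE))
    a, b, c, d = DE_EQTL_TABLE
    marginal_pct = 100.0 * (a + b) / (a + b + c + d)
    return {
        "correlation_mapping_odds_ratio": t_corr.odds_ratio,
        "correlation_mapping_p": t_corr.p_value,
        "de_eqtl_odds_ratio": t_de.odds_ratio,
        "de_eqtl_p": t_de.p_value,
        "de_eqtl_marginal_pct": marginal_pct,
    }


def lod_oracle_deviation(seed: int, n_instances: int = 50) -> float:
    """Max |scan LOD - closed-form Haley-Knott oracle| with kinship zeroed.

    Oracle: two plain least-squares fits per marker,
    ``(n/2) log10(RSS0 / RSS1)``, independent of the scan implementation.
    """
    rng = _rng(seed, 41)
    worst = 0.0
    for _ in range(n_instances):
        n = 12
        markers = pd.DataFrame(
            {"chrom": ["1", "1", "1", "2", "2"], "pos_mb": [0.0, 1, 2, 0, 1]},
            index=pd.Index([f"m{j}" for j in range(5)], name="marker"),
        )
        labels = rng.integers(0, N_FOUNDERS, size=(n, 2, 5))
        probs = np.eye(N_FOUNDERS)[labels].mean(axis=1)
        geno = AlleleProbabilityTensor(
            probs, [f"i{k}" for k in range(n)], markers
        )
        y = rng.standard_normal(n)
        res = scan(geno, y, kinship=None)
        for m in range(5):
            X0 = np.ones((n, 1))
            X1 = probs[:, m, :]
            b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
            b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
            rss0 = float(((y - X0 @ b0) ** 2).sum())
            rss1 = float(((y - X1 @ b1) ** 2).sum())
            oracle = (n / 2) * np.log10(rss0 / rss1)
            worst = max(worst, abs(float(res.lod.iloc[m, 0]) - oracle))
    return worst


def _panel_with_planted(
    seed_stream: np.random.Generator,
    sim: SimulationConfig,
    planter,
) -> tuple[AlleleProbabilityTensor, ExpressionPanel, GroundTruth]:
    """Simulate genotypes, let ``planter(rng, geno)`` build the truth and
    annotations, and emit the expression panel."""
    mosaics = simulate_mosaics(sim, seed_stream)
    geno = mosaics_to_alleleprobs(mosaics, sim.softening)
    diets = assign_diets(sim, seed_stream)
    truth, annotations = planter(seed_stream, geno)
    panel = simulate_expression(
        geno, truth, diets, annotations,
        seed=int(seed_stream.integers(2**31)),
    )
    return geno, panel, truth


def _annotate(features: list[str], chroms, tss) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": list(chroms),
            "tss_mb": list(tss),
            "feature_class": ["mrna"] * len(features),
        },
        index=pd.Index(features, name="feature"),
    )


def two_stage_agreement(seed: int) -> dict[str, float]:
    """Two-stage screen vs exhaustive full permutation on a planted panel.

    200 phenotypes, 20 with planted QTL, 200 full permutations per
    phenotype.  Returns the sizes of both significant sets and the size of
    their symmetric difference (0 means exact agreement, the study's own
    validation result reproduced in miniature).
    """
    sim = SimulationConfig(
        n_individuals=150,
        chromosomes=(("1", 100.0, 60), ("2", 100.0, 60)),
        n_mrna=200,
        n_mirna=0,
        seed=seed,
    )
    rng = _rng(seed, 5)

    def planter(rng, geno):
        features = [f"t{i:03d}" for i in range(200)]
        chroms = rng.choice(["1", "2"], size=200)
        tss = rng.uniform(0, 100, size=200)
        truth = GroundTruth(
            h2={f: 0.3 for f in features},
            diet_effect={f: 0.0 for f in features},
        )
        pos = geno.markers["pos_mb"].to_numpy()
        mchrom = geno.markers["chrom"].to_numpy()
        names = geno.markers.index.to_numpy()
        for i in range(20):
            near = (mchrom == chroms[i]) & (np.abs(pos - tss[i]) <= 4.0)
            marker = str(rng.choice(names[near]))
            eff = rng.normal(0.0, 1.2, N_FOUNDERS)
            eff -= eff.mean()
            truth.qtl.append(
                PlantedQtl(features[i], marker, eff, np.zeros(8), "cis")
            )
        return truth, _annotate(features, chroms, tss)

    geno, panel, _ = _panel_with_planted(rng, sim, planter)
    kinship = loco_kinship(geno)
    ctx = ScanContext(
        geno, panel.diet_indicator(), ["diet"], kinship, "additive"
    )
    observed = pd.Series(
        {
            str(f): ctx.max_lod(panel.values.loc[f].to_numpy(float))
            for f in panel.values.index
        }
    )
    pcfg = PermutationConfig(
        n_perm_full=200, n_perm_screen=50, seed=int(_rng(seed, 6).integers(2**31))
    )
    screen = two_stage_screen(ctx, panel.values, pcfg, observed_max=observed)
    exhaustive, _ = exhaustive_significant(
        ctx, panel.values, pcfg, observed_max=observed
    )
    a, b = set(screen.significant), set(exhaustive)
    return {
        "n_two_stage": float(len(a)),
        "n_exhaustive": float(len(b)),
        "n_disagreements": float(len(a ^ b)),
    }


def threshold_type1_error(
    seed: int, n_traits: int = 100, n_perm: int = 200
) -> float:
    """Fraction of independent null traits exceeding their own permutation
    threshold (nominal 0.05)."""
    sim = SimulationConfig(
        n_individuals=120,
        chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
        n_mrna=1,
        n_mirna=0,
        seed=seed,
    )
    rng = _rng(seed, 7)
    mosaics = simulate_mosaics(sim, rng)
    geno = mosaics_to_alleleprobs(mosaics, sim.softening)
    kinship = loco_kinship(geno)
    ctx = ScanContext(geno, kinship=kinship)
    exceed = 0
    for _ in range(n_traits):
        y = rng.standard_normal(sim.n_individuals)
        obs = ctx.max_lod(y)
        draws = permutation_null(ctx, y, n_perm, rng)
        exceed += obs > threshold_from_null(draws, 0.95)
    return exceed / n_traits


def h2_recovery(
    seed: int, targets: tuple[float, ...] = (0.2, 0.4, 0.8), n_reps: int = 20
) -> dict[float, float]:
    """Median estimated narrow-sense heritability per target at n=400."""
    sim = SimulationConfig(
        n_individuals=400,
        chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
        n_mrna=len(targets) * n_reps,
        n_mirna=0,
        seed=seed,
    )
    rng = _rng(seed, 8)

    def planter(rng, geno):
        features = [
            f"h{int(t * 100)}_{r}" for t in targets for r in range(n_reps)
        ]
        truth = GroundTruth(
            h2={f"h{int(t * 100)}_{r}": t for t in targets for r in range(n_reps)},
            diet_effect={f: 0.0 for f in features},
        )
        return truth, _annotate(
            features, ["1"] * len(features), [50.0] * len(features)
        )

    geno, panel, truth = _panel_with_planted(rng, sim, planter)
    K = loco_kinship(geno).full
    medians = {}
    for t in targets:
        ests = [
            estimate_heritability(
                panel.values.loc[f"h{int(t * 100)}_{r}"].to_numpy(float), K
            ).h2
            for r in range(n_reps)
        ]
        medians[t] = float(np.median(ests))
    return medians


def cis_trans_accuracy(seed: int, n_each: int = 40) -> dict[str, float]:
    """Fraction of detected planted QTL classified with their true class.

    Half the planted QTL are cis (marker inside the 4-Mb TSS window), half
    trans (different chromosome, or same chromosome at least 12 Mb away);
    detection uses per-phenotype two-stage permutation thresholds.
    """
    n_pheno = 2 * n_each
    sim = SimulationConfig(
        n_individuals=200,
        chromosomes=(("1", 100.0, 60), ("2", 100.0, 60)),
        n_mrna=n_pheno,
        n_mirna=0,
        seed=seed,
    )
    rng = _rng(seed, 9)

    def planter(rng, geno):
        features = [f"q{i:03d}" for i in range(n_pheno)]
        chroms = rng.choice(["1", "2"], size=n_pheno)
        tss = rng.uniform(0, 100, size=n_pheno)
        truth = GroundTruth(
            h2={f: 0.3 for f in features},
            diet_effect={f: 0.0 for f in features},
        )
        pos = geno.markers["pos_mb"].to_numpy()
        mchrom = geno.markers["chrom"].to_numpy()
        names = geno.markers.index.to_numpy()
        for i, f in enumerate(features):
            if i < n_each:  # cis
                mask = (mchrom == chroms[i]) & (np.abs(pos - tss[i]) <= 4.0)
                qclass = "cis"
            elif i % 2 == 0:  # trans on the other chromosome
                mask = mchrom != chroms[i]
                qclass = "trans"
            else:  # distant trans on the same chromosome
                mask = (mchrom == chroms[i]) & (np.abs(pos - tss[i]) >= 12.0)
                qclass = "trans"
            marker = str(rng.choice(names[mask]))
            eff = rng.normal(0.0, 1.0, N_FOUNDERS)
            eff -= eff.mean()
            truth.qtl.append(PlantedQtl(f, marker, eff, np.zeros(8), qclass))
        return truth, _annotate(features, chroms, tss)

    geno, panel, truth = _panel_with_planted(rng, sim, planter)
    kinship = loco_kinship(geno)
    ctx = ScanContext(
        geno, panel.diet_indicator(), ["diet"], kinship, "additive"
    )
    pcfg = PermutationConfig(
        n_perm_full=100, n_perm_screen=30,
        seed=int(_rng(seed, 10).integers(2**31)),
    )
    screen = two_stage_screen(ctx, panel.values, pcfg)
    thresholds = {
        r.phenotype: r.threshold for r in screen.records if r.stage == "full"
    }
    correct = detected = 0
    for q in truth.qtl:
        if q.phenotype not in screen.significant:
            continue
        y = panel.values.loc[q.phenotype].to_numpy(float)
        lod, _ = ctx.scan_phenotype(y)
        peaks = find_peaks(lod, geno.markers, thresholds[q.phenotype])
        if not peaks:
            continue
        chrom, marker, pos, peak_lod = max(peaks, key=lambda p: p[3])
        ann = panel.annotations.loc[q.phenotype]
        from .peaks import classify_peak

        call = classify_peak(chrom, pos, str(ann["chrom"]), float(ann["tss_mb"]))
        detected += 1
        correct += call == q.qtl_class
    return {
        "accuracy": correct / detected if detected else float("nan"),
        "n_detected": float(detected),
    }


def wild_enrichment_recovery(seed: int, n_reps: int = 20) -> dict[str, float]:
    """Replicates where 3x-inflated CAST/PWK effects are the (only) founders
    flagged by Kruskal-Wallis + Dunn/BH on BLUP effects at planted QTL."""
    successes = 0
    for rep in range(n_reps):
        sim = SimulationConfig(
            n_individuals=200,
            chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
            n_mrna=80,
            n_mirna=0,
            seed=seed,
        )
        rng = _rng(seed, 1000 + rep)

        def planter(rng, geno):
            features = [f"e{i:03d}" for i in range(80)]
            names = geno.markers.index.to_numpy()
            truth = GroundTruth(
                h2={f: 0.15 for f in features},
                diet_effect={f: 0.0 for f in features},
            )
            for f in features:
                eff = rng.normal(0.0, 1.0, N_FOUNDERS)
                eff[5] *= 3.0  # CAST/EiJ
                eff[6] *= 3.0  # PWK/PhJ
                eff -= eff.mean()
                truth.qtl.append(
                    PlantedQtl(f, str(rng.choice(names)), eff, np.zeros(8), "trans")
                )
            return truth, _annotate(features, ["1"] * 80, [50.0] * 80)

        geno, panel, truth = _panel_with_planted(rng, sim, planter)
        kinship = loco_kinship(geno)
        effects = []
        for q in truth.qtl:
            chrom = geno.markers.loc[q.marker, "chrom"]
            fx = blup_effects(
                geno,
                q.marker,
                panel.values.loc[q.phenotype].to_numpy(float),
                None,
                kinship.loco[chrom],
                q.phenotype,
            )
            effects.append(fx.effects)
        enr = founder_enrichment(np.array(effects))
        flagged = set(enr.enriched_founders())
        successes += flagged == {"CAST/EiJ", "PWK/PhJ"}
    return {"successes": float(successes), "n_reps": float(n_reps)}


def _characterized_peaks(
    geno, panel, phenotypes, ctx, model, covariates, kinship, threshold
) -> list[QtlPeak]:
    peaks: list[QtlPeak] = []
    for pid in phenotypes:
        y = panel.values[ctx.geno.individuals].loc[pid].to_numpy(float)
        lod, _ = ctx.scan_phenotype(y)
        ann = panel.annotations.loc[pid]
        peaks.extend(
            characterize_phenotype(
                ctx.geno,
                y,
                pid,
                str(ann["feature_class"]),
                str(ann["chrom"]),
                float(ann["tss_mb"]),
                lod,
                threshold,
                model,
                covariates=covariates,
                kinship=kinship,
            )
        )
    return peaks


def diet_interaction_recovery(
    seed: int, n_reps: int = 20, detection_lod: float = 6.0
) -> dict[str, float]:
    """Replicates where a planted NZO-only-in-HFCA interaction ranks in the
    top 5% of allele-diet divergence scores.

    Every phenotype carries a strong shared cis QTL, normalized so the
    dosage term has SD 1.5 against the unit-variance background (a large
    local effect, detectable in the interactive and both diet-subset scans
    at a fixed LOD threshold even in the smaller diet subsets); one
    phenotype additionally responds to the HFCA diet only through the
    NZO/HlLtJ allele, with the interaction term normalized to SD 1.
    """
    successes = 0
    scored = []
    for rep in range(n_reps):
        sim = SimulationConfig(
            n_individuals=160,
            chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
            n_mrna=30,
            n_mirna=0,
            seed=seed,
        )
        rng = _rng(seed, 2000 + rep)

        def planter(rng, geno):
            features = [f"d{i:02d}" for i in range(30)]
            chroms = rng.choice(["1", "2"], size=30)
            tss = rng.uniform(5, 95, size=30)
            pos = geno.markers["pos_mb"].to_numpy()
            mchrom = geno.markers["chrom"].to_numpy()
            names = geno.markers.index.to_numpy()
            truth = GroundTruth(
                h2={f: 0.2 for f in features},
                diet_effect={f: 0.0 for f in features},
            )
            for i, f in enumerate(features):
                mask = (mchrom == chroms[i]) & (np.abs(pos - tss[i]) <= 4.0)
                marker = str(rng.choice(names[mask]))
                dosages = geno.dosages(marker)
                eff = rng.normal(0.0, 1.0, N_FOUNDERS)
                eff -= eff.mean()
                eff *= 1.5 / max(float((dosages @ eff).std()), 1e-9)
                dint = np.zeros(N_FOUNDERS)
                if i == 0:  # NZO/HlLtJ effect present only under HFCA
                    dint[4] = 1.0
                    dint -= dint.mean()
                    dint *= 1.0 / max(float((dosages @ dint).std()), 1e-9)
                truth.qtl.append(PlantedQtl(f, marker, eff, dint, "cis"))
            return truth, _annotate(features, chroms, tss)

        geno, panel, truth = _panel_with_planted(rng, sim, planter)
        kinship = loco_kinship(geno)
        diet = panel.diet_indicator()
        phenotypes = list(panel.values.index)

        ctx_i = ScanContext(
            geno, diet, ["diet"], kinship, "interactive", interactive=diet
        )
        interactive_peaks = _characterized_peaks(
            geno, panel, phenotypes, ctx_i, "interactive", diet, kinship,
            detection_lod,
        )
        subset_peaks = {}
        for level in ("HFCA", "HP"):
            mask = (panel.covariates["diet"] == level).to_numpy()
            sub_geno = geno.subset(mask)
            sub_kin = kinship.subset(mask)
            ctx_s = ScanContext(sub_geno, kinship=sub_kin, model=f"subset-{level}")
            subset_peaks[level] = _characterized_peaks(
                sub_geno, panel, phenotypes, ctx_s, f"subset-{level}", None,
                sub_kin, detection_lod,
            )
        records = allele_diet_ranking(
            interactive_peaks,
            subset_peaks["HFCA"],
            subset_peaks["HP"],
            panel.values,
            geno,
            panel.covariates["diet"],
        )
        ranks = {r.phenotype: i + 1 for i, r in enumerate(records)}
        scored.append(len(records))
        if "d00" in ranks:
            cutoff = max(1, int(np.ceil(0.05 * len(records))))
            successes += ranks["d00"] <= cutoff
    return {
        "successes": float(successes),
        "n_reps": float(n_reps),
        "mean_scored": float(np.mean(scored)),
    }


def interval_coverage(
    seed: int, n_qtl: int = 200, detection_lod: float = 6.0
) -> dict[str, float]:
    """Empirical coverage of planted markers by 1.8-LOD support intervals."""
    sim = SimulationConfig(
        n_individuals=200,
        chromosomes=(("1", 100.0, 60), ("2", 100.0, 60)),
        n_mrna=n_qtl,
        n_mirna=0,
        seed=seed,
    )
    rng = _rng(seed, 11)

    def planter(rng, geno):
        features = [f"s{i:03d}" for i in range(n_qtl)]
        names = geno.markers.index.to_numpy()
        truth = GroundTruth(
            h2={f: 0.3 for f in features},
            diet_effect={f: 0.0 for f in features},
        )
        for f in features:
            eff = rng.normal(0.0, 1.0, N_FOUNDERS)
            eff -= eff.mean()
            truth.qtl.append(
                PlantedQtl(f, str(rng.choice(names)), eff, np.zeros(8), "trans")
            )
        return truth, _annotate(features, ["1"] * n_qtl, [50.0] * n_qtl)

    geno, panel, truth = _panel_with_planted(rng, sim, planter)
    kinship = loco_kinship(geno)
    ctx = ScanContext(geno, kinship=kinship)
    covered = detected = 0
    for q in truth.qtl:
        y = panel.values.loc[q.phenotype].to_numpy(float)
        lod, _ = ctx.scan_phenotype(y)
        chrom = str(geno.markers.loc[q.marker, "chrom"])
        idx = geno.chrom_indices(chrom)
        j = idx[int(np.argmax(lod[idx]))]
        if lod[j] <= detection_lod:
            continue
        iv = support_interval(lod, geno.markers, str(geno.markers.index[j]))
        detected += 1
        covered += iv.contains(float(geno.markers.loc[q.marker, "pos_mb"]))
    return {
        "coverage": covered / detected if detected else float("nan"),
        "n_detected": float(detected),
    }
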
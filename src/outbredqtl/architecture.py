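"""Downstream architecture statistics for eQTL/mirQTL panels.

Covers the analyses layered on top of the scans: enrichment of wild-derived
founder alleles among QTL effects, colocalization of mRNA eQTL with miRNA
mirQTL by support-interval overlap, the global miRNA x mRNA Spearman
correlation structure with BH correction and category comparisons,
Fisher's exact association tables, diet differential expression with
abundance filters, and the ranking of allele x diet interactions by the
percent-difference divergence of founder effects between diet models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DIET_LEVELS, FOUNDER_LETTERS, FOUNDER_STRAINS, N_FOUNDERS
from .peaks import QtlPeak

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher association


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("yes", "no")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    conf_int: tuple[float, float] | None = None


def fisher_association(table: ContingencyTable2x2) -> FisherResult:
    """Sample odds ratio (a*d)/(b*c) and two-sided exact p-value.

    A zero denominator yields an infinite odds ratio (flagged via the value
    itself); the p-value is still computed from the hypergeometric
    distribution.
    """
    arr = table.as_array()
    denom = table.b * table.c
    if denom == 0:
        oratio = float("inf") if table.a * table.d > 0 else float("nan")
    else:
        oratio = (table.a * table.d) / denom
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return FisherResult(float(oratio), float(p))


# ---------------------------------------------------------------------------
# Founder-allele enrichment


@dataclass
class EnrichmentResult:
    #: peaks x 8 mean-center-scaled founder effects.
    scaled_effects: pd.DataFrame
    kruskal_statistic: float
    kruskal_p: float
    #: pairwise founder comparisons: founder_a, founder_b, z, p, p_bh.
    dunn: pd.DataFrame

    def enriched_founders(self, alpha: float = 0.05) -> list[str]:
        """Founders whose |scaled effect| is significantly larger than every
        other (non-enriched) founder's by Dunn/BH."""
        med = self.scaled_effects.abs().median(axis=0)
        sig = {}
        for _, row in self.dunn.iterrows():
            sig[(row["founder_a"], row["founder_b"])] = row["p_bh"] < alpha
            sig[(row["founder_b"], row["founder_a"])] = row["p_bh"] < alpha
        out = []
        for f in self.scaled_effects.columns:
            others = [g for g in self.scaled_effects.columns if g != f]
            beats = [g for g in others if sig[(f, g)] and med[f] > med[g]]
            if len(beats) >= len(others) - 1:  # allow one co-enriched partner
                out.append(f)
        return out


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's test from the pooled Kruskal-Wallis ranking, BH-corrected."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(labels, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"founder_a": a, "founder_b": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def founder_enrichment(
    effects: pd.DataFrame | np.ndarray,
    founder_names: tuple[str, ...] = FOUNDER_STRAINS,
) -> EnrichmentResult:
    """Test whether particular founders carry disproportionate QTL effects.

    Each peak's eight BLUP founder effects are mean-centered and scaled to
    unit SD; the Kruskal-Wallis test compares the absolute scaled effects
    across the eight founder groups and Dunn's post hoc (BH-corrected)
    locates the enriched founders.
    """
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_FOUNDERS:
        raise ValueError("effects must be peaks x 8")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 peaks")
    centered = arr - arr.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 peaks with non-degenerate effects")
    scaled = centered[keep] / sd[keep]
    scaled_df = pd.DataFrame(scaled, columns=list(founder_names))
    groups = {f: np.abs(scaled_df[f].to_numpy()) for f in founder_names}
    populated = [f for f in founder_names if len(groups[f]) > 0]
    if len(populated) < 2:
        raise ValueError("fewer than 2 founder groups populated")
    kw = stats.kruskal(*[groups[f] for f in populated])
    dunn = _dunn_posthoc(groups)
    return EnrichmentResult(scaled_df, float(kw.statistic), float(kw.pvalue), dunn)


# ---------------------------------------------------------------------------
# Colocalization


@dataclass
class ColocalizationPair:
    mirqtl: QtlPeak
    eqtl: QtlPeak
    chrom: str
    distance_mb: float

    def __post_init__(self) -> None:
        if self.distance_mb < 0:
            raise ValueError("distance must be >= 0")


def colocalize(
    eqtl_peaks: list[QtlPeak], mirqtl_peaks: list[QtlPeak]
) -> list[ColocalizationPair]:
    """All same-chromosome eQTL/mirQTL pairs with overlapping support
    intervals; distance 0 means the two map to the same marker."""
    out = []
    for mq in mirqtl_peaks:
        for eq in eqtl_peaks:
            if mq.chrom != eq.chrom:
                continue
            if mq.interval.overlaps(eq.interval):
                out.append(
                    ColocalizationPair(
                        mq, eq, mq.chrom, abs(mq.pos_mb - eq.pos_mb)
                    )
                )
    return out


# ---------------------------------------------------------------------------
# miRNA x mRNA correlation structure


@dataclass
class CorrelationSummary:
    #: per-pair records: mirna, mrna, rho, p, p_bh, significant, category,
    #: known_interaction.
    records: pd.DataFrame
    #: pairwise Wilcoxon rank-sum p-values on |rho| between eQTL categories
    #: among BH-significant correlations.
    category_tests: pd.DataFrame
    #: Fisher test of mapping status x known interaction among significant
    #: correlations.
    mapping_fisher: FisherResult
    n_significant: int


def _spearman_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every row pair of two matrices.

    Rank-transforms along individuals, then computes the Pearson correlation
    of ranks; p-values use the t approximation (the same convention as
    scipy.stats.spearmanr, which tests verify on small inputs).
    """
    n = a.shape[1]
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = (ra - ra.mean(axis=1, keepdims=True))
    rb = (rb - rb.mean(axis=1, keepdims=True))
    sa = np.sqrt((ra**2).sum(axis=1))
    sb = np.sqrt((rb**2).sum(axis=1))
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    rho = (ra @ rb.T) / np.outer(sa, sb)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1
    p[np.isnan(rho)] = np.nan
    return rho, p


def correlation_structure(
    mirna_values: pd.DataFrame,
    mrna_values: pd.DataFrame,
    mrna_categories: pd.Series,
    interaction_catalog: pd.DataFrame | None = None,
    alpha: float = 0.05,
    exclude_mrna: list[str] | None = None,
) -> CorrelationSummary:
    """Global pairwise Spearman structure between the two RNA classes.

    ``mrna_categories`` maps each mRNA to ``cis`` / ``trans`` / ``no-eqtl``;
    multi-mapping mRNAs should be passed in ``exclude_mrna`` (they are
    removed before the category comparisons, as mixed cis/trans signals
    cannot be categorized).  ``interaction_catalog`` is a two-column
    (mirna, mrna) table of validated target interactions.
    """
    shared = [i for i in mirna_values.columns if i in set(mrna_values.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared individuals")
    if exclude_mrna:
        mrna_values = mrna_values.drop(index=exclude_mrna, errors="ignore")
    a = mirna_values[shared].to_numpy(dtype=float)
    b = mrna_values[shared].to_numpy(dtype=float)
    rho, p = _spearman_matrix(a, b)
    mir_ids = np.repeat(mirna_values.index.to_numpy(), len(mrna_values))
    mrna_ids = np.tile(mrna_values.index.to_numpy(), len(mirna_values))
    flat_p = p.ravel()
    p_bh = multipletests(flat_p, method="fdr_bh")[1]
    records = pd.DataFrame(
        {
            "mirna": mir_ids,
            "mrna": mrna_ids,
            "rho": rho.ravel(),
            "p": flat_p,
            "p_bh": p_bh,
        }
    )
    records["significant"] = records["p_bh"] < alpha
    cats = mrna_categories.reindex(records["mrna"]).to_numpy()
    records["category"] = pd.Series(cats).fillna("no-eqtl").to_numpy()
    known = set()
    if interaction_catalog is not None and len(interaction_catalog):
        cols = list(interaction_catalog.columns[:2])
        known = set(
            zip(interaction_catalog[cols[0]], interaction_catalog[cols[1]])
        )
    records["known_interaction"] = [
        (mi, mr) in known for mi, mr in zip(records["mirna"], records["mrna"])
    ]

    sig = records[records["significant"]]
    rows = []
    for ca, cb in combinations(("cis", "trans", "no-eqtl"), 2):
        xa = sig.loc[sig["category"] == ca, "rho"].abs()
        xb = sig.loc[sig["category"] == cb, "rho"].abs()
        if len(xa) and len(xb):
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                {"category_a": ca, "category_b": cb, "p": float(res.pvalue)}
            )
    category_tests = pd.DataFrame(rows)

    mapping = sig["category"].isin(["cis", "trans"])
    inter = sig["known_interaction"]
    table = ContingencyTable2x2(
        int((mapping & inter).sum()),
        int((mapping & ~inter).sum()),
        int((~mapping & inter).sum()),
        int((~mapping & ~inter).sum()),
        row_labels=("mapping", "no mapping"),
        col_labels=("interaction", "no interaction"),
    )
    fisher = fisher_association(table)
    return CorrelationSummary(records, category_tests, fisher, int(sig.shape[0]))


# ---------------------------------------------------------------------------
# Differential expression


@dataclass
class FilterConfig:
    """Abundance filters applied before diet differential expression."""

    mrna_floor: float = 4.0  # log-intensity scale
    mrna_prevalence: float = 0.25
    mirna_floor: float = 50.0  # RPMMM scale
    mirna_prevalence: float = 0.25

    def __post_init__(self) -> None:
        for prev in (self.mrna_prevalence, self.mirna_prevalence):
            if not 0.0 < prev <= 1.0:
                raise ValueError("prevalence must be in (0, 1]")


def expression_filter(
    values: pd.DataFrame, floor: float, prevalence: float
) -> pd.Series:
    """Keep features at or above ``floor`` in at least ``prevalence`` of
    samples (both comparisons inclusive)."""
    frac = (values >= floor).mean(axis=1)
    return frac >= prevalence


def differential_expression(
    values: pd.DataFrame,
    feature_class: pd.Series,
    diets: pd.Series,
    filters: FilterConfig | None = None,
    alpha: float = 0.05,
    exact_max_n: int = 50,
) -> pd.DataFrame:
    """Diet differential expression by Wilcoxon rank-sum with BH correction.

    Features failing their class's abundance filter are excluded before
    testing.  The exact null distribution is used when both diet groups have
    at most ``exact_max_n`` individuals and the data are tie-free; otherwise
    the normal approximation with tie correction applies.  Direction is the
    sign of the first-diet-level minus reference median difference.
    """
    filters = filters or FilterConfig()
    diets = diets.reindex(values.columns)
    groups = diets.unique()
    if len(groups) < 2:
        raise ValueError("need two diet groups")
    g1 = values.columns[(diets == DIET_LEVELS[0]).to_numpy()]
    g2 = values.columns[(diets == DIET_LEVELS[1]).to_numpy()]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each diet group needs >= 2 individuals")

    is_mirna = (feature_class.reindex(values.index) == "mirna").to_numpy()
    keep = np.zeros(len(values), dtype=bool)
    keep[~is_mirna] = expression_filter(
        values.loc[~is_mirna], filters.mrna_floor, filters.mrna_prevalence
    ).to_numpy()
    keep[is_mirna] = expression_filter(
        values.loc[is_mirna], filters.mirna_floor, filters.mirna_prevalence
    ).to_numpy()

    rows = []
    for feat in values.index[keep]:
        x = values.loc[feat, g1].to_numpy(dtype=float)
        y = values.loc[feat, g2].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = (
            "exact"
            if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "feature": feat,
                "p": float(res.pvalue),
                "direction": float(np.sign(np.median(x) - np.median(y))),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["p", "direction", "p_bh", "significant"]
        ).rename_axis("feature")
    table = pd.DataFrame(rows).set_index("feature")
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p_bh"] < alpha
    return table


# ---------------------------------------------------------------------------
# Allele x diet interaction ranking


@dataclass
class DietInteractionRecord:
    phenotype: str
    interaction_p: float
    interaction_p_bh: float
    #: per-founder percent difference of HFCA vs HP BLUP effects.
    percent_difference: np.ndarray
    #: sum of absolute percent differences over the 8 founders.
    divergence_score: float

    def __post_init__(self) -> None:
        if self.divergence_score < 0:
            raise ValueError("divergence score must be >= 0")


def interaction_anova(
    dosages: np.ndarray,
    y: np.ndarray,
    diet: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """F-test p-value of the allele x diet block by plain least squares.

    Full model: covariates + dosages + dosage x diet; reduced: covariates +
    dosages.  No kinship -- the post-hoc ANOVA is deliberately a fixed-effects
    analysis, separate from the mixed-model scan.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    diet = np.asarray(diet, dtype=float)
    base = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base.append(cov)
    D = np.asarray(dosages, dtype=float)
    X_red = np.column_stack(base + [D])
    X_full = np.column_stack(base + [D, D * diet[:, None]])
    rss_red = _anova_rss(X_red, y)
    rss_full = _anova_rss(X_full, y)
    df_red = n - np.linalg.matrix_rank(X_red)
    df_full = n - np.linalg.matrix_rank(X_full)
    df_num = df_red - df_full
    if df_num <= 0 or df_full <= 0:
        return 1.0
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_full)
    return float(stats.f.sf(max(f, 0.0), df_num, df_full))


def _anova_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def percent_difference(
    effects_hfca: np.ndarray,
    effects_hp: np.ndarray,
    eps_fraction: float = 0.05,
) -> np.ndarray:
    """Per-founder percent change of HFCA effects with HP as reference.

    Near-zero reference effects are floored at ``eps_fraction`` times the SD
    of all sixteen effects to keep the ratio defined.
    """
    bh = np.asarray(effects_hfca, dtype=float)
    bp = np.asarray(effects_hp, dtype=float)
    pooled_sd = float(np.concatenate([bh, bp]).std(ddof=0))
    eps = eps_fraction * pooled_sd if pooled_sd > 0 else eps_fraction
    denom = np.maximum(np.abs(bp), eps if eps > 0 else np.finfo(float).tiny)
    return 100.0 * (bh - bp) / denom


def _concordant(a: QtlPeak, b: QtlPeak) -> bool:
    return (
        a.chrom == b.chrom
        and a.qtl_class == b.qtl_class
        and a.interval.overlaps(b.interval)
    )


def allele_diet_ranking(
    interactive_peaks: list[QtlPeak],
    hfca_peaks: list[QtlPeak],
    hp_peaks: list[QtlPeak],
    expression: pd.DataFrame,
    geno,
    diets: pd.Series,
    alpha: float = 0.05,
    eps_fraction: float = 0.05,
) -> list[DietInteractionRecord]:
    """Rank eQTL by diet-driven divergence of their founder effects.

    For every interactive-model eQTL the allele x diet ANOVA is run at its
    peak marker and BH-adjusted across eQTL; significant phenotypes that
    also carry a concordant eQTL (same chromosome, overlapping intervals,
    matching cis/trans class) in BOTH diet-subset models are scored by the
    sum of absolute per-founder percent differences of the HFCA vs HP BLUP
    effects (HP as reference), and returned in descending score order.
    """
    diet = (diets.reindex(expression.columns) == DIET_LEVELS[0]).to_numpy(float)
    pvals = []
    for pk in interactive_peaks:
        y = expression.loc[pk.phenotype].to_numpy(dtype=float)
        pvals.append(
            interaction_anova(geno.dosages(pk.marker), y, diet, covariates=None)
        )
    if not interactive_peaks:
        return []
    p_bh = multipletests(pvals, method="fdr_bh")[1]

    hfca_by_pheno: dict[str, list[QtlPeak]] = {}
    for pk in hfca_peaks:
        hfca_by_pheno.setdefault(pk.phenotype, []).append(pk)
    hp_by_pheno: dict[str, list[QtlPeak]] = {}
    for pk in hp_peaks:
        hp_by_pheno.setdefault(pk.phenotype, []).append(pk)

    records = []
    for pk, p, pb in zip(interactive_peaks, pvals, p_bh):
        if pb >= alpha:
            continue
        match = None
        for h in hfca_by_pheno.get(pk.phenotype, []):
            for q in hp_by_pheno.get(pk.phenotype, []):
                if _concordant(h, q):
                    match = (h, q)
                    break
            if match:
                break
        if match is None:
            logger.info(
                "phenotype %s lacks concordant eQTL in both diet models",
                pk.phenotype,
            )
            continue
        h, q = match
        if h.founder_effects is None or q.founder_effects is None:
            logger.info("phenotype %s missing founder effects; excluded", pk.phenotype)
            continue
        pct = percent_difference(
            h.founder_effects.effects, q.founder_effects.effects, eps_fraction
        )
        records.append(
            DietInteractionRecord(
                pk.phenotype, float(p), float(pb), pct, float(np.abs(pct).sum())
            )
        )
    records.sort(key=lambda r: r.divergence_score, reverse=True)
    return records


def ranking_to_frame(records: list[DietInteractionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "phenotype": r.phenotype,
            "interaction_p": r.interaction_p,
            "interaction_p_bh": r.interaction_p_bh,
            "divergence_score": r.divergence_score,
        }
        for letter, v in zip(FOUNDER_LETTERS, r.percent_difference):
            row[f"pct_diff_{letter}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
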
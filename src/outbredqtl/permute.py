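"""Empirical significance thresholds by permutation.

Per-phenotype genome-wide thresholds: the individual labels of the phenotype
are shuffled against the genotype/covariate/kinship rows, the genome-wide
maximum LOD recorded, and the process repeated to build a null distribution.
The 95th quantile of that distribution is the phenotype's individual
significance threshold at P = 0.05.

A two-stage screen reduces the cost of thresholding thousands of phenotypes:
stage one runs a small number of permutations (default 50) and keeps
phenotypes whose observed maximum LOD exceeds a deliberately conservative
threshold, the 90th quantile minus the standard error of that quantile;
stage two runs the full null (default 1000 permutations) only for those
candidates and applies the 95th-quantile threshold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanContext


@dataclass
class PermutationConfig:
    n_perm_full: int = 1000
    n_perm_screen: int = 50
    final_quantile: float = 0.95
    screen_quantile: float = 0.90
    #: quantile-SE estimator for the screen stage.
    se_method: str = "maritz_jarrett"  # or "bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.screen_quantile < self.final_quantile < 1.0:
            raise ValueError("need 0 < screen_quantile < final_quantile < 1")
        if self.n_perm_full < 2 or self.n_perm_screen < 2:
            raise ValueError("permutation counts must be >= 2")
        if self.se_method not in ("maritz_jarrett", "bootstrap"):
            raise ValueError("se_method must be 'maritz_jarrett' or 'bootstrap'")


@dataclass
class ThresholdRecord:
    phenotype: str
    threshold: float
    n_perm: int
    stage: str  # "screen" | "full"
    quantile_se: float | None = None


@dataclass
class ScreenOutcome:
    records: list[ThresholdRecord]
    candidates: list[str]
    significant: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phenotype": r.phenotype,
                    "stage": r.stage,
                    "n_perm": r.n_perm,
                    "threshold": r.threshold,
                    "quantile_se": r.quantile_se,
                }
                for r in self.records
            ]
        )


def phenotype_seed(master_seed: int, phenotype: str) -> np.random.SeedSequence:
    """Stable per-phenotype seed: adding phenotypes never changes existing
    nulls."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(phenotype.encode())]
    )


def _stage_rngs(
    master_seed: int, phenotype: str
) -> tuple[np.random.Generator, np.random.Generator]:
    screen_ss, full_ss = phenotype_seed(master_seed, phenotype).spawn(2)
    return np.random.default_rng(screen_ss), np.random.default_rng(full_ss)


def permutation_null(
    ctx: ScanContext,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Vector of genome-wide max-LOD draws under permutation of ``y``."""
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    draws = np.empty(n_perm)
    constant = float(np.std(y)) < 1e-12
    for i in range(n_perm):
        perm = rng.permutation(n)
        draws[i] = 0.0 if constant else ctx.max_lod(y[perm])
    return draws


def threshold_from_null(draws: np.ndarray, quantile: float) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty null distribution")
    return float(np.quantile(draws, quantile, method="linear"))


def maritz_jarrett_se(draws: np.ndarray, quantile: float) -> float:
    """Maritz-Jarrett standard error of an empirical quantile.

    Weights order statistics by increments of the Beta(q(n+1), (1-q)(n+1))
    CDF; the SE is the square root of the implied weighted variance.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    a = quantile * (n + 1)
    b = (1.0 - quantile) * (n + 1)
    grid = np.arange(n + 1) / n
    wts = np.diff(stats.beta.cdf(grid, a, b))
    c1 = float(wts @ x)
    c2 = float(wts @ x**2)
    return float(np.sqrt(max(c2 - c1**2, 0.0)))


def bootstrap_se(
    draws: np.ndarray,
    quantile: float,
    rng: np.random.Generator,
    n_boot: int = 200,
) -> float:
    x = np.asarray(draws, dtype=float)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = np.quantile(rng.choice(x, size=x.size, replace=True), quantile)
    return float(reps.std(ddof=1))


def full_threshold(
    ctx: ScanContext,
    y: np.ndarray,
    phenotype: str,
    config: PermutationConfig,
) -> ThresholdRecord:
    """Full-permutation threshold with the phenotype's own seeded stream.

    The stream is the same whether reached via the two-stage screen or via
    exhaustive permutation, so the two routes produce identical thresholds.
    """
    _, full_rng = _stage_rngs(config.seed, phenotype)
    draws = permutation_null(ctx, y, config.n_perm_full, full_rng)
    thr = threshold_from_null(draws, config.final_quantile)
    return ThresholdRecord(phenotype, thr, config.n_perm_full, "full")


def two_stage_screen(
    ctx: ScanContext,
    phenotypes: pd.DataFrame,
    config: PermutationConfig,
    observed_max: pd.Series | None = None,
) -> ScreenOutcome:
    """Two-stage permutation screen over a phenotype panel.

    ``phenotypes`` is features x individuals, aligned with ``ctx``.  Returns
    the per-phenotype threshold records, the stage-one candidates and the
    final significant set.
    """
    if observed_max is None:
        observed_max = pd.Series(
            {
                str(f): ctx.max_lod(phenotypes.loc[f].to_numpy(float))
                for f in phenotypes.index
            }
        )
    records: list[ThresholdRecord] = []
    candidates: list[str] = []
    significant: list[str] = []
    for f in phenotypes.index:
        pid = str(f)
        y = phenotypes.loc[f].to_numpy(float)
        screen_rng, _ = _stage_rngs(config.seed, pid)
        draws = permutation_null(ctx, y, config.n_perm_screen, screen_rng)
        q = threshold_from_null(draws, config.screen_quantile)
        if config.se_method == "bootstrap":
            se = bootstrap_se(draws, config.screen_quantile, screen_rng)
        else:
            se = maritz_jarrett_se(draws, config.screen_quantile)
        screen_thr = q - se
        records.append(
            ThresholdRecord(
                pid, screen_thr, config.n_perm_screen, "screen", quantile_se=se
            )
        )
        if observed_max[pid] > screen_thr:
            candidates.append(pid)
            rec = full_threshold(ctx, y, pid, config)
            records.append(rec)
            if observed_max[pid] > rec.threshold:
                significant.append(pid)
    return ScreenOutcome(records, candidates, significant)


def exhaustive_significant(
    ctx: ScanContext,
    phenotypes: pd.DataFrame,
    config: PermutationConfig,
    observed_max: pd.Series | None = None,
) -> tuple[list[str], list[ThresholdRecord]]:
    """Full permutation thresholds for every phenotype (no screening)."""
    if observed_max is None:
        observed_max = pd.Series(
            {
                str(f): ctx.max_lod(phenotypes.loc[f].to_numpy(float))
                for f in phenotypes.index
            }
        )
    records = []
    significant = []
    for f in phenotypes.index:
        pid = str(f)
        rec = full_threshold(ctx, phenotypes.loc[f].to_numpy(float), pid, config)
        records.append(rec)
        if observed_max[pid] > rec.threshold:
            significant.append(pid)
    return significant, records
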
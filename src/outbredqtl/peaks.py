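"""From LOD curves to classified QTL.

A phenotype's significant loci are summarized as peaks: at most one per
chromosome (the maximum-LOD marker, if it exceeds the phenotype's
permutation threshold; ties break to the smallest position).  Each peak gets
a 1.8-LOD-drop support interval (approximating 95% coverage), a cis/trans
call (cis iff the peak marker is within 4 Mb of the feature's transcription
start site on the same chromosome), the phenotypic variance explained by
plain Haley-Knott regression at the peak (full minus covariate-only R^2 --
deliberately unmixed, unlike the scan), BLUP founder effects, and the
phenotype's narrow-sense heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleProbabilityTensor
from .kinship import KinshipSet
from .scan import (
    FounderEffectVector,
    blup_effects,
    estimate_heritability,
    _null_design,
)

logger = logging.getLogger(__name__)


@dataclass
class ClassificationConfig:
    """cis window around the TSS (Mb); 1.0 reproduces the sensitivity check."""

    cis_window_mb: float = 4.0

    def __post_init__(self) -> None:
        if self.cis_window_mb <= 0:
            raise ValueError("cis window must be > 0")


@dataclass
class SupportInterval:
    chrom: str
    lower_mb: float
    upper_mb: float
    drop: float = 1.8

    def overlaps(self, other: "SupportInterval") -> bool:
        """Closed-interval overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.lower_mb <= other.upper_mb
            and other.lower_mb <= self.upper_mb
        )

    def contains(self, pos_mb: float) -> bool:
        return self.lower_mb <= pos_mb <= self.upper_mb


@dataclass
class QtlPeak:
    """One significant QTL with its full characterization."""

    phenotype: str
    feature_class: str  # "mrna" | "mirna"
    model: str
    chrom: str
    marker: str
    pos_mb: float
    lod: float
    threshold: float
    interval: SupportInterval
    qtl_class: str  # "cis" | "trans"
    variance_explained: float
    founder_effects: FounderEffectVector | None = None
    h2: float | None = None

    def __post_init__(self) -> None:
        if self.lod <= self.threshold:
            raise ValueError("peak LOD must exceed its threshold")
        if self.qtl_class not in ("cis", "trans"):
            raise ValueError("qtl_class must be 'cis' or 'trans'")
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValueError("variance explained outside [0, 1]")


def find_peaks(
    lod: np.ndarray | pd.Series,
    markers: pd.DataFrame,
    threshold: float,
) -> list[tuple[str, str, float, float]]:
    """At most one peak per chromosome exceeding the threshold (strict).

    Returns ``(chrom, marker, pos_mb, lod)`` tuples.  Ties within a
    chromosome break to the smallest position.
    """
    lod = np.asarray(lod, dtype=float)
    out = []
    for c in dict.fromkeys(markers["chrom"]):
        idx = np.flatnonzero((markers["chrom"] == c).to_numpy())
        sub = lod[idx]
        best = float(sub.max())
        if best > threshold:
            # smallest-position tie-break: first index at the max (marker
            # maps are position-sorted within chromosome)
            j = idx[int(np.flatnonzero(sub == best)[0])]
            out.append(
                (c, str(markers.index[j]), float(markers["pos_mb"].iloc[j]), best)
            )
    return out


def support_interval(
    lod: np.ndarray | pd.Series,
    markers: pd.DataFrame,
    peak_marker: str,
    drop: float = 1.8,
) -> SupportInterval:
    """LOD-drop support interval around a peak on its chromosome.

    Walking outward from the peak, each bound is the position of the first
    marker whose LOD is ``drop`` or more below the peak LOD; if no such
    marker exists before the chromosome end, the bound is censored at the
    outermost marker.
    """
    lod = np.asarray(lod, dtype=float)
    j = int(markers.index.get_loc(peak_marker))
    chrom = markers["chrom"].iloc[j]
    idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
    sub_lod = lod[idx]
    sub_pos = markers["pos_mb"].to_numpy()[idx]
    k = int(np.flatnonzero(idx == j)[0])
    cutoff = sub_lod[k] - drop
    lower = sub_pos[0]
    for i in range(k - 1, -1, -1):
        if sub_lod[i] <= cutoff:
            lower = sub_pos[i]
            break
    upper = sub_pos[-1]
    for i in range(k + 1, len(idx)):
        if sub_lod[i] <= cutoff:
            upper = sub_pos[i]
            break
    return SupportInterval(str(chrom), float(lower), float(upper), drop)


def classify_peak(
    peak_chrom: str,
    peak_pos_mb: float,
    tss_chrom: str,
    tss_mb: float,
    config: ClassificationConfig | None = None,
) -> str:
    """cis iff same chromosome and |peak - TSS| <= window (inclusive)."""
    window = (config or ClassificationConfig()).cis_window_mb
    if str(peak_chrom) == str(tss_chrom) and abs(peak_pos_mb - tss_mb) <= window:
        return "cis"
    return "trans"


def variance_explained(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Haley-Knott R^2 difference: full (covariates + dosages) minus null
    (covariates only), by plain least squares with no kinship."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("degenerate phenotype: zero variance")
    X0 = _null_design(n, covariates)
    X1 = np.column_stack([X0, np.asarray(dosages, dtype=float)])
    r0 = _ls_rss(X0, y)
    r1 = _ls_rss(X1, y)
    return float(np.clip((r0 - r1) / tss, 0.0, 1.0))


def _ls_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def characterize_phenotype(
    geno: AlleleProbabilityTensor,
    y: np.ndarray,
    phenotype: str,
    feature_class: str,
    tss_chrom: str,
    tss_mb: float,
    lod: np.ndarray | pd.Series,
    threshold: float,
    model: str,
    covariates: np.ndarray | None = None,
    kinship: KinshipSet | None = None,
    config: ClassificationConfig | None = None,
    drop: float = 1.8,
) -> list[QtlPeak]:
    """All significant peaks of one phenotype, fully characterized.

    Features without an annotated TSS cannot be classified and yield no
    peaks (a warning is logged).
    """
    if tss_chrom is None or (isinstance(tss_mb, float) and np.isnan(tss_mb)):
        logger.warning("feature %s has no TSS annotation; skipped", phenotype)
        return []
    config = config or ClassificationConfig()
    peaks: list[QtlPeak] = []
    h2 = None
    if kinship is not None:
        h2 = estimate_heritability(y, kinship.full, covariates, phenotype).h2
    for chrom, marker, pos, peak_lod in find_peaks(lod, geno.markers, threshold):
        interval = support_interval(lod, geno.markers, marker, drop)
        qclass = classify_peak(chrom, pos, tss_chrom, tss_mb, config)
        ve = variance_explained(geno.dosages(marker), y, covariates)
        effects = None
        if kinship is not None:
            effects = blup_effects(
                geno, marker, y, covariates, kinship.loco[chrom], phenotype
            )
        else:
            effects = blup_effects(geno, marker, y, covariates, None, phenotype)
        peaks.append(
            QtlPeak(
                phenotype=phenotype,
                feature_class=feature_class,
                model=model,
                chrom=chrom,
                marker=marker,
                pos_mb=pos,
                lod=peak_lod,
                threshold=threshold,
                interval=interval,
                qtl_class=qclass,
                variance_explained=ve,
                founder_effects=effects,
                h2=h2,
            )
        )
    return peaks


def peaks_to_frame(peaks: list[QtlPeak]) -> pd.DataFrame:
    """QTL table mirroring the supplementary-table schema."""
    from .data import FOUNDER_LETTERS

    rows = []
    for p in peaks:
        row = {
            "phenotype": p.phenotype,
            "class": p.feature_class,
            "model": p.model,
            "chrom": p.chrom,
            "marker": p.marker,
            "peak_mb": p.pos_mb,
            "lod": p.lod,
            "threshold": p.threshold,
            "ci_lo": p.interval.lower_mb,
            "ci_hi": p.interval.upper_mb,
            "cis_trans": p.qtl_class,
            "var_explained": p.variance_explained,
            "h2": p.h2,
        }
        eff = (
            p.founder_effects.effects
            if p.founder_effects is not None
            else [np.nan] * 8
        )
        for letter, e in zip(FOUNDER_LETTERS, eff):
            row[f"effect_{letter}"] = e
        rows.append(row)
    return pd.DataFrame(rows)
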
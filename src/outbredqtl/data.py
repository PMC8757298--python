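"""Core containers for Diversity Outbred genotype and expression data.

The Diversity Outbred (DO) population descends from eight founder strains,
five classical inbred (A/J, C57BL/6J, 129S1/SvImJ, NOD/LtJ, NZO/HlLtJ) and
three wild-derived (CAST/EiJ, PWK/PhJ, WSB/EiJ).  Every DO genome is a mosaic
of founder haplotypes, and genetic mapping works on the reduced representation
of per-marker probabilities over the eight founders rather than on SNP
genotypes.  The containers here hold that representation together with the
expression phenotypes and sample covariates every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical DO founder order (letters A-H).
FOUNDER_STRAINS = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/LtJ",
    "NZO/HlLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)
FOUNDER_LETTERS = tuple("ABCDEFGH")
#: Indices of the wild-derived founders (CAST/EiJ, PWK/PhJ, WSB/EiJ).
WILD_DERIVED = (5, 6, 7)
N_FOUNDERS = 8

#: Default two-level diet factor: atherogenic high-fat cholic-acid diet vs
#: high-protein diet.  HP serves as the reference level throughout.
DIET_LEVELS = ("HFCA", "HP")


@dataclass
class AlleleProbabilityTensor:
    """Founder allele probabilities for a cohort.

    Parameters
    ----------
    probs
        Array of shape ``(n_individuals, n_markers, 8)``; each
        ``(individual, marker)`` slice is a probability vector over the eight
        founders (homolog-averaged dosage scale, so it sums to 1).
    individuals
        Sample identifiers, aligned with the first axis.
    markers
        Marker map indexed by marker name with columns ``chrom`` (string) and
        ``pos_mb`` (position in megabases).
    """

    probs: np.ndarray
    individuals: list[str]
    markers: pd.DataFrame
    founders: tuple[str, ...] = FOUNDER_STRAINS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_FOUNDERS:
            raise ValueError(
                f"probs must have shape (n, M, {N_FOUNDERS}); got {self.probs.shape}"
            )
        n, m, _ = self.probs.shape
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match probs")
        if len(self.markers) != m:
            raise ValueError("marker map length does not match probs")
        if not {"chrom", "pos_mb"}.issubset(self.markers.columns):
            raise ValueError("marker map needs 'chrom' and 'pos_mb' columns")
        if self.markers["pos_mb"].isna().any():
            bad = self.markers.index[self.markers["pos_mb"].isna()].tolist()
            raise ValueError(f"NaN positions for markers {bad}")

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.probs.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in marker-map order."""
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def marker_index(self, marker: str) -> int:
        return int(self.markers.index.get_loc(marker))

    def dosages(self, marker: str) -> np.ndarray:
        """``(n, 8)`` founder dosages at one marker."""
        return self.probs[:, self.marker_index(marker), :]

    def subset(self, mask: np.ndarray) -> "AlleleProbabilityTensor":
        """Restrict to a boolean/index subset of individuals."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AlleleProbabilityTensor(
            self.probs[idx],
            [self.individuals[i] for i in idx],
            self.markers,
            self.founders,
        )

    def validate_simplex(self, atol: float = 1e-9) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("allele-probability slices do not sum to 1")


@dataclass
class ExpressionPanel:
    """Expression phenotypes plus feature annotations and sample covariates.

    ``values`` is features x individuals (mRNA on a log-intensity scale,
    miRNA on a nonnegative RPMMM-like scale).  ``annotations`` is indexed by
    feature with columns ``chrom``, ``tss_mb`` and ``feature_class``
    (``"mrna"`` or ``"mirna"``).  ``covariates`` is indexed by individual with
    at least a ``diet`` column.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.annotations.index):
            missing = self.values.index.difference(self.annotations.index)
            if len(missing):
                raise ValueError(f"features missing annotations: {list(missing)[:5]}")
            self.annotations = self.annotations.loc[self.values.index]
        if list(self.values.columns) != list(self.covariates.index):
            extra = self.values.columns.difference(self.covariates.index)
            if len(extra):
                raise ValueError(f"individuals missing covariates: {list(extra)[:5]}")
            self.covariates = self.covariates.loc[self.values.columns]

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def of_class(self, feature_class: str) -> "ExpressionPanel":
        keep = self.annotations["feature_class"] == feature_class
        return ExpressionPanel(
            self.values.loc[keep.to_numpy()],
            self.annotations.loc[keep.to_numpy()],
            self.covariates,
        )

    def phenotype(self, feature: str) -> np.ndarray:
        return self.values.loc[feature].to_numpy(dtype=float)

    def diet_indicator(self, level: str = DIET_LEVELS[0]) -> np.ndarray:
        """0/1 indicator of ``level`` (default HFCA; HP is the reference)."""
        return (self.covariates["diet"] == level).to_numpy(dtype=float)


def align_to_individuals(
    geno: AlleleProbabilityTensor, panel: ExpressionPanel
) -> tuple[AlleleProbabilityTensor, ExpressionPanel]:
    """Align genotypes and expression on their shared individuals.

    Raises a descriptive error when one table lists individuals the other
    lacks; reorders otherwise.
    """
    g = set(geno.individuals)
    p = set(panel.individuals)
    only_g = sorted(g - p)
    only_p = sorted(p - g)
    if only_g or only_p:
        raise ValueError(
            "individuals not shared across inputs: "
            f"genotypes-only={only_g[:5]}, expression-only={only_p[:5]}"
        )
    order = [i for i in geno.individuals]
    panel2 = ExpressionPanel(
        panel.values[order], panel.annotations, panel.covariates.loc[order]
    )
    return geno, panel2
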
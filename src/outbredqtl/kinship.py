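"""Kinship matrices from founder allele probabilities.

Relatedness between two individuals is measured as the marker-averaged
probability that they carry the same founder allele,

    K_ij = (1/M) sum_m sum_f p_imf * p_jmf ,

the standard genetic-relationship construction for multiparent allele
probabilities.  Genome scans use the leave-one-chromosome-out (LOCO)
variant: the kinship used while scanning chromosome c excludes all of c's
markers, avoiding proximal contamination of the polygenic term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import AlleleProbabilityTensor


@dataclass
class KinshipSet:
    """Full kinship plus per-chromosome LOCO matrices."""

    full: np.ndarray
    loco: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not np.allclose(self.full, self.full.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.full.shape[0]

    def subset(self, idx: np.ndarray) -> "KinshipSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return KinshipSet(
            self.full[np.ix_(idx, idx)],
            {c: K[np.ix_(idx, idx)] for c, K in self.loco.items()},
        )


def overall_kinship(geno: AlleleProbabilityTensor) -> np.ndarray:
    """Single full kinship matrix over all markers."""
    n, m, f = geno.probs.shape
    flat = geno.probs.reshape(n, m * f)
    return (flat @ flat.T) / m


def loco_kinship(geno: AlleleProbabilityTensor) -> KinshipSet:
    """Full and leave-one-chromosome-out kinship matrices.

    With a single chromosome the LOCO exclusion would empty the kinship;
    a zero matrix is substituted with a warning (the scan then reduces to
    plain least squares).
    """
    n, m, f = geno.probs.shape
    chroms = geno.chromosomes
    per_chrom: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    total = np.zeros((n, n))
    for c in chroms:
        idx = geno.chrom_indices(c)
        flat = geno.probs[:, idx, :].reshape(n, len(idx) * f)
        s = flat @ flat.T
        per_chrom[c] = s
        counts[c] = len(idx)
        total += s
    full = total / m
    loco: dict[str, np.ndarray] = {}
    if len(chroms) == 1:
        warnings.warn(
            "single-chromosome input: LOCO kinship falls back to a zero matrix",
            stacklevel=2,
        )
        loco[chroms[0]] = np.zeros((n, n))
    else:
        for c in chroms:
            loco[c] = (total - per_chrom[c]) / (m - counts[c])
    return KinshipSet(full, loco)
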
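"""Linear mixed model genome scans over founder allele probabilities.

The model at a marker is Haley-Knott regression of the phenotype on the
eight founder dosages inside a mixed model that controls for population
structure,

    y = X beta + g + e,   g ~ N(0, sigma_g^2 K_LOCO),  e ~ N(0, sigma_e^2 I).

Variance components are estimated once per (phenotype x LOCO chromosome)
under the null by REML (a single eigendecomposition of K plus a bounded 1-D
optimization over the heritability ratio) and held fixed across that
chromosome's markers.  The LOD at a marker is then

    LOD = (n / 2) * log10(RSS_0 / RSS_1)

computed in the whitened space defined by those components, where the full
model adds the eight allele-dosage columns (cell-means coding: the marker
block replaces the intercept) and, in the interactive model, the
dosage x covariate products.  With the kinship zeroed the whitening is the
identity and the LOD reduces to the plain least-squares closed form.

Founder effects at a marker are best linear unbiased predictions (BLUPs):
the dosages are treated as a random effect with its own REML-estimated
variance, giving ridge-shrunken per-founder coefficients in the canonical
A-H founder order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .data import N_FOUNDERS, AlleleProbabilityTensor
from .kinship import KinshipSet

MODEL_TAGS = ("additive", "interactive", "subset-HFCA", "subset-HP")

_RSS_FLOOR = 1e-14  # relative floor keeping LOD finite on perfect fits


@dataclass
class VarianceComponents:
    """REML null-model variance components for one phenotype/kinship."""

    sigma_g: float
    sigma_e: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g + self.sigma_e
        return self.sigma_g / tot if tot > 0 else 0.0


@dataclass
class FounderEffectVector:
    """BLUP founder coefficients at one marker (canonical A-H order)."""

    phenotype: str
    marker: str
    effects: np.ndarray  # (8,)
    intercept: float

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (N_FOUNDERS,):
            raise ValueError("founder effect vector must have 8 entries")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("non-finite founder effects")


@dataclass
class HeritabilityEstimate:
    phenotype: str
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 outside [0, 1]")


@dataclass
class ScanResult:
    """LOD per (marker, phenotype) for one model."""

    lod: pd.DataFrame  # markers x phenotypes
    model: str
    #: phenotype -> chromosome -> VarianceComponents under the null.
    null_components: dict[str, dict[str, VarianceComponents]] = field(
        default_factory=dict
    )

    def max_lod(self, phenotype: str) -> float:
        return float(self.lod[phenotype].max())


def _check_design(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise naming the collinear columns if the design is singular."""
    n, p = X.shape
    if names is None:
        names = [f"col{i}" for i in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank >= p:
        return
    # identify dependent columns greedily
    bad = []
    kept: list[int] = []
    for j in range(p):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    raise ValueError(f"singular fixed-effect design; collinear columns: {bad}")


class _RemlObjective:
    """Concentrated REML criterion with precomputed sufficient statistics.

    Working in the kinship eigenbasis, every evaluation at a heritability
    ``h2`` needs only ``X' W^-1 X``, ``X' W^-1 y`` and ``y' W^-1 y`` for the
    diagonal ``W = h2 s + (1 - h2)``; all three are linear in ``1/w``, so a
    single matvec against the stacked per-observation products suffices.
    """

    def __init__(self, y_r: np.ndarray, X_r: np.ndarray, s: np.ndarray) -> None:
        n, p = X_r.shape
        self.n, self.p, self.s = n, p, s
        outer = np.einsum("ni,nj->nij", X_r, X_r).reshape(n, p * p)
        self.M = np.column_stack([outer, X_r * y_r[:, None], y_r * y_r])

    def _gls(self, h2: float) -> tuple[float, float, np.ndarray]:
        """(rss_w, logdet) at h2, plus the weight vector."""
        w = h2 * self.s + (1.0 - h2)
        v = (1.0 / w) @ self.M
        p = self.p
        G = v[: p * p].reshape(p, p)
        xty = v[p * p : p * p + p]
        yWy = float(v[-1])
        if p == 1 and G[0, 0] > 0:
            rss = yWy - xty[0] ** 2 / G[0, 0]
            logdet = float(np.log(G[0, 0]))
        elif p == 2:
            det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
            if det <= 0:
                return self._gls_generic(G, xty, yWy, w)
            beta0 = (G[1, 1] * xty[0] - G[0, 1] * xty[1]) / det
            beta1 = (-G[1, 0] * xty[0] + G[0, 0] * xty[1]) / det
            rss = yWy - (beta0 * xty[0] + beta1 * xty[1])
            logdet = float(np.log(det))
        else:
            return self._gls_generic(G, xty, yWy, w)
        return max(float(rss), 0.0), logdet, w

    @staticmethod
    def _gls_generic(G, xty, yWy, w) -> tuple[float, float, np.ndarray]:
        try:
            beta = np.linalg.solve(G, xty)
            sign, logdet = np.linalg.slogdet(G)
            if sign <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(G, hermitian=True) @ xty
            ev = np.linalg.eigvalsh(G)
            logdet = float(np.log(ev[ev > 1e-12 * max(ev.max(), 1.0)]).sum())
        return max(float(yWy - beta @ xty), 0.0), float(logdet), w

    def __call__(self, h2: float) -> float:
        rss, logdet, w = self._gls(h2)
        return (
            (self.n - self.p) * np.log(max(rss, 1e-300))
            + float(np.log(w).sum())
            + logdet
        )

    def sigma_tot(self, h2: float) -> float:
        return self._gls(h2)[0] / max(self.n - self.p, 1)


def _reml_h2(
    y_r: np.ndarray,
    X_r: np.ndarray,
    s: np.ndarray,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Concentrated REML over h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

    Inputs are already rotated into the kinship eigenbasis (``s`` holds the
    eigenvalues).  Returns ``(h2, sigma_tot)`` with
    ``sigma_g^2 = h2 * sigma_tot`` and ``sigma_e^2 = (1 - h2) * sigma_tot``.
    When the eigenvalue spectrum is flat (K proportional to the identity, or
    zero) the likelihood does not depend on h2 and 0 is returned.
    """
    n, p = X_r.shape
    smax = float(s.max(initial=0.0))
    if smax <= 0 or float(np.ptp(s)) < 1e-10 * max(1.0, smax):
        rss = _weighted_rss(y_r, X_r, np.ones(n))[0]
        return 0.0, rss / max(n - p, 1)
    obj = _RemlObjective(y_r, X_r, s)
    res = minimize_scalar(
        obj, bounds=(0.0, 1.0 - 1e-9), method="bounded", options={"xatol": tol}
    )
    h2 = float(res.x)
    # the bounded optimizer never evaluates the exact boundary; check it
    if obj(0.0) <= res.fun:
        h2 = 0.0
    return h2, obj.sigma_tot(h2)


def _weighted_rss(
    y_r: np.ndarray, X_r: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """GLS residual sum of squares and log|X' W^-1 X| for diagonal W."""
    inv_w = 1.0 / w
    Xw = X_r * inv_w[:, None]  # W^-1 X
    G = X_r.T @ Xw
    xty = Xw.T @ y_r
    try:
        L = np.linalg.cholesky(G)
        beta = np.linalg.solve(G, xty)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
    except np.linalg.LinAlgError:
        # rank-deficient design: pseudo-inverse and pseudo-determinant
        beta = np.linalg.pinv(G, hermitian=True) @ xty
        ev = np.linalg.eigvalsh(G)
        logdet = float(np.log(ev[ev > 1e-12 * max(ev.max(), 1.0)]).sum())
    r = y_r - X_r @ beta
    return float(np.dot(r * inv_w, r)), float(logdet)


def fit_null(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    covariate_names: list[str] | None = None,
) -> VarianceComponents:
    """REML variance components under the no-marker null model.

    ``covariates`` excludes the intercept, which is always included.
    Raises on a singular fixed-effect design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = _null_design(n, covariates)
    names = ["intercept"] + (
        covariate_names
        if covariate_names is not None
        else [f"covar{i + 1}" for i in range(X.shape[1] - 1)]
    )
    _check_design(X, names)
    if n < X.shape[1] + 2:
        raise ValueError("too few individuals for the fixed-effect design")
    s, U = _eigendecompose(K)
    y_r = U.T @ y
    X_r = U.T @ X
    h2, sigma_tot = _reml_h2(y_r, X_r, s)
    return VarianceComponents(h2 * sigma_tot, (1.0 - h2) * sigma_tot)


def _null_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, U = np.linalg.eigh(K)
    return np.clip(s, 0.0, None), U


class ScanContext:
    """Precomputed state for scanning many phenotypes on one design.

    Holds, per chromosome, the eigendecomposition of the LOCO kinship and the
    rotated covariate/marker blocks, so scanning a phenotype (or one of its
    permutations) costs one rotation, one 1-D REML fit per chromosome, and a
    batched GLS solve across that chromosome's markers.
    """

    def __init__(
        self,
        geno: AlleleProbabilityTensor,
        covariates: np.ndarray | None = None,
        covariate_names: list[str] | None = None,
        kinship: KinshipSet | None = None,
        model: str = "additive",
        interactive: np.ndarray | None = None,
    ) -> None:
        if model not in MODEL_TAGS:
            raise ValueError(f"model must be one of {MODEL_TAGS}")
        if model == "interactive" and interactive is None:
            raise ValueError("interactive model requires an interactive covariate")
        self.geno = geno
        self.model = model
        self.n = geno.n_individuals
        cov = None
        if covariates is not None and np.size(covariates) > 0:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != self.n:
                cov = cov.T
        self.covariates = cov
        self.covariate_names = covariate_names
        self.interactive = (
            np.asarray(interactive, dtype=float) if interactive is not None else None
        )
        X0 = _null_design(self.n, cov)
        names = ["intercept"] + (
            covariate_names
            if covariate_names is not None
            else [f"covar{i + 1}" for i in range(X0.shape[1] - 1)]
        )
        _check_design(X0, names)

        # fixed block of the full model: covariates without intercept; in the
        # interactive model, columns identical to the interactive covariate
        # are dropped (they are spanned by the dosage x covariate products)
        if cov is None:
            F = np.empty((self.n, 0))
        elif model == "interactive":
            keep = [
                j
                for j in range(cov.shape[1])
                if not np.allclose(cov[:, j], self.interactive)
            ]
            F = cov[:, keep]
        else:
            F = cov

        self._chrom: list[dict] = []
        for c in geno.chromosomes:
            idx = geno.chrom_indices(c)
            P = geno.probs[:, idx, :]  # (n, Mc, 8)
            if kinship is not None and np.any(kinship.loco[c]):
                s, U = _eigendecompose(kinship.loco[c])
            else:
                s, U = np.zeros(self.n), None
            entry = {
                "chrom": c,
                "idx": idx,
                "s": s,
                "U": U,
                "X0": _rotate(U, X0),
                "F": _rotate(U, F),
                "P": _rotate_tensor(U, P),
            }
            if model == "interactive":
                entry["PX"] = _rotate_tensor(U, P * self.interactive[:, None, None])
            self._chrom.append(entry)

    # -- scanning ---------------------------------------------------------

    def scan_phenotype(
        self, y: np.ndarray
    ) -> tuple[np.ndarray, dict[str, VarianceComponents]]:
        """LOD at every marker plus per-chromosome null components."""
        y = np.asarray(y, dtype=float)
        lod = np.zeros(self.geno.n_markers)
        components: dict[str, VarianceComponents] = {}
        if float(np.std(y)) < 1e-12:
            warnings.warn("constant phenotype: LOD is 0 everywhere", stacklevel=2)
            for entry in self._chrom:
                components[entry["chrom"]] = VarianceComponents(0.0, 0.0)
            return lod, components
        for entry in self._chrom:
            y_r = entry["U"].T @ y if entry["U"] is not None else y
            h2, sigma_tot = _reml_h2(y_r, entry["X0"], entry["s"])
            components[entry["chrom"]] = VarianceComponents(
                h2 * sigma_tot, (1.0 - h2) * sigma_tot
            )
            w = h2 * entry["s"] + (1.0 - h2)
            lod[entry["idx"]] = self._chrom_lods(entry, y_r, w)
        return lod, components

    def _chrom_lods(self, entry: dict, y_r: np.ndarray, w: np.ndarray) -> np.ndarray:
        n = self.n
        d = 1.0 / np.sqrt(w)
        yw = y_r * d
        yty = float(yw @ yw)
        # null RSS
        X0w = entry["X0"] * d[:, None]
        rss0, _ = _plain_rss(X0w, yw, yty)
        # full-model blocks
        blocks = [entry["P"] * d[None, :, None]]
        if self.model == "interactive":
            blocks.append(entry["PX"] * d[None, :, None])
        Fw = entry["F"] * d[:, None]
        rss1 = _batched_marker_rss(Fw, blocks, yw, yty)
        rss1 = np.minimum(rss1, rss0)
        floor = _RSS_FLOOR * max(yty, 1e-300)
        rss1 = np.maximum(rss1, floor)
        if rss0 <= floor:
            return np.zeros(len(rss1))
        return (n / 2.0) * np.log10(rss0 / rss1)

    def max_lod(self, y: np.ndarray) -> float:
        return float(self.scan_phenotype(y)[0].max())


def _rotate(U: np.ndarray | None, X: np.ndarray) -> np.ndarray:
    return X if U is None or X.size == 0 else U.T @ X


def _rotate_tensor(U: np.ndarray | None, P: np.ndarray) -> np.ndarray:
    """Rotate an (n, Mc, 8) block to (Mc, n, 8) in the eigenbasis."""
    if U is None:
        return np.ascontiguousarray(P.transpose(1, 0, 2))
    out = np.tensordot(U.T, P, axes=(1, 0))  # (n, Mc, 8)
    return np.ascontiguousarray(out.transpose(1, 0, 2))


def _plain_rss(Xw: np.ndarray, yw: np.ndarray, yty: float) -> tuple[float, np.ndarray]:
    G = Xw.T @ Xw
    xty = Xw.T @ yw
    beta = np.linalg.pinv(G, hermitian=True) @ xty
    return float(yty - beta @ xty), beta


def _batched_marker_rss(
    Fw: np.ndarray, blocks: list[np.ndarray], yw: np.ndarray, yty: float
) -> np.ndarray:
    """RSS of [F, block_1(m), block_2(m), ...] for every marker m at once."""
    mc = blocks[0].shape[0]
    p0 = Fw.shape[1]
    widths = [b.shape[2] for b in blocks]
    k = p0 + sum(widths)
    XtX = np.empty((mc, k, k))
    Xty = np.empty((mc, k))
    if p0:
        XtX[:, :p0, :p0] = Fw.T @ Fw
        Xty[:, :p0] = Fw.T @ yw
    offs = [p0]
    for wdt in widths:
        offs.append(offs[-1] + wdt)
    for a, Ba in enumerate(blocks):
        ia, ja = offs[a], offs[a + 1]
        if p0:
            FtB = np.einsum("np,mnf->mpf", Fw, Ba, optimize=True)
            XtX[:, :p0, ia:ja] = FtB
            XtX[:, ia:ja, :p0] = FtB.transpose(0, 2, 1)
        Xty[:, ia:ja] = np.einsum("mnf,n->mf", Ba, yw, optimize=True)
        for b in range(a, len(blocks)):
            Bb = blocks[b]
            ib, jb = offs[b], offs[b + 1]
            AtB = np.einsum("mnf,mng->mfg", Ba, Bb, optimize=True)
            XtX[:, ia:ja, ib:jb] = AtB
            if b != a:
                XtX[:, ib:jb, ia:ja] = AtB.transpose(0, 2, 1)
    beta = _batched_normal_solve(XtX, Xty)
    return yty - np.einsum("mk,mk->m", beta, Xty)


def _batched_normal_solve(XtX: np.ndarray, Xty: np.ndarray) -> np.ndarray:
    """Solve the per-marker normal equations, batched.

    Fast LU path with a verified fallback: markers whose solution does not
    actually satisfy the normal equations (rank-deficient designs, e.g. a
    founder entirely absent under hard probabilities) are redone with the
    pseudo-inverse, matching least-squares semantics.
    """
    try:
        beta = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return (np.linalg.pinv(XtX, hermitian=True, rcond=1e-12) @ Xty[:, :, None])[
            :, :, 0
        ]
    resid = np.einsum("mij,mj->mi", XtX, beta) - Xty
    scale = np.abs(Xty).max(axis=1) + np.abs(XtX).max(axis=(1, 2))
    bad = ~np.isfinite(beta).all(axis=1) | (
        np.abs(resid).max(axis=1) > 1e-8 * np.maximum(scale, 1e-300)
    )
    if np.any(bad):
        beta[bad] = (
            np.linalg.pinv(XtX[bad], hermitian=True, rcond=1e-12)
            @ Xty[bad][:, :, None]
        )[:, :, 0]
    return beta


def scan(
    geno: AlleleProbabilityTensor,
    phenotypes: pd.DataFrame | pd.Series | np.ndarray,
    covariates: np.ndarray | None = None,
    kinship: KinshipSet | None = None,
    model: str = "additive",
    interactive: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> ScanResult:
    """Genome scan of one or many phenotypes.

    ``phenotypes`` may be a single vector, a Series, or a features x
    individuals DataFrame.  Fitting is deterministic given the inputs.
    """
    ctx = ScanContext(
        geno, covariates, covariate_names, kinship, model, interactive
    )
    if isinstance(phenotypes, pd.DataFrame):
        items = [(str(f), phenotypes.loc[f].to_numpy(float)) for f in phenotypes.index]
    elif isinstance(phenotypes, pd.Series):
        items = [(str(phenotypes.name or "phenotype"), phenotypes.to_numpy(float))]
    else:
        arr = np.asarray(phenotypes, dtype=float)
        if arr.ndim == 1:
            items = [("phenotype", arr)]
        else:
            items = [(f"phenotype{i + 1}", row) for i, row in enumerate(arr)]
    lods = {}
    comps = {}
    for name, y in items:
        lod, comp = ctx.scan_phenotype(y)
        lods[name] = lod
        comps[name] = comp
    lod_df = pd.DataFrame(lods, index=geno.markers.index)
    return ScanResult(lod_df, model, comps)


def blup_effects(
    geno: AlleleProbabilityTensor,
    marker: str,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    kinship_matrix: np.ndarray | None = None,
    phenotype: str = "phenotype",
) -> FounderEffectVector:
    """BLUP founder coefficients at one marker.

    The phenotype is first whitened by the null-model kinship fit, then the
    eight founder dosages enter as a random effect whose variance ratio is
    estimated by REML; the returned coefficients are the ridge-shrunken
    founder deviations around an explicit intercept, so their L2 norm never
    exceeds that of the unpenalized least-squares solution on the same
    whitened design.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Z = geno.dosages(marker)
    represented = (Z.max(axis=0) > 1e-6).sum()
    if represented < 2:
        raise ValueError(f"fewer than 2 founders represented at {marker}")
    X = _null_design(n, covariates)
    if kinship_matrix is not None and np.any(kinship_matrix):
        s, U = _eigendecompose(kinship_matrix)
        y_r, X_r, Z_r = U.T @ y, U.T @ X, U.T @ Z
        h2, _ = _reml_h2(y_r, X_r, s)
        d = 1.0 / np.sqrt(h2 * s + (1.0 - h2))
        yw, Xw, Zw = y_r * d, X_r * d[:, None], Z_r * d[:, None]
    else:
        yw, Xw, Zw = y, X, Z

    # residualize against the fixed block
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    Z_res = Zw - Q @ (Q.T @ Zw)

    # REML for the dosage random effect: V = sigma_e^2 (I + gamma Z Z')
    Uz, dz, _ = np.linalg.svd(Z_res, full_matrices=True)
    ev = np.zeros(n)
    ev[: len(dz)] = dz**2
    y2 = Uz.T @ yw
    X2 = Uz.T @ Xw

    def neg2(log_gamma: float) -> float:
        w = 1.0 + np.exp(log_gamma) * ev
        rss, logdet = _weighted_rss(y2, X2, w)
        p = X2.shape[1]
        return (n - p) * np.log(max(rss, 1e-300)) + float(np.log(w).sum()) + logdet

    res = minimize_scalar(
        neg2, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-8}
    )
    gamma = float(np.exp(res.x))
    if neg2(-30.0) <= res.fun:  # effectively no marker variance
        gamma = 0.0
    if gamma == 0.0:
        u = np.zeros(N_FOUNDERS)
    else:
        G = Z_res.T @ Z_res + (1.0 / gamma) * np.eye(N_FOUNDERS)
        u = np.linalg.solve(G, Z_res.T @ y_res)
    beta, *_ = np.linalg.lstsq(Xw, yw - Zw @ u, rcond=None)
    return FounderEffectVector(phenotype, marker, u, float(beta[0]))


def estimate_heritability(
    y: np.ndarray,
    full_kinship: np.ndarray,
    covariates: np.ndarray | None = None,
    phenotype: str = "phenotype",
) -> HeritabilityEstimate:
    """Narrow-sense heritability from the single full (non-LOCO) kinship."""
    vc = fit_null(y, covariates, full_kinship)
    return HeritabilityEstimate(phenotype, float(np.clip(vc.h2, 0.0, 1.0)))
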
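"""Q+K mixed-model genome scan: realized kinship, REML, EMMAX/P3D F-tests.

The model for a phenotype vector y is

    y = X beta + Q v + u + eps,   Var(u) = K sigma_G^2,  Var(eps) = R sigma_e^2

with X the per-locus incidence matrix (intercept + allele-dosage columns),
Q optional fixed structure covariates, K the realized-relationship kinship
matrix and R a diagonal weight matrix (identity for one observation per
genotype, the default). Variance components are estimated once by REML on
the no-marker null model via a spectral decomposition of K and a 1-D
search over the variance ratio, then recycled at every tested locus
(the EMMAX/P3D approximation); each locus is tested with a generalized
least squares F-test of the joint null that all of its allele-effect
coefficients are zero.

Kinship is computed as K = D D^t / Delta with D a column-centered dosage
matrix (SNP dosages, or concatenated per-allele dosages for multiallelic
markers) and Delta the mean diagonal of D D^t, on a thinned subset of one
marker per cM to mitigate marker-density bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .encoding import LocusSet, build_haploblocks, haploblock_map, ibd_loci, snp_dosages, _dosage_locus
from .genmap import GeneticMap
from .population import PhasedPopulation

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "ScanResult",
    "GenomeScanner",
    "thin_one_per_cM",
    "realized_kinship",
    "kinship_for_model",
    "reml_null",
    "reml_profile_loglik",
    "scan",
    "permutation_threshold",
]

_RANK_TOL = 1e-10
_PSD_TOL = 1e-8
LOG_RATIO_BOUNDS = (-10.0, 10.0)


@dataclass
class KinshipMatrix:
    """Realized-relationship matrix K = DD^t / Delta (mean diagonal = 1)."""

    values: np.ndarray
    delta: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceComponents:
    """REML estimates of the null-model variance components."""

    sigma_g2: float
    sigma_e2: float
    loglik: float = float("nan")

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def ratio(self) -> float:
        """lambda = sigma_G^2 / sigma_e^2."""
        return self.sigma_g2 / self.sigma_e2 if self.sigma_e2 > 0 else math.inf


@dataclass
class ScanResult:
    """Per-locus association results on the -log10 p scale."""

    table: pd.DataFrame  # locus, chromosome, position_cM, F, df1, neglog10p, flag
    model: str
    vc: VarianceComponents

    def max_neglog10p(self) -> float:
        return float(self.table["neglog10p"].max())


def thin_one_per_cM(gmap: GeneticMap) -> np.ndarray:
    """Evenly spaced marker subset: nearest marker to each integer cM gridpoint.

    Per chromosome, gridpoints run from 0 to the chromosome length
    (rounded up); the nearest marker to each gridpoint is kept, duplicates
    dropped, map order preserved. Input already sparser than one marker
    per cM is returned in full. The selection depends only on the map.
    """
    keep: list[int] = []
    for chrom in gmap.chrom_names:
        sl = gmap.chrom_slice(chrom)
        pos = gmap.positions[sl]
        grid = np.arange(0.0, math.ceil(pos.max()) + 1.0)
        idx = np.searchsorted(pos, grid)
        idx = np.clip(idx, 1, pos.size - 1)
        left_closer = (grid - pos[idx - 1]) <= (pos[idx] - grid)
        nearest = np.where(left_closer, idx - 1, idx)
        seen = set()
        for i in nearest:
            j = sl.start + int(i)
            if j not in seen:
                seen.add(j)
                keep.append(j)
    return np.array(sorted(keep), dtype=np.int64)


def realized_kinship(D: np.ndarray) -> KinshipMatrix:
    """K = DD^t / Delta from a dosage matrix (individuals x dosage columns).

    Columns are centered to mean zero; Delta is the mean diagonal of DD^t,
    so the mean diagonal of K is exactly 1.
    """
    D = np.asarray(D, dtype=float)
    Dc = D - D.mean(axis=0, keepdims=True)
    G = Dc @ Dc.T
    delta = float(np.mean(np.diag(G)))
    if delta <= 0:
        raise ValueError("all-constant dosage matrix: kinship undefined (Delta = 0)")
    return KinshipMatrix(values=G / delta, delta=delta)


def _allele_dosage_matrix(loci) -> np.ndarray:
    """Concatenated per-allele dosage columns (all alleles of every locus)."""
    return np.concatenate([loc.dosages.astype(float) for loc in loci], axis=1)


def kinship_for_model(
    pop: PhasedPopulation, model: str, window: int = 6, overlap: int = 4
) -> KinshipMatrix:
    """Kinship matched to the marker system under test.

    ``snp`` uses centered SNP dosages of the one-per-cM thinned markers;
    ``ibd`` and ``hap`` use the concatenated per-allele dosage columns of
    the thinned loci, so the number of columns equals the total number of
    alleles across the loci used.
    """
    if model == "snp":
        idx = thin_one_per_cM(pop.gmap)
        return realized_kinship(snp_dosages(pop)[:, idx].astype(float))
    if model == "ibd":
        idx = thin_one_per_cM(pop.gmap)
        loci = [
            _dosage_locus(
                pop.labels[:, :, m],
                name=pop.gmap.names[m],
                chrom=str(pop.gmap.chromosomes[m]),
                position=pop.gmap.positions[m],
                allele_namer=int,
            )
            for m in idx
        ]
        return realized_kinship(_allele_dosage_matrix(loci))
    if model == "hap":
        blocks = build_haploblocks(pop, window=window, overlap=overlap)
        idx = thin_one_per_cM(haploblock_map(blocks))
        return realized_kinship(_allele_dosage_matrix([blocks[i] for i in idx]))
    raise ValueError(f"unknown model {model!r}; expected snp, ibd or hap")


# ---------------------------------------------------------------------------
# REML and the EMMAX scan
# ---------------------------------------------------------------------------


def _weighted_lstsq(Xr: np.ndarray, yr: np.ndarray, w: np.ndarray):
    """Rank and residual sum of squares of weighted LS on rotated data."""
    sw = np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    beta, rss, rank, sv = np.linalg.lstsq(Xw, yw, rcond=_RANK_TOL)
    resid = yw - Xw @ beta
    return int(rank), float(resid @ resid), beta


class _RotatedNull:
    """Null model rotated to the kinship eigenbasis; profiled REML over the ratio."""

    def __init__(self, S: np.ndarray, X0r: np.ndarray, logdet_x0tx0: float):
        self.S = S
        self.X0r = X0r
        self.logdet_x0tx0 = logdet_x0tx0

    def loglik(self, log_lambda: float, yr: np.ndarray) -> float:
        """Profiled restricted log-likelihood at ratio lambda = exp(log_lambda)."""
        lam = math.exp(log_lambda)
        w = 1.0 / (lam * self.S + 1.0)
        n, p = self.X0r.shape
        rank, rss, _ = _weighted_lstsq(self.X0r, yr, w)
        df = n - rank
        sigma_e2 = rss / df
        sw = np.sqrt(w)
        Xw = self.X0r * sw[:, None]
        sign, logdet_xwx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (
            df * math.log(2.0 * math.pi * sigma_e2)
            + df
            - float(np.sum(np.log(w)))
            + logdet_xwx
            - self.logdet_x0tx0
        )
        return ll

    def fit(self, yr: np.ndarray) -> VarianceComponents:
        lo, hi = LOG_RATIO_BOUNDS
        grid = np.linspace(lo, hi, 100)
        vals = np.array([self.loglik(g, yr) for g in grid])
        i = int(np.argmax(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda x: -self.loglik(x, yr),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        best_ll = -res.fun
        best_x = float(res.x)
        # endpoints can beat the interior optimum (boundary solutions)
        for cand_x, cand_ll in ((grid[0], vals[0]), (grid[-1], vals[-1])):
            if cand_ll > best_ll:
                best_x, best_ll = float(cand_x), float(cand_ll)
        lam = math.exp(best_x)
        w = 1.0 / (lam * self.S + 1.0)
        rank, rss, _ = _weighted_lstsq(self.X0r, yr, w)
        sigma_e2 = rss / (self.X0r.shape[0] - rank)
        return VarianceComponents(
            sigma_g2=lam * sigma_e2, sigma_e2=sigma_e2, loglik=best_ll
        )


def _prepare_rotation(K: KinshipMatrix, Q: np.ndarray | None, weights: np.ndarray | None, n: int):
    """Eigendecompose (weight-standardized) K; rotate the null fixed design."""
    Kv = K.values
    if weights is not None:
        r = np.asarray(weights, dtype=float)
        if r.shape != (n,) or np.any(r <= 0):
            raise ValueError("weights must be a positive length-n diagonal")
        rinv_sqrt = 1.0 / np.sqrt(r)
        Kv = Kv * rinv_sqrt[:, None] * rinv_sqrt[None, :]
    else:
        rinv_sqrt = None
    S, U = np.linalg.eigh(Kv)
    if S[0] < -_PSD_TOL * max(S[-1], 1.0):
        raise ValueError(f"kinship is not positive semidefinite (min eigenvalue {S[0]:.3g})")
    S = np.clip(S, 0.0, None)
    X0 = np.ones((n, 1))
    if Q is not None:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[0] != n:
            Q = Q.T
        if Q.shape[0] != n:
            raise ValueError("structure matrix Q must have one row per individual")
        X0 = np.column_stack([X0, Q])
    if rinv_sqrt is not None:
        X0 = X0 * rinv_sqrt[:, None]
    X0r = U.T @ X0
    sign, logdet = np.linalg.slogdet(X0.T @ X0)
    return S, U, X0, X0r, logdet, rinv_sqrt


def reml_null(
    y: np.ndarray,
    K: KinshipMatrix,
    Q: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> VarianceComponents:
    """REML variance components of the no-marker null model.

    One eigendecomposition of K followed by a bounded 1-D maximization of
    the profiled restricted likelihood over log(sigma_G^2/sigma_e^2) in
    [-10, 10] (coarse 100-point grid, then refinement to 1e-8).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    S, U, X0, X0r, logdet, rinv_sqrt = _prepare_rotation(K, Q, weights, n)
    if n < X0.shape[1] + 2:
        raise ValueError("need at least n_fixed + 2 observations for REML")
    yt = y * rinv_sqrt if rinv_sqrt is not None else y
    return _RotatedNull(S, X0r, logdet).fit(U.T @ yt)


def reml_profile_loglik(
    y: np.ndarray,
    K: KinshipMatrix,
    log_lambdas: np.ndarray,
    Q: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Profiled REML log-likelihood on a grid of log variance ratios."""
    y = np.asarray(y, dtype=float)
    S, U, X0, X0r, logdet, rinv_sqrt = _prepare_rotation(K, Q, weights, y.size)
    yt = y * rinv_sqrt if rinv_sqrt is not None else y
    null = _RotatedNull(S, X0r, logdet)
    yr = U.T @ yt
    return np.array([null.loglik(float(g), yr) for g in np.asarray(log_lambdas, dtype=float)])


class GenomeScanner:
    """Precomputed EMMAX scan machinery for one (loci, K, Q) combination.

    The kinship eigendecomposition and the rotated locus design columns are
    computed once at construction and reused for every phenotype vector —
    the observed one and each permutation — so permutation thresholds cost
    one cheap weighted pass per permutation. Loci are grouped by their
    number of design columns and tested in batched linear algebra.
    """

    def __init__(
        self,
        loci: LocusSet,
        K: KinshipMatrix,
        Q: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ):
        n = loci.n_individuals
        if K.n != n:
            raise ValueError("kinship size does not match the number of individuals")
        self.loci = loci
        S, U, X0, X0r, logdet, rinv_sqrt = _prepare_rotation(K, Q, weights, n)
        self.S, self.U, self.X0r = S, U, X0r
        self._null = _RotatedNull(S, X0r, logdet)
        self._rinv_sqrt = rinv_sqrt
        self.n = n
        self.p0 = X0r.shape[1]
        X_all = loci.X_all
        if rinv_sqrt is not None:
            X_all = X_all * rinv_sqrt[:, None]
        Xr_all = U.T @ X_all
        # group loci by column count; stack each group to (L_g, n, p0 + k)
        widths = [sl[1] - sl[0] for sl in loci.col_slices]
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []
        by_width: dict[int, list[int]] = {}
        for j, wd in enumerate(widths):
            by_width.setdefault(wd, []).append(j)
        for wd, idx in sorted(by_width.items()):
            stack = np.empty((len(idx), n, self.p0 + wd))
            stack[:, :, : self.p0] = X0r[None, :, :]
            for t, j in enumerate(idx):
                s = loci.col_slices[j]
                stack[t, :, self.p0 :] = Xr_all[:, s[0] : s[1]]
            self._groups.append((np.array(idx, dtype=np.int64), stack))

    # -- variance components -------------------------------------------
    def reml(self, y: np.ndarray) -> VarianceComponents:
        yr = self._rotate_y(y)
        return self._null.fit(yr)

    def _rotate_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self._rinv_sqrt is not None:
            y = y * self._rinv_sqrt
        return self.U.T @ y

    # -- the scan --------------------------------------------------------
    def scan(self, y: np.ndarray, vc: VarianceComponents | None = None) -> ScanResult:
        """GLS F-test at every locus under recycled variance components.

        With ``vc=None`` the components are first estimated by REML on the
        null model (the P3D step). A locus whose tested columns are all
        linearly dependent on the null design (e.g. monomorphic) gets
        p = 1 and a ``degenerate`` flag.
        """
        if vc is None:
            vc = self.reml(y)
        yr = self._rotate_y(y)
        lam = vc.ratio
        if math.isinf(lam):
            raise ValueError("sigma_e2 = 0: GLS weights undefined")
        w = 1.0 / (lam * self.S + 1.0)
        rank0, rss0, _ = _weighted_lstsq(self.X0r, yr, w)
        ywy = float((yr * w) @ yr)

        L = len(self.loci)
        F = np.full(L, np.nan)
        df1 = np.zeros(L, dtype=np.int64)
        neglog10p = np.zeros(L)
        flags = np.array(["ok"] * L, dtype=object)
        wy = w * yr
        for idx, stack in self._groups:
            G = np.einsum("lnj,n,lnk->ljk", stack, w, stack, optimize=True)
            b = np.einsum("lnj,n->lj", stack, wy)
            evals, evecs = np.linalg.eigh(G)
            thr = _RANK_TOL * evals[:, -1:].clip(min=_RANK_TOL)
            keep = evals > thr
            rank_full = keep.sum(axis=1)
            c = np.einsum("ljk,lj->lk", evecs, b)
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(keep, c * c / np.where(keep, evals, 1.0), 0.0)
            rss1 = np.maximum(ywy - contrib.sum(axis=1), 0.0)
            q = rank_full - rank0
            df2 = self.n - rank_full
            ok = (q > 0) & (df2 > 0) & (rss1 > 0)
            Fg = np.full(idx.size, np.nan)
            nl = np.zeros(idx.size)
            Fg[ok] = ((rss0 - rss1[ok]) / q[ok]) / (rss1[ok] / df2[ok])
            Fg[ok] = np.maximum(Fg[ok], 0.0)
            nl[ok] = -stats.f.logsf(Fg[ok], q[ok], df2[ok]) / math.log(10.0)
            F[idx] = Fg
            df1[idx] = q
            neglog10p[idx] = nl
            for t, j in enumerate(idx):
                if not ok[t]:
                    flags[j] = "degenerate"
        table = pd.DataFrame(
            {
                "locus": self.loci.names,
                "chromosome": self.loci.chromosomes,
                "position_cM": self.loci.positions,
                "F": F,
                "df1": df1,
                "neglog10p": neglog10p,
                "flag": flags,
            }
        )
        return ScanResult(table=table, model=self.loci.model, vc=vc)

    # -- permutation threshold -------------------------------------------
    def permutation_threshold(
        self,
        y: np.ndarray,
        n_perm: int = 100,
        alpha: float = 0.05,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Genome-wide empirical threshold on -log10 p by phenotype permutation.

        The phenotype vector is permuted across individuals (K fixed),
        variance components are re-estimated under each permuted null, the
        genome-wide maximum -log10 p is recorded, and the empirical
        (1 - alpha) quantile of the maxima is returned.
        """
        if n_perm < 20:
            raise ValueError("need at least 20 permutations")
        if rng is None:
            rng = np.random.default_rng()
        y = np.asarray(y, dtype=float)
        maxima = np.empty(n_perm)
        for p in range(n_perm):
            yp = y[rng.permutation(y.size)]
            maxima[p] = self.scan(yp).max_neglog10p()
        return float(np.quantile(maxima, 1.0 - alpha))


def scan(
    loci: LocusSet,
    y: np.ndarray,
    K: KinshipMatrix,
    Q: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
    weights: np.ndarray | None = None,
) -> ScanResult:
    """One-shot EMMAX genome scan (see :class:`GenomeScanner`)."""
    return GenomeScanner(loci, K, Q=Q, weights=weights).scan(y, vc=vc)


def permutation_threshold(
    loci: LocusSet,
    y: np.ndarray,
    K: KinshipMatrix,
    Q: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """One-shot permutation threshold (see :meth:`GenomeScanner.permutation_threshold`)."""
    scanner = GenomeScanner(loci, K, Q=Q, weights=weights)
    return scanner.permutation_threshold(y, n_perm=n_perm, alpha=alpha, rng=rng)
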
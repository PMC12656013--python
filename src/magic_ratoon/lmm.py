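"""Mixed linear model association scans.

The model is y = X beta + W gamma + Z u + e with polygenic effects
u ~ N(0, K sigma_g^2) over a kinship matrix K estimated from the marker
data, and e ~ N(0, I sigma_e^2).  The variance ratio delta = sigma_e^2 /
sigma_g^2 is estimated once under the null by REML on the spectral
decomposition of K (the EMMA approach); marker tests then use generalized
least squares with the null variance held fixed (P3D/EMMAX mode) or
re-optimized per marker (exact mode).

Organized statsmodels-style: :class:`LinearMixedModel` is built from data,
``fit()`` returns :class:`LMMResults` carrying the variance components and
their diagnostics, and the genome scans hang off the results object.
Significance thresholds use a Li-Ji effective number of independent tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric PSD kinship with its sample order.

    ``matrix`` has been bent to positive semi-definiteness by flooring
    negative eigenvalues at zero (recorded in ``min_eigenvalue_prebend``).
    """

    matrix: np.ndarray
    ids: list[str]
    method: str
    min_eigenvalue_prebend: float = 0.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def kinship(genotypes, method: str = "allele_sharing", ids=None) -> KinshipMatrix:
    """Estimate kinship from an (n_lines x n_sites) alt-dosage matrix.

    ``allele_sharing`` (default) sets K_ij = 1 - d_ij where d_ij is the
    mean per-site nucleotide difference fraction |g_i - g_j| / 2 over sites
    called in both lines — the direct operationalization of kinship from
    nucleotide diversities.  ``vanraden`` is the centered GRM alternative.
    Missing genotypes are allowed; a pair of lines with no jointly called
    site is an error.
    """
    if isinstance(genotypes, pd.DataFrame):
        ids = ids or [str(i) for i in genotypes.index]
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        ids = ids or [f"S{i}" for i in range(G.shape[0])]
    n, m = G.shape
    called = np.isfinite(G)
    if method == "allele_sharing":
        # |a-b| over {0,1,2} decomposes over allele-class indicators, so the
        # pairwise sum is a handful of matmuls instead of an n^2 m loop.
        A = [((G == k) & called).astype(float) for k in (0, 1, 2)]
        S = (
            A[0] @ A[1].T + A[1] @ A[0].T
            + A[1] @ A[2].T + A[2] @ A[1].T
            + 2.0 * (A[0] @ A[2].T + A[2] @ A[0].T)
        )
        N = called.astype(float) @ called.astype(float).T
        bad = np.argwhere(N == 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"samples {ids[i]} and {ids[j]} share no called site")
        # per-site difference fraction is |g_i - g_j| / 2
        K = 1.0 - S / (2.0 * N)
    elif method == "vanraden":
        p = np.nanmean(G, axis=0) / 2.0
        Z = np.where(called, G - 2 * p, 0.0)
        denom = 2.0 * float(np.sum(p * (1 - p)))
        if denom == 0:
            raise ValueError("all sites monomorphic; kinship undefined")
        K = (Z @ Z.T) / denom
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    min_eig = float(w.min())
    if min_eig < 0:
        K = (V * np.maximum(w, 0.0)) @ V.T
        K = (K + K.T) / 2.0
    return KinshipMatrix(matrix=K, ids=list(ids), method=method, min_eigenvalue_prebend=min_eig)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _as_design(W, n) -> np.ndarray:
    if W is None:
        return np.ones((n, 1))
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    return W


def restricted_loglik_dense(delta: float, y, K, W) -> float:
    """Restricted log-likelihood of delta via dense solves (oracle form).

    V = K + delta I up to the scale sigma_g^2, which is profiled out.
    """
    y = np.asarray(y, float)
    n = len(y)
    W = _as_design(W, n)
    q = W.shape[1]
    V = K + delta * np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_W = np.linalg.solve(V, W)
    WtViW = W.T @ Vi_W
    beta = np.linalg.solve(WtViW, W.T @ Vi_y)
    r = y - W @ beta
    S = float(r @ np.linalg.solve(V, r))
    sigma2 = S / (n - q)
    _, ld_V = np.linalg.slogdet(V)
    _, ld_WtViW = np.linalg.slogdet(WtViW)
    _, ld_WtW = np.linalg.slogdet(W.T @ W)
    return -0.5 * (
        (n - q) * math.log(2 * math.pi * sigma2) + (n - q) + ld_V + ld_WtViW - ld_WtW
    )


class LinearMixedModel:
    """Null mixed model y = W gamma + u + e over a kinship matrix.

    Parameters
    ----------
    y : (n,) phenotype (one value per line; replicate means upstream)
    K : KinshipMatrix or (n, n) array
    W : optional fixed-effect design (intercept prepended if absent);
        sowing-batch dummies belong here.
    """

    def __init__(self, y, K, W=None, ids=None):
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        if isinstance(K, KinshipMatrix):
            self.K = K.matrix
            self.ids = ids or K.ids
        else:
            self.K = np.asarray(K, dtype=float)
            self.ids = ids or [f"S{i}" for i in range(n)]
        if self.K.shape != (n, n):
            raise ValueError("kinship dimension does not match phenotype length")
        W = _as_design(W, n)
        ones = np.ones((n, 1))
        if np.linalg.matrix_rank(np.hstack([W, ones])) > np.linalg.matrix_rank(W):
            W = np.hstack([ones, W])  # ensure an intercept in the column space
        self.W = W
        q = np.linalg.matrix_rank(self.W)
        if n < q + 2:
            raise ValueError("need n >= rank(W) + 2 observations")
        if np.std(self.y) == 0:
            raise ValueError("phenotype is constant; variance components undefined")
        # spectral pieces, computed once
        self._d, self._U = np.linalg.eigh(self.K)
        self._d = np.maximum(self._d, 0.0)
        self._ys = self._U.T @ self.y
        self._Ws = self._U.T @ self.W

    # -- restricted likelihood on the spectral decomposition ---------------
    def restricted_loglik(self, delta: float) -> float:
        d = self._d + delta
        n, q = len(self.y), self.W.shape[1]
        Wd = self._Ws / d[:, None]
        WtViW = self._Ws.T @ Wd
        beta = np.linalg.solve(WtViW, Wd.T @ self._ys)
        r = self._ys - self._Ws @ beta
        S = float(r @ (r / d))
        sigma2 = S / (n - q)
        ld_V = float(np.sum(np.log(d)))
        _, ld_WtViW = np.linalg.slogdet(WtViW)
        _, ld_WtW = np.linalg.slogdet(self.W.T @ self.W)
        return -0.5 * (
            (n - q) * math.log(2 * math.pi * sigma2) + (n - q) + ld_V + ld_WtViW - ld_WtW
        )

    def fit(self, grid_points: int = 121) -> "LMMResults":
        """REML estimate of delta on a log grid over [1e-5, 1e5], refined by
        bounded scalar optimization; deterministic."""
        grid = np.logspace(-5, 5, grid_points)
        ll = np.asarray([self.restricted_loglik(d) for d in grid])
        k = int(np.argmax(ll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -self.restricted_loglik(math.exp(t)),
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        delta = float(math.exp(res.x))
        if -res.fun < ll[k]:
            delta = float(grid[k])
        n, q = len(self.y), self.W.shape[1]
        d = self._d + delta
        Wd = self._Ws / d[:, None]
        WtViW = self._Ws.T @ Wd
        beta = np.linalg.solve(WtViW, Wd.T @ self._ys)
        r = self._ys - self._Ws @ beta
        sigma_g2 = float(r @ (r / d)) / (n - q)
        return LMMResults(
            model=self,
            delta=delta,
            sigma_g2=sigma_g2,
            sigma_e2=delta * sigma_g2,
            loglik=self.restricted_loglik(delta),
            gamma=beta,
        )


@dataclass
class LMMResults:
    """Null-model REML fit: variance components and scan entry points."""

    model: LinearMixedModel
    delta: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    gamma: np.ndarray = field(repr=False, default=None)

    @property
    def heritability_marker(self) -> float:
        """sigma_g^2 / (sigma_g^2 + sigma_e^2), the pseudo-heritability."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")

    def summary(self) -> str:
        lines = [
            "Linear mixed model (REML, spectral)",
            f"  n observations : {len(self.model.y)}",
            f"  fixed effects  : {self.model.W.shape[1]} columns",
            f"  sigma_g^2      : {self.sigma_g2:.6g}",
            f"  sigma_e^2      : {self.sigma_e2:.6g}",
            f"  delta (e/g)    : {self.delta:.6g}",
            f"  pseudo-h2      : {self.heritability_marker:.4f}",
            f"  restricted logL: {self.loglik:.6f}",
        ]
        return "\n".join(lines)

    # -- rotated data under the fitted variance, cached --------------------
    def _rotated(self):
        m = self.model
        c = 1.0 / np.sqrt(m._d + self.delta)
        yt = c * m._ys
        Wt = c[:, None] * m._Ws
        Qw, _ = np.linalg.qr(Wt)
        resid_y = yt - Qw @ (Qw.T @ yt)
        return c, yt, Wt, Qw, resid_y

    def scan_snps(
        self,
        genotypes,
        sites: pd.DataFrame | None = None,
        mode: str = "p3d",
    ) -> pd.DataFrame:
        """Single-marker scan (1-df Wald F per SNP).

        ``genotypes``: (n_sites x n_lines) or DataFrame lines x sites of
        alt dosage; NaN entries drop those lines for that marker only.
        ``mode='p3d'`` reuses the null variance components (default);
        ``'exact'`` re-optimizes delta per marker.
        """
        m = self.model
        if isinstance(genotypes, pd.DataFrame):
            X = genotypes.to_numpy(dtype=float).T
            if sites is None:
                sites = pd.DataFrame(
                    [k if isinstance(k, tuple) else (None, None, None, None) for k in genotypes.columns],
                    columns=["chrom", "pos", "ref", "alt"],
                )
        else:
            X = np.asarray(genotypes, dtype=float)
        n = len(m.y)
        if X.shape[1] != n:
            raise ValueError("genotype matrix does not match phenotype length")
        q = m.W.shape[1]
        c, yt, Wt, Qw, ry = self._rotated()
        U = m._U
        records = []
        sd = np.nanstd(X, axis=1)
        missing_any = ~np.isfinite(X).all(axis=1)
        # vectorized path for complete markers under P3D
        complete = np.flatnonzero(~missing_any & (sd > 0))
        if mode == "p3d" and complete.size:
            Xs = (U.T @ X[complete].T) * c[:, None]       # rotated markers
            Rx = Xs - Qw @ (Qw.T @ Xs)                    # residualized vs W
            xx = np.einsum("ij,ij->j", Rx, Rx)
            xy = Rx.T @ ry
            beta = xy / xx
            ssr = beta * xy
            sse = float(ry @ ry) - ssr
            dfree = n - q - 1
            with np.errstate(divide="ignore", invalid="ignore"):
                F = ssr / (sse / dfree)
            p = stats.f.sf(F, 1, dfree)
            for idx, b, pv in zip(complete, beta, p):
                records.append((idx, 1, float(b), float(pv), n))
        for idx in range(X.shape[0]):
            if not missing_any[idx] and sd[idx] > 0 and mode == "p3d":
                continue
            x = X[idx]
            keep = np.isfinite(x)
            xk = x[keep]
            if xk.size == 0 or np.std(xk) == 0:
                log.info("marker %d monomorphic or empty; skipped", idx)
                continue
            if mode == "exact" and not missing_any[idx]:
                sub = LinearMixedModel(m.y, m.K, np.column_stack([m.W, x]), ids=m.ids)
                fit = sub.fit()
                b, F, pv, dfree = _gls_ftest(
                    m.y, m.K, m.W, x[:, None], fit.delta
                )
            else:
                b, F, pv, dfree = _gls_ftest(
                    m.y[keep],
                    m.K[np.ix_(keep, keep)],
                    m.W[keep],
                    xk[:, None],
                    self.delta,
                )
            records.append((idx, 1, float(b), float(pv), int(keep.sum())))
        out = pd.DataFrame(records, columns=["index", "df", "beta", "p", "n"])
        out = out.sort_values("index").reset_index(drop=True)
        out["pve"] = [
            pve(m.y, m.W, X[i], mask=np.isfinite(X[i])) for i in out["index"]
        ]
        if sites is not None:
            meta = sites.iloc[out["index"]].reset_index(drop=True)
            out = pd.concat([meta[["chrom", "pos", "ref", "alt"]], out], axis=1)
        out["method"] = "snp"
        return out

    def scan_genes(self, designs, gene_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Joint (K-1)-df F-test per gene on haplotype dummy columns.

        ``designs`` is an iterable of
        :class:`~magic_ratoon.haplotypes.HaplotypeDesign`; genes with fewer
        than two testable classes, or rank-deficient designs after masking,
        are skipped and logged.
        """
        m = self.model
        n = len(m.y)
        q = m.W.shape[1]
        c, yt, Wt, Qw, ry = self._rotated()
        U = m._U
        records = []
        for des in designs:
            if not des.testable:
                continue
            mask = des.mask
            X = des.matrix
            if X.shape[0] != int(mask.sum()) or len(mask) != n:
                raise ValueError(f"{des.gene_id}: design/mask shape mismatch")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                log.info("%s: rank-deficient design after masking; skipped", des.gene_id)
                continue
            if mask.all():
                # complete design: reuse the cached spectral rotation
                Xt = (U.T @ X) * c[:, None]
                Rx = Xt - Qw @ (Qw.T @ Xt)
                df1 = X.shape[1]
                beta = np.linalg.solve(Rx.T @ Rx, Rx.T @ ry)
                ssr = float(ry @ Rx @ beta)
                sse = float(ry @ ry) - ssr
                dfree = n - q - df1
                F = (ssr / df1) / (sse / dfree)
                pv = float(stats.f.sf(F, df1, dfree))
                pv = min(max(pv, np.nextafter(0, 1)), 1.0)
            else:
                beta, F, pv, dfree = _gls_ftest(
                    m.y[mask], m.K[np.ix_(mask, mask)], m.W[mask], X, self.delta
                )
            full = np.full((n, X.shape[1]), np.nan)
            full[mask] = X
            records.append(
                {
                    "gene_id": des.gene_id,
                    "df": X.shape[1],
                    "beta": beta,
                    "p": float(pv),
                    "n": int(mask.sum()),
                    "pve": pve(m.y, m.W, full, mask=mask),
                }
            )
        out = pd.DataFrame(records, columns=["gene_id", "df", "beta", "p", "n", "pve"])
        if gene_meta is not None and len(out):
            out = out.merge(gene_meta, on="gene_id", how="left")
        out["method"] = "gene"
        return out


def _gls_ftest(y, K, W, X, delta):
    """GLS F-test of X (joint, df = n columns) with V = K + delta I fixed.

    Returns (beta for X columns, F, p, residual df)."""
    from scipy.linalg import solve_triangular

    n = len(y)
    V = K + delta * np.eye(n)
    L = np.linalg.cholesky(V)
    yt = solve_triangular(L, y, lower=True)
    Wt = solve_triangular(L, W, lower=True)
    Xt = solve_triangular(L, X, lower=True)
    Qw, _ = np.linalg.qr(Wt)
    ry = yt - Qw @ (Qw.T @ yt)
    Rx = Xt - Qw @ (Qw.T @ Xt)
    q = W.shape[1]
    df1 = X.shape[1]
    XtX = Rx.T @ Rx
    beta = np.linalg.solve(XtX, Rx.T @ ry)
    ssr = float(ry @ Rx @ beta)
    sse = float(ry @ ry) - ssr
    dfree = n - q - df1
    if dfree <= 0 or sse <= 0:
        return beta, np.inf, 0.0, max(dfree, 0)
    F = (ssr / df1) / (sse / dfree)
    p = float(stats.f.sf(F, df1, dfree))
    beta = float(beta[0]) if df1 == 1 else beta
    return beta, F, min(max(p, np.nextafter(0, 1)), 1.0), dfree


# ---------------------------------------------------------------------------
# module-surface wrappers
# ---------------------------------------------------------------------------


def fit_null_mlm(y, W, K) -> LMMResults:
    """Fit the null mixed model (argument order: y, covariates, kinship)."""
    return LinearMixedModel(y, K, W).fit()


def scan_snps(y, W, fit: LMMResults | None, genotype_matrix, sites=None, K=None, mode="p3d"):
    if fit is None:
        fit = fit_null_mlm(y, W, K)
    return fit.scan_snps(genotype_matrix, sites=sites, mode=mode)


def scan_genes(y, W, fit: LMMResults | None, haplotype_designs, K=None):
    if fit is None:
        fit = fit_null_mlm(y, W, K)
    return fit.scan_genes(haplotype_designs)


# ---------------------------------------------------------------------------
# effective number of tests
# ---------------------------------------------------------------------------


@dataclass
class MeffResult:
    scope: str
    meff: float
    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.meff

    @property
    def threshold_2sf(self) -> float:
        return round_sig(self.threshold, 2)


def round_sig(x: float, digits: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1))


def _liji_meff(corr: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(corr)
    lam = np.maximum(lam, 0.0)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_tests(
    scores,
    chrom=None,
    scope: str = "snp",
    alpha: float = 0.05,
    window: int = 200,
) -> MeffResult:
    """Li-Ji effective number of independent tests.

    ``scores`` is an (n_markers x n_lines) matrix (or DataFrame lines x
    markers) of the quantities actually tested — SNP dosages or numeric
    gene-haplotype codes; ``chrom`` labels markers so blocks never span
    chromosomes.  Within each chromosome the eigenvalue decomposition runs
    on consecutive ``window``-marker blocks of the marker correlation
    matrix and block contributions are summed; the threshold is
    alpha / Meff.  Monomorphic markers carry no test and are excluded.
    """
    if isinstance(scores, pd.DataFrame):
        if chrom is None and isinstance(scores.columns[0], tuple):
            chrom = [c[0] for c in scores.columns]
        scores = scores.to_numpy(dtype=float).T
    X = np.asarray(scores, dtype=float)
    m = X.shape[0]
    if chrom is None:
        chrom = np.zeros(m)
    chrom = np.asarray(chrom)
    # drop markers with no data, mean-impute the rest, drop monomorphic ones
    has_data = np.isfinite(X).any(axis=1)
    X, chrom = X[has_data], chrom[has_data]
    col_mean = np.nanmean(X, axis=1, keepdims=True) if X.size else X
    X = np.where(np.isfinite(X), X, col_mean)
    sd = X.std(axis=1)
    keep = sd > 0
    X, chrom = X[keep], chrom[keep]
    m = X.shape[0]
    if m < 2:
        return MeffResult(scope=scope, meff=float(max(m, 1)), alpha=alpha, n_tests=m)
    meff = 0.0
    for c in pd.unique(chrom):
        sub = X[chrom == c]
        for start in range(0, sub.shape[0], window):
            block = sub[start : start + window]
            if block.shape[0] == 1:
                meff += 1.0
                continue
            corr = np.corrcoef(block)
            meff += _liji_meff(corr)
    meff = min(max(meff, 1.0), float(m))
    return MeffResult(scope=scope, meff=meff, alpha=alpha, n_tests=m)


# ---------------------------------------------------------------------------
# PVE, inflation factor, plot tables
# ---------------------------------------------------------------------------


def pve(y, W, marker_or_design, mask=None) -> float:
    """Percent phenotypic variance explained by a marker or design, from an
    ordinary least-squares refit: 100 (R2_full - R2_covariates)."""
    y = np.asarray(y, float)
    n = len(y)
    W = _as_design(W, n)
    X = np.asarray(marker_or_design, float)
    if X.ndim == 1:
        X = X[:, None]
    if mask is None:
        mask = np.isfinite(X).all(axis=1)
    yk, Wk, Xk = y[mask], W[mask], X[mask]
    if yk.size < Wk.shape[1] + Xk.shape[1] + 1 or np.std(yk) == 0:
        return float("nan")
    sst = float(np.sum((yk - yk.mean()) ** 2))

    def rss(D):
        beta, *_ = np.linalg.lstsq(D, yk, rcond=None)
        r = yk - D @ beta
        return float(r @ r)

    r2_cov = 1 - rss(Wk) / sst
    r2_full = 1 - rss(np.column_stack([Wk, Xk])) / sst
    return float(np.clip(100.0 * (r2_full - r2_cov), 0.0, 100.0))


def genomic_lambda(pvalues) -> float:
    """Genomic-control inflation factor: median chi2(1) quantile ratio."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    obs = stats.chi2.isf(p, df=1)
    return float(np.median(obs) / stats.chi2.ppf(0.5, df=1))


def qq_table(pvalues) -> pd.DataFrame:
    """Observed vs expected -log10 p for a Q-Q plot."""
    p = np.sort(np.asarray(pvalues, float))
    p = p[np.isfinite(p)]
    k = len(p)
    expected = (np.arange(1, k + 1) - 0.5) / k
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(np.maximum(p, 1e-300))}
    )


def manhattan_table(records: pd.DataFrame, pos_col: str = "pos") -> pd.DataFrame:
    """Chrom, position, -log10 p — the data behind a Manhattan plot."""
    out = records.copy()
    out["neglog10p"] = -np.log10(np.maximum(out["p"].to_numpy(float), 1e-300))
    return out[["chrom", pos_col, "neglog10p"]]


def plot_manhattan(records: pd.DataFrame, threshold: float | None = None, path=None):
    """Optional Manhattan plot (PNG when ``path`` given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (c, grp) in enumerate(records.groupby("chrom", sort=True)):
        ax.scatter(grp["pos"], -np.log10(grp["p"]), s=4, color=f"C{i % 2}")
    if threshold:
        ax.axhline(-math.log10(threshold), color="b", lw=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
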
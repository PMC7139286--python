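"""Mixed-linear-model SNP-trait association with dominance decomposition.

The model is y = mu + Q beta + SNP effects + u + e with cov(u)
proportional to a kinship matrix K and independent residuals.  Variance
components are estimated by restricted maximum likelihood profiled over
the heritability on the spectral decomposition of K, so each SNP test
reduces to weighted least squares in the rotated basis.  SNP terms are
an additive dosage (0/1/2) plus a heterozygote indicator; significance
is an F test of both terms, and R^2 is the share of the (whitened)
phenotypic sum of squares they explain.  Genotypic effects are
decomposed as a = (mean(AA) - mean(aa)) / 2 and d = mean(Aa) -
(mean(AA) + mean(aa)) / 2, with |d|/|a| > 2 (strict) defining a
prominent dominant-effect locus.  Multiple testing is controlled with
Benjamini-Hochberg q-values; an association is significant at p < 0.001
and q < 0.10.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .simulate import vanraden_grm


# -------------------------------------------------------- SNP filtering

def snp_minor_allele_frequency(g: np.ndarray) -> float:
    """MAF from a 0/1/2 dosage vector with NaN missing."""
    g = g[~np.isnan(g)]
    if len(g) == 0:
        return np.nan
    f = g.mean() / 2.0
    return min(f, 1.0 - f)


def filter_snps(
    genotypes: pd.DataFrame,
    maf_min: float = 0.05,
    missing_max: float = 0.25,
    min_class_count: int = 3,
) -> pd.DataFrame:
    """Marker QC: MAF, missingness, and genotype-class representation.

    Keeps SNPs with MAF >= ``maf_min`` (markers with MAF < 5% excluded),
    missing fraction <= ``missing_max``, and every genotype class
    (0, 1, 2) carried by at least ``min_class_count`` individuals — the
    last rule drops markers whose alternative genotype class is too
    thinly represented to estimate a dominance deviation.
    """
    keep = []
    for snp in genotypes.columns:
        g = genotypes[snp].to_numpy(dtype=float)
        miss = np.isnan(g).mean()
        if miss > missing_max:
            continue
        maf = snp_minor_allele_frequency(g)
        if not np.isfinite(maf) or maf < maf_min:
            continue
        gg = g[~np.isnan(g)]
        counts = [(gg == k).sum() for k in (0, 1, 2)]
        if min(counts) < min_class_count:
            continue
        keep.append(snp)
    return genotypes[keep]


def grm(genotypes: pd.DataFrame) -> pd.DataFrame:
    """VanRaden genomic relationship matrix (mean-imputed missing)."""
    K = vanraden_grm(genotypes.to_numpy(dtype=float))
    return pd.DataFrame(K, index=genotypes.index, columns=genotypes.index)


# ------------------------------------------------------------ REML core

def _reml_neg_loglik(h2: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    w = h2 * d + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf
    sw = np.sqrt(w)
    Xs = Xt / sw[:, None]
    ys = yt / sw
    XtX = Xs.T @ Xs
    try:
        beta = np.linalg.solve(XtX, Xs.T @ ys)
    except np.linalg.LinAlgError:
        return np.inf
    resid = ys - Xs @ beta
    n, p = Xt.shape
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xx + (n - p))


def _fit_h2(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(1e-6, 1.0 - 1e-6),
        args=(d, yt, Xt),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (greedy)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cols = keep + [j]
        if np.linalg.matrix_rank(X[:, cols], tol=tol) == len(cols):
            keep.append(j)
    return np.asarray(keep, dtype=int)


@dataclass
class MixedModel:
    """Phenotype + structure covariates + kinship, rotated once.

    ``method='reml'`` refits the heritability per SNP; ``method='p3d'``
    (population parameters previously determined) estimates it once
    under the covariate-only model and reuses it for every SNP.
    """

    y: np.ndarray
    Q: np.ndarray | None = None
    K: np.ndarray | None = None
    method: str = "reml"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.y)
        X0 = [np.ones((n, 1))]
        if self.Q is not None:
            Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
            if Q.shape[0] != n:
                Q = Q.T
            X0.append(Q)
        X0 = np.hstack(X0)
        keep = _drop_collinear(X0)
        if len(keep) < X0.shape[1]:
            import warnings

            warnings.warn("collinear structure covariates dropped", stacklevel=2)
        self.X0 = X0[:, keep]
        if self.K is None:
            self.K = np.eye(n)
        self.K = np.asarray(self.K, dtype=float)
        d, U = np.linalg.eigh(self.K)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.yt = U.T @ self.y
        self.X0t = U.T @ self.X0
        self._h2_null = _fit_h2(self.d, self.yt, self.X0t) if self.method == "p3d" else None

    # -- per-SNP test ------------------------------------------------------

    def test_snp(self, g: np.ndarray) -> dict:
        """F test of the additive + dominance SNP terms.

        Missing genotypes are dropped casewise (with a sub-K refit).
        Returns p_value, r_squared, the fitted heritability and the
        degrees of freedom used.
        """
        g = np.asarray(g, dtype=float)
        present = ~np.isnan(g)
        if present.all():
            return self._test_complete(g, self.d, self.yt, self.X0t, self._h2_null)
        # casewise drop: re-rotate on the individual subset
        y = self.y[present]
        X0 = self.X0[present]
        K = self.K[np.ix_(present, present)]
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        yt, X0t = U.T @ y, U.T @ X0
        gt = U.T @ self._snp_design(g[present])
        ones_t = U.T @ np.ones(present.sum())
        h2 = _fit_h2(d, yt, X0t) if self.method == "p3d" else None
        return self._ftest(d, yt, X0t, gt, ones_t, h2)

    @staticmethod
    def _snp_design(g: np.ndarray) -> np.ndarray:
        return np.column_stack([g, (g == 1).astype(float)])

    def _test_complete(self, g, d, yt, X0t, h2):
        gt = self.U.T @ self._snp_design(g)
        ones_t = self.U.T @ np.ones(len(self.y))
        return self._ftest(d, yt, X0t, gt, ones_t, h2)

    def _ftest(self, d, yt, X0t, gt, ones_t, h2) -> dict:
        X1t = np.hstack([X0t, gt])
        keep = _drop_collinear(X1t)
        X1t = X1t[:, keep]
        q = X1t.shape[1] - X0t.shape[1]
        n = len(yt)
        if q == 0 or n - X1t.shape[1] <= 0:
            return {"p_value": np.nan, "r_squared": np.nan, "h2": np.nan, "df_num": 0,
                    "df_den": 0}
        if h2 is None:
            h2 = _fit_h2(d, yt, X1t)
        w = h2 * d + (1.0 - h2)
        sw = np.sqrt(w)
        ys = yt / sw
        rss0 = _ols_rss(X0t / sw[:, None], ys)
        rss1 = _ols_rss(X1t / sw[:, None], ys)
        rss_mean = _ols_rss(ones_t[:, None] / sw[:, None], ys)
        df_den = n - X1t.shape[1]
        f = ((rss0 - rss1) / q) / (rss1 / df_den)
        p = float(stats.f.sf(f, q, df_den))
        r2 = float((rss0 - rss1) / rss_mean) if rss_mean > 0 else np.nan
        return {"p_value": p, "r_squared": r2, "h2": float(h2), "df_num": q,
                "df_den": df_den}


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mlm_assoc(
    y: np.ndarray,
    snp: np.ndarray,
    Q: np.ndarray | None = None,
    K: np.ndarray | None = None,
    method: str = "reml",
) -> dict:
    """One-shot mixed-model association test for a single SNP."""
    return MixedModel(y=y, Q=Q, K=K, method=method).test_snp(snp)


# ------------------------------------------------- effect decomposition

def effect_decomposition(
    y_adjusted: np.ndarray, genotypes: np.ndarray, min_class_count: int = 3
) -> dict:
    """Additive and dominance effects from genotype-class means.

    a is half the difference between the major-allele homozygote mean
    and the minor-allele homozygote mean; d is the heterozygote
    deviation from the homozygote midpoint.  |d|/|a| uses absolute
    values; a = 0 yields an infinite ratio (prominent iff |d| > 0).
    """
    y = np.asarray(y_adjusted, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    present = ~np.isnan(g)
    y, g = y[present], g[present]
    counts = {k: int((g == k).sum()) for k in (0, 1, 2)}
    if min(counts.values()) < min_class_count:
        raise ValueError(f"all genotype classes need >= {min_class_count} individuals, got {counts}")
    alt_freq = g.mean() / 2.0
    major_hom, minor_hom = (0, 2) if alt_freq <= 0.5 else (2, 0)
    mean_major = y[g == major_hom].mean()
    mean_minor = y[g == minor_hom].mean()
    mean_het = y[g == 1].mean()
    a = (mean_major - mean_minor) / 2.0
    d = mean_het - (mean_major + mean_minor) / 2.0
    if a == 0.0:
        d_over_a = np.inf if d != 0.0 else np.nan
        prominent = bool(abs(d) > 0)
    else:
        d_over_a = abs(d) / abs(a)
        prominent = bool(d_over_a > 2.0)
    return {"a": float(a), "d": float(d), "d_over_a": float(d_over_a),
            "prominent_dominant": prominent}


# --------------------------------------------------------------- FDR

def qvalues(p_values, q_threshold: float = 0.10, p_threshold: float = 0.001):
    """Benjamini-Hochberg q-values (the lambda = 0 Storey variant).

    Returns (q, significant) with significance requiring both p <
    ``p_threshold`` and q < ``q_threshold``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    significant = (p < p_threshold) & (q < q_threshold)
    return q, significant


# ------------------------------------------------------------ pipeline

def run_association(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    method: str = "reml",
    maf_min: float = 0.05,
    missing_max: float = 0.25,
    p_threshold: float = 0.001,
    q_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per SNP x trait association with q-values and a/d decomposition.

    ``genotypes`` is individuals x SNPs (0/1/2, NaN missing); K defaults
    to the VanRaden relationship matrix of the filtered markers; the
    decomposition runs on the phenotype adjusted for the structure
    covariates (OLS residual on [1, Q]).
    """
    G = filter_snps(genotypes, maf_min=maf_min, missing_max=missing_max)
    if K is None:
        K = grm(G)
    K_arr = K.loc[G.index, G.index].to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K)
    Q_arr = Q.loc[G.index].to_numpy() if isinstance(Q, pd.DataFrame) else Q
    rows = []
    for trait in phenotypes.columns:
        y = phenotypes.loc[G.index, trait].to_numpy(dtype=float)
        model = MixedModel(y=y, Q=Q_arr, K=K_arr, method=method)
        # adjust for fixed structure effects before class-mean decomposition
        X0 = model.X0
        beta, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
        y_adj = y - X0 @ beta + y.mean()
        trait_rows = []
        for snp in G.columns:
            g = G[snp].to_numpy(dtype=float)
            res = model.test_snp(g)
            try:
                dec = effect_decomposition(y_adj, g)
            except ValueError:
                dec = {"a": np.nan, "d": np.nan, "d_over_a": np.nan,
                       "prominent_dominant": False}
            trait_rows.append({"snp_id": snp, "trait": trait, **res, **dec})
        tdf = pd.DataFrame(trait_rows)
        q, sig = qvalues(tdf["p_value"].fillna(1.0), q_threshold, p_threshold)
        tdf["q_value"] = q
        tdf["significant"] = sig
        rows.append(tdf)
    return pd.concat(rows, ignore_index=True)


def association_summary(results: pd.DataFrame) -> pd.Series:
    """Per-trait significant-association counts plus the grand total."""
    sig = results.loc[results["significant"]]
    per_trait = sig.groupby("trait", observed=True).size()
    out = per_trait.to_dict()
    out["total"] = int(per_trait.sum())
    return pd.Series(out)
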
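"""Mixed-linear-model association with structure covariates and kinship.

The model per marker is y = W a + x b + u + e with u ~ N(0, sg^2 K) and
e ~ N(0, se^2 I).  Variance components are estimated once by REML under
the null model (no marker) and reused for every marker — the
population-parameters-previously-determined (P3D/EMMAX) approximation —
after which each marker test is a generalized-least-squares t-test in the
eigenspace of K.  With K = I and no covariates this reduces exactly to
ordinary least squares.

Binary phenotypes (brittle rachis = 1) are analysed with the linear model,
the convention of the standard mixed-model association tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from feralscan.variants import MISSING, GenotypeTable

__all__ = [
    "NullModel",
    "genotype_pca",
    "kinship_matrix",
    "fit_null_model",
    "mlm_association",
    "bonferroni_threshold",
    "encode_sv_pseudo_variants",
    "variance_explained",
    "local_structure_covariates",
]


def _imputed_dosage(table: GenotypeTable) -> np.ndarray:
    """Float dosage matrix with missing calls mean-imputed per site."""
    d = table.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.broadcast_to(mean, d.shape)[nan_mask]
    return d


def genotype_pca(table: GenotypeTable, k: int = 5) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    Returns (n_samples, k) PC scores.  Component signs are fixed by making
    the largest-magnitude variant loading of each component positive.
    """
    if k >= table.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    d = _imputed_dosage(table)
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    keep = sd > 0
    d = d[:, keep] / sd[keep]
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(min(k, vt.shape[0])):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


def kinship_matrix(table: GenotypeTable) -> np.ndarray:
    """Centered genomic relationship matrix (VanRaden): ZZ'/sum 2p(1-p).

    Z is the mean-imputed dosage matrix centered by 2p per site; sites
    monomorphic after imputation contribute nothing.
    """
    d = _imputed_dosage(table)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites for kinship")
    z = d[:, poly] - 2.0 * p[poly]
    denom = float((2.0 * p[poly] * (1.0 - p[poly])).sum())
    return z @ z.T / denom


@dataclass
class NullModel:
    """Null-model fit reused across markers (P3D approximation)."""

    u: np.ndarray  # eigenvectors of K
    s: np.ndarray  # eigenvalues of K
    delta: float  # se^2 / sg^2 at the REML optimum
    w_rot: np.ndarray  # covariates rotated into eigenspace
    y_rot: np.ndarray
    rss_null: float
    df_null: int


def _reml_neg_loglik(log_delta, s, w_rot, y_rot):
    delta = np.exp(log_delta)
    v = s + delta
    dw = w_rot / v[:, None]
    wtw = w_rot.T @ dw
    try:
        alpha = np.linalg.solve(wtw, dw.T @ y_rot)
    except np.linalg.LinAlgError:
        return np.inf
    resid = y_rot - w_rot @ alpha
    rss = float(resid @ (resid / v))
    n, c = w_rot.shape
    df = n - c
    sign, logdet_wtw = np.linalg.slogdet(wtw)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * (df * np.log(rss / df) + np.log(v).sum() + logdet_wtw)


def fit_null_model(
    y: np.ndarray, covariates: np.ndarray | None, K: np.ndarray
) -> NullModel:
    """REML fit of y = W a + u + e with u ~ N(0, sg^2 K).

    ``covariates`` excludes the intercept, which is always added.  A
    non-PSD K is stabilized with a small diagonal ridge (logged).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    W = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        W = np.column_stack([W, np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular covariate matrix")

    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2.0
    s, u = np.linalg.eigh(K)
    if s.min() < -1e-8:
        warnings.warn("kinship not PSD; adding diagonal ridge", stacklevel=2)
        ridge = -s.min() + 1e-8
        s = s + ridge
    s = np.clip(s, 0.0, None)

    y_rot = u.T @ y
    w_rot = u.T @ W
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(s, w_rot, y_rot),
        method="bounded",
    )
    delta = float(np.exp(res.x))

    v = s + delta
    dw = w_rot / v[:, None]
    alpha = np.linalg.solve(w_rot.T @ dw, dw.T @ y_rot)
    resid = y_rot - w_rot @ alpha
    rss = float(resid @ (resid / v))
    return NullModel(
        u=u, s=s, delta=delta, w_rot=w_rot, y_rot=y_rot, rss_null=rss,
        df_null=n - W.shape[1],
    )


def _marker_gls(null: NullModel, x: np.ndarray):
    """GLS fit of one marker given the null fit; returns (beta, t, p, rss)."""
    v = null.s + null.delta
    sqrt_v = np.sqrt(v)
    x_rot = null.u.T @ x
    X = np.column_stack([null.w_rot, x_rot]) / sqrt_v[:, None]
    yt = null.y_rot / sqrt_v
    coef, _, rank, _ = np.linalg.lstsq(X, yt, rcond=None)
    resid = yt - X @ coef
    rss = float(resid @ resid)
    n, p = X.shape
    df = n - p
    if rank < p or df <= 0:
        return np.nan, np.nan, np.nan, rss
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    beta = float(coef[-1])
    if se == 0.0:
        return beta, np.inf, 0.0, rss
    t = beta / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(pval), rss


def mlm_association(
    table: GenotypeTable,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-variant mixed-model association scan.

    Returns the variant frame with ``beta``, ``stat`` (t), ``p`` columns
    plus the Bonferroni threshold alpha/n_sites in ``df.attrs``.
    Missing marker dosages are mean-imputed.
    """
    null = fit_null_model(phenotype, covariates, K)
    d = _imputed_dosage(table)
    betas, ts, ps = [], [], []
    for j in range(table.n_sites):
        beta, t, pval, _ = _marker_gls(null, d[:, j])
        betas.append(beta)
        ts.append(t)
        ps.append(pval)
    out = table.variants.copy()
    out["beta"] = betas
    out["stat"] = ts
    out["p"] = ps
    out.attrs["bonferroni"] = bonferroni_threshold(alpha, table.n_sites)
    out.attrs["delta"] = null.delta
    return out


def bonferroni_threshold(alpha: float, n_sites: int) -> float:
    """Family-wise threshold alpha / n_sites."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return alpha / n_sites


def encode_sv_pseudo_variants(
    sv_calls: pd.DataFrame, samples: list
) -> GenotypeTable:
    """Encode binary structural-variant calls as pseudo-VCF genotypes.

    ``sv_calls`` has one row per SV with columns ``id``, ``chrom``, ``pos``
    and per-sample status columns taking values ``present`` (-> 1/1),
    ``absent`` (-> 0/0) or ``unknown`` (-> ./.).  Returns a
    :class:`GenotypeTable` whose dosages are 2 / 0 / missing, ready to be
    written with :func:`feralscan.variants.write_vcf` or concatenated to a
    SNP table for association.
    """
    status_to_dosage = {"present": 2, "absent": 0, "unknown": MISSING}
    dosage = np.zeros((len(samples), len(sv_calls)), dtype=np.int8)
    for j, (_, row) in enumerate(sv_calls.iterrows()):
        for i, s in enumerate(samples):
            status = row[s]
            if status not in status_to_dosage:
                raise ValueError(f"bad SV status {status!r} for sample {s}")
            dosage[i, j] = status_to_dosage[status]
    variants = pd.DataFrame(
        {
            "chrom": sv_calls["chrom"].to_numpy(),
            "pos": sv_calls["pos"].to_numpy(),
            "ref": ["A"] * len(sv_calls),
            "alt": ["T"] * len(sv_calls),
        }
    )
    return GenotypeTable(variants=variants, dosage=dosage, samples=list(samples))


def variance_explained(
    x: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
) -> float:
    """Partial R^2 of one marker on the GLS-decorrelated model:
    (RSS_null - RSS_marker) / RSS_null."""
    null = fit_null_model(phenotype, covariates, K)
    if null.rss_null <= 0:
        raise ValueError("null model has zero residual variance")
    x = np.asarray(x, dtype=float)
    x = np.where(x == MISSING, np.nan, x)
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x), x)
    _, _, _, rss_marker = _marker_gls(null, x)
    return (null.rss_null - rss_marker) / null.rss_null


def local_structure_covariates(
    table: GenotypeTable, target_chrom: str, k_local: int = 5, k_global: int = 5
) -> np.ndarray:
    """Concatenate chromosome-local and genome-wide PCs.

    Used to absorb chromosome-specific population structure (e.g. the
    chr3B stratification): the top ``k_local`` PCs computed from sites on
    ``target_chrom`` are column-joined with the top ``k_global``
    genome-wide PCs; collinear columns are dropped with a warning.
    """
    on_target = (table.variants["chrom"] == target_chrom).to_numpy()
    if on_target.sum() < k_local:
        raise ValueError(f"too few sites on {target_chrom} for {k_local} PCs")
    local = genotype_pca(table.subset_sites(on_target), k_local)
    global_ = genotype_pca(table, k_global)
    combined = np.column_stack([local, global_])
    # drop rank-deficient columns via pivoted QR
    from scipy.linalg import qr as scipy_qr

    _, rmat, piv = scipy_qr(combined, pivoting=True, mode="economic")
    diag = np.abs(np.diag(rmat))
    rank = int((diag > 1e-8 * max(diag[0], 1e-300)).sum())
    if rank < combined.shape[1]:
        warnings.warn("dropping collinear local-structure columns", stacklevel=2)
        keep = sorted(piv[:rank])
        combined = combined[:, keep]
    return combined
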
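"""Sex-stratified genome-wide association for inbred-line panels.

Line means are regressed on genotypes under a linear mixed model with a
genomic relationship matrix (GRM) absorbing cryptic relatedness.  The null
model's two variance components (genetic, residual) are estimated once by
REML on the eigendecomposition of the GRM; every variant is then tested by
generalized least squares with that covariance held fixed (the EMMAX-style
approximation), giving a per-allele effect ``beta``, its standard error and
a Wald P-value against chi-square with 1 df.  With the 0/2 homozygous
genotype coding, ``beta`` is half the difference between the two homozygote
class means, i.e. an additive allelic effect.

Four phenotypes are analyzed per panel: female, male, their average and
their difference — the difference phenotype is what exposes
sex-antagonistic variants that cancel in the average.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

ANALYSES = ("female", "male", "average", "difference")


# ---------------------------------------------------------------------------
# filtering and covariates


def filter_variants(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.015,
) -> GenotypeMatrix:
    """Keep variants with missing rate <= ``max_missing`` and MAF >= ``min_maf``.

    Monomorphic variants are always removed.  Idempotent.
    """
    miss = genotypes.missing_rate()
    maf = genotypes.maf()
    with np.errstate(invalid="ignore"):
        keep = (miss <= max_missing) & (maf >= min_maf) & (maf > 0)
    keep &= ~np.isnan(maf)
    n_drop = int((~keep).sum())
    logger.info(
        "variant filter: kept %d of %d (removed %d)",
        int(keep.sum()),
        genotypes.n_variants,
        n_drop,
    )
    if keep.sum() == 0:
        warnings.warn("no variants survive filtering")
    return genotypes.subset_variants(keep)


def classify_infection(read_counts, threshold: int = 7000) -> np.ndarray:
    """Infection status from indicator-gene read counts: infected iff
    strictly more than ``threshold`` reads."""
    counts = np.asarray(read_counts)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    return (counts > threshold).astype(int)


def derive_phenotypes(pooled: pd.DataFrame) -> pd.DataFrame:
    """Per-line phenotype vectors for the four analyses.

    ``pooled`` has one row per line x sex with column ``p`` (pooled survival
    proportion).  Lines missing one sex get ``nan`` for average/difference.
    """
    wide = pooled.pivot_table(index="line_id", columns="sex", values="p")
    out = pd.DataFrame(index=wide.index)
    out["female"] = wide.get("F")
    out["male"] = wide.get("M")
    out["average"] = (out["female"] + out["male"]) / 2.0
    out["difference"] = out["female"] - out["male"]
    return out


def screen_covariates(
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Single-covariate linear-model screen.

    Each covariate is regressed against the phenotype separately; covariates
    with a two-sided slope P below ``alpha`` are flagged for inclusion in
    the mixed model.  Constant covariates are excluded with a warning.
    Returns a table (covariate, p_value, included).
    """
    common = phenotype.dropna().index.intersection(covariates.index)
    if len(common) < 10:
        raise ValueError("need >= 10 lines for the covariate screen")
    y = phenotype.loc[common].to_numpy(dtype=float)
    rows = []
    for name in covariates.columns:
        x = covariates.loc[common, name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"covariate {name!r} is constant; excluded")
            rows.append((name, float("nan"), False))
            continue
        res = stats.linregress(x, y)
        rows.append((name, float(res.pvalue), bool(res.pvalue < alpha)))
    return pd.DataFrame(rows, columns=["covariate", "p_value", "included"])


# ---------------------------------------------------------------------------
# GRM and the mixed model


def compute_grm(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centered genomic relationship matrix.

    ``G = (1/m) sum_k (x_k - xbar_k)(x_k - xbar_k)^T`` over the m variants,
    with missing genotypes mean-imputed per variant.  Symmetric PSD.
    """
    if genotypes.n_variants < 1:
        raise ValueError("GRM needs at least one variant")
    X = genotypes.calls.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    Xc = X - X.mean(axis=0)
    G = (Xc @ Xc.T) / genotypes.n_variants
    return (G + G.T) / 2.0


def _null_reml_delta(yr: np.ndarray, Wr: np.ndarray, lam: np.ndarray) -> float:
    """REML-optimal delta = s2_e / s2_g on the rotated model."""
    n, p = Wr.shape

    def neg_loglik(log_delta: float) -> float:
        w = lam + np.exp(log_delta)
        if np.any(w <= 0):
            return 1e12
        Dw = 1.0 / w
        WtW = Wr.T @ (Wr * Dw[:, None])
        Wty = Wr.T @ (yr * Dw)
        sign, ld_w = np.linalg.slogdet(WtW)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(WtW, Wty)
        ypy = float(yr @ (yr * Dw)) - float(Wty @ beta)
        if ypy <= 0:
            return 1e12
        return 0.5 * (
            (n - p) * np.log(ypy / (n - p)) + np.log(w).sum() + ld_w + (n - p)
        )

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_loglik(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_loglik, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def fit_null_model(
    y: np.ndarray, W: np.ndarray, grm: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """REML fit of ``y = W a + g + e`` with ``g ~ N(0, s2_g GRM)``.

    Returns ``(s2_g, s2_e, eigvals, eigvecs)`` of the GRM decomposition.
    """
    eigval, eigvec = np.linalg.eigh(grm)
    if eigval.min() < -1e-8 * max(1.0, eigval.max()):
        raise ValueError("GRM is not positive semidefinite")
    eigval = np.maximum(eigval, 0.0)
    yr = eigvec.T @ y
    Wr = eigvec.T @ W
    if eigval.max() <= 0:
        # no genetic variance representable: pure residual model
        resid = yr - Wr @ np.linalg.lstsq(Wr, yr, rcond=None)[0]
        s2e = float(resid @ resid) / (len(y) - W.shape[1])
        return 0.0, s2e, eigval, eigvec
    delta = _null_reml_delta(yr, Wr, eigval)
    w = eigval + delta
    Dw = 1.0 / w
    WtW = Wr.T @ (Wr * Dw[:, None])
    Wty = Wr.T @ (yr * Dw)
    beta = np.linalg.solve(WtW, Wty)
    ypy = float(yr @ (yr * Dw)) - float(Wty @ beta)
    n, p = Wr.shape
    s2g = ypy / (n - p)
    s2e = s2g * delta
    return float(s2g), float(s2e), eigval, eigvec


def lmm_wald(
    phenotype: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    grm: np.ndarray,
    analysis: str = "phenotype",
) -> pd.DataFrame:
    """Per-variant mixed-model Wald tests.

    ``phenotype`` is indexed by line id and aligned with ``genotypes`` /
    ``grm``; lines with missing phenotype are dropped up front.  Variants
    with missing genotypes are tested by case deletion against the submatrix
    of the fitted null covariance (exact GLS); variants monomorphic in the
    analysis subset are skipped.  The per-variant residual scale is
    re-estimated under the alternative, so with an identity-proportional GRM
    the test reduces exactly to ordinary least squares.
    """
    lids = np.asarray(genotypes.line_ids)
    pheno = phenotype.reindex(lids)
    keep = pheno.notna().to_numpy()
    if keep.sum() < 3:
        raise ValueError("too few lines with phenotype")
    y = pheno.to_numpy(dtype=float)[keep]
    sub_ids = lids[keep]
    G = grm[np.ix_(keep, keep)]
    X_all = genotypes.calls[keep, :]

    W = np.ones((y.size, 1))
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.reindex(sub_ids).to_numpy(dtype=float)
        if np.isnan(C).any():
            raise ValueError("missing covariate values for analysis lines")
        W = np.column_stack([W, C])

    phenotype_is_constant = bool(np.allclose(y, y[0]))
    if phenotype_is_constant:
        logger.warning("phenotype constant; all beta = 0, P = 1")
        s2g, s2e = 0.0, 1.0
        eigval, eigvec = np.linalg.eigh(G)
        eigval = np.maximum(eigval, 0.0)
    else:
        s2g, s2e, eigval, eigvec = fit_null_model(y, W, grm=G)
    V = s2g * G + s2e * np.eye(y.size)

    n, p = y.size, W.shape[1]
    w = s2g * eigval + s2e
    yr = eigvec.T @ y
    Wr = eigvec.T @ W
    Dw = 1.0 / w
    WtVW = Wr.T @ (Wr * Dw[:, None])
    WtVW_inv = np.linalg.inv(WtVW)
    Sy = (yr * Dw) - (Wr * Dw[:, None]) @ (WtVW_inv @ (Wr.T @ (yr * Dw)))
    ySy = float(yr @ Sy)

    rows = []
    maf_all = np.minimum(
        np.nanmean(X_all, axis=0) / 2.0, 1.0 - np.nanmean(X_all, axis=0) / 2.0
    )
    for k in range(genotypes.n_variants):
        x = X_all[:, k]
        obs = ~np.isnan(x)
        n_used = int(obs.sum())
        xo = x[obs]
        if n_used < 3 or np.all(xo == xo[0]):
            continue  # monomorphic or unusable in this subset
        vid = genotypes.variants["variant_id"].iloc[k]
        if phenotype_is_constant:
            rows.append((vid, analysis, 0.0, float("nan"), 1.0, maf_all[k], n_used))
            continue
        if obs.all():
            xr = eigvec.T @ x
            xSx = float(xr @ (xr * Dw)) - float(
                (Wr.T @ (xr * Dw)) @ (WtVW_inv @ (Wr.T @ (xr * Dw)))
            )
            xSy = float(xr @ Sy)
            ySy_k = ySy
            dof = n - p - 1
        else:
            Vo = V[np.ix_(obs, obs)]
            try:
                c, low = linalg.cho_factor(Vo, lower=True)
            except linalg.LinAlgError:
                continue
            yo = y[obs]
            Wo = W[obs]
            Vi_y = linalg.cho_solve((c, low), yo)
            Vi_W = linalg.cho_solve((c, low), Wo)
            Vi_x = linalg.cho_solve((c, low), xo)
            WtVWo_inv = np.linalg.inv(Wo.T @ Vi_W)
            xSx = float(xo @ Vi_x) - float((Wo.T @ Vi_x) @ WtVWo_inv @ (Wo.T @ Vi_x))
            xSy = float(xo @ Vi_y) - float((Wo.T @ Vi_x) @ WtVWo_inv @ (Wo.T @ Vi_y))
            ySy_k = float(yo @ Vi_y) - float((Wo.T @ Vi_y) @ WtVWo_inv @ (Wo.T @ Vi_y))
            dof = n_used - p - 1
        if xSx <= 0 or dof <= 0:
            continue
        beta = xSy / xSx
        rss = max(ySy_k - beta * xSy, 0.0)
        scale = rss / dof
        se = float(np.sqrt(scale / xSx))
        if se == 0.0:
            pval = 0.0 if beta != 0 else 1.0
        else:
            pval = float(stats.chi2.sf((beta / se) ** 2, df=1))
        rows.append((vid, analysis, float(beta), se, max(pval, 5e-324), maf_all[k], n_used))

    return pd.DataFrame(
        rows,
        columns=["variant_id", "analysis", "beta", "se_beta", "wald_p", "maf", "n_lines_used"],
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m`` for ``m`` tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def run_gwas(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    screen_alpha: float = 0.1,
    suggestive_p: float = 1e-5,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """All four analyses with per-analysis covariate screening and flags."""
    grm = compute_grm(genotypes)
    results = []
    for analysis in ANALYSES:
        y = phenotypes[analysis]
        cov_used = None
        if covariates is not None and covariates.shape[1] > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                screen = screen_covariates(y, covariates, alpha=screen_alpha)
            chosen = screen.loc[screen["included"], "covariate"].tolist()
            cov_used = covariates[chosen] if chosen else None
        res = lmm_wald(y, genotypes, cov_used, grm, analysis=analysis)
        results.append(res)
    out = pd.concat(results, ignore_index=True)
    thr = bonferroni_threshold(bonferroni_alpha, genotypes.n_variants)
    out["suggestive"] = out["wald_p"] <= suggestive_p
    out["bonferroni"] = out["wald_p"] < thr
    return out


def classify_sex_effects(
    results: pd.DataFrame, suggestive_p: float = 1e-5
) -> pd.DataFrame:
    """Classify variants by the sex architecture of their effects.

    A variant significant only in one sex is ``sex_specific_F``/``_M``; one
    significant in the difference analysis with opposite-signed per-sex
    effects is ``sex_antagonistic``; a single-sex hit that also crosses the
    threshold in the average analysis with a same-signed effect in the other
    sex additionally carries ``concordant_sex_specific``.  Everything else
    (including non-significant variants) is ``unclassified``.
    """
    have = set(results["analysis"].unique())
    missing = set(ANALYSES) - have
    if missing:
        raise ValueError(f"results missing analyses: {sorted(missing)}")
    p = results.pivot_table(index="variant_id", columns="analysis", values="wald_p")
    b = results.pivot_table(index="variant_id", columns="analysis", values="beta")

    rows = []
    for vid in p.index:
        sig = {a: bool(p.loc[vid].get(a, np.nan) <= suggestive_p) for a in ANALYSES}
        bf, bm = b.loc[vid].get("female", np.nan), b.loc[vid].get("male", np.nan)
        labels = []
        if sig["difference"] and np.isfinite(bf) and np.isfinite(bm) and bf * bm < 0:
            labels.append("sex_antagonistic")
        for sex, other_b in (("female", bm), ("male", bf)):
            other = "male" if sex == "female" else "female"
            if sig[sex] and not sig[other]:
                tag = "sex_specific_F" if sex == "female" else "sex_specific_M"
                labels.append(tag)
                same_sign = (
                    np.isfinite(bf) and np.isfinite(bm) and bf * bm > 0
                )
                if sig["average"] and same_sign:
                    labels.append("concordant_sex_specific")
        if not labels:
            labels = ["unclassified"]
        rows.append((vid, ";".join(labels)))
    return pd.DataFrame(rows, columns=["variant_id", "effect_class"])
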
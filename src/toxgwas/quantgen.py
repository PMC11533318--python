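"""Variance components, heritability and the cross-sex genetic correlation.

The screen's mixed model is ``Y = mu + L + S + LxS + eps`` with line (L) and
line-by-sex (LxS) random and sex (S) fixed; reduced per-sex models are
``Y = mu + L + eps``.  From the full-model components broad-sense
heritability is

    H2 = (s2_L + s2_LxS) / (s2_L + s2_LxS + s2_eps)

and, combining the full model with the two per-sex reduced models, the
cross-sex genetic correlation is

    r_GS = s2_L / (sqrt(s2_L,F) * sqrt(s2_L,M))

since the full-model among-line variance estimates the covariance of line
effects between sexes while each reduced-model line variance estimates the
per-sex genetic variance.

Estimation is REML, maximizing the restricted likelihood directly over the
non-negative variance components.  The covariance matrix is block-diagonal
by line (observations from different lines are independent), so the
likelihood is accumulated line-block by line-block, which keeps a 204-line
fit — and the leave-one-line-out jackknife for the r_GS standard error —
cheap.  For perfectly balanced designs the ANOVA / expected-mean-squares
method-of-moments solution is the REML optimum whenever it is interior, and
is used as the optimizer start.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .containers import QuantGenSummary, VarianceComponents

logger = logging.getLogger(__name__)

_REQUIRED = {"line_id", "sex", "value"}


def _check(df: pd.DataFrame, need_both_sexes: bool) -> None:
    missing = _REQUIRED - set(df.columns)
    if missing and not (missing == {"sex"} and not need_both_sexes):
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    if df["line_id"].nunique() < 2:
        raise ValueError("singular design: need >= 2 lines (factor 'line')")
    if need_both_sexes:
        sexes = df.groupby("line_id")["sex"].nunique()
        if (sexes < 2).any():
            raise ValueError(
                "singular design: every line needs both sexes (factor 'sex')"
            )


def is_balanced(df: pd.DataFrame, by_sex: bool = True) -> bool:
    cols = ["line_id", "sex"] if by_sex and "sex" in df.columns else ["line_id"]
    counts = df.groupby(cols)["value"].count()
    return counts.nunique() == 1 and counts.iloc[0] >= 2


# ---------------------------------------------------------------------------
# method of moments (expected mean squares), balanced designs


def anova_mean_squares(df: pd.DataFrame) -> dict:
    """Two-way mean squares for the balanced line x sex design with reps."""
    y = df["value"].to_numpy(dtype=float)
    g = y.mean()
    lines = df["line_id"].to_numpy()
    sexes = df["sex"].to_numpy()
    ulin, usex = np.unique(lines), np.unique(sexes)
    l, s = ulin.size, usex.size
    r = len(df) // (l * s)
    cell = df.groupby(["line_id", "sex"])["value"].mean().unstack()
    line_mean = cell.mean(axis=1)
    sex_mean = cell.mean(axis=0)
    ss_line = s * r * float(((line_mean - g) ** 2).sum())
    ss_sex = l * r * float(((sex_mean - g) ** 2).sum())
    inter = cell.sub(line_mean, axis=0).sub(sex_mean, axis=1) + g
    ss_inter = r * float((inter**2).to_numpy().sum())
    resid = y - df.merge(
        cell.stack().rename("cm"), left_on=["line_id", "sex"], right_index=True
    )["cm"].to_numpy()
    ss_err = float((resid**2).sum())
    df_line, df_sex, df_inter = l - 1, s - 1, (l - 1) * (s - 1)
    df_err = l * s * (r - 1)
    return {
        "l": l,
        "s": s,
        "r": r,
        "MS_line": ss_line / df_line,
        "MS_sex": ss_sex / df_sex,
        "MS_inter": ss_inter / df_inter,
        "MS_err": ss_err / df_err if df_err > 0 else float("nan"),
        "df": (df_line, df_sex, df_inter, df_err),
    }


def _mom_full(df: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...], dict]:
    ms = anova_mean_squares(df)
    s, r = ms["s"], ms["r"]
    raw = np.array(
        [
            (ms["MS_line"] - ms["MS_inter"]) / (s * r),
            (ms["MS_inter"] - ms["MS_err"]) / r,
            ms["MS_err"],
        ]
    )
    clamped = tuple(
        name
        for name, v in zip(("sigma2_line", "sigma2_line_sex", "sigma2_resid"), raw)
        if v < 0
    )
    return np.maximum(raw, 0.0), clamped, ms


def _mom_oneway(df: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    """One-way random model sigma2 estimates: ((MS_line - MS_err)/r, MS_err)."""
    grp = df.groupby("line_id")["value"]
    counts = grp.count()
    l = counts.size
    r = int(counts.iloc[0])
    g = df["value"].mean()
    ms_line = r * float(((grp.mean() - g) ** 2).sum()) / (l - 1)
    resid = df["value"].to_numpy() - grp.transform("mean").to_numpy()
    df_err = l * (r - 1)
    ms_err = float((resid**2).sum()) / df_err if df_err > 0 else float("nan")
    raw = np.array([(ms_line - ms_err) / r, ms_err])
    clamped = ("sigma2_line",) if raw[0] < 0 else ()
    return np.maximum(raw, 0.0), clamped


# ---------------------------------------------------------------------------
# REML, block-diagonal by line


def _line_blocks(df: pd.DataFrame, with_sex: bool):
    """Per-line (y, sex-code, X) blocks; X = [1, male] or [1]."""
    blocks = []
    for _, grp in df.groupby("line_id", sort=True):
        y = grp["value"].to_numpy(dtype=float)
        if with_sex:
            male = (grp["sex"].to_numpy() == "M").astype(float)
            X = np.column_stack([np.ones_like(y), male])
        else:
            male = None
            X = np.ones((y.size, 1))
        blocks.append((y, male, X))
    return blocks


def _neg_reml(theta: np.ndarray, blocks, with_inter: bool) -> float:
    if with_inter:
        s2l, s2ls, s2e = theta
    else:
        s2l, s2e = theta
        s2ls = 0.0
    p = blocks[0][2].shape[1]
    logdet = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for y, male, X in blocks:
        n = y.size
        V = np.full((n, n), s2l)
        if with_inter:
            same = male[:, None] == male[None, :]
            V += np.where(same, s2ls, 0.0)
        V[np.diag_indices(n)] += s2e
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * float(np.log(np.diag(c)).sum())
        Vi_X = linalg.cho_solve((c, low), X)
        Vi_y = linalg.cho_solve((c, low), y)
        xtvx += X.T @ Vi_X
        xtvy += X.T @ Vi_y
        ytvy += float(y @ Vi_y)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - float(xtvy @ beta)
    return 0.5 * (logdet + logdet_x + ypy)


def _reml_fit(
    df: pd.DataFrame, with_inter: bool, start: np.ndarray
) -> tuple[np.ndarray, tuple[str, ...]]:
    blocks = _line_blocks(df, with_sex=with_inter)
    vals = df["value"].to_numpy()
    scale = float(np.var(vals, ddof=1))
    if scale <= 1e-24 * max(1.0, float(np.mean(vals)) ** 2):
        k = 3 if with_inter else 2
        return np.zeros(k), ()
    floor = 1e-10 * scale
    x0 = np.maximum(np.asarray(start, dtype=float), 0.0)
    x0[-1] = max(x0[-1], 1e-3 * scale)
    bounds = [(0.0, None)] * (len(x0) - 1) + [(floor, None)]
    res = optimize.minimize(
        _neg_reml,
        x0,
        args=(blocks, with_inter),
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    theta = np.maximum(res.x, 0.0)
    clamped = ()
    return theta, clamped


# ---------------------------------------------------------------------------
# public fitting API


def fit_full_model(df: pd.DataFrame, method: str = "reml") -> VarianceComponents:
    """Fit ``Y = mu + L + S + LxS + eps`` to replicate-level phenotypes.

    ``df`` needs columns ``line_id, sex, value`` (one row per replicate).
    ``method`` is ``"reml"`` (default), ``"mom"`` (balanced designs only) or
    ``"auto"`` (method of moments when balanced, REML otherwise).
    """
    _check(df, need_both_sexes=True)
    balanced = is_balanced(df)
    if method == "mom" and not balanced:
        raise ValueError("method-of-moments requires a balanced design")
    if method == "auto":
        method = "mom" if balanced else "reml"

    if balanced:
        mom, clamped, _ = _mom_full(df)
    else:
        v = float(np.var(df["value"], ddof=1))
        mom, clamped = np.array([v / 3, v / 3, v / 3]), ()
    if method == "mom":
        theta = mom
    else:
        theta, _ = _reml_fit(df, with_inter=True, start=mom)
        clamped = tuple(
            n
            for n, t in zip(
                ("sigma2_line", "sigma2_line_sex", "sigma2_resid"), theta
            )
            if t == 0.0
        )
    return VarianceComponents(
        sigma2_line=float(theta[0]),
        sigma2_line_sex=float(theta[1]),
        sigma2_resid=float(theta[2]),
        estimation_method=method.upper(),
        clamped=clamped,
    )


def fit_reduced_model(
    df: pd.DataFrame, method: str = "reml"
) -> tuple[float, float]:
    """Fit the one-sex reduced model ``Y = mu + L + eps``.

    Returns ``(sigma2_line, sigma2_resid)``.  ``df`` holds one sex only.
    """
    _check(df, need_both_sexes=False)
    if "sex" in df.columns and df["sex"].nunique() > 1:
        raise ValueError("reduced model expects a single-sex table")
    balanced = is_balanced(df, by_sex=False)
    if method == "mom" and not balanced:
        raise ValueError("method-of-moments requires a balanced design")
    if method == "auto":
        method = "mom" if balanced else "reml"
    if balanced:
        mom, _ = _mom_oneway(df)
    else:
        v = float(np.var(df["value"], ddof=1))
        mom = np.array([v / 2, v / 2])
    if method == "mom":
        theta = mom
    else:
        theta, _ = _reml_fit(df, with_inter=False, start=mom)
    return float(theta[0]), float(theta[1])


def heritability(components: VarianceComponents) -> dict[str, float]:
    """Broad-sense heritabilities from fitted variance components.

    Pooled: ``(s2_L + s2_LxS) / (s2_L + s2_LxS + s2_eps)``; per sex:
    ``s2_L,sex / (s2_L,sex + s2_eps,sex)`` from the reduced models when
    present.  Zero total variance yields ``nan``.
    """
    tot = (
        components.sigma2_line
        + components.sigma2_line_sex
        + components.sigma2_resid
    )
    out = {
        "H2_pooled": (
            (components.sigma2_line + components.sigma2_line_sex) / tot
            if tot > 0
            else float("nan")
        )
    }
    for sex in ("F", "M"):
        s2l = getattr(components, f"sigma2_line_{sex}")
        s2e = getattr(components, f"sigma2_resid_{sex}")
        if s2l is None or s2e is None:
            out[f"H2_{'female' if sex == 'F' else 'male'}"] = float("nan")
        else:
            t = s2l + s2e
            out[f"H2_{'female' if sex == 'F' else 'male'}"] = (
                s2l / t if t > 0 else float("nan")
            )
    return out


def cross_sex_correlation(components: VarianceComponents) -> float:
    """``r_GS = s2_L / (sqrt(s2_L,F) sqrt(s2_L,M))``.

    May exceed 1 through sampling noise; that is reported as computed.
    Returns ``nan`` when either per-sex line variance is zero/absent.
    """
    s2lf, s2lm = components.sigma2_line_F, components.sigma2_line_M
    if not s2lf or not s2lm or s2lf <= 0 or s2lm <= 0:
        warnings.warn("per-sex line variance zero or missing; r_GS undefined")
        return float("nan")
    return components.sigma2_line / math.sqrt(s2lf * s2lm)


def _r_gs_estimator(df: pd.DataFrame, method: str) -> float:
    vc = fit_full_model(df, method=method)
    s2lf, _ = fit_reduced_model(df[df["sex"] == "F"], method=method)
    s2lm, _ = fit_reduced_model(df[df["sex"] == "M"], method=method)
    if s2lf <= 0 or s2lm <= 0:
        return float("nan")
    return vc.sigma2_line / math.sqrt(s2lf * s2lm)


def jackknife_r_gs_se(df: pd.DataFrame, method: str = "auto") -> float:
    """Leave-one-line-out jackknife standard error of r_GS."""
    lines = df["line_id"].unique()
    n = lines.size
    vals = []
    for lid in lines:
        v = _r_gs_estimator(df[df["line_id"] != lid], method=method)
        if np.isfinite(v):
            vals.append(v)
    if len(vals) < max(3, n // 2):
        return float("nan")
    vals = np.asarray(vals)
    k = vals.size
    return float(np.sqrt((k - 1) / k * ((vals - vals.mean()) ** 2).sum()))


def sex_effect_test(df: pd.DataFrame) -> float:
    """P-value of the fixed sex effect.

    Balanced designs: exact F-test with the interaction mean square as
    denominator, ``F = MS_S / MS_LxS`` on ``(s-1, (l-1)(s-1))`` df.
    Unbalanced designs fall back to a GLS Wald z-test under the REML fit.
    """
    if is_balanced(df):
        ms = anova_mean_squares(df)
        f = ms["MS_sex"] / ms["MS_inter"]
        _, df_sex, df_inter, _ = ms["df"]
        return float(stats.f.sf(f, df_sex, df_inter))
    vc = fit_full_model(df, method="reml")
    blocks = _line_blocks(df, with_sex=True)
    theta = np.array([vc.sigma2_line, vc.sigma2_line_sex, vc.sigma2_resid])
    theta[2] = max(theta[2], 1e-12)
    xtvx = np.zeros((2, 2))
    xtvy = np.zeros(2)
    for y, male, X in blocks:
        n = y.size
        V = np.full((n, n), theta[0])
        same = male[:, None] == male[None, :]
        V += np.where(same, theta[1], 0.0)
        V[np.diag_indices(n)] += theta[2]
        Vi_X = np.linalg.solve(V, X)
        xtvx += X.T @ Vi_X
        xtvy += X.T @ np.linalg.solve(V, y)
    cov = np.linalg.inv(xtvx)
    beta = cov @ xtvy
    z = beta[1] / math.sqrt(cov[1, 1])
    return float(2 * stats.norm.sf(abs(z)))


def quantgen_summary(
    df: pd.DataFrame,
    method: str = "reml",
    jackknife: bool = True,
) -> QuantGenSummary:
    """Full + reduced model fits with H2, r_GS (and jackknife SE) in one call."""
    vc = fit_full_model(df, method=method)
    s2lf, s2ef = fit_reduced_model(df[df["sex"] == "F"], method=method)
    s2lm, s2em = fit_reduced_model(df[df["sex"] == "M"], method=method)
    vc = replace(
        vc,
        sigma2_line_F=s2lf,
        sigma2_resid_F=s2ef,
        sigma2_line_M=s2lm,
        sigma2_resid_M=s2em,
    )
    h2 = heritability(vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_gs = cross_sex_correlation(vc)
    flags = []
    if np.isfinite(r_gs) and abs(r_gs) > 1:
        flags.append("r_GS_outside_unit_interval")
    if vc.clamped:
        flags.append("components_clamped")
    se = (
        jackknife_r_gs_se(df, method="auto" if method == "reml" else method)
        if jackknife and np.isfinite(r_gs)
        else None
    )
    ratio = (
        vc.sigma2_line_sex / vc.sigma2_line if vc.sigma2_line > 0 else float("nan")
    )
    return QuantGenSummary(
        H2_pooled=h2["H2_pooled"],
        H2_female=h2["H2_female"],
        H2_male=h2["H2_male"],
        r_GS=r_gs if np.isfinite(r_gs) else None,
        r_GS_se=se,
        sex_effect_p=sex_effect_test(df),
        interaction_to_line_ratio=ratio,
        components=vc,
        flags=tuple(flags),
    )
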
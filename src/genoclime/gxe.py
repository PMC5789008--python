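"""Gene-by-environment moderated regression at the population level.

The core test asks whether the dopaminergic gene index (DA) predicts a
population trait mean only under high climatic demand (CD): OLS of the trait
on mean-centred DA, CD and their product, where the product term carries the
interaction hypothesis.  The module reports the nested-model variance
partition (main effects vs interaction increment, with the incremental F),
directional one-sided tests, simple slopes of DA at ±1 SD of CD, a
population-resampling percentile bootstrap for the interaction, hierarchical
control blocks (wealth/parasite stress; climate × wealth), a Mahalanobis
multivariate outlier screen, and Bonferroni adjustment for families of
tests.

Coefficients are reported on two scales: the centred raw scale of the input
variables, and a predictor-standardised scale (each predictor z-scored, the
product formed from z-scores) on which effect sizes are comparable across
traits and instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def mean_center(values):
    """Subtract the mean; differences between entries are preserved."""
    arr = np.asarray(values, dtype=float)
    centred = arr - arr.mean()
    if isinstance(values, pd.Series):
        return pd.Series(centred, index=values.index, name=values.name)
    return centred


def _one_sided_p(estimate: float, p_two: float, hyp_sign: int) -> float:
    """Directional p: half the two-sided p if the sign matches, else 1 - half."""
    if np.sign(estimate) == np.sign(hyp_sign) or estimate == 0:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    # walk columns to name the ones that add no rank
    culprits = []
    rank = 0
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(mat[:, : j + 1])
        if r == rank:
            culprits.append(str(col))
        rank = r
    raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def _dummy_columns(cat: pd.Series, prefix: str) -> pd.DataFrame:
    """Dummy-code a categorical column, dropping the alphabetically first level."""
    levels = sorted(cat.astype(str).unique())
    cols = {}
    for level in levels[1:]:
        cols[f"{prefix}[{level}]"] = (cat.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=cat.index)


def _build_design(
    cc: pd.DataFrame,
    x: str,
    z: str,
    covariates: Sequence[str],
    dummies: str | None,
    extra_products: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, str, dict[str, float]]:
    """Mean-centred design matrix (without the focal product term).

    Returns the frame of centred predictors plus dummy codes, the name of
    the focal interaction column (not yet included), and the SD of every
    centred continuous predictor (ddof=1), used for standardised reporting.
    """
    design = pd.DataFrame(index=cc.index)
    sds: dict[str, float] = {}
    for col in [x, z, *covariates]:
        centred = mean_center(cc[col])
        design[col] = centred
        sds[col] = float(centred.std(ddof=1))
    for a, b in extra_products:
        name = f"{a}:{b}"
        design[name] = design[a] * design[b]
        sds[name] = sds[a] * sds[b]
    if dummies is not None:
        design = pd.concat([design, _dummy_columns(cc[dummies], dummies)], axis=1)
    return design, f"{x}:{z}", sds


@dataclass
class ModeratedRegressionResult:
    """Everything the moderated-regression contract reports."""

    y: str
    x: str
    z: str
    direction: str
    n: int
    terms: pd.DataFrame  # estimate, se, t, p_two, p_one, estimate_std, se_std
    r2_main: float
    r2_full: float
    delta_r2: float
    delta_F: float
    delta_F_df: tuple[int, int]
    delta_F_p: float
    f_full: float
    f_df: tuple[int, int]
    f_p: float
    sd_moderator: float
    df_resid: int
    cov_params: pd.DataFrame
    interaction_term: str
    simple_slopes: pd.DataFrame | None = None
    bootstrap: dict | None = None
    dropped_rows: tuple = ()

    def to_dict(self) -> dict:
        out = {
            "y": self.y, "x": self.x, "z": self.z,
            "direction": self.direction, "n": self.n,
            "coefficients": {
                term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for term, row in self.terms.iterrows()
            },
            "r2_main": float(self.r2_main),
            "r2_full": float(self.r2_full),
            "delta_r2": float(self.delta_r2),
            "delta_F": float(self.delta_F),
            "delta_F_df": list(self.delta_F_df),
            "delta_F_p": float(self.delta_F_p),
            "f_full": float(self.f_full),
            "f_df": list(self.f_df),
            "f_p": float(self.f_p),
            "sd_moderator": float(self.sd_moderator),
        }
        if self.simple_slopes is not None:
            out["simple_slopes"] = self.simple_slopes.to_dict("records")
        if self.bootstrap is not None:
            out["bootstrap"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.bootstrap.items()
                if k != "estimates"
            }
        return out


def fit_moderated(
    data: pd.DataFrame,
    y: str,
    x: str,
    z: str,
    covariates: Sequence[str] = (),
    dummies: str | None = None,
    direction: str = "pos",
    bootstrap: int = 0,
    bootstrap_seed: int | None = None,
) -> ModeratedRegressionResult:
    """Moderated regression of ``y`` on centred ``x``, ``z`` and their product.

    The reduced model contains everything but the product term; the full
    model adds it.  ``direction`` ("pos"/"neg") is the a-priori sign of the
    interaction (and of the focal predictor's effect under high demand) and
    determines the one-sided p-values for ``x`` and ``x:z``; other terms get
    two-sided p-values only.  Optional covariates are mean-centred and enter
    both models, as do dummy codes for the categorical ``dummies`` column
    (reference level = alphabetically first).

    With ``bootstrap > 0``, populations are resampled with replacement and a
    percentile confidence interval for the interaction coefficient is
    attached.
    """
    if direction not in ("pos", "neg"):
        raise ValueError("direction must be 'pos' or 'neg'")
    cols = [y, x, z, *covariates] + ([dummies] if dummies else [])
    cc = data[cols].dropna()
    n = len(cc)
    if n < 8:
        raise ValueError(f"only {n} complete cases; need at least 8")
    dropped = tuple(data.index.difference(cc.index))
    if dropped:
        logger.info("fit_moderated %s: excluded %d incomplete rows: %s", y, len(dropped), list(dropped))

    design, inter, sds = _build_design(cc, x, z, covariates, dummies)
    X_reduced = sm.add_constant(design, prepend=True, has_constant="add")
    X_full = X_reduced.copy()
    X_full[inter] = design[x] * design[z]
    sds[inter] = sds[x] * sds[z]
    _check_full_rank(X_full)

    yv = cc[y].astype(float)
    fit_r = sm.OLS(yv, X_reduced).fit()
    fit_f = sm.OLS(yv, X_full).fit()

    p_full = X_full.shape[1]
    hyp_sign = 1 if direction == "pos" else -1
    rows = {}
    for term in X_full.columns:
        est = fit_f.params[term]
        p2 = fit_f.pvalues[term]
        scale = sds.get(term, 1.0) if term != "const" else 1.0
        rows[term] = {
            "estimate": est,
            "se": fit_f.bse[term],
            "t": fit_f.tvalues[term],
            "p_two": p2,
            "p_one": _one_sided_p(est, p2, hyp_sign) if term in (x, inter) else np.nan,
            "estimate_std": est * scale,
            "se_std": fit_f.bse[term] * scale,
        }
    terms = pd.DataFrame.from_dict(rows, orient="index")

    r2_main = float(fit_r.rsquared)
    r2_full = float(fit_f.rsquared)
    if 1.0 - r2_full < 1e-12:
        # saturated (noise-free) fit: the incremental F diverges
        dF, df1, df2, dFp = np.inf, 1, n - p_full, 0.0
    else:
        dF, df1, df2, dFp = delta_f(r2_main, r2_full, n, p_full)

    result = ModeratedRegressionResult(
        y=y, x=x, z=z, direction=direction, n=n,
        terms=terms,
        r2_main=r2_main, r2_full=r2_full, delta_r2=r2_full - r2_main,
        delta_F=dF, delta_F_df=(df1, df2), delta_F_p=dFp,
        f_full=float(fit_f.fvalue), f_df=(p_full - 1, n - p_full),
        f_p=float(fit_f.f_pvalue),
        sd_moderator=sds[z],
        df_resid=int(fit_f.df_resid),
        cov_params=fit_f.cov_params(),
        interaction_term=inter,
        dropped_rows=dropped,
    )
    result.simple_slopes = simple_slopes(result, sds[z])
    if bootstrap:
        result.bootstrap = bootstrap_interaction(
            data, y, x, z, covariates=covariates, dummies=dummies,
            B=bootstrap, seed=bootstrap_seed,
        )
    return result


class DeltaF(tuple):
    """(F, df1, df2, p) for an incremental-R² test."""
    __slots__ = ()

    def __new__(cls, F, df1, df2, p):
        return super().__new__(cls, (F, df1, df2, p))

    F = property(lambda self: self[0])
    df1 = property(lambda self: self[1])
    df2 = property(lambda self: self[2])
    p = property(lambda self: self[3])


def delta_f(r2_reduced: float, r2_full: float, n: int, p_full: int, q: int = 1) -> DeltaF:
    """Incremental F for ``q`` added terms: ((R²f−R²r)/q) / ((1−R²f)/(n−p_full)).

    ``p_full`` counts all parameters of the full model including the
    intercept; the test has (q, n − p_full) degrees of freedom.
    """
    if not (0.0 <= r2_reduced <= r2_full):
        raise ValueError("need 0 <= r2_reduced <= r2_full")
    if r2_full >= 1.0:
        raise ValueError("r2_full must be < 1")
    if n <= p_full:
        raise ValueError("need n > p_full")
    df2 = n - p_full
    F = ((r2_full - r2_reduced) / q) / ((1.0 - r2_full) / df2)
    p = float(stats.f.sf(F, q, df2))
    return DeltaF(float(F), q, df2, p)


def simple_slopes(result: ModeratedRegressionResult, sd_z: float) -> pd.DataFrame:
    """Conditional slope of ``x`` at moderator values ±``sd_z`` around its mean.

    slope(z0) = b_x + b_xz·z0 with variance var(b_x) + z0²·var(b_xz) +
    2·z0·cov; t is referred to the full model's residual df and the
    one-sided p uses the model's hypothesised direction.
    """
    cov = result.cov_params
    x, inter = result.x, result.interaction_term
    if x not in cov.index or inter not in cov.index:
        raise ValueError("coefficient covariance for x and x:z is unavailable")
    b1 = result.terms.loc[x, "estimate"]
    b3 = result.terms.loc[inter, "estimate"]
    hyp_sign = 1 if result.direction == "pos" else -1
    rows = []
    for label, z0 in (("-1SD", -sd_z), ("+1SD", +sd_z)):
        slope = b1 + b3 * z0
        var = (
            cov.loc[x, x] + z0**2 * cov.loc[inter, inter] + 2 * z0 * cov.loc[x, inter]
        )
        se = float(np.sqrt(var))
        t = slope / se
        p2 = 2 * stats.t.sf(abs(t), result.df_resid)
        rows.append({
            "at": label, "z0": float(z0), "slope": float(slope), "se": se,
            "t": float(t), "p_one": _one_sided_p(slope, p2, hyp_sign),
            "p_two": float(p2),
        })
    return pd.DataFrame(rows)


def bootstrap_interaction(
    data: pd.DataFrame,
    y: str,
    x: str,
    z: str,
    covariates: Sequence[str] = (),
    dummies: str | None = None,
    B: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Percentile bootstrap of the interaction coefficient over populations.

    Populations (rows) are resampled with replacement ``B`` times and the
    full model is refit on each resample (recentring within the resample).
    Rank-deficient resamples — e.g. a dummy level vanishing — are redrawn,
    up to ``10·B`` attempts.  Returns the percentile CI and the sign-based
    two-tailed bootstrap p ``2·min(frac ≤ 0, frac ≥ 0)``.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100")
    cols = [y, x, z, *covariates] + ([dummies] if dummies else [])
    cc = data[cols].dropna().reset_index(drop=True)
    n = len(cc)
    rng = np.random.default_rng(seed)

    estimates = np.empty(B)
    redrawn = 0
    attempts = 0
    b = 0
    while b < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("too many rank-deficient bootstrap resamples")
        idx = rng.integers(0, n, n)
        boot = cc.iloc[idx]
        design, inter, _ = _build_design(boot, x, z, covariates, dummies)
        X = np.column_stack([
            np.ones(n), design.to_numpy(dtype=float),
            (design[x] * design[z]).to_numpy(dtype=float),
        ])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            redrawn += 1
            logger.debug("redrawing rank-deficient bootstrap resample %d", attempts)
            continue
        coef, *_ = np.linalg.lstsq(X, boot[y].to_numpy(dtype=float), rcond=None)
        estimates[b] = coef[-1]
        b += 1

    lo_q = 100 * (1 - ci_level) / 2
    ci = (float(np.percentile(estimates, lo_q)), float(np.percentile(estimates, 100 - lo_q)))
    frac_le = float(np.mean(estimates <= 0))
    frac_ge = float(np.mean(estimates >= 0))
    return {
        "B": B,
        "seed": seed,
        "ci_level": ci_level,
        "ci": ci,
        "p": min(1.0, 2.0 * min(frac_le, frac_ge)),
        "n_redrawn": redrawn,
        "estimates": estimates,
    }


def outlier_screen(
    data: pd.DataFrame, variables: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Mahalanobis multivariate outlier test.

    Squared Mahalanobis distance of each complete row from the centroid is
    referred to a chi-square with ``len(variables)`` df; rows whose
    Bonferroni-adjusted p falls below ``alpha`` are flagged.
    """
    cc = data[list(variables)].dropna()
    p = len(variables)
    if len(cc) < p + 2:
        raise ValueError(f"need at least {p + 2} complete rows for {p} variables")
    X = cc.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < p:
        raise ValueError("singular covariance matrix; outlier distances undefined")
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    pvals = stats.chi2.sf(d2, df=p)
    p_adj = adjust_pvalues(pvals)
    return pd.DataFrame(
        {"d2": d2, "p": pvals, "p_bonferroni": p_adj, "flagged": p_adj < alpha},
        index=cc.index,
    )


def hierarchical_controls(
    data: pd.DataFrame,
    y: str,
    blocks: Sequence[Sequence[str]],
    dummies: str | None = None,
) -> list[dict]:
    """Hierarchical regression: ΔR² and incremental F at each block boundary.

    ``blocks`` is an ordered list of predictor sets; a term ``"a:b"`` denotes
    the product of mean-centred ``a`` and ``b``.  Typical orders are
    ``[[wealth, parasite], [DA, CD], [DA:CD]]`` (covariate controls first)
    and ``[[CD, wealth, CD:wealth], [DA], [DA:CD]]`` (the climate-by-wealth
    competitive model first).  Returns one record per block with the
    cumulative R², the block's ΔR² and its F test.
    """
    base_vars = sorted({v for block in blocks for t in block for v in t.split(":")})
    cols = [y, *base_vars] + ([dummies] if dummies else [])
    cc = data[cols].dropna()
    n = len(cc)
    if n < 8:
        raise ValueError(f"only {n} complete cases; need at least 8")

    centred = {v: mean_center(cc[v]) for v in base_vars}

    def term_column(term: str) -> pd.Series:
        parts = term.split(":")
        col = centred[parts[0]].copy()
        for p_ in parts[1:]:
            col = col * centred[p_]
        return col

    X = pd.DataFrame({"const": np.ones(n)}, index=cc.index)
    if dummies is not None:
        X = pd.concat([X, _dummy_columns(cc[dummies], dummies)], axis=1)
    yv = cc[y].astype(float)

    prev_r2 = float(sm.OLS(yv, X).fit().rsquared) if X.shape[1] > 1 else 0.0
    report: list[dict] = []
    for block in blocks:
        for term in block:
            X[term] = term_column(term)
        # an identically-zero term contributes nothing (its delta-R2 is 0);
        # only genuinely collinear nonzero columns are an error
        nonzero = X.loc[:, (X != 0).any()]
        _check_full_rank(nonzero)
        fit = sm.OLS(yv, X).fit()
        r2 = float(fit.rsquared)
        q = len(block)
        dF, df1, df2, p = delta_f(prev_r2, r2, n, X.shape[1], q=q)
        report.append({
            "block": list(block), "n": n, "r2": r2,
            "delta_r2": r2 - prev_r2, "F": dF, "df": (df1, df2), "p": p,
        })
        prev_r2 = r2
    return report


def adjust_pvalues(pvals, method: str = "bonferroni", m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment; Bonferroni is ``min(1, m·p)``."""
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bonferroni":
        raise ValueError(f"unsupported adjustment method {method!r}")
    m = len(arr) if m is None else m
    return np.minimum(1.0, m * arr)
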
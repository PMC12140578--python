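"""Paired tests, sign-flip permutation edge statistics, FDR, and regressions.

The permutation test for the condition effect on edge-wise IC changes uses
subject-level sign flips: under the null hypothesis of no stimulation
effect, each subject's (active - control) difference vector is symmetric
around zero, so flipping its sign is an exchangeable transformation. One
sign vector is drawn per permutation and applied to *all* edges, which
preserves the correlation structure between edges. Monte-Carlo p-values use
the +1 correction, p = (1 + #{|t*| >= |t|}) / (1 + n_perm), so they are
valid (never zero).

Multiple-testing correction is Benjamini-Hochberg by default
(Benjamini-Yekutieli by flag). Brain-behavior models are ordinary least
squares with backward elimination at a removal threshold of p >= 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError

__all__ = [
    "StatResult",
    "RegressionResult",
    "paired_t",
    "perm_paired_edges",
    "fdr_bh",
    "backward_regression",
    "simple_regression",
]


@dataclass
class StatResult:
    """A single test statistic with its p-value(s)."""

    statistic: float
    df: float
    p: float
    p_adjusted: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    degenerate: bool = False


@dataclass
class RegressionResult:
    """An OLS fit (possibly after backward elimination).

    ``coef``/``se``/``beta`` are indexed by the retained predictor names;
    ``beta`` is the fully standardized coefficient (slope after z-scoring
    response and predictor). ``trace`` records each elimination step.
    """

    predictors: list[str]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    beta: pd.Series
    intercept: float
    intercept_se: float
    r_squared: float
    model_p: float
    n: int
    trace: list[dict] = field(default_factory=list)


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Classical two-sided paired t-test on equal-length samples.

    Zero variance of the differences is degenerate: with all differences
    zero the result is t = 0, p = 1; with a non-zero constant difference
    the statistic is unbounded and only the flag is meaningful.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired_t needs two equal-length 1-D samples")
    n = x.size
    if n < 2:
        raise InputError("paired_t needs n >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(np.abs(d).max(), 1.0):
        if np.all(d == 0.0):
            return StatResult(statistic=0.0, df=n - 1, p=1.0, degenerate=True)
        return StatResult(
            statistic=float(np.sign(d.mean()) * np.inf), df=n - 1, p=0.0, degenerate=True
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return StatResult(statistic=float(t), df=n - 1, p=float(p))


def _edge_t(D: np.ndarray) -> np.ndarray:
    """Paired t statistics per column of a subjects x edges difference matrix."""
    n = D.shape[0]
    mean = D.mean(axis=0)
    var = D.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[var == 0.0] = np.where(mean[var == 0.0] == 0.0, 0.0, np.inf)
    return t


def perm_paired_edges(
    delta_active: np.ndarray | pd.DataFrame,
    delta_control: np.ndarray | pd.DataFrame,
    n_perm: int = 5000,
    seed: int | None = None,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Sign-flip permutation paired t-test per edge with FDR correction.

    Parameters
    ----------
    delta_active, delta_control : (n_subjects, n_edges)
        Per-subject post-pre IC change under the active and control
        condition; the tested quantity is their difference.
    n_perm : int
        Monte-Carlo draws from the 2^n sign-flip distribution (default 5000).
    seed : int
        Seed of the permutation stream (recorded in the output attrs).

    Returns
    -------
    DataFrame with per-edge columns ``t``, ``p``, ``p_fdr``, ``sign``;
    ``.attrs`` carries ``n_perm``, ``seed``, ``n_subjects``.
    """
    A = np.asarray(delta_active, dtype=np.float64)
    C = np.asarray(delta_control, dtype=np.float64)
    if A.shape != C.shape or A.ndim != 2:
        raise InputError("need matching (n_subjects, n_edges) matrices")
    n, n_edges = A.shape
    if n < 2:
        raise InputError("permutation test needs >= 2 subjects")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    D = A - C
    t_obs = _edge_t(D)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # Sum of squares per edge is invariant under sign flips, so the permuted
    # t statistic is a function of the permuted mean alone.
    ss = (D**2).sum(axis=0)
    M = signs @ D / n  # (n_perm, n_edges)
    var = (ss[None, :] - n * M**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = M / np.sqrt(var / n)
    t_star[~np.isfinite(t_star)] = np.where(
        M[~np.isfinite(t_star)] == 0.0, 0.0, np.inf
    )
    exceed = (np.abs(t_star) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)

    out = pd.DataFrame(
        {
            "t": t_obs,
            "p": p,
            "p_fdr": fdr_bh(p, method=fdr_method),
            "sign": np.sign(t_obs).astype(int),
        }
    )
    out.attrs.update({"n_perm": n_perm, "seed": seed, "n_subjects": n})
    return out


def fdr_bh(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or, with ``method="by"``, Benjamini-Yekutieli)
    step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise InputError(f"unknown FDR method {method!r}")
    return multipletests(p, method=sm_method)[1]


def _check_design(X: pd.DataFrame, n_min: int) -> None:
    if X.shape[0] < n_min:
        raise InputError(f"need at least {n_min} observations, got {X.shape[0]}")
    design = add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns involved in the exact collinearity
        corr = X.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else (X.columns[0],)
        raise InputError(f"singular design matrix; check predictors {sorted(set(worst))}")


def _fit_ols(y: pd.Series, X: pd.DataFrame) -> tuple:
    model = OLS(y.to_numpy(), add_constant(X, has_constant="add").to_numpy()).fit()
    return model


def _standardized_betas(y: pd.Series, X: pd.DataFrame, coef: pd.Series) -> pd.Series:
    sy = y.std(ddof=1)
    return pd.Series(
        {c: coef[c] * X[c].std(ddof=1) / sy for c in X.columns}, dtype=float
    )


def backward_regression(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    removal_p: float = 0.10,
    min_predictors: int = 0,
) -> RegressionResult:
    """Backward stepwise OLS: start full, repeatedly drop the least
    significant predictor while its p-value exceeds ``removal_p``.

    Returns the final model with unstandardized B, SE B, standardized beta,
    model R-squared and F-test p, plus the elimination trace. With
    ``removal_p=1`` this is the full model; with ``removal_p=0`` elimination
    runs to the intercept-only model.
    """
    y = pd.Series(np.asarray(y, dtype=np.float64))
    X = pd.DataFrame(X).reset_index(drop=True).astype(float)
    if y.size != X.shape[0]:
        raise InputError("response and predictors differ in length")
    _check_design(X, n_min=X.shape[1] + 2)

    kept = list(X.columns)
    trace: list[dict] = []
    while True:
        if not kept:
            resid = y - y.mean()
            return RegressionResult(
                predictors=[], coef=pd.Series(dtype=float), se=pd.Series(dtype=float),
                pvalues=pd.Series(dtype=float), beta=pd.Series(dtype=float),
                intercept=float(y.mean()),
                intercept_se=float(y.std(ddof=1) / np.sqrt(y.size)),
                r_squared=0.0, model_p=np.nan, n=int(y.size), trace=trace,
            )
        model = _fit_ols(y, X[kept])
        pvals = pd.Series(model.pvalues[1:], index=kept)
        worst = pvals.idxmax()
        if pvals[worst] > removal_p and len(kept) > min_predictors:
            trace.append({"removed": worst, "p": float(pvals[worst]),
                          "step_r_squared": float(model.rsquared)})
            kept.remove(worst)
            continue
        coef = pd.Series(model.params[1:], index=kept)
        return RegressionResult(
            predictors=list(kept),
            coef=coef,
            se=pd.Series(model.bse[1:], index=kept),
            pvalues=pvals,
            beta=_standardized_betas(y, X[kept], coef),
            intercept=float(model.params[0]),
            intercept_se=float(model.bse[0]),
            r_squared=float(model.rsquared),
            model_p=float(model.f_pvalue),
            n=int(y.size),
            trace=trace,
        )


def simple_regression(y: np.ndarray, x: np.ndarray, name: str = "x") -> RegressionResult:
    """Simple OLS of ``y`` on one predictor; standardized beta equals the
    Pearson correlation and R-squared equals its square."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise InputError("simple_regression needs two equal-length 1-D arrays")
    if y.size < 3:
        raise InputError("simple_regression needs n >= 3")
    if np.std(x, ddof=1) == 0.0:
        raise DegenerateInputError("zero-variance predictor")
    return backward_regression(pd.Series(y), pd.DataFrame({name: x}), removal_p=1.0)
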
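"""Variance partition of single-gene expression in an inbred panel.

Compares a fixed-effects-only linear model with a line-random-intercept
mixed model

    y = X beta + Z b + eps,   b ~ N(0, sigma2_line I),  eps ~ N(0, sigma2_resid I)

fitted to one gene's expression with season and sex as fixed effects
(treatment coding, reference levels female and winter, so the season
coefficient is positive when summer expression is higher).  The mixed
model is estimated by profiling the likelihood over the variance ratio
lambda = sigma2_line / sigma2_resid: for fixed lambda the GLS fixed
effects and the residual variance have closed forms, leaving a bounded
deterministic 1-D search on log(lambda).  Between-line variance is
truncated at the boundary sigma2_line = 0.

Reported statistics: multiple R2 (linear), marginal/conditional R2 and
ICC (mixed), Gaussian log-likelihoods, AIC (2k - 2 logL with k counting
the residual variance, plus the line variance for the mixed model), the
likelihood-ratio test for the random intercept on chi^2_1 (no boundary
mixture correction), and per-term Wald chi^2 tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_GENE = "bdnf"
DEFAULT_INTERACTION_ALPHA = 0.05

#: search bounds for log(lambda); lambda spans ~3e-7 .. 3e6
_LOG_RATIO_BOUNDS = (-15.0, 15.0)
_RATIO_XATOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit for the focal gene."""

    response: str = DEFAULT_GENE
    interaction: bool = False
    random_intercept: bool = True
    estimation: str = "REML"  # REML or ML; ignored for the linear model

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError(f"estimation must be REML or ML, got {self.estimation!r}")


@dataclass
class VarianceFit:
    """Fitted model state for either the linear or the mixed model."""

    kind: str  # "linear" | "mixed"
    method: str  # "ML" (linear is always ML) | "REML"
    beta: pd.Series
    bse: pd.Series
    sigma2_line: float
    sigma2_resid: float
    loglik: float
    k: int
    n: int
    r2_multiple: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    var_fixed: float = 0.0
    exog_names: list[str] = field(default_factory=list)
    boundary: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def icc(self) -> float:
        return icc(self)


def build_design(metadata: pd.DataFrame, interaction: bool = False) -> pd.DataFrame:
    """Treatment-coded design matrix with reference levels female/winter."""
    for col, levels in (("sex", {"F", "M"}), ("season", {"summer", "winter"})):
        observed = set(metadata[col].unique())
        if not observed <= levels:
            raise ValueError(f"unexpected {col} levels: {sorted(observed - levels)}")
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "season[summer]": (metadata["season"] == "summer").astype(float),
            "sex[M]": (metadata["sex"] == "M").astype(float),
        },
        index=metadata.index,
    )
    if interaction:
        X["season[summer]:sex[M]"] = X["season[summer]"] * X["sex[M]"]
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the first column whose removal restores full rank
        for j, name in enumerate(X.columns):
            reduced = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(arr):
                raise ValueError(f"design is rank deficient; offending column: {name!r}")
        raise ValueError("design is rank deficient")


def fit_linear(y: np.ndarray | pd.Series, X: pd.DataFrame) -> VarianceFit:
    """Ordinary least squares with the Gaussian ML log-likelihood."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    _check_full_rank(X)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    beta = pd.Series(res.params, index=list(X.columns))
    xb = X.to_numpy(dtype=float) @ beta.to_numpy()
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(res.ssr)
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    return VarianceFit(
        kind="linear",
        method="ML",
        beta=beta,
        bse=pd.Series(res.bse, index=list(X.columns)),
        sigma2_line=0.0,
        sigma2_resid=sse / n,  # ML variance, consistent with the loglik
        loglik=float(res.llf),
        k=p + 1,
        n=n,
        r2_multiple=r2,
        var_fixed=float(np.var(xb)),
        exog_names=list(X.columns),
    )


def _profile_pieces(
    lam: float,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    x_sums: np.ndarray,
    y_sums: np.ndarray,
    sizes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """GLS building blocks at variance ratio lambda.

    For block-diagonal Vtilde = I + lam * Z Z^T the inverse acts per group
    as I - (lam / (1 + lam * n_i)) J, so the weighted cross-products are
    the unweighted ones minus rank-one group-sum corrections.
    """
    c = lam / (1.0 + lam * sizes)
    A = XtX - (x_sums * c[:, None]).T @ x_sums
    b = Xty - x_sums.T @ (c * y_sums)
    q_y = yty - float(np.sum(c * y_sums**2))
    logdet = float(np.sum(np.log1p(lam * sizes)))
    return A, b, q_y, logdet


def _neg2_profile(
    lam: float, method: str, pieces_args: tuple, n: int, p: int
) -> float:
    A, b, q_y, logdet = _profile_pieces(lam, *pieces_args)
    beta = np.linalg.solve(A, b)
    q = q_y - float(b @ beta)
    q = max(q, 1e-300)
    if method == "ML":
        return n * np.log(2.0 * np.pi * q / n) + logdet + n
    df = n - p
    sign, logdet_A = np.linalg.slogdet(A)
    return df * np.log(2.0 * np.pi * q / df) + logdet + logdet_A + df


def fit_mixed(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    method: str = "REML",
) -> VarianceFit:
    """Single-random-intercept mixed model via profiled (RE)ML.

    The criterion is minimised over log(lambda) with a deterministic
    grid pre-search followed by bounded Brent refinement, then compared
    against the lambda = 0 boundary; sigma2_line is truncated at zero
    when the boundary wins.  Fixed effects are the GLS solution at the
    optimum; their covariance is sigma2_resid * (X' Vtilde^-1 X)^-1.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be REML or ML, got {method!r}")
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model needs >= 2 groups")
    _check_full_rank(X)

    Xa = X.to_numpy(dtype=float)
    labels, inverse = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    sizes = np.bincount(inverse).astype(float)
    x_sums = np.zeros((n_groups, p))
    for j in range(p):
        x_sums[:, j] = np.bincount(inverse, weights=Xa[:, j])
    y_sums = np.bincount(inverse, weights=y)
    pieces_args = (Xa.T @ Xa, Xa.T @ y, float(y @ y), x_sums, y_sums, sizes)

    def objective(t: float) -> float:
        return _neg2_profile(np.exp(t), method, pieces_args, n, p)

    lo, hi = _LOG_RATIO_BOUNDS
    grid = np.linspace(lo, hi, 61)
    values = [objective(t) for t in grid]
    t0 = grid[int(np.argmin(values))]
    res = optimize.minimize_scalar(
        objective,
        bounds=(max(lo, t0 - 1.0), min(hi, t0 + 1.0)),
        method="bounded",
        options={"xatol": _RATIO_XATOL, "maxiter": 500},
    )
    lam = float(np.exp(res.x))
    crit_interior = float(res.fun)
    crit_boundary = _neg2_profile(0.0, method, pieces_args, n, p)
    boundary = crit_boundary <= crit_interior
    if boundary:
        lam, crit = 0.0, crit_boundary
        logger.warning("between-line variance estimated at the zero boundary")
    else:
        crit = crit_interior

    A, b, q_y, _ = _profile_pieces(lam, *pieces_args)
    beta = np.linalg.solve(A, b)
    q = max(q_y - float(b @ beta), 0.0)
    df = n - p if method == "REML" else n
    sigma2_resid = q / df
    sigma2_line = lam * sigma2_resid
    cov_beta = sigma2_resid * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov_beta))

    xb = Xa @ beta
    var_f = float(np.var(xb))
    total = var_f + sigma2_line + sigma2_resid
    fit = VarianceFit(
        kind="mixed",
        method=method,
        beta=pd.Series(beta, index=list(X.columns)),
        bse=pd.Series(bse, index=list(X.columns)),
        sigma2_line=float(sigma2_line),
        sigma2_resid=float(sigma2_resid),
        loglik=-0.5 * crit,
        k=p + 2,
        n=n,
        r2_marginal=var_f / total,
        r2_conditional=(var_f + sigma2_line) / total,
        var_fixed=var_f,
        exog_names=list(X.columns),
        boundary=boundary,
    )
    return fit


def icc(fit: VarianceFit) -> float:
    """Intraclass correlation: sigma2_line / (sigma2_line + sigma2_resid)."""
    if fit.kind != "mixed":
        raise ValueError("ICC is defined only for the mixed model")
    return fit.sigma2_line / (fit.sigma2_line + fit.sigma2_resid)


def r2_conditional(fit: VarianceFit) -> tuple[float, float]:
    """(marginal, conditional) R2 of a mixed fit.

    var_f is the population variance of the fixed-effect predictor;
    marginal R2 = var_f / (var_f + sigma2_line + sigma2_resid) and the
    conditional R2 adds sigma2_line to the numerator.
    """
    if fit.kind != "mixed":
        raise ValueError("conditional R2 is defined only for the mixed model")
    total = fit.var_fixed + fit.sigma2_line + fit.sigma2_resid
    return fit.var_fixed / total, (fit.var_fixed + fit.sigma2_line) / total


def lrt_random_effect(
    fit_without: VarianceFit, fit_with: VarianceFit
) -> tuple[float, int, float]:
    """Likelihood-ratio test for the line random intercept, chi^2 on 1 df.

    Both fits must be ML on the same data with the same fixed part (the
    REML likelihoods of models differing in the random part are not
    comparable).  The statistic is floored at zero since the mixed fit
    can sit on the sigma2_line = 0 boundary.
    """
    if fit_without.kind != "linear" or fit_with.kind != "mixed":
        raise ValueError("expected (linear fit, mixed fit)")
    if fit_with.method != "ML":
        raise ValueError("LRT requires an ML mixed fit; refit with method='ML'")
    if fit_without.exog_names != fit_with.exog_names or fit_without.n != fit_with.n:
        raise ValueError("fits must share the same fixed part and data")
    stat = max(0.0, 2.0 * (fit_with.loglik - fit_without.loglik))
    p_value = float(stats.chi2.sf(stat, 1))
    return stat, 1, p_value


def term_chisq(fit: VarianceFit, terms: list[str] | None = None) -> pd.DataFrame:
    """Per-term Wald chi^2 tests, (beta/SE)^2 on 1 df.

    For 1-df terms that do not participate in an interaction this
    coincides with the Type-II test.  Aliased terms (zero SE) are
    rejected.
    """
    if terms is None:
        terms = [c for c in fit.exog_names if c != "Intercept"]
    rows = []
    for term in terms:
        if term not in fit.beta.index:
            raise ValueError(f"term {term!r} not in the fitted model")
        se = fit.bse[term]
        if not np.isfinite(se) or se == 0:
            raise ValueError(f"term {term!r} is aliased (zero standard error)")
        chi2 = float((fit.beta[term] / se) ** 2)
        rows.append({"term": term, "chisq": chi2, "df": 1, "p_value": float(stats.chi2.sf(chi2, 1))})
    return pd.DataFrame(rows)


def interaction_screen(
    y: np.ndarray | pd.Series,
    metadata: pd.DataFrame,
    alpha: float = DEFAULT_INTERACTION_ALPHA,
    estimation: str = "REML",
) -> tuple[ModelSpec, float]:
    """Decide whether the sex x season interaction stays in the model.

    Fits the mixed model with the interaction and drops it iff its Wald
    p-value exceeds alpha.  Returns the resulting ModelSpec and the
    interaction p-value.
    """
    cells = metadata.groupby(["sex", "season"]).size()
    if len(cells) < 4:
        raise ValueError("interaction screen needs the full 2x2 design")
    X = build_design(metadata, interaction=True)
    fit = fit_mixed(y, X, metadata["line_id"].to_numpy(), method=estimation)
    table = term_chisq(fit, terms=["season[summer]:sex[M]"])
    p_int = float(table["p_value"].iloc[0])
    keep = p_int <= alpha
    logger.info(
        "sex x season interaction p = %.4g -> %s", p_int, "kept" if keep else "dropped"
    )
    return ModelSpec(interaction=keep, estimation=estimation), p_int


def analyze_gene(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    gene: str = DEFAULT_GENE,
    interaction_alpha: float = DEFAULT_INTERACTION_ALPHA,
) -> dict:
    """Full single-gene model comparison.

    Screens the interaction, then fits the linear model and the mixed
    model.  Variance components, ICC and R2s are reported from the REML
    mixed fit; the AIC comparison and the LRT use ML fits of both
    models so they sit on a common likelihood.
    """
    if gene not in expression.index:
        raise ValueError(f"gene {gene!r} not in the expression table")
    y = expression.loc[gene, metadata["sample_id"]].to_numpy(dtype=float)
    groups = metadata["line_id"].to_numpy()

    spec, p_int = interaction_screen(y, metadata, alpha=interaction_alpha)
    X = build_design(metadata, interaction=spec.interaction)

    linear = fit_linear(y, X)
    mixed_reml = fit_mixed(y, X, groups, method="REML")
    mixed_ml = fit_mixed(y, X, groups, method="ML")
    lrt_stat, lrt_df, lrt_p = lrt_random_effect(linear, mixed_ml)
    terms = term_chisq(mixed_reml)
    r2m, r2c = r2_conditional(mixed_reml)

    return {
        "gene": gene,
        "interaction_p": p_int,
        "interaction_kept": spec.interaction,
        "linear": linear,
        "mixed_reml": mixed_reml,
        "mixed_ml": mixed_ml,
        "icc": icc(mixed_reml),
        "r2_multiple": linear.r2_multiple,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "aic_linear": linear.aic,
        "aic_mixed": mixed_ml.aic,
        "lrt": {"statistic": lrt_stat, "df": lrt_df, "p_value": lrt_p},
        "terms": terms,
    }
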
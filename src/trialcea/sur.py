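"""Seemingly unrelated regression for joint cost-effect contrasts.

Two linear equations — total follow-up costs and one health effect — are
estimated jointly by Zellner's two-step feasible GLS: equation-wise OLS,
a cross-equation residual covariance, then GLS on the stacked system.
With identical regressors in both equations FGLS collapses exactly to
OLS; with the different covariate sets used here the joint step borrows
strength from the cost-effect error correlation.

The binary reliable-improvement outcome enters as a linear probability
model so the system stays jointly linear and the arm coefficient is the
adjusted percentage-point difference (reported caveats apply: predicted
probabilities are not constrained to [0, 1]).

Adjusted group means come from g-computation — predict every participant
under each arm assignment and average — which for a linear model without
interactions makes the mean difference equal the arm coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFFECT_COLUMNS",
    "SURSpec",
    "SURFit",
    "AdjustedContrast",
    "UnadjustedComparison",
    "SURData",
    "EstimationError",
    "prepare_sur_data",
    "fit_sur_arrays",
    "fit_sur",
    "adjusted_contrast",
    "unadjusted_comparison",
]

#: analysis-table column backing each effect measure
EFFECT_COLUMNS = {
    "QALY_EQ5D": "qaly_eq5d",
    "QALY_VAS": "qaly_vas",
    "RELIABLE_IMPROVEMENT": "reliable_improvement",
}

_DEFAULT_COST_COVARIATES = (
    "arm_ig",
    "gi_trans_feminine",
    "gi_nonbinary",
    "age_years",
    "baseline_cost",
)
_DEFAULT_EFFECT_COVARIATES = (
    "arm_ig",
    "gi_trans_feminine",
    "gi_nonbinary",
    "age_years",
    "eq5d_index_t0",
    "gsi_t0",
)


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SURSpec:
    """Variable lists for the two-equation system.

    Covariate names refer to analysis-table columns; the arm indicator
    (``arm_ig``) must appear in both equations.  Gender identity enters
    as two indicators with trans-masculine as the reference level.
    """

    cost_outcome: str = "cost_t1"
    effect_name: str = "QALY_EQ5D"
    cost_covariates: tuple[str, ...] = _DEFAULT_COST_COVARIATES
    effect_covariates: tuple[str, ...] = _DEFAULT_EFFECT_COVARIATES
    arm_column: str = "arm_ig"
    add_intercept: bool = True

    def __post_init__(self) -> None:
        if self.effect_name not in EFFECT_COLUMNS:
            raise ValueError(f"effect_name must be one of {sorted(EFFECT_COLUMNS)}")
        if self.arm_column not in self.cost_covariates or self.arm_column not in self.effect_covariates:
            raise ValueError("the arm indicator must appear in both equations")

    @property
    def effect_outcome(self) -> str:
        return EFFECT_COLUMNS[self.effect_name]


@dataclass
class SURData:
    """Dense design matrices for fast (re)fitting on index subsets."""

    X_cost: np.ndarray
    X_effect: np.ndarray
    y_cost: np.ndarray
    y_effect: np.ndarray
    cost_names: list[str]
    effect_names: list[str]
    arm_idx_cost: int
    arm_idx_effect: int
    index: pd.Index

    @property
    def n(self) -> int:
        return self.y_cost.shape[0]


@dataclass
class SURFit:
    params_cost: pd.Series
    params_effect: pd.Series
    sigma: np.ndarray  # 2x2 cross-equation residual covariance
    cov_params: np.ndarray  # FGLS joint covariance (cost block first)
    cov_robust: np.ndarray  # HC0 sandwich covariance
    n_used: int
    spec: SURSpec
    condition_numbers: tuple[float, float]
    iterations: int = 1

    def se(self, equation: str, name: str, robust: bool = False) -> float:
        offset = 0 if equation == "cost" else len(self.params_cost)
        eq_names = self.params_cost.index if equation == "cost" else self.params_effect.index
        j = offset + list(eq_names).index(name)
        cov = self.cov_robust if robust else self.cov_params
        return float(np.sqrt(cov[j, j]))


@dataclass
class AdjustedContrast:
    """Adjusted arm means and IG-CG difference for one outcome."""

    outcome: str
    mean_ig: float
    mean_cg: float
    difference: float
    se: float
    p_value: float


@dataclass
class UnadjustedComparison:
    mean_ig: float
    mean_cg: float
    difference: float
    f_stat: float
    p_value: float
    df_num: int
    df_den: int


def prepare_sur_data(table: pd.DataFrame, spec: SURSpec) -> SURData:
    """Complete-case design matrices for the two equations.

    Rows missing any model variable (either equation) are dropped, so
    the two equations share one estimation sample.
    """
    cols = sorted(
        {spec.cost_outcome, spec.effect_outcome}
        | set(spec.cost_covariates)
        | set(spec.effect_covariates)
    )
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise EstimationError(f"analysis table is missing columns {missing_cols}")
    sub = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if sub.empty:
        raise EstimationError("no complete cases on the model variables")

    def design(covs: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
        names = (["const"] if spec.add_intercept else []) + list(covs)
        X = sub[list(covs)].to_numpy(float)
        if spec.add_intercept:
            X = np.column_stack([np.ones(len(sub)), X])
        return X, names

    X1, names1 = design(spec.cost_covariates)
    X2, names2 = design(spec.effect_covariates)
    return SURData(
        X_cost=X1,
        X_effect=X2,
        y_cost=sub[spec.cost_outcome].to_numpy(float),
        y_effect=sub[spec.effect_outcome].to_numpy(float),
        cost_names=names1,
        effect_names=names2,
        arm_idx_cost=names1.index(spec.arm_column),
        arm_idx_effect=names2.index(spec.arm_column),
        index=sub.index,
    )


def _check_rank(X: np.ndarray, names: list[str], label: str) -> float:
    n, k = X.shape
    if n <= k:
        raise EstimationError(f"{label} equation: n={n} <= {k} parameters")
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in range(k) if diag[j] <= tol]
    if bad:
        raise EstimationError(f"{label} equation design is rank deficient; collinear: {bad}")
    return float(np.linalg.cond(X))


def fit_sur_arrays(
    data: SURData,
    idx: np.ndarray | None = None,
    iterate: bool = False,
    tol: float = 1e-10,
    max_iter: int = 50,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Core FGLS on numpy arrays; ``idx`` selects a (re)sample of rows.

    Returns ``(beta_cost, beta_effect, sigma, cov_fgls, iterations)``.
    """
    if idx is None:
        X1, X2, y1, y2 = data.X_cost, data.X_effect, data.y_cost, data.y_effect
    else:
        X1, X2 = data.X_cost[idx], data.X_effect[idx]
        y1, y2 = data.y_cost[idx], data.y_effect[idx]
    n = y1.shape[0]
    k1, k2 = X1.shape[1], X2.shape[1]
    if check:
        _check_rank(X1, data.cost_names, "cost")
        _check_rank(X2, data.effect_names, "effect")

    # step 1: equation-wise OLS residuals
    b1, *_ = np.linalg.lstsq(X1, y1, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, y2, rcond=None)
    iterations = 0
    for _ in range(max_iter if iterate else 1):
        e1 = y1 - X1 @ b1
        e2 = y2 - X2 @ b2
        sigma = np.array(
            [[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]], dtype=float
        ) / n
        s = np.linalg.inv(sigma)
        # step 2: GLS normal equations on the stacked system
        A = np.empty((k1 + k2, k1 + k2))
        A[:k1, :k1] = s[0, 0] * (X1.T @ X1)
        A[:k1, k1:] = s[0, 1] * (X1.T @ X2)
        A[k1:, :k1] = s[1, 0] * (X2.T @ X1)
        A[k1:, k1:] = s[1, 1] * (X2.T @ X2)
        rhs = np.concatenate(
            [
                s[0, 0] * (X1.T @ y1) + s[0, 1] * (X1.T @ y2),
                s[1, 0] * (X2.T @ y1) + s[1, 1] * (X2.T @ y2),
            ]
        )
        beta = np.linalg.solve(A, rhs)
        new_b1, new_b2 = beta[:k1], beta[k1:]
        iterations += 1
        converged = (
            np.max(np.abs(new_b1 - b1)) < tol and np.max(np.abs(new_b2 - b2)) < tol
        )
        b1, b2 = new_b1, new_b2
        if not iterate or converged:
            break
    cov = np.linalg.inv(A)
    return b1, b2, sigma, cov, iterations


def _robust_cov(data: SURData, idx, b1, b2, sigma) -> np.ndarray:
    """Heteroskedasticity-consistent sandwich for the FGLS estimator."""
    if idx is None:
        X1, X2, y1, y2 = data.X_cost, data.X_effect, data.y_cost, data.y_effect
    else:
        X1, X2 = data.X_cost[idx], data.X_effect[idx]
        y1, y2 = data.y_cost[idx], data.y_effect[idx]
    k1, k2 = X1.shape[1], X2.shape[1]
    s = np.linalg.inv(sigma)
    A = np.empty((k1 + k2, k1 + k2))
    A[:k1, :k1] = s[0, 0] * (X1.T @ X1)
    A[:k1, k1:] = s[0, 1] * (X1.T @ X2)
    A[k1:, :k1] = s[1, 0] * (X2.T @ X1)
    A[k1:, k1:] = s[1, 1] * (X2.T @ X2)
    e1 = y1 - X1 @ b1
    e2 = y2 - X2 @ b2
    # per-observation score: g_i = [X1_i * (s00 e1 + s01 e2); X2_i * (s10 e1 + s11 e2)]
    w1 = s[0, 0] * e1 + s[0, 1] * e2
    w2 = s[1, 0] * e1 + s[1, 1] * e2
    G = np.column_stack([X1 * w1[:, None], X2 * w2[:, None]])
    B = G.T @ G
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def fit_sur(table: pd.DataFrame, spec: SURSpec, iterate: bool = False) -> SURFit:
    """Fit the two-equation system on the complete cases of a table."""
    data = prepare_sur_data(table, spec)
    b1, b2, sigma, cov, iters = fit_sur_arrays(data, iterate=iterate)
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise EstimationError("residual covariance is not positive semi-definite")
    cond = (float(np.linalg.cond(data.X_cost)), float(np.linalg.cond(data.X_effect)))
    return SURFit(
        params_cost=pd.Series(b1, index=data.cost_names),
        params_effect=pd.Series(b2, index=data.effect_names),
        sigma=sigma,
        cov_params=cov,
        cov_robust=_robust_cov(data, None, b1, b2, sigma),
        n_used=data.n,
        spec=spec,
        condition_numbers=cond,
        iterations=iters,
    )


def _gcomp(table: pd.DataFrame, fit: SURFit, equation: str) -> tuple[float, float]:
    spec = fit.spec
    params = fit.params_cost if equation == "cost" else fit.params_effect
    data = prepare_sur_data(table, spec)
    X = data.X_cost if equation == "cost" else data.X_effect
    names = data.cost_names if equation == "cost" else data.effect_names
    arm_j = names.index(spec.arm_column)
    means = []
    for arm_val in (1.0, 0.0):
        Xc = X.copy()
        Xc[:, arm_j] = arm_val
        means.append(float(np.mean(Xc @ params.to_numpy())))
    return means[0], means[1]


def adjusted_contrast(
    fit: SURFit, table: pd.DataFrame, robust: bool = True
) -> tuple[AdjustedContrast, AdjustedContrast]:
    """Adjusted (cost, effect) arm means and differences via g-computation.

    Without arm interactions the counterfactual mean difference equals
    the arm coefficient exactly; this identity is asserted.  The reported
    SE is the model-based (HC0-robust by default) SE of the arm
    coefficient with a two-sided normal p-value — bootstrap inference,
    when wanted, comes from the resampling module.
    """
    out = []
    for equation, outcome in (("cost", fit.spec.cost_outcome), ("effect", fit.spec.effect_outcome)):
        mean_ig, mean_cg = _gcomp(table, fit, equation)
        params = fit.params_cost if equation == "cost" else fit.params_effect
        coef = float(params[fit.spec.arm_column])
        if abs((mean_ig - mean_cg) - coef) > 1e-9 * max(1.0, abs(coef)):
            raise EstimationError(
                "g-computation difference does not equal the arm coefficient; "
                "does the model contain arm interactions?"
            )
        se = fit.se(equation, fit.spec.arm_column, robust=robust)
        p = 2.0 * stats.norm.sf(abs(coef) / se) if se > 0 else float(coef == 0.0)
        out.append(
            AdjustedContrast(
                outcome=outcome,
                mean_ig=mean_ig,
                mean_cg=mean_cg,
                difference=coef,
                se=se,
                p_value=p,
            )
        )
    return out[0], out[1]


def unadjusted_comparison(values_ig, values_cg) -> UnadjustedComparison:
    """One-way linear-model F test of the raw IG-CG mean difference.

    For two groups the F statistic equals the square of the
    equal-variance two-sample t statistic.
    """
    a = np.asarray(values_ig, dtype=float)
    b = np.asarray(values_cg, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise EstimationError("need at least 2 observations per arm")
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_num, df_den = 1, n - 2
    if ss_within <= 0:
        raise EstimationError("degenerate within-group variance")
    f = (ss_between / df_num) / (ss_within / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return UnadjustedComparison(
        mean_ig=float(a.mean()),
        mean_cg=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        f_stat=float(f),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
    )
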
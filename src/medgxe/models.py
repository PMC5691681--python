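"""Conditional and unconditional logistic regression with interaction tests.

For 1:1 matched pairs the conditional likelihood factorizes over pairs: with
d_i the case-minus-control covariate difference,

    L(beta) = prod_i exp(d_i' beta) / (1 + exp(d_i' beta)),

i.e. an intercept-free logistic likelihood on the differences with outcome
identically 1.  Concordant pairs (d_i = 0) carry no information about beta.
Both fitters use Newton-Raphson on the exact log-likelihood with standard
errors from the inverse observed information; interaction p-values come from
the likelihood-ratio test between nested fits, and trend tests are Wald
tests on a per-quartile-median continuous covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 50
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
#: |beta| cap while iterating, to keep diverging (separated) fits finite
BETA_CAP = 30.0


@dataclass
class FitResult:
    """A fitted logistic-family model: coefficients, covariance, likelihood."""

    beta: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_obs: int
    converged: bool
    model_label: str = ""
    diagnostics: list = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.beta.index)

    @property
    def n_params(self) -> int:
        return len(self.beta)


@dataclass(frozen=True)
class InteractionTest:
    """Likelihood-ratio test between nested fits."""

    lr_chi2: float
    df: int
    p_value: float


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(eta: np.ndarray) -> np.ndarray:
    # log sigma(eta), numerically stable on both tails
    return -np.logaddexp(0.0, -eta)


def _newton_logistic(X: np.ndarray, y: np.ndarray, diagnostics: list) -> tuple:
    """Newton-Raphson MLE for a Bernoulli-logit likelihood; returns
    (beta, cov, loglik, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        p = _sigmoid(eta)
        score = X.T @ (y - p)
        w = p * (1 - p)
        info = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular observed information matrix: {err}"
            ) from err
        beta = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        if np.max(np.abs(step)) < STEP_TOL:
            converged = True
            break
    if not converged:
        diagnostics.append("maximum Newton iterations reached without convergence")
    if np.any(np.abs(beta) >= BETA_CAP):
        converged = False
        diagnostics.append("coefficient hit magnitude cap (possible separation)")
    eta = X @ beta
    p = _sigmoid(eta)
    w = p * (1 - p)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular observed information matrix: {err}"
        ) from err
    loglik = float(np.sum(y * _log_sigmoid(eta) + (1 - y) * _log_sigmoid(-eta)))
    return beta, cov, loglik, converged


def clogit_fit(pair_diffs: pd.DataFrame, model_label: str = "clogit") -> FitResult:
    """Conditional logistic regression for 1:1 matched pairs.

    ``pair_diffs`` holds one row per pair: case-minus-control differences of
    the model covariates (named columns).  Maximizes the pair-conditional
    likelihood by Newton-Raphson; standard errors come from the inverse
    observed information.  A covariate whose nonzero differences all share
    one sign separates the likelihood: the fit is returned flagged
    non-converged with a diagnostic rather than raising.
    """
    X = pair_diffs.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("pair differences contain missing values")
    diagnostics: list = []
    for j, name in enumerate(pair_diffs.columns):
        col = X[:, j]
        nz = col[col != 0]
        if nz.size == 0:
            raise ValueError(f"column {name!r} has no discordant pairs")
        if np.all(nz > 0) or np.all(nz < 0):
            diagnostics.append(
                f"column {name!r}: all discordant differences share one sign "
                "(separation likely)"
            )
    y = np.ones(len(X))
    beta, cov, loglik, converged = _newton_logistic(X, y, diagnostics)
    if diagnostics and any("separation" in d for d in diagnostics):
        converged = False
    return FitResult(
        beta=pd.Series(beta, index=pair_diffs.columns),
        cov=pd.DataFrame(cov, index=pair_diffs.columns, columns=pair_diffs.columns),
        loglik=loglik,
        n_obs=len(X),
        converged=converged,
        model_label=model_label,
        diagnostics=diagnostics,
    )


def logit_fit(
    design: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    add_intercept: bool = True,
    model_label: str = "logit",
) -> FitResult:
    """Unconditional maximum-likelihood logistic regression.

    Fits by the same Newton-Raphson core as the conditional model.  The
    design must be full rank; separation is flagged, not silently absorbed.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = design.copy()
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    mat = X.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("design matrix contains missing values")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    diagnostics: list = []
    beta, cov, loglik, converged = _newton_logistic(mat, y, diagnostics)
    return FitResult(
        beta=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        loglik=loglik,
        n_obs=len(y),
        converged=converged,
        model_label=model_label,
        diagnostics=diagnostics,
    )


def lrt_interaction(
    full: FitResult, reduced: FitResult, df: int | None = None
) -> InteractionTest:
    """Likelihood-ratio test of the full against the nested reduced model."""
    if df is None:
        df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced models fit different observations")
    delta = full.loglik - reduced.loglik
    if delta < -1e-6:
        raise ValueError(
            f"full-model log-likelihood ({full.loglik:.6f}) below reduced "
            f"({reduced.loglik:.6f}); a fit failed to converge"
        )
    lr_chi2 = max(2.0 * delta, 0.0)
    return InteractionTest(lr_chi2, df, float(stats.chi2.sf(lr_chi2, df)))


def wald_p(fit: FitResult, term: str) -> float:
    """Two-sided Wald p-value for a single coefficient."""
    z = fit.beta[term] / fit.se[term]
    return float(2 * stats.norm.sf(abs(z)))


def quartile_median_covariate(quartile: pd.Series, score: pd.Series) -> pd.Series:
    """Replace a quartile factor by the median score within each quartile.

    This is the continuous covariate of the trend test.
    """
    quartile = pd.Series(quartile)
    score = pd.Series(np.asarray(score, dtype=float), index=quartile.index)
    med = score.groupby(quartile).median()
    return quartile.map(med).astype(float).rename("trend")


def trend_test(fit: FitResult, term: str = "trend") -> float:
    """Wald p-value for the trend slope (quartile medians as continuous)."""
    return wald_p(fit, term)


def or_report(fit: FitResult, terms: list[str] | None = None, z: float = 1.959963984540054) -> pd.DataFrame:
    """Odds ratios with 95% Wald confidence intervals per term.

    OR = exp(beta), CI = exp(beta -/+ z*se).  Reference levels are not in
    the fit; callers prepend an OR=1 reference row where a table needs one.
    """
    terms = list(fit.beta.index) if terms is None else terms
    beta = fit.beta[terms]
    se = fit.se[terms]
    return pd.DataFrame(
        {
            "term": terms,
            "beta": beta.to_numpy(),
            "se": se.to_numpy(),
            "or": np.exp(beta.to_numpy()),
            "ci_low": np.exp(beta.to_numpy() - z * se.to_numpy()),
            "ci_high": np.exp(beta.to_numpy() + z * se.to_numpy()),
            "p": [wald_p(fit, t) for t in terms],
        }
    )


def pair_difference_design(
    pairs: pd.DataFrame, covariates: pd.DataFrame, terms: list[str]
) -> pd.DataFrame:
    """Case-minus-control covariate differences for a matched-pair design.

    ``covariates`` is indexed by subject id; ``pairs`` has case_id and
    control_id columns.  Returns one row per pair, columns ``terms``.
    """
    case = covariates.loc[pairs["case_id"], terms].to_numpy(dtype=float)
    ctrl = covariates.loc[pairs["control_id"], terms].to_numpy(dtype=float)
    return pd.DataFrame(case - ctrl, columns=terms)


def interaction_design(
    data: pd.DataFrame,
    genotype_col: str,
    quartile_col: str,
    adjust: list[str] | None = None,
    ordinal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full and reduced covariate sets for the gene-diet interaction test.

    The headline parameterization treats the MDS quartile as ordinal (1-4)
    and forms a single genotype x quartile product term (1-df LRT); with
    ``ordinal=False`` the quartile enters as dummies and the interaction is
    the 3-df set of products.  Returns (full, reduced) covariate frames
    indexed like ``data``.
    """
    adjust = adjust or []
    g = data[genotype_col].astype(float)
    if ordinal:
        e = data[quartile_col].astype(float)
        reduced = pd.DataFrame({genotype_col: g, "mds_q": e})
        full = reduced.copy()
        full["gxe"] = g * e
    else:
        dummies = pd.get_dummies(
            data[quartile_col].astype(int), prefix="mds_q", drop_first=True
        ).astype(float)
        reduced = pd.concat([g.rename(genotype_col), dummies], axis=1)
        full = reduced.copy()
        for c in dummies.columns:
            full[f"gx{c}"] = g * dummies[c]
    for c in adjust:
        full[c] = data[c].astype(float)
        reduced[c] = data[c].astype(float)
    return full, reduced


def cohort_descriptives(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Table-1-style case/control comparison.

    Continuous variables: mean (SD) per group and a two-sample Student's t
    test.  Categorical variables: percentage per level and a chi-square test
    on the level x group contingency table.
    """
    rows = []
    for var in continuous or []:
        a = cases[var].dropna().to_numpy(dtype=float)
        b = controls[var].dropna().to_numpy(dtype=float)
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "variable": var,
                "level": "",
                "case_mean_or_pct": a.mean(),
                "case_sd": a.std(ddof=1),
                "control_mean_or_pct": b.mean(),
                "control_sd": b.std(ddof=1),
                "test": "t",
                "p": p,
            }
        )
    for var in categorical or []:
        table = pd.crosstab(
            pd.concat([cases[var], controls[var]]),
            np.r_[np.ones(len(cases)), np.zeros(len(controls))],
        )
        if table.shape[0] < 2:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        for level in table.index:
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "case_mean_or_pct": (cases[var] == level).mean() * 100,
                    "case_sd": np.nan,
                    "control_mean_or_pct": (controls[var] == level).mean() * 100,
                    "control_sd": np.nan,
                    "test": "chi2",
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
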
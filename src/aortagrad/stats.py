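"""Cohort statistics around Firth's penalized logistic regression.

With only a handful of events per outcome, the unpenalized logistic MLE is
biased and can diverge under separation.  Firth's correction maximises the
Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where I is the Fisher information; estimates stay finite even under
complete separation.  Model building mirrors the small-cohort procedure:
simple linear regressions flag anatomical/acquisition confounders,
forward selection by penalized likelihood ratio (PLR) adds predictors while
the entry p-value stays below ``alpha_entry``, and Benjamini-Hochberg FDR
adjusts the selected predictors' p-values across the family of outcome
models.  Diagnostic cross-tabulation metrics and ROC points support the
comparison against binary clinical markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "FirthFit",
    "SelectionResult",
    "DiagnosticMetrics",
    "firth_fit",
    "firth_fit_frame",
    "penalized_loglik",
    "or_from_beta",
    "plr_test",
    "forward_select",
    "bh_fdr",
    "confounder_scan",
    "flagged_confounders",
    "crosstab_metrics",
    "model_metrics_at_cutoff",
    "roc_points",
    "roc_auc",
]

_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Firth penalized logistic regression
# ---------------------------------------------------------------------------


@dataclass
class FirthFit:
    """Result of a (possibly constrained) Firth penalized logistic regression.

    ``fixed_zero`` lists terms that were held at coefficient 0 while the
    Jeffreys penalty was still computed from the full design; such
    constrained fits are the reduced models of penalized likelihood-ratio
    tests (comparing penalized likelihoods across designs of different
    dimension is not calibrated, because the 0.5 log det I term itself
    grows with the dimension).
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float  # penalized log-likelihood at the optimum
    p_wald: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    fixed_zero: tuple[str, ...] = ()

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci_beta(self, level: float = 0.95) -> np.ndarray:
        z = sps.norm.ppf(0.5 + level / 2)
        return np.stack([self.beta - z * self.se, self.beta + z * self.se], axis=1)

    def predict_proba(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.X if X is None else np.asarray(X, float)
        return expit(X @ self.beta)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci_beta()
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "or_ci_low": np.exp(ci[:, 0]),
                "or_ci_high": np.exp(ci[:, 1]),
                "p_wald": self.p_wald,
            }
        )


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Jeffreys-penalized binomial log-likelihood l(beta) + 0.5 log det I."""
    eta = X @ beta
    pi = expit(eta)
    eps = 1e-12
    ll = float(np.sum(y * np.log(pi + eps) + (1 - y) * np.log(1 - pi + eps)))
    w = pi * (1 - pi)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _modified_score(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Firth-modified score, Fisher information and its inverse."""
    pi = expit(X @ beta)
    w = pi * (1 - pi)
    info = X.T @ (X * w[:, None])
    info_inv = np.linalg.inv(info)
    # hat diagonal h_i = w_i * x_i' I^{-1} x_i
    h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
    score = X.T @ (y - pi + h * (0.5 - pi))
    return score, info, info_inv


def firth_fit(
    design: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
    fixed_zero: tuple[str, ...] = (),
) -> FirthFit:
    """Newton iteration on the Firth-modified score with step-halving.

    The modified score replaces the residual y - pi by
    y - pi + h * (0.5 - pi), with h the hat-matrix diagonal; standard
    errors come from the inverse Fisher information at the optimum.
    Terms named in ``fixed_zero`` are constrained to coefficient 0 but kept
    in the design (and hence in the Jeffreys penalty), which is the correct
    reduced model for a penalized likelihood-ratio test.
    """
    X = np.atleast_2d(np.asarray(design, float))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("design and response lengths differ")
    intercept_only = X.shape[1] == 0 or (not add_intercept and X.shape[1] == 1)
    if np.ptp(y) == 0 and not intercept_only:
        # an intercept-only Firth fit of an all-0/all-1 response is well
        # defined ((k + 1/2) / (n + 1)); with predictors it is degenerate
        raise ValueError("response is constant; no model can be fitted")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["constant"] + (names or [f"x{i}" for i in range(X.shape[1] - 1)])
    else:
        names = names or [f"x{i}" for i in range(X.shape[1])]
    # at most one constant column (the intercept) may be present
    if int(np.sum(X.std(axis=0) == 0)) > 1:
        raise ValueError("design contains a constant column besides the intercept")
    unknown = set(fixed_zero) - set(names)
    if unknown:
        raise ValueError(f"fixed_zero names not in the design: {sorted(unknown)}")
    free = np.array([nm not in fixed_zero for nm in names])
    if not free.any():
        raise ValueError("all coefficients are constrained")

    n, p = X.shape
    beta = np.zeros(p)
    pll = penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info, _ = _modified_score(X, y, beta)
        if np.max(np.abs(score[free])) < tol:
            converged = True
            break
        delta = np.zeros(p)
        delta[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
        # safeguarded step: halve until the penalized likelihood improves
        new_pll = penalized_loglik(X, y, beta + delta)
        halvings = 0
        while new_pll < pll - 1e-12 and halvings < 30:
            delta *= 0.5
            new_pll = penalized_loglik(X, y, beta + delta)
            halvings += 1
        if np.max(np.abs(delta)) < 1e-14:
            converged = np.max(np.abs(score[free])) < 1e-4
            break
        beta = beta + delta
        pll = new_pll
    else:
        score, _, _ = _modified_score(X, y, beta)
        if np.max(np.abs(score[free])) >= 1e-4:
            raise RuntimeError(
                f"Firth fit did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(score[free])):.2e})"
            )
        converged = True

    _, info, info_inv = _modified_score(X, y, beta)
    se = np.sqrt(np.diag(info_inv))
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p_wald = np.where(free, 2 * sps.norm.sf(np.abs(zval)), np.nan)
    return FirthFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=penalized_loglik(X, y, beta),
        p_wald=p_wald,
        converged=converged,
        n_iter=it,
        n_obs=n,
        X=X,
        y=y,
        fixed_zero=tuple(fixed_zero),
    )


def firth_fit_frame(
    df: pd.DataFrame, outcome: str, predictors: list[str], **kwargs
) -> FirthFit:
    """Firth fit on DataFrame columns after list-wise exclusion."""
    sub = df[[outcome] + list(predictors)].dropna()
    y = sub[outcome].to_numpy(float)
    if predictors:
        X = sub[list(predictors)].to_numpy(float)
    else:
        X = np.empty((len(sub), 0))
    return firth_fit(X, y, names=list(predictors), **kwargs)


def or_from_beta(fit: FirthFit, rescale_units: float = 1.0) -> pd.DataFrame:
    """Odds ratios per ``rescale_units`` change of each predictor.

    Rescaling a predictor by a factor c multiplies its coefficient by c,
    so OR = exp(beta * rescale_units) with the CI transformed identically.
    ``pct_change_odds`` is (1 - OR) x 100, the percent reduction in odds
    when OR < 1 (negative values denote an increase).
    """
    ci = fit.ci_beta()
    b = fit.beta * rescale_units
    lo, hi = ci[:, 0] * rescale_units, ci[:, 1] * rescale_units
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    or_ = np.exp(b)
    return pd.DataFrame(
        {
            "term": fit.names,
            "beta_rescaled": b,
            "or": or_,
            "or_ci_low": np.exp(lo),
            "or_ci_high": np.exp(hi),
            "pct_change_odds": (1.0 - or_) * 100.0,
            "p_wald": fit.p_wald,
        }
    )


def constrained_fit(full: FirthFit, keep_terms) -> FirthFit:
    """Refit ``full`` with every term not in ``keep_terms`` fixed at 0."""
    keep = set(keep_terms) | {"constant"}
    fixed = tuple(nm for nm in full.names if nm not in keep)
    return firth_fit(full.X, full.y, names=full.names, add_intercept=False, fixed_zero=fixed)


def _free_terms(fit: FirthFit) -> set[str]:
    return {nm for nm in fit.names if nm not in fit.fixed_zero and nm != "constant"}


def plr_test(full: FirthFit, reduced: FirthFit, df: int | None = None) -> tuple[float, float]:
    """Penalized likelihood-ratio test of nested Firth models.

    The penalized likelihoods of both models must share the same Jeffreys
    penalty, so the reduced model is evaluated as a constrained fit on the
    full design (coefficients of the dropped terms fixed at 0).  A
    ``reduced`` fitted on a smaller design is transparently refitted that
    way; a ``reduced`` built with :func:`constrained_fit` is used as is.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced models use different rows")
    full_terms, red_terms = _free_terms(full), _free_terms(reduced)
    if not red_terms <= full_terms:
        raise ValueError("models are not nested")
    if reduced.X.shape[1] == full.X.shape[1] and reduced.names == full.names:
        constrained = reduced
    else:
        constrained = constrained_fit(full, red_terms)
    stat = 2.0 * (full.loglik - constrained.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"negative PLR statistic ({stat:.3g}): models are not nested or not converged"
        )
    stat = max(stat, 0.0)
    if df is None:
        df = len(full_terms) - len(red_terms)
    if df <= 0:
        return stat, 1.0
    return stat, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    outcome: str
    n_used: int
    selected: list[str]
    entry_trace: list[dict]  # per evaluation: step, candidate, plr_stat, entry_p, entered
    excluded_entry_p: dict  # candidate -> entry p at the last evaluated step
    final_fit: FirthFit
    constant_fit: FirthFit
    model_chi2: float
    model_df: int
    model_p: float
    fdr_adjusted_p: dict = field(default_factory=dict)

    def selected_wald_p(self) -> dict:
        return {
            name: float(p)
            for name, p in zip(self.final_fit.names, self.final_fit.p_wald)
            if name in self.selected
        }


def forward_select(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    alpha_entry: float = 0.05,
) -> SelectionResult:
    """Forward selection by penalized likelihood ratio.

    At every step the remaining candidate with the smallest PLR entry
    p-value joins the model if that p-value is below ``alpha_entry``
    (ties broken by candidate order).  Entry p-values of candidates that
    never entered are reported from the terminating step.
    """
    cols = [outcome] + list(candidates)
    sub = cohort[cols].dropna()
    if len(sub) == 0:
        raise ValueError(f"no complete rows for outcome {outcome!r}")
    y = sub[outcome].to_numpy(float)

    def _fit(predictors: list[str]) -> FirthFit:
        X = sub[predictors].to_numpy(float) if predictors else np.empty((len(sub), 0))
        return firth_fit(X, y, names=predictors)

    constant_fit = _fit([])
    current = constant_fit
    selected: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []
    excluded: dict[str, float] = {}
    step = 0
    while remaining:
        step += 1
        evals = []
        for cand in remaining:
            cand_fit = _fit(selected + [cand])
            stat, p = plr_test(cand_fit, current, df=1)
            evals.append((cand, stat, p, cand_fit))
        best = min(evals, key=lambda e: e[2])  # first-in-order wins ties (stable min)
        entered = best[2] < alpha_entry
        for cand, stat, p, _ in evals:
            trace.append(
                {
                    "step": step,
                    "candidate": cand,
                    "plr_stat": stat,
                    "entry_p": p,
                    "entered": entered and cand == best[0],
                }
            )
        if not entered:
            excluded = {cand: p for cand, _, p, _ in evals}
            break
        selected.append(best[0])
        remaining.remove(best[0])
        current = best[3]
    else:
        excluded = {}

    chi2, model_p = plr_test(current, constant_fit)
    df_m = len(selected)
    return SelectionResult(
        outcome=outcome,
        n_used=len(sub),
        selected=selected,
        entry_trace=trace,
        excluded_entry_p=excluded,
        final_fit=current,
        constant_fit=constant_fit,
        model_chi2=chi2,
        model_df=df_m,
        model_p=model_p,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over all j with p_j >= p_i of min(1, p_j * m / rank_j);
    order-preserving and bounded by 1.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Confounder scan
# ---------------------------------------------------------------------------


def confounder_scan(
    cohort: pd.DataFrame,
    parameters: list[str],
    confounders: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simple linear regression of every parameter on every confounder.

    Returns one row per (confounder, parameter) pair with R-squared, the
    F-test p-value, the slope and its 95 % CI, and a significance flag.
    List-wise exclusion is applied per pair.
    """
    rows = []
    for conf in confounders:
        for param in parameters:
            sub = cohort[[conf, param]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete rows for {conf} vs {param}")
            x = sub[conf].to_numpy(float)
            if np.ptp(x) == 0:
                raise ValueError(f"zero-variance regressor {conf!r}")
            model = sm.OLS(sub[param].to_numpy(float), sm.add_constant(x)).fit()
            ci = model.conf_int()[1]
            rows.append(
                {
                    "confounder": conf,
                    "parameter": param,
                    "r_squared": float(model.rsquared),
                    "p_value": float(model.f_pvalue),
                    "beta": float(model.params[1]),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "significant": bool(model.f_pvalue < alpha),
                }
            )
    return pd.DataFrame(rows)


def flagged_confounders(scan: pd.DataFrame) -> list[str]:
    """Confounders significantly associated with at least one parameter."""
    flagged = scan.loc[scan["significant"], "confounder"].unique().tolist()
    return [c for c in scan["confounder"].unique() if c in flagged]


# ---------------------------------------------------------------------------
# Diagnostic metrics and ROC
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float  # all four in percent
    specificity: float
    ppv: float
    accuracy: float
    p_association: float

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int, p: float = np.nan):
        n = tp + fn + fp + tn
        sen = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spc = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        ppv = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        acc = 100.0 * (tp + tn) / n if n else np.nan
        return cls(tp, fn, fp, tn, sen, spc, ppv, acc, p)


def crosstab_metrics(predictor, outcome) -> DiagnosticMetrics:
    """2x2 diagnostic metrics of a binary predictor against a binary outcome.

    The association p-value is a Pearson chi-square without continuity
    correction, replaced by Fisher's exact test when any expected count is
    below 5; it is NaN when either vector is constant.
    """
    pred = np.asarray(predictor, float).ravel()
    out = np.asarray(outcome, float).ravel()
    if pred.size == 0 or out.size == 0:
        raise ValueError("empty vectors")
    if pred.size != out.size:
        raise ValueError("predictor and outcome lengths differ")
    keep = np.isfinite(pred) & np.isfinite(out)
    pred, out = pred[keep] > 0.5, out[keep] > 0.5
    tp = int(np.sum(pred & out))
    fp = int(np.sum(pred & ~out))
    fn = int(np.sum(~pred & out))
    tn = int(np.sum(~pred & ~out))
    p = np.nan
    if 0 < tp + fp < pred.size and 0 < tp + fn < pred.size:
        table = np.array([[tp, fn], [fp, tn]])
        expected = sps.contingency.expected_freq(table)
        if expected.min() < 5:
            p = float(sps.fisher_exact(table)[1])
        else:
            p = float(sps.chi2_contingency(table, correction=False)[1])
    return DiagnosticMetrics.from_counts(tp, fn, fp, tn, p)


def model_metrics_at_cutoff(
    fit: FirthFit,
    design: np.ndarray | None = None,
    y: np.ndarray | None = None,
    cutoff: float = 0.5,
) -> DiagnosticMetrics:
    """Binarise fitted probabilities at ``cutoff`` and cross-tabulate."""
    proba = fit.predict_proba(design)
    yy = fit.y if y is None else np.asarray(y, float)
    return crosstab_metrics(proba >= cutoff, yy)


def roc_points(
    fit: FirthFit,
    design: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Ordered (1 - specificity, sensitivity) pairs at every threshold."""
    proba = fit.predict_proba(design)
    yy = (fit.y if y is None else np.asarray(y, float)).ravel()
    if np.ptp(yy) == 0:
        raise ValueError("outcome is constant; ROC undefined")
    fpr, tpr, _ = _sk_roc_curve(yy, proba, drop_intermediate=False)
    return np.stack([fpr, tpr], axis=1)


def roc_auc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))
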
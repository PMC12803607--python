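"""Cox proportional-hazards fitting and the model ladder.

The partial likelihood is maximised by damped Newton iterations on the
analytic gradient and Hessian, with Efron's correction for tied event
times by default (Breslow available).  On top of the fitter sit the
model-comparison operations used for prognostic-factor evaluation:

* single-predictor vs CVF-adjusted two-predictor model ladder with AIC,
* backward elimination (enter at 10%, stay at 5%, Wald tests),
* restricted-cubic-spline nonlinearity likelihood-ratio test.

All model-ladder operations accept a list of multiply-imputed datasets and
pool coefficients by Rubin's rules; AIC is computed per imputation and
averaged (a reporting convention — AIC is not defined for pooled fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import pool_rubin
from .survstats import rcs_basis

__all__ = [
    "CoxModel",
    "TermEstimate",
    "fit_cox",
    "two_predictor_ladder",
    "backward_eliminate",
    "BackwardEliminationResult",
    "nonlinearity_test",
]

_Z95 = 1.959963984540054


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TermEstimate:
    coef: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float


@dataclass
class CoxModel:
    """Fitted proportional-hazards model.

    ``terms`` maps covariate name to its estimate; ``aic`` satisfies
    -2 * logPL + 2 * k with k the number of coefficients.
    """

    covariates: list[str]
    coef: np.ndarray
    cov: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    ties: str
    converged: bool
    flagged: str | None = None  # e.g. monotone likelihood
    terms: dict[str, TermEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            se = np.sqrt(np.diag(self.cov)) if self.cov.size else np.array([])
            for i, name in enumerate(self.covariates):
                b, s = float(self.coef[i]), float(se[i])
                z = b / s if s > 0 else np.inf
                self.terms[name] = TermEstimate(
                    coef=b,
                    se=s,
                    hr=float(np.exp(b)),
                    ci95=(float(np.exp(b - _Z95 * s)), float(np.exp(b + _Z95 * s))),
                    p_value=float(stats.chi2.sf(z * z, df=1)),
                )

    @property
    def aic(self) -> float:
        return -2.0 * self.log_partial_likelihood + 2.0 * len(self.covariates)

    def wald_test(self, names: list[str]) -> tuple[float, int, float]:
        """Multi-df Wald test that the named coefficients are jointly zero."""
        idx = [self.covariates.index(n) for n in names]
        b = self.coef[idx]
        v = self.cov[np.ix_(idx, idx)]
        w = float(b @ np.linalg.solve(v, b))
        return w, len(idx), float(stats.chi2.sf(w, df=len(idx)))


def _partial_lik_derivs(
    beta: np.ndarray,
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian (Efron or Breslow ties)."""
    n, p = x.shape
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    xs = x[order]
    eta = xs @ beta
    eta = eta - eta.max()  # guard against overflow; cancels in the ratios
    w = np.exp(eta)

    # suffix (risk-set) sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((xs * w[:, None])[::-1], axis=0)[::-1]
    outer = xs[:, :, None] * xs[:, None, :] * w[:, None, None]
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]

    uniq, first = np.unique(t, return_index=True)
    logl = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    if len(uniq) == n:
        # no tied times: fully vectorised (Efron and Breslow coincide)
        ev = np.flatnonzero(e)
        s0e = s0[ev]
        r1 = s1[ev] / s0e[:, None]
        logl = float(eta[ev].sum() - np.log(s0e).sum())
        grad = (xs[ev] - r1).sum(0)
        hess = -(
            np.einsum("ijk,i->jk", s2[ev], 1.0 / s0e) - np.einsum("ij,ik->jk", r1, r1)
        )
        return logl, grad, hess
    for m, start in enumerate(first):
        stop = first[m + 1] if m + 1 < len(first) else n
        ev = np.flatnonzero(e[start:stop]) + start
        d = len(ev)
        if d == 0:
            continue
        xd = xs[ev]
        wd = w[ev]
        s0d, s1d, s2d = wd.sum(), (xd * wd[:, None]).sum(0), (
            xd[:, :, None] * xd[:, None, :] * wd[:, None, None]
        ).sum(0)
        logl += float(eta[ev].sum())
        grad += xd.sum(0)
        fracs = np.arange(d) / d if ties == "efron" else np.zeros(d)
        for frac in fracs:
            den = s0[start] - frac * s0d
            num1 = s1[start] - frac * s1d
            num2 = s2[start] - frac * s2d
            logl -= np.log(den)
            grad -= num1 / den
            hess -= num2 / den - np.outer(num1, num1) / den**2
    return logl, grad, hess


def fit_cox(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 60,
) -> CoxModel:
    """Maximise the Cox partial likelihood by Newton's method.

    Raises :class:`ConvergenceError` on non-convergence; a monotone
    likelihood (perfect separation of event order, coefficients drifting
    without bound) is reported via ``flagged``.
    """
    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    if not covariates:
        raise ValueError("need at least one covariate")
    sub = records[[duration_col, event_col, *covariates]].dropna()
    times = sub[duration_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=int)
    x = sub[covariates].to_numpy(dtype=float)
    if events.sum() < 1:
        raise ValueError("no events in the data")
    if np.any(np.ptp(x, axis=0) == 0):
        bad = covariates[int(np.argmin(np.ptp(x, axis=0)))]
        raise ValueError(f"covariate {bad!r} is constant")
    # standardise internally for numerical stability; back-transform at the end
    scale = x.std(axis=0, ddof=0)
    xc = (x - x.mean(axis=0)) / scale

    beta = np.zeros(x.shape[1])
    logl, grad, hess = _partial_lik_derivs(beta, xc, times, events, ties)
    flagged = None
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # damped update
        alpha = 1.0
        for _ in range(30):
            new_beta = beta + alpha * step
            new = _partial_lik_derivs(new_beta, xc, times, events, ties)
            if new[0] >= logl - 1e-12:
                break
            alpha /= 2.0
        beta = new_beta
        logl, grad, hess = new
        if np.abs(beta).max() > 30:
            # a hazard ratio beyond e+-30 per SD only arises when the partial
            # likelihood is monotone (perfect ordering / separation)
            flagged = "monotone_likelihood"
            break
    else:
        if np.linalg.norm(grad) < tol:
            converged = True
    if converged and np.abs(beta).max() > 15:
        flagged = "monotone_likelihood"
    if not converged and flagged is None:
        if np.linalg.norm(grad) < 1e-4:
            converged = True  # flat but acceptable optimum
        else:
            raise ConvergenceError(
                f"Newton iterations did not converge (|grad| = {np.linalg.norm(grad):.2e})"
            )
    cov_std = np.linalg.inv(-hess)
    # undo standardisation
    coef = beta / scale
    cov = cov_std / np.outer(scale, scale)
    return CoxModel(
        covariates=list(covariates),
        coef=coef,
        cov=cov,
        log_partial_likelihood=float(logl),
        n=len(times),
        n_events=int(events.sum()),
        ties=ties,
        converged=converged,
        flagged=flagged,
    )


def _as_datasets(records) -> list[pd.DataFrame]:
    if isinstance(records, pd.DataFrame):
        return [records]
    return list(records)


def _fit_stack(
    datasets: list[pd.DataFrame],
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> tuple[dict[str, dict], float]:
    """Fit on every imputed dataset; Rubin-pool if m > 1, else pass through."""
    fits = [fit_cox(df, duration_col, event_col, covariates) for df in datasets]
    mean_aic = float(np.mean([f.aic for f in fits]))
    if len(fits) == 1:
        terms = {
            name: {"coef": est.coef, "se": est.se, "p_value": est.p_value}
            for name, est in fits[0].terms.items()
        }
    else:
        terms = pool_rubin(fits).terms
    return terms, mean_aic


def two_predictor_ladder(
    records,
    duration_col: str,
    event_col: str,
    predictors: dict[str, list[str]],
    adjust_name: str = "cvf_percent",
    adjust_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Single-predictor models and models additionally adjusted for CVF.

    ``records`` is a DataFrame or a list of multiply-imputed DataFrames;
    coefficients are pooled by Rubin's rules and AIC is the mean across
    imputations.  Each row reports the predictor's pooled HR (first column
    of a multi-column term), 95% CI, p and the two AICs.  Predictors
    collinear with the adjuster are flagged rather than silently dropped;
    per-row fit failures are recorded in ``status``.
    """
    datasets = _as_datasets(records)
    if adjust_cols is None:
        adjust_cols = [adjust_name]
    rows = []
    for name, cols in predictors.items():
        row: dict = {"predictor": name, "status": "ok"}
        try:
            first = datasets[0]
            collinear = False
            for c in cols:
                for ac in adjust_cols:
                    if c == ac:
                        collinear = True
                        continue
                    pair = first[[c, ac]].dropna()
                    if len(pair) > 2 and np.ptp(pair[c]) > 0 and np.ptp(pair[ac]) > 0:
                        if abs(np.corrcoef(pair[c], pair[ac])[0, 1]) > 0.999:
                            collinear = True
            if collinear:
                row["status"] = "collinear_with_adjuster"
                rows.append(row)
                continue
            terms_s, aic_single = _fit_stack(datasets, duration_col, event_col, cols)
            terms_a, aic_adj = _fit_stack(
                datasets, duration_col, event_col, cols + adjust_cols
            )
            lead = cols[0]
            for prefix, terms, aic in (
                ("single", terms_s, aic_single),
                ("adjusted", terms_a, aic_adj),
            ):
                est = terms[lead]
                row[f"{prefix}_hr"] = float(np.exp(est["coef"]))
                row[f"{prefix}_ci95"] = (
                    float(np.exp(est["coef"] - _Z95 * est["se"])),
                    float(np.exp(est["coef"] + _Z95 * est["se"])),
                )
                row[f"{prefix}_p"] = est["p_value"]
                row[f"{prefix}_aic"] = aic
        except (ValueError, ConvergenceError) as exc:
            row["status"] = f"fit_error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BackwardEliminationResult:
    model: CoxModel | None
    included_terms: list[str]
    screened_out: list[str]
    removal_history: list[tuple[str, float]]
    status: str  # "ok" or "empty"


def backward_eliminate(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: dict[str, list[str]],
    enter_alpha: float = 0.10,
    stay_alpha: float = 0.05,
) -> BackwardEliminationResult:
    """Univariable screening then backward elimination on Wald p-values.

    Terms enter if univariably associated at ``enter_alpha``; the term with
    the largest multivariable Wald p is removed (ties broken towards the
    later term in the declared order) until all remaining terms satisfy
    ``stay_alpha``.  Deterministic for a fixed dataset and candidate order.
    """
    screened_in: list[str] = []
    screened_out: list[str] = []
    for name, cols in candidates.items():
        fit = fit_cox(records, duration_col, event_col, cols)
        _, _, p = fit.wald_test(cols)
        (screened_in if p < enter_alpha else screened_out).append(name)

    history: list[tuple[str, float]] = []
    current = list(screened_in)
    model = None
    while current:
        cols = [c for name in current for c in candidates[name]]
        model = fit_cox(records, duration_col, event_col, cols)
        pvals = [model.wald_test(candidates[name])[2] for name in current]
        worst = max(pvals)
        if worst < stay_alpha:
            break
        # ties -> later term in declared order: scan from the end
        for i in range(len(current) - 1, -1, -1):
            if pvals[i] == worst:
                history.append((current[i], worst))
                del current[i]
                break
        model = None
    if not current:
        return BackwardEliminationResult(
            model=None,
            included_terms=[],
            screened_out=screened_out,
            removal_history=history,
            status="empty",
        )
    return BackwardEliminationResult(
        model=model,
        included_terms=current,
        screened_out=screened_out,
        removal_history=history,
        status="ok",
    )


def nonlinearity_test(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    term: str,
    n_knots: int = 4,
) -> dict:
    """Likelihood-ratio test of a restricted-cubic-spline effect vs linear.

    The spline model nests the linear one; 2 * (logPL_spline - logPL_linear)
    is referred to chi-square with (n_knots - 2) df.
    """
    sub = records[[duration_col, event_col, term]].dropna()
    basis = rcs_basis(sub[term].to_numpy(), n_knots=n_knots)
    cols = basis.transform(sub[term].to_numpy())
    names = [term] + [f"{term}_rcs{j}" for j in range(1, basis.n_nonlinear + 1)]
    aug = sub.copy()
    for i, name in enumerate(names):
        aug[name] = cols[:, i]
    linear = fit_cox(aug, duration_col, event_col, [term])
    spline = fit_cox(aug, duration_col, event_col, names)
    lr = 2.0 * (spline.log_partial_likelihood - linear.log_partial_likelihood)
    lr = max(lr, 0.0)
    df = basis.n_nonlinear
    return {
        "lr_statistic": lr,
        "df": df,
        "p_value": float(stats.chi2.sf(lr, df=df)),
        "linear_model": linear,
        "spline_model": spline,
    }
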
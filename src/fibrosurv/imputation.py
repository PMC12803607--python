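"""Multiple imputation by bootstrap + predictive mean matching, and Rubin pooling.

Each of the ``m`` imputations draws a nonparametric bootstrap sample of the
cohort, fits a linear predictor for every incomplete variable from the other
imputation variables on the bootstrap sample's complete cases, and fills
every missing value with the *observed* value of a randomly chosen donor
among the ``donors`` nearest predicted means (predictive mean matching).
The bootstrap propagates parameter uncertainty; PMM guarantees imputed
values are always members of the observed-value set, so binary and ordinal
variables stay valid without special casing (they are matched on the linear
predicted score).

Variables are chained in order of increasing missingness for one full pass
(configurable to iterate); predictor columns that are themselves missing
are temporarily filled with random observed draws before the pass.

Coefficients fitted per imputation are combined by Rubin's rules with
Barnard–Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationResult", "PooledResult", "impute_pmm_bootstrap", "pool_rubin"]


@dataclass
class ImputationResult:
    datasets: list[pd.DataFrame]
    variables: list[str]
    m: int
    donors: int


def _linear_fit_predict(
    x_fit: np.ndarray, y_fit: np.ndarray, x_all: np.ndarray
) -> np.ndarray:
    a = np.column_stack([np.ones(len(x_fit)), x_fit])
    coef, *_ = np.linalg.lstsq(a, y_fit, rcond=None)
    return np.column_stack([np.ones(len(x_all)), x_all]) @ coef


def impute_pmm_bootstrap(
    records: pd.DataFrame,
    variables: list[str],
    m: int = 50,
    donors: int = 5,
    seed: int = 0,
    passes: int = 1,
) -> ImputationResult:
    """Generate ``m`` completed datasets by bootstrap + PMM.

    Only columns named in ``variables`` are imputed (and used as
    predictors); all other columns pass through untouched.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if donors < 1:
        raise ValueError("donors must be at least 1")
    missing_counts = {}
    for v in variables:
        if v not in records.columns:
            raise KeyError(v)
        n_obs = records[v].notna().sum()
        if n_obs == 0:
            raise ValueError(f"variable {v!r} has no observed values")
        missing_counts[v] = len(records) - n_obs
    incomplete = sorted(
        (v for v in variables if missing_counts[v] > 0), key=lambda v: missing_counts[v]
    )
    if not incomplete:
        return ImputationResult(
            datasets=[records.copy() for _ in range(m)],
            variables=list(variables),
            m=m,
            donors=donors,
        )

    rng = np.random.default_rng(seed)
    n = len(records)
    datasets = []
    for _ in range(m):
        boot_idx = rng.integers(0, n, size=n)
        work = records.copy()
        # provisional fill of predictor gaps with random observed draws
        filled = {}
        for v in variables:
            col = records[v].to_numpy(dtype=float)
            miss = np.isnan(col)
            if miss.any():
                obs = col[~miss]
                col = col.copy()
                col[miss] = rng.choice(obs, size=miss.sum(), replace=True)
            filled[v] = col
        x_mat = {v: filled[v] for v in variables}

        for _ in range(passes):
            for v in incomplete:
                others = [u for u in variables if u != v]
                x_all = np.column_stack([x_mat[u] for u in others])
                y_true = records[v].to_numpy(dtype=float)
                obs_mask = ~np.isnan(y_true)
                boot_obs = boot_idx[obs_mask[boot_idx]]
                if len(boot_obs) < len(others) + 2:
                    boot_obs = np.flatnonzero(obs_mask)  # degenerate bootstrap fallback
                yhat = _linear_fit_predict(
                    x_all[boot_obs], y_true[boot_obs], x_all
                )
                donors_idx = np.flatnonzero(obs_mask)
                donor_yhat = yhat[donors_idx]
                for i in np.flatnonzero(~obs_mask):
                    dist = np.abs(donor_yhat - yhat[i])
                    k = min(len(donors_idx), donors)
                    nearest = donors_idx[np.argpartition(dist, k - 1)[:k]]
                    value = y_true[int(rng.choice(nearest))]
                    x_mat[v][i] = value
                work[v] = x_mat[v]
        datasets.append(work)
    return ImputationResult(datasets=datasets, variables=list(variables), m=m, donors=donors)


@dataclass
class PooledResult:
    """Rubin-pooled estimates across imputations.

    ``terms`` maps coefficient name to a dict with pooled coef, total se,
    between/within variance components, Barnard–Rubin df and t-based p.
    """

    terms: dict[str, dict]
    m: int

    def __post_init__(self) -> None:
        for name, t in self.terms.items():
            if t["se"] ** 2 < t["within_var"] - 1e-12:
                raise AssertionError(f"pooled variance below within-variance for {name}")


def pool_rubin(fits, nu_complete: float | None = None) -> PooledResult:
    """Rubin's rules over a list of fitted models sharing the same terms.

    Accepts any objects exposing ``terms`` mapping name -> estimate with
    ``coef`` and ``se`` attributes (or dict keys).  Pooled coef is the mean,
    total variance W + (1 + 1/m) B, df per Barnard–Rubin (infinite
    complete-data df when ``nu_complete`` is omitted).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to pool")

    def _extract(fit) -> dict[str, tuple[float, float]]:
        out = {}
        for name, est in fit.terms.items():
            if isinstance(est, dict):
                out[name] = (float(est["coef"]), float(est["se"]))
            else:
                out[name] = (float(est.coef), float(est.se))
        return out

    per_fit = [_extract(f) for f in fits]
    names = list(per_fit[0])
    for pf in per_fit[1:]:
        if list(pf) != names:
            raise ValueError("mismatched term sets across imputations")
    m = len(fits)
    terms = {}
    for name in names:
        coefs = np.array([pf[name][0] for pf in per_fit])
        ses = np.array([pf[name][1] for pf in per_fit])
        qbar = float(coefs.mean())
        w = float(np.mean(ses**2))
        b = float(coefs.var(ddof=1))
        t = w + (1.0 + 1.0 / m) * b
        if b == 0.0 or t == 0.0:
            df = np.inf
        else:
            lam = (1.0 + 1.0 / m) * b / t
            df_old = (m - 1) / lam**2
            if nu_complete is None or not np.isfinite(nu_complete):
                df = df_old
            else:
                nu_obs = (nu_complete + 1) / (nu_complete + 3) * nu_complete * (1 - lam)
                df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
        se = float(np.sqrt(t))
        if se > 0:
            stat = qbar / se
            p = float(2.0 * stats.t.sf(abs(stat), df=df)) if np.isfinite(df) else float(
                2.0 * stats.norm.sf(abs(stat))
            )
        else:
            p = 1.0 if qbar == 0 else 0.0
        terms[name] = {
            "coef": qbar,
            "se": se,
            "within_var": w,
            "between_var": b,
            "df": float(df) if np.isfinite(df) else float("inf"),
            "p_value": max(min(p, 1.0), np.finfo(float).tiny),
        }
    return PooledResult(terms=terms, m=m)
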
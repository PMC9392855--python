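"""Logistic regression by Newton-Raphson and p-value-driven stepwise selection.

The selection procedure is the classic forward-selection /
backward-elimination hybrid used by clinical statistics packages: at each
round the candidate with the smallest Wald p enters if that p is below the
entry threshold (default 0.05), then any fitted variable whose Wald p has
drifted above the removal threshold (default 0.10) is dropped, worst
first.  The procedure stops when a round changes nothing; a step bound
guards against entry/removal cycling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

_Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge (separation is the usual cause)."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference per coefficient."""

    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    odds_ratio: np.ndarray
    or_ci: np.ndarray  # (k, 2)
    log_likelihood: float
    n_iter: int

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for i, name in enumerate(self.names):
            out[name] = {
                "coef": float(self.coef[i]),
                "se": float(self.se[i]),
                "p": float(self.wald_p[i]),
                "odds_ratio": float(self.odds_ratio[i]),
                "or_ci_low": float(self.or_ci[i, 0]),
                "or_ci_high": float(self.or_ci[i, 1]),
            }
        return out


def fit_logistic(
    X,
    y,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Fit P(y=1|x) = expit(x'b) by Newton-Raphson (IRLS).

    Convergence: relative log-likelihood change below ``tol`` (default
    1e-8) within ``max_iter`` (default 50) iterations; otherwise a
    :class:`ConvergenceError` naming the separation-suspect variable (the
    one with the largest coefficient magnitude) is raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    names = list(names)
    if len(names) != k:
        raise ValueError("one name per column required")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model undefined")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
        k += 1

    beta = np.zeros(k)
    ll_old = -math.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it}: "
                "collinear columns or separated data"
            ) from exc
        beta = beta + step
        with np.errstate(divide="ignore"):
            ll = float(y @ np.log(np.clip(mu, 1e-300, 1)) + (1 - y) @ np.log(np.clip(1 - mu, 1e-300, 1)))
        if ll_old > -math.inf and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            break
        ll_old = ll
    else:
        suspect = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations; suspect separation "
            f"driven by {suspect!r} (|coef|={np.abs(beta).max():.3g})"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix at optimum") from exc
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2 * _sps.norm.sf(np.abs(z))
    ll = float(y @ np.log(np.clip(mu, 1e-300, 1)) + (1 - y) @ np.log(np.clip(1 - mu, 1e-300, 1)))
    with np.errstate(over="ignore"):  # a wide CI may overflow to inf; keep it
        odds_ratio = np.exp(beta)
        or_ci = np.exp(np.column_stack([beta - _Z975 * se, beta + _Z975 * se]))
    return LogisticFit(
        names=tuple(names),
        coef=beta,
        cov=cov,
        se=se,
        wald_p=wald_p,
        odds_ratio=odds_ratio,
        or_ci=or_ci,
        log_likelihood=ll,
        n_iter=it,
    )


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of stepwise selection: the final fit plus the full step log."""

    selected: tuple[str, ...]
    fit: LogisticFit | None
    log: tuple[tuple[str, str, float], ...]  # (action, variable, wald_p)

    def summary(self) -> dict[str, dict[str, float]]:
        if self.fit is None:
            return {}
        return {k: v for k, v in self.fit.summary().items() if k != "intercept"}


def stepwise_logistic(
    X,
    y,
    names: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> StepwiseResult:
    """Forward selection with backward elimination on Wald p-values.

    A variable enters when its Wald p in the augmented model is the
    smallest among candidates and below ``p_enter``; after each entry,
    fitted variables with Wald p above ``p_remove`` are eliminated worst
    first.  Candidates whose augmented fit fails (separation, collinearity)
    are passed over with a log entry rather than aborting the search.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("X must be (n, k) with one name per column")
    if len(names) < 1:
        raise ValueError("need at least one candidate variable")
    cols = {name: X[:, j] for j, name in enumerate(names)}
    selected: list[str] = []
    log: list[tuple[str, str, float]] = []
    fit: LogisticFit | None = None

    for _ in range(max_steps):
        changed = False
        # forward step: best entrant under p_enter
        best_name, best_p, best_fit = None, None, None
        for name in names:
            if name in selected:
                continue
            trial = selected + [name]
            try:
                f = fit_logistic(
                    np.column_stack([cols[v] for v in trial]), y, names=trial
                )
            except (ConvergenceError, ValueError):
                log.append(("skipped", name, float("nan")))
                continue
            p = float(f.wald_p[f.names.index(name)])
            if best_p is None or p < best_p:
                best_name, best_p, best_fit = name, p, f
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            fit = best_fit
            log.append(("entered", best_name, best_p))
            changed = True
        # backward step: eliminate worst variable above p_remove
        while fit is not None and len(selected) > 0:
            ps = {v: float(fit.wald_p[fit.names.index(v)]) for v in selected}
            worst = max(ps, key=ps.get)
            if ps[worst] <= p_remove:
                break
            selected.remove(worst)
            log.append(("removed", worst, ps[worst]))
            changed = True
            fit = (
                fit_logistic(
                    np.column_stack([cols[v] for v in selected]), y, names=selected
                )
                if selected
                else None
            )
        if not changed:
            break
    else:
        raise RuntimeError(
            f"stepwise selection did not settle within {max_steps} steps "
            "(entry/removal cycling)"
        )
    return StepwiseResult(selected=tuple(selected), fit=fit, log=tuple(log))
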
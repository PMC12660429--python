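"""Cox partial-likelihood solver with delayed entry.

Newton-Raphson maximization of the Cox partial likelihood on an arbitrary
time axis (here: age), with subjects entering the risk set at ``entry`` and
leaving at ``exit``.  Ties are handled with the Efron approximation by
default; Breslow is available for comparison.  The implementation is fully
vectorized: risk-set sums at the distinct event times are obtained from
suffix cumulative sums over the exit- and entry-sorted data, so a fit on
20,000 subjects with a handful of covariates takes milliseconds.  This is
what makes the Monte-Carlo validation studies (hundreds of replicate fits)
tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoxFit", "ConvergenceError", "cox_fit"]


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge (reported with the gradient norm)."""


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit.

    ``params`` are log hazard ratios in the column order of the design
    matrix; ``cov`` is the inverse observed information.
    """

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_iter: int
    ties: str = "efron"
    names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _risk_sums(entry, exit_, w, wX, event_times):
    """S0(t), S1(t) over risk sets {i: entry_i < t <= exit_i} at each t.

    Uses the identity  sum_{entry<t<=exit} = sum_{exit>=t} - sum_{entry>=t}
    (valid because entry < exit for every subject), each term a suffix sum
    in the respective sort order.
    """
    n, p = wX.shape
    o_ex = np.argsort(exit_, kind="mergesort")
    o_en = np.argsort(entry, kind="mergesort")
    ex_s, en_s = exit_[o_ex], entry[o_en]

    cw_ex = np.concatenate([np.cumsum(w[o_ex][::-1])[::-1], [0.0]])
    cw_en = np.concatenate([np.cumsum(w[o_en][::-1])[::-1], [0.0]])
    cX_ex = np.vstack([np.cumsum(wX[o_ex][::-1], axis=0)[::-1], np.zeros((1, p))])
    cX_en = np.vstack([np.cumsum(wX[o_en][::-1], axis=0)[::-1], np.zeros((1, p))])

    i_ex = np.searchsorted(ex_s, event_times, side="left")
    i_en = np.searchsorted(en_s, event_times, side="left")
    S0 = cw_ex[i_ex] - cw_en[i_en]
    S1 = cX_ex[i_ex] - cX_en[i_en]
    return S0, S1, (o_ex, o_en, i_ex, i_en)


def _risk_sums2(X, w, idx):
    """S2(t) = sum over risk set of w_i x_i x_i' at each event time."""
    o_ex, o_en, i_ex, i_en = idx
    n, p = X.shape
    wXX = np.einsum("ij,i,ik->ijk", X, w, X)
    c_ex = np.concatenate(
        [np.cumsum(wXX[o_ex][::-1], axis=0)[::-1], np.zeros((1, p, p))]
    )
    c_en = np.concatenate(
        [np.cumsum(wXX[o_en][::-1], axis=0)[::-1], np.zeros((1, p, p))]
    )
    return c_ex[i_ex] - c_en[i_en]


def _tie_groups(exit_, event):
    """Distinct event times, per-time event counts and event-row indices."""
    times = exit_[event]
    uniq, inv, counts = np.unique(times, return_inverse=True, return_counts=True)
    return uniq, inv, counts


def cox_fit(
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    *,
    ties: str = "efron",
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Cox partial likelihood with delayed entry.

    Parameters
    ----------
    entry, exit_ : arrays of risk-set entry and exit times; ``entry < exit_``.
    event : 0/1 indicator that ``exit_`` is an event (not a censoring).
    X : (n, p) design matrix of covariates (no intercept — the partial
        likelihood has none).
    ties : "efron" (default) or "breslow".

    Raises
    ------
    ValueError
        on malformed input or if there are no events.
    ConvergenceError
        if Newton iteration does not converge within ``max_iter``.
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if not (len(entry) == len(exit_) == len(event) == n):
        raise ValueError("entry, exit, event and X must have equal length")
    if not np.all(np.isfinite(entry)) or not np.all(np.isfinite(exit_)):
        raise ValueError("entry/exit times must be finite")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if np.any(exit_ <= entry):
        raise ValueError("every exit time must exceed the entry time")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the data; the partial likelihood is flat")

    # Center columns: the partial likelihood is exactly invariant, and the
    # exponentials stay well-scaled.
    Xc = X - X.mean(axis=0)

    et, inv, d = _tie_groups(exit_, event)
    m = len(et)
    evX = Xc[event]
    # Per-group sums over tied events.
    dX = np.zeros((m, p))
    np.add.at(dX, inv, evX)
    sum_evX = evX.sum(axis=0)

    # Efron expansion: one row per (group, l) for l = 0..d_g-1.
    grp = np.repeat(np.arange(m), d)
    l_over_d = (np.arange(len(grp)) - np.repeat(np.cumsum(d) - d, d)) / d[grp]
    if ties == "breslow":
        l_over_d = np.zeros_like(l_over_d)

    beta = np.zeros(p)
    beta_prev = None
    loglik_prev = -np.inf
    n_halvings = 0
    grad_norm = np.nan
    for it in range(1, max_iter + 1):
        eta = Xc @ beta
        w = np.exp(np.clip(eta, -500, 500))
        wX = Xc * w[:, None]
        S0, S1, idx = _risk_sums(entry, exit_, w, wX, et)
        S2 = _risk_sums2(Xc, w, idx)

        # Tied-event sums at the current beta.
        wev = w[event]
        s0 = np.zeros(m)
        np.add.at(s0, inv, wev)
        s1 = np.zeros((m, p))
        np.add.at(s1, inv, wX[event])
        s2g = np.zeros((m, p, p))
        np.add.at(s2g, inv, np.einsum("ij,i,ik->ijk", evX, wev, evX))

        denom = S0[grp] - l_over_d * s0[grp]
        num1 = S1[grp] - l_over_d[:, None] * s1[grp]
        num2 = S2[grp] - l_over_d[:, None, None] * s2g[grp]

        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = float(eta[event].sum() - np.log(denom).sum())

        # Backtrack on divergence or a real likelihood decrease (a relative
        # threshold: suffix-sum round-off jitters the log-likelihood at the
        # ~1e-10 relative level near the optimum).
        decreased = loglik < loglik_prev - 1e-8 * (1.0 + abs(loglik_prev))
        if not np.isfinite(loglik) or decreased:
            if beta_prev is None:
                raise ConvergenceError(
                    "partial likelihood not finite at the starting value"
                )
            n_halvings += 1
            if n_halvings > 60:
                raise ConvergenceError(
                    f"step-halving failed to restore the likelihood "
                    f"(|grad| = {grad_norm:.3g}); check for complete "
                    "separation or a category with no events"
                )
            beta = 0.5 * (beta + beta_prev)
            continue
        n_halvings = 0

        r = num1 / denom[:, None]
        U = sum_evX - r.sum(axis=0)
        info = (num2 / denom[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", r, num1 / denom[:, None]
        )
        grad_norm = float(np.linalg.norm(U))
        if not np.all(np.isfinite(U)) or not np.all(np.isfinite(info)):
            raise ConvergenceError(
                f"non-finite score at iteration {it}; check for complete "
                "separation or extreme covariate scaling"
            )

        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:  # singular information
            raise ConvergenceError(
                f"singular information matrix at iteration {it} "
                f"(|grad| = {grad_norm:.3g}); "
                "check for collinear covariates or complete separation"
            ) from exc

        beta_prev, loglik_prev = beta.copy(), loglik
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(|grad| = {grad_norm:.3g})"
        )

    cov = np.linalg.inv(info)
    return CoxFit(
        params=beta,
        cov=cov,
        loglik=loglik,
        n=n,
        n_events=n_events,
        n_iter=it,
        ties=ties,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )
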
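"""Ordinary least squares with per-coefficient inference and fit metrics.

The regression machinery behind every QSRR fit.  Solutions come from a QR
decomposition of the design (never an explicit Gram inverse); rank is
judged against a machine-epsilon-scaled largest singular value.  The fit
metrics are the triple this field reports for each model: average absolute
error, maximum absolute error, and the standard error of the estimate
SEE = sqrt(SSE / (n - p)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "FitReport", "fit_ols", "fit_metrics", "RankDeficientError"]

INTERCEPT = "const"


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is numerically rank deficient.

    Carries ``dependent`` — names of columns linearly dependent on the
    preceding ones.
    """

    def __init__(self, dependent: list[str]):
        self.dependent = dependent
        super().__init__(f"rank-deficient design; dependent column(s): {dependent}")


@dataclass
class OLSFit:
    """A fitted least-squares model with coefficient-level inference.

    ``params`` etc. are ordered as the design columns, with the intercept
    (named ``const``) last when fitted.  ``degenerate`` marks a perfect
    fit (SSE numerically zero): standard errors and p-values are then
    reported as 0 rather than from the t distribution.
    """

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    sse: float
    n: int
    p: int
    has_intercept: bool
    degenerate: bool = False

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def param_table(self) -> dict[str, tuple[float, float, float, float]]:
        """name -> (estimate, SE, t, two-sided p)."""
        return {
            nm: (float(b), float(se), float(t), float(pv))
            for nm, b, se, t, pv in zip(
                self.names, self.params, self.bse, self.tvalues, self.pvalues
            )
        }


def _rank_tol(s: np.ndarray, n: int, k: int) -> float:
    return s[0] * max(n, k) * np.finfo(float).eps if s.size else 0.0


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan: columns that do not increase the rank of their prefix."""
    dep = []
    kept = np.empty((X.shape[0], 0))
    for j, nm in enumerate(names):
        trial = np.column_stack([kept, X[:, j]])
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] <= _rank_tol(s, *trial.shape):
            dep.append(nm)
        else:
            kept = trial
    return dep


def fit_ols(
    design: np.ndarray,
    response: np.ndarray,
    include_intercept: bool = False,
    names: list[str] | None = None,
) -> OLSFit:
    """Fit y = X b (+ c) by least squares, with SEs, t and p values.

    Parameters
    ----------
    design : (n, k) array; may have k = 0 with an intercept.
    response : (n,) array of retention times (minutes).
    include_intercept : append a constant column (named ``const``).
    names : column names; defaults to x1..xk.

    Raises
    ------
    RankDeficientError  if the (augmented) design is numerically singular.
    ValueError          if n <= number of fitted parameters.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError(f"design has {n} rows but response has {y.shape[0]}")
    if names is None:
        names = [f"x{j + 1}" for j in range(k)]
    names = list(names)
    if len(names) != k:
        raise ValueError("names length does not match design columns")

    if include_intercept:
        X = np.column_stack([X, np.ones(n)])
        names = names + [INTERCEPT]
    p = X.shape[1]
    if p == 0:
        raise ValueError("empty design and no intercept: nothing to fit")
    if n <= p:
        raise ValueError(f"need n > p: n={n}, parameters={p}")

    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= _rank_tol(s, n, p):
        raise RankDeficientError(_dependent_columns(X, names))

    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)

    # Gram inverse diagonal via R^{-1} R^{-T}; scale-aware perfect-fit test.
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)
    yscale = float(y @ y)
    degenerate = sse <= max(yscale, 1.0) * n * np.finfo(float).eps ** 2 * 1e4
    if degenerate:
        sse = max(sse, 0.0)
        bse = np.zeros(p)
        tvals = np.where(beta != 0, np.inf * np.sign(beta), 0.0)
        pvals = np.zeros(p)
    else:
        sigma2 = sse / (n - p)
        bse = np.sqrt(sigma2 * xtx_inv_diag)
        with np.errstate(divide="ignore"):
            tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)

    return OLSFit(
        names=names,
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        residuals=resid,
        fitted=fitted,
        sse=sse,
        n=n,
        p=p,
        has_intercept=include_intercept,
        degenerate=degenerate,
    )


@dataclass
class FitReport:
    """The field's model-quality triple, plus sizes.

    mae / max_ae / see are all in minutes.  ``see`` is the standard error
    of the estimate sqrt(SSE / (n - p)); the model with the smallest SEE
    is the preferred one among models of the same data.
    """

    mae: float
    max_ae: float
    see: float
    n: int
    p: int

    def triple(self, digits: int = 1) -> str:
        """Rounded "mae/max_ae/see" string as printed in QSRR tables."""
        return "/".join(
            f"{round(v, digits):g}" for v in (self.mae, self.max_ae, self.see)
        )

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "max_ae": self.max_ae,
            "see": self.see,
            "n": self.n,
            "p": self.p,
        }


def fit_metrics(observed, predicted, p: int) -> FitReport:
    """Average |error|, max |error| and SEE for a prediction vector."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    n = obs.shape[0]
    if n <= p:
        raise ValueError(f"need n > p for SEE: n={n}, p={p}")
    err = np.abs(obs - pred)
    sse = float(np.sum((obs - pred) ** 2))
    return FitReport(
        mae=float(err.mean()),
        max_ae=float(err.max()),
        see=float(np.sqrt(sse / (n - p))),
        n=n,
        p=p,
    )
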
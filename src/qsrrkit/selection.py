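"""Forward variable entry over a candidate descriptor pool.

The selection rule mirrors the classic Forward procedure of statistical
packages: at each step every not-yet-entered candidate is tried in the
enlarged model, and the one with the smallest two-sided coefficient
p-value is entered — provided that p is strictly below the entry
threshold alpha.  Selection stops when no candidate qualifies.  For a
single added variable this p is numerically identical to the
probability-of-F-to-enter criterion (t^2 = F).

Forward only: there is no removal step.  Variables may be *forced* into
the model first (used to pre-enter the reference-column retention time);
forced variables never leave and are exempt from the alpha rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .regression import RankDeficientError, fit_ols

__all__ = ["SelectionStep", "SelectionTrace", "forward_select"]


@dataclass
class SelectionStep:
    """One entry event: variable name, its entry p-value, model SSE after."""

    name: str
    p_enter: float
    sse: float
    forced: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "p_enter": self.p_enter,
            "sse": self.sse,
            "forced": self.forced,
        }


@dataclass
class SelectionTrace:
    """Ordered record of a forward-selection run."""

    steps: list[SelectionStep] = field(default_factory=list)
    alpha: float = 0.05
    stopped_reason: str = ""
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def final_set(self) -> list[str]:
        return [s.name for s in self.steps]

    @property
    def selected(self) -> list[str]:
        """Competitively entered names only (forced excluded)."""
        return [s.name for s in self.steps if not s.forced]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "stopped_reason": self.stopped_reason,
            "steps": [s.to_dict() for s in self.steps],
            "skipped": list(self.skipped),
        }


def _as_frame(candidates) -> pd.DataFrame:
    if isinstance(candidates, DescriptorMatrix):
        return candidates.frame
    return pd.DataFrame(candidates)


def forward_select(
    candidates,
    response,
    alpha: float = 0.05,
    include_intercept: bool = False,
    forced: list[str] | None = None,
    max_terms: int | None = None,
) -> SelectionTrace:
    """Run forward selection and return the trace.

    Parameters
    ----------
    candidates
        DescriptorMatrix or DataFrame of cleaned candidate columns
        (no missing values, no zero variance).
    response
        Retention vector, aligned with the candidate rows.
    alpha
        Entry threshold on the candidate's two-sided p-value
        (strictly-less-than, so alpha=1 admits everything non-degenerate).
    forced
        Column names entered first, unconditionally, in the given order.
    max_terms
        Optional cap on the total number of entered terms (forced
        included); None means unlimited.

    Notes
    -----
    Ties on the smallest p are broken by larger |t|, then by earlier
    candidate column order, so the procedure is deterministic for a given
    column order — and column order is immaterial whenever p-values are
    untied.  Candidates that would make the design rank deficient at a
    step are ineligible at that step only and recorded in ``skipped``.
    """
    frame = _as_frame(candidates)
    if frame.isna().any().any():
        raise ValueError("candidates contain missing values; clean the matrix first")
    y = np.asarray(response, dtype=float).ravel()
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    forced = list(forced or [])
    absent = [f for f in forced if f not in frame.columns]
    if absent:
        raise KeyError(f"forced variable(s) not among candidates: {absent}")

    trace = SelectionTrace(alpha=alpha)
    entered: list[str] = []

    def _fit(cols: list[str]):
        return fit_ols(
            frame[cols].to_numpy(), y, include_intercept=include_intercept, names=cols
        )

    for name in forced:
        entered.append(name)
        fit = _fit(entered)
        trace.steps.append(
            SelectionStep(
                name=name,
                p_enter=float(fit.pvalues[len(entered) - 1]),
                sse=fit.sse,
                forced=True,
            )
        )

    pool = [c for c in frame.columns if c not in entered]
    current_degenerate = bool(entered) and _fit(entered).degenerate
    while True:
        if current_degenerate:
            # Perfect fit: no candidate can reduce SSE, entry inference is
            # undefined, so nothing further qualifies.
            trace.stopped_reason = "no-candidate-below-alpha"
            break
        if max_terms is not None and len(entered) >= max_terms:
            trace.stopped_reason = "max-terms-reached"
            break
        if not pool:
            trace.stopped_reason = "pool-exhausted"
            break
        best = None  # ((p, -|t|, pool_index), name, sse, degenerate)
        for idx, cand in enumerate(pool):
            cols = entered + [cand]
            try:
                fit = _fit(cols)
            except RankDeficientError:
                trace.skipped.append((cand, "collinear with current model"))
                continue
            except ValueError:
                trace.skipped.append((cand, "n <= p in enlarged model"))
                continue
            j = cols.index(cand)
            key = (float(fit.pvalues[j]), -abs(float(fit.tvalues[j])), idx)
            if best is None or key < best[0]:
                best = (key, cand, fit.sse, fit.degenerate)
        if best is None or best[0][0] >= alpha:
            trace.stopped_reason = "no-candidate-below-alpha"
            break
        _, cand, sse, degen = best
        entered.append(cand)
        pool.remove(cand)
        current_degenerate = degen
        trace.steps.append(SelectionStep(name=cand, p_enter=best[0][0], sse=sse))

    return trace
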
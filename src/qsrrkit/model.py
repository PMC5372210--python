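"""QSRR model construction, fitting, prediction and comparison.

The modelling objects follow the model/results convention of statistical
packages: :class:`QSRR` holds the data and the model specification, its
:meth:`QSRR.fit` returns a :class:`QSRRResults` carrying coefficient
estimates with standard errors, the fit-quality triple and (in forward
mode) the selection trace.

Two model forms are supported, both linear in the parameters and written
without a constant term by default:

* classic:     t_R(A) = a_1 MD_1 + ... + a_n MD_n
* augmented:   t_R(A) = a_1 MD_1 + ... + a_n MD_n + b t_R(R)

where t_R(R) is the analyte's retention time measured under the same
elution conditions on a second, *reference*, chromatographic column.  In
the augmented form the reference term is forced into the model (always
entered, never removed); the molecular descriptors are either a fixed
list ("enter" mode) or competitively forward-selected at an entry
threshold alpha ("forward" mode).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .descriptors import DescriptorMatrix
from .regression import FitReport, fit_metrics, fit_ols
from .selection import SelectionTrace, forward_select

__all__ = [
    "RetentionTable",
    "QSRR",
    "QSRRResults",
    "ModelComparison",
    "build_classic_model",
    "build_augmented_model",
    "build_group_models",
    "compare_models",
    "load_results",
]

REFERENCE_TERM = "tR(R)"


@dataclass
class RetentionTable:
    """Retention times in minutes per (solute, chromatographic column).

    Wraps a DataFrame with solute ids as index and column/condition
    labels as columns; NaN marks a retention time not measured.  All
    present values must be positive.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate retention column labels")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate solute ids in retention table")
        self.frame = self.frame.astype(float)
        vals = self.frame.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("retention times must be positive where present")

    @property
    def solute_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def series(self, column: str) -> pd.Series:
        if column not in self.frame.columns:
            raise KeyError(f"retention column {column!r} not in table")
        return self.frame[column]


class QSRR:
    """Specification of a QSRR retention model, ready to fit.

    Parameters
    ----------
    descriptors
        DescriptorMatrix of candidate (forward mode) or chosen (enter
        mode) molecular descriptors.
    retention
        RetentionTable holding at least the target column, and the
        reference column when one is named.
    target
        Label of the column/condition whose retention is modelled.
    reference
        Optional label of the reference column; its retention times join
        the design as a forced extra descriptor with coefficient b.
    mode
        "forward" — competitive selection at entry threshold ``alpha``;
        "enter"   — fit exactly ``descriptor_names``, no selection.
    descriptor_names
        Required in enter mode; ignored in forward mode.
    include_intercept
        Fit a constant term.  Off by default: the canonical model forms
        are written without one.
    group
        Informational label stored with the results ("all" by default).

    Solutes are restricted to those with every needed retention value
    present; the row order of the descriptor matrix is preserved.
    """

    def __init__(
        self,
        descriptors: DescriptorMatrix,
        retention: RetentionTable,
        target: str,
        reference: str | None = None,
        mode: str = "forward",
        descriptor_names: list[str] | None = None,
        alpha: float = 0.05,
        include_intercept: bool = False,
        group: str = "all",
    ):
        if mode not in ("forward", "enter"):
            raise ValueError(f"mode must be 'forward' or 'enter', got {mode!r}")
        if reference is not None and reference == target:
            raise ValueError("reference column must differ from target column")
        if mode == "enter" and not descriptor_names:
            raise ValueError("enter mode requires a nonempty descriptor_names list")
        self.descriptors = descriptors
        self.retention = retention
        self.target = target
        self.reference = reference
        self.mode = mode
        self.descriptor_names = list(descriptor_names or [])
        self.alpha = alpha
        self.include_intercept = include_intercept
        self.group = group

        y = retention.series(target)
        needed = [y]
        if reference is not None:
            needed.append(retention.series(reference))
        ids = [i for i in descriptors.solute_ids if i in retention.frame.index]
        mask = pd.Series(True, index=pd.Index(ids))
        for s in needed:
            mask &= s.reindex(mask.index).notna()
        self.solute_ids = [i for i in ids if mask[i]]
        if not self.solute_ids:
            raise ValueError("no solute has all required retention values")

    def _design_frame(self) -> pd.DataFrame:
        frame = self.descriptors.frame.loc[self.solute_ids].copy()
        if self.mode == "enter":
            missing = [n for n in self.descriptor_names if n not in frame.columns]
            if missing:
                raise KeyError(f"descriptor(s) not in matrix: {missing}")
            frame = frame[self.descriptor_names]
        if self.reference is not None:
            ref = self.retention.series(self.reference).loc[self.solute_ids]
            frame[REFERENCE_TERM] = ref
        return frame

    def fit(self, max_terms: int | None = None) -> "QSRRResults":
        """Estimate the model and return a results object."""
        frame = self._design_frame()
        y = self.retention.series(self.target).loc[self.solute_ids].to_numpy()

        trace: SelectionTrace | None = None
        if self.mode == "forward":
            forced = [REFERENCE_TERM] if self.reference is not None else []
            trace = forward_select(
                frame,
                y,
                alpha=self.alpha,
                include_intercept=self.include_intercept,
                forced=forced,
                max_terms=max_terms,
            )
            cols = trace.final_set
            if not trace.selected:
                warnings.warn(
                    f"forward selection entered no descriptor for "
                    f"{self.target!r} (alpha={self.alpha})",
                    stacklevel=2,
                )
        else:
            cols = self.descriptor_names + (
                [REFERENCE_TERM] if self.reference is not None else []
            )

        # Reference term last for readability, matching the printed forms.
        if REFERENCE_TERM in cols:
            cols = [c for c in cols if c != REFERENCE_TERM] + [REFERENCE_TERM]

        if cols:
            ols = fit_ols(
                frame[cols].to_numpy(),
                y,
                include_intercept=self.include_intercept,
                names=cols,
            )
            report = fit_metrics(y, ols.fitted, p=ols.p)
        elif self.include_intercept:
            ols = fit_ols(
                np.empty((len(y), 0)), y, include_intercept=True, names=[]
            )
            report = fit_metrics(y, ols.fitted, p=1)
        else:
            ols = None
            report = FitReport(
                mae=float(np.mean(np.abs(y))),
                max_ae=float(np.max(np.abs(y))),
                see=float(np.sqrt(np.sum(y**2) / len(y))),
                n=len(y),
                p=0,
            )
        return QSRRResults(model=self, ols=ols, fit_report=report, trace=trace)


@dataclass
class QSRRResults:
    """A fitted QSRR model.

    Coefficients live in :attr:`params` (a pandas Series indexed by
    descriptor name; the reference term is named ``tR(R)``, the intercept
    ``const``), with standard errors in :attr:`bse`, t statistics in
    :attr:`tvalues` and two-sided p-values in :attr:`pvalues`.
    """

    model: QSRR
    ols: object
    fit_report: FitReport
    trace: SelectionTrace | None = None

    @property
    def target(self) -> str:
        return self.model.target

    def _series(self, attr: str) -> pd.Series:
        if self.ols is None:
            return pd.Series(dtype=float)
        return pd.Series(getattr(self.ols, attr), index=self.ols.names)

    @property
    def params(self) -> pd.Series:
        return self._series("params")

    @property
    def bse(self) -> pd.Series:
        return self._series("bse")

    @property
    def tvalues(self) -> pd.Series:
        return self._series("tvalues")

    @property
    def pvalues(self) -> pd.Series:
        return self._series("pvalues")

    @property
    def descriptor_names(self) -> list[str]:
        return [
            n for n in self.params.index if n not in (REFERENCE_TERM, "const")
        ]

    @property
    def is_augmented(self) -> bool:
        return self.model.reference is not None

    @property
    def reference_coefficient(self) -> tuple[float, float] | None:
        """(b, SE(b)) for the reference term, or None in a classic model."""
        if REFERENCE_TERM not in self.params.index:
            return None
        return (
            float(self.params[REFERENCE_TERM]),
            float(self.bse[REFERENCE_TERM]),
        )

    @property
    def degenerate(self) -> bool:
        """True when the fit is numerically perfect (SSE ~ 0)."""
        return bool(self.ols is not None and self.ols.degenerate)

    @property
    def sse(self) -> float:
        return float(self.ols.sse) if self.ols is not None else float("nan")

    def predict(
        self,
        descriptors: DescriptorMatrix | pd.DataFrame,
        reference_retention: pd.Series | np.ndarray | None = None,
    ) -> pd.Series:
        """Predict retention times (minutes) for new solutes.

        ``descriptors`` must contain every descriptor the model uses; an
        augmented model additionally needs ``reference_retention``
        aligned with the descriptor rows.
        """
        frame = (
            descriptors.frame
            if isinstance(descriptors, DescriptorMatrix)
            else pd.DataFrame(descriptors)
        )
        missing = [n for n in self.descriptor_names if n not in frame.columns]
        if missing:
            raise KeyError(f"missing descriptor column(s): {missing}")
        X = frame[self.descriptor_names].astype(float)
        if self.is_augmented:
            if reference_retention is None:
                raise ValueError(
                    "augmented model: reference_retention is required"
                )
            ref = np.asarray(reference_retention, dtype=float).ravel()
            if ref.shape[0] != X.shape[0]:
                raise ValueError("reference_retention length mismatch")
            X = X.assign(**{REFERENCE_TERM: ref})
        elif reference_retention is not None:
            raise ValueError("classic model takes no reference_retention")
        cols = [c for c in self.params.index if c != "const"]
        yhat = X[cols].to_numpy() @ self.params[cols].to_numpy()
        if "const" in self.params.index:
            yhat = yhat + self.params["const"]
        return pd.Series(yhat, index=frame.index, name=f"pred_{self.target}")

    def summary(self) -> str:
        """Human-readable coefficient table and fit metrics."""
        m = self.model
        head = [
            f"QSRR model for {m.target}"
            + (f" (reference: {m.reference})" if m.reference else ""),
            f"mode={m.mode}  alpha={m.alpha}  intercept={m.include_intercept}  "
            f"group={m.group}  n={self.fit_report.n}  p={self.fit_report.p}",
            "-" * 64,
            f"{'term':<20}{'coef':>10}{'SE':>10}{'t':>9}{'p':>10}",
        ]
        rows = []
        for nm in self.params.index:
            rows.append(
                f"{nm:<20}{self.params[nm]:>10.4g}{self.bse[nm]:>10.3g}"
                f"{self.tvalues[nm]:>9.3g}{self.pvalues[nm]:>10.3g}"
            )
        fr = self.fit_report
        tail = [
            "-" * 64,
            f"avg|err|/max|err|/SEE = {fr.triple()}  (full precision: "
            f"{fr.mae:.6g}/{fr.max_ae:.6g}/{fr.see:.6g} min)",
        ]
        if self.degenerate:
            tail.append("note: perfect fit (SSE ~ 0); SEs and p-values degenerate")
        return "\n".join(head + rows + tail)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        m = self.model
        digest = hashlib.sha256(
            pd.util.hash_pandas_object(
                m.descriptors.frame.loc[m.solute_ids]
            ).to_numpy().tobytes()
        ).hexdigest()[:16]
        return {
            "format": "qsrrkit-model",
            "version": _pkg_version,
            "target": m.target,
            "reference": m.reference,
            "mode": m.mode,
            "alpha": m.alpha,
            "include_intercept": m.include_intercept,
            "group": m.group,
            "n_solutes": len(m.solute_ids),
            "input_digest": digest,
            "terms": [
                {
                    "name": nm,
                    "coef": float(self.params[nm]),
                    "se": float(self.bse[nm]),
                    "t": float(self.tvalues[nm]),
                    "p": float(self.pvalues[nm]),
                }
                for nm in self.params.index
            ],
            "degenerate": self.degenerate,
            "fit_report": self.fit_report.to_dict(),
            "trace": self.trace.to_dict() if self.trace is not None else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class LoadedModel:
    """A deserialized model: prediction-capable, without training data."""

    target: str
    reference: str | None
    params: pd.Series
    bse: pd.Series
    fit_report: FitReport
    include_intercept: bool

    @property
    def is_augmented(self) -> bool:
        return self.reference is not None

    @property
    def descriptor_names(self) -> list[str]:
        return [n for n in self.params.index if n not in (REFERENCE_TERM, "const")]

    predict = QSRRResults.predict


def load_results(path) -> LoadedModel:
    """Load a serialized model JSON for prediction."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "qsrrkit-model":
        raise ValueError(f"{path}: not a qsrrkit model file")
    names = [t["name"] for t in doc["terms"]]
    params = pd.Series([t["coef"] for t in doc["terms"]], index=names)
    bse = pd.Series([t["se"] for t in doc["terms"]], index=names)
    fr = FitReport(**doc["fit_report"])
    return LoadedModel(
        target=doc["target"],
        reference=doc["reference"],
        params=params,
        bse=bse,
        fit_report=fr,
        include_intercept=doc["include_intercept"],
    )


# ---------------------------------------------------------------------------
# Convenience constructors mirroring the pipeline operations.
# ---------------------------------------------------------------------------


def build_classic_model(
    dm: DescriptorMatrix,
    rt: RetentionTable,
    target: str,
    mode: str = "forward",
    descriptor_names: list[str] | None = None,
    alpha: float = 0.05,
    include_intercept: bool = False,
    group: str = "all",
) -> QSRRResults:
    """Fit the classic form t_R = sum a_i MD_i (no reference term)."""
    return QSRR(
        dm,
        rt,
        target,
        mode=mode,
        descriptor_names=descriptor_names,
        alpha=alpha,
        include_intercept=include_intercept,
        group=group,
    ).fit()


def build_augmented_model(
    dm: DescriptorMatrix,
    rt: RetentionTable,
    target: str,
    reference: str,
    mode: str = "enter",
    descriptor_names: list[str] | None = None,
    alpha: float = 0.05,
    include_intercept: bool = False,
    group: str = "all",
) -> QSRRResults:
    """Fit the augmented form with t_R(R) forced into the design.

    The default recipe is enter mode with a fixed descriptor list — in
    practice the descriptors previously forward-selected for the classic
    model — plus the forced reference term; forward mode lets the
    remaining descriptors compete after t_R(R) is entered.
    """
    return QSRR(
        dm,
        rt,
        target,
        reference=reference,
        mode=mode,
        descriptor_names=descriptor_names,
        alpha=alpha,
        include_intercept=include_intercept,
        group=group,
    ).fit()


def build_group_models(
    dm: DescriptorMatrix,
    rt: RetentionTable,
    target: str,
    reference: str,
    groups: pd.Series | dict,
    alpha: float = 0.05,
    include_intercept: bool = False,
    min_size: int = 4,
) -> dict[str, tuple[QSRRResults, QSRRResults]]:
    """Per-chemical-group classic + augmented model pairs.

    For each group label: forward-select a classic model on the group's
    solutes, then refit the selected descriptors with the forced
    reference term (the fixed-descriptor augmentation recipe).  Groups
    whose size cannot support a fit are skipped with a warning.
    """
    groups = pd.Series(groups)
    out: dict[str, tuple[QSRRResults, QSRRResults]] = {}
    for label in groups.dropna().unique():
        ids = [i for i in dm.solute_ids if groups.get(i) == label]
        if len(ids) < min_size:
            warnings.warn(
                f"group {label!r}: only {len(ids)} solutes, skipped", stacklevel=2
            )
            continue
        sub_dm = DescriptorMatrix(
            dm.frame.loc[ids].copy(), dict(dm.provenance)
        )
        try:
            classic = build_classic_model(
                sub_dm, rt, target, mode="forward", alpha=alpha,
                include_intercept=include_intercept, group=str(label),
            )
            augmented = build_augmented_model(
                sub_dm, rt, target, reference, mode="enter",
                descriptor_names=classic.descriptor_names or None,
                include_intercept=include_intercept, group=str(label),
            ) if classic.descriptor_names else build_augmented_model(
                sub_dm, rt, target, reference, mode="forward", alpha=alpha,
                include_intercept=include_intercept, group=str(label),
            )
        except ValueError as exc:
            warnings.warn(f"group {label!r}: fit failed ({exc})", stacklevel=2)
            continue
        out[str(label)] = (classic, augmented)
    return out


@dataclass
class ModelComparison:
    """Side-by-side comparison of a classic and an augmented model."""

    target: str
    classic_report: FitReport
    augmented_report: FitReport
    delta_mae: float
    delta_max_ae: float
    delta_see: float
    b: float | None
    b_se: float | None
    b_pvalue: float | None
    b_significant: bool | None

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "classic": self.classic_report.to_dict(),
            "augmented": self.augmented_report.to_dict(),
            "delta_mae": self.delta_mae,
            "delta_max_ae": self.delta_max_ae,
            "delta_see": self.delta_see,
            "reference_coefficient": self.b,
            "reference_coefficient_se": self.b_se,
            "reference_coefficient_pvalue": self.b_pvalue,
            "reference_significant": self.b_significant,
        }

    def summary(self) -> str:
        c, a = self.classic_report, self.augmented_report
        lines = [
            f"Model comparison for {self.target}",
            f"{'':<12}{'avg|err|':>10}{'max|err|':>10}{'SEE':>8}",
            f"{'classic':<12}{c.mae:>10.3g}{c.max_ae:>10.3g}{c.see:>8.3g}",
            f"{'augmented':<12}{a.mae:>10.3g}{a.max_ae:>10.3g}{a.see:>8.3g}",
            f"{'delta':<12}{self.delta_mae:>10.3g}{self.delta_max_ae:>10.3g}"
            f"{self.delta_see:>8.3g}",
            f"paper-style triples: classic {c.triple()}, augmented {a.triple()}",
        ]
        if self.b is not None:
            sig = "significant" if self.b_significant else "not significant"
            lines.append(
                f"reference coefficient b = {self.b:.4g} ± {self.b_se:.2g} "
                f"(p = {self.b_pvalue:.3g}, {sig} at 0.05)"
            )
        return "\n".join(lines)


def compare_models(
    classic: QSRRResults, augmented: QSRRResults
) -> ModelComparison:
    """Quantify what the reference term buys: metric deltas + b inference."""
    if classic.model.target != augmented.model.target:
        raise ValueError("models target different retention columns")
    if classic.model.solute_ids != augmented.model.solute_ids:
        raise ValueError("models were fitted on different solute sets")
    b = b_se = b_p = None
    b_sig = None
    rc = augmented.reference_coefficient
    if rc is not None:
        b, b_se = rc
        b_p = float(augmented.pvalues[REFERENCE_TERM])
        b_sig = bool(b_p < 0.05)
    c, a = classic.fit_report, augmented.fit_report
    return ModelComparison(
        target=classic.model.target,
        classic_report=c,
        augmented_report=a,
        delta_mae=a.mae - c.mae,
        delta_max_ae=a.max_ae - c.max_ae,
        delta_see=a.see - c.see,
        b=b,
        b_se=b_se,
        b_pvalue=b_p,
        b_significant=b_sig,
    )
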
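"""Cohort-level association analysis.

Each vascular parameter (area, sumL, FD, flow density) is related to
two outcomes — the 3-year intravitreal injection count and the visual
acuity change (3-year logMAR minus baseline logMAR, with the baseline
entered as confounder) — in separate fence-weighted linear regressions.
MNV type (1/2/3) enters as two indicator terms with a joint F test
against both outcomes.  Per-observation weights are the geometric mean
of the fence weights of the numeric variables involved in each model.
No multiple-testing correction is applied by default (raw p-values at
the 5% level); an optional Holm adjustment is available.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import MnvQuantError
from .io import validate_cohort
from .robust import (
    FenceThresholds,
    combine_weights,
    fence_thresholds,
    outlier_weight,
    weighted_linear_fit,
)

VASCULAR_PARAMETERS = ["area_mm2", "suml_mm", "fd", "flow_density_pct"]


@dataclasses.dataclass
class ModelResult:
    """One fitted (or failed) association model."""

    name: str
    outcome: str
    terms_of_interest: list[str]
    kind: str = "linear"
    estimates: dict = dataclasses.field(default_factory=dict)
    std_errors: dict = dataclasses.field(default_factory=dict)
    pvalues: dict = dataclasses.field(default_factory=dict)
    pvalue: float | None = None  # headline p (single term or joint test)
    joint: bool = False
    fences: dict = dataclasses.field(default_factory=dict)
    weight_summary: dict = dataclasses.field(default_factory=dict)
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "outcome": self.outcome,
            "kind": self.kind,
            "terms": {
                t: {
                    "estimate": self.estimates.get(t),
                    "se": self.std_errors.get(t),
                    "p": self.pvalues.get(t),
                }
                for t in self.estimates
            },
            "p": self.pvalue,
            "joint": self.joint,
            "fences": self.fences,
            "weights": self.weight_summary,
            "error": self.error,
        }


@dataclasses.dataclass
class AnalysisReport:
    """All association models of one cohort run."""

    models: list[ModelResult]
    alpha: float
    weights_mode: str
    n_eyes: int

    def model(self, name: str) -> ModelResult:
        for m in self.models:
            if m.name == name:
                return m
        raise KeyError(name)

    def significant(self) -> list[str]:
        return [m.name for m in self.models if not m.failed and m.pvalue < self.alpha]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "weights": self.weights_mode,
            "n_eyes": self.n_eyes,
            "models": [m.to_dict() for m in self.models],
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append(
                {
                    "model": m.name,
                    "outcome": m.outcome,
                    "p": m.pvalue,
                    "estimate": (
                        m.estimates.get(m.terms_of_interest[0])
                        if len(m.terms_of_interest) == 1
                        else None
                    ),
                    "failed": m.failed,
                    "error": m.error,
                }
            )
        return pd.DataFrame(rows)


def _fit_one(
    df: pd.DataFrame,
    name: str,
    outcome: str,
    iv_cols: list[str],
    confounder_cols: list[str],
    weight_cols: list[str],
    fences: dict[str, FenceThresholds],
    weights_mode: str,
    terms_of_interest: list[str],
    joint: bool,
) -> ModelResult:
    result = ModelResult(
        name=name, outcome=outcome, terms_of_interest=terms_of_interest, joint=joint
    )
    try:
        if weights_mode == "fence" and weight_cols:
            stack = np.vstack(
                [outlier_weight(df[c].to_numpy(), fences[c]) for c in weight_cols]
            )
            w = combine_weights(stack)
            result.fences = {c: fences[c].to_dict() for c in weight_cols}
        else:
            w = np.ones(len(df))
        ivs = df[iv_cols]
        confounder = df[confounder_cols] if confounder_cols else None
        fit = weighted_linear_fit(df[outcome].to_numpy(), ivs, confounder=confounder, weights=w)
        result.estimates = {k: float(v) for k, v in fit.params.items()}
        result.std_errors = {k: float(v) for k, v in fit.bse.items()}
        result.pvalues = {k: float(v) for k, v in fit.pvalues.items()}
        if joint:
            result.pvalue = fit.joint_pvalue(terms_of_interest)
        else:
            result.pvalue = float(fit.pvalues[terms_of_interest[0]])
        result.weight_summary = {
            "min": float(w.min()),
            "mean": float(w.mean()),
            "n_downweighted": int((w < 1.0 - 1e-12).sum()),
        }
    except MnvQuantError as exc:
        result.error = f"{type(exc).__name__}: {exc}"
    return result


def analyze_cohort(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    weights: str = "fence",
    holm: bool = False,
) -> AnalysisReport:
    """Fit the full battery of association models for one cohort.

    Produces 4 parameters x 2 outcomes = 8 single-parameter models plus
    2 MNV-type models (joint tests), i.e. 10 models.  Models that cannot
    be fit are reported as failed entries, never dropped silently.  The
    report depends on the data only through sums and order statistics,
    so it is invariant to row order.
    """
    if weights not in ("fence", "none"):
        raise MnvQuantError(f"unknown weights mode {weights!r}")
    df = validate_cohort(cohort).reset_index(drop=True)
    df = df.copy()
    df["va_change"] = df["bcva_3y_logmar"] - df["bcva_baseline_logmar"]
    df["type_2"] = (df["mnv_type"] == 2).astype(float)
    df["type_3"] = (df["mnv_type"] == 3).astype(float)

    numeric_cols = VASCULAR_PARAMETERS + [
        "ivi_count_3y",
        "va_change",
        "bcva_baseline_logmar",
    ]
    fences = {c: fence_thresholds(df[c]) for c in numeric_cols}

    models: list[ModelResult] = []
    for param in VASCULAR_PARAMETERS:
        models.append(
            _fit_one(
                df,
                name=f"{param}~ivi_count_3y",
                outcome="ivi_count_3y",
                iv_cols=[param],
                confounder_cols=[],
                weight_cols=[param, "ivi_count_3y"],
                fences=fences,
                weights_mode=weights,
                terms_of_interest=[param],
                joint=False,
            )
        )
    for param in VASCULAR_PARAMETERS:
        models.append(
            _fit_one(
                df,
                name=f"{param}~va_change",
                outcome="va_change",
                iv_cols=[param],
                confounder_cols=["bcva_baseline_logmar"],
                weight_cols=[param, "va_change", "bcva_baseline_logmar"],
                fences=fences,
                weights_mode=weights,
                terms_of_interest=[param],
                joint=False,
            )
        )
    models.append(
        _fit_one(
            df,
            name="mnv_type~ivi_count_3y",
            outcome="ivi_count_3y",
            iv_cols=["type_2", "type_3"],
            confounder_cols=[],
            weight_cols=["ivi_count_3y"],
            fences=fences,
            weights_mode=weights,
            terms_of_interest=["type_2", "type_3"],
            joint=True,
        )
    )
    models.append(
        _fit_one(
            df,
            name="mnv_type~va_change",
            outcome="va_change",
            iv_cols=["type_2", "type_3"],
            confounder_cols=["bcva_baseline_logmar"],
            weight_cols=["va_change", "bcva_baseline_logmar"],
            fences=fences,
            weights_mode=weights,
            terms_of_interest=["type_2", "type_3"],
            joint=True,
        )
    )

    if holm:
        fitted = [m for m in models if not m.failed]
        order = np.argsort([m.pvalue for m in fitted])
        k = len(fitted)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (k - rank) * fitted[idx].pvalue)
            running = max(running, adj)
            fitted[idx].pvalue = running

    return AnalysisReport(
        models=models, alpha=alpha, weights_mode=weights, n_eyes=len(df)
    )
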
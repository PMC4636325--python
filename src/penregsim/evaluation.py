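"""Monte-Carlo performance metrics aggregated over replicate fits.

For each method the study records, per replicate, the fitted model and its
squared prediction error on an independently generated evaluation set.
This module turns collections of such records into the summary quantities
of interest:

* prediction RMSE of y on fresh data;
* per-variable bias, RMSE, selection probability, wrong-sign percentage
  and non-selection percentage of the coefficient estimates;
* model complexity (mean count of nonzero coefficients, overall and among
  the true-zero nuisance variables);
* median and quartiles of the cross-validated tuning parameters.

Conventions: bias and coefficient RMSE average over *all* replicates,
including those where the variable was not selected (estimate zero).  The
wrong-sign percentage counts replicates where a *nonzero* estimate opposes
the sign of a nonzero true coefficient, as a fraction of all replicates;
for true-zero variables it is undefined and the selection probability is
the type-1 error.  Selection and non-selection percentages sum to one by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import FitResult
from .scenarios import ScenarioSpec

__all__ = [
    "ReplicateRecord",
    "MetricsSummary",
    "prediction_rmse",
    "coefficient_metrics",
    "model_complexity",
    "summarize",
]


@dataclass
class ReplicateRecord:
    """One method's fit on one replicate, plus its out-of-sample error."""

    replicate_id: int
    method: str
    fit: FitResult
    test_error: float  # per-observation squared prediction error, fresh data
    insample_mse: float | None = None

    def __post_init__(self):
        if self.test_error < 0:
            raise ValueError("test_error must be nonnegative")


def prediction_rmse(records: list[ReplicateRecord]) -> float:
    """Root of the mean (over replicates) per-observation squared prediction error."""
    if not records:
        raise ValueError("records must be nonempty")
    return float(np.sqrt(np.mean([r.test_error for r in records])))


def coefficient_metrics(records: list[ReplicateRecord], spec: ScenarioSpec) -> pd.DataFrame:
    """Per-variable accuracy metrics of the coefficient estimates.

    Returns a frame indexed by variable label with columns ``true_beta``,
    ``bias``, ``rmse_beta``, ``selection_probability``, ``wrong_sign_pct``
    and ``not_selected_pct`` (probabilities as fractions in [0, 1];
    ``wrong_sign_pct`` is NaN for true-zero variables).
    """
    if not records:
        raise ValueError("records must be nonempty")
    B = np.vstack([r.fit.coefficients for r in records])  # m x k
    beta = np.asarray(spec.beta)
    m = B.shape[0]
    selected = B != 0.0
    sel_prob = selected.mean(axis=0)
    wrong = np.where(
        beta != 0.0,
        ((np.sign(B) == -np.sign(beta)) & selected).sum(axis=0) / m,
        np.nan,
    )
    return pd.DataFrame(
        {
            "true_beta": beta,
            "bias": B.mean(axis=0) - beta,
            "rmse_beta": np.sqrt(((B - beta) ** 2).mean(axis=0)),
            "selection_probability": sel_prob,
            "wrong_sign_pct": wrong,
            "not_selected_pct": 1.0 - sel_prob,
        },
        index=list(spec.labels),
    )


def model_complexity(records: list[ReplicateRecord], noise_indices=()) -> tuple[float, float]:
    """Mean count of nonzero coefficients (total, and among ``noise_indices``)."""
    if not records:
        raise ValueError("records must be nonempty")
    B = np.vstack([r.fit.coefficients for r in records])
    total = float((B != 0.0).sum(axis=1).mean())
    ni = list(noise_indices)
    nuisance = float((B[:, ni] != 0.0).sum(axis=1).mean()) if ni else 0.0
    return total, nuisance


def _tuning_quartiles(records: list[ReplicateRecord]) -> dict:
    lam1 = [r.fit.penalty.lambda1 for r in records if r.fit.penalty is not None]
    lam2 = [r.fit.penalty.lambda2 for r in records if r.fit.penalty is not None]
    out = {}
    for name, vals in (("lambda1", lam1), ("lambda2", lam2)):
        if vals:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out.update({f"{name}_q1": q1, f"{name}_median": med, f"{name}_q3": q3})
        else:
            out.update({f"{name}_q1": np.nan, f"{name}_median": np.nan, f"{name}_q3": np.nan})
    return out


@dataclass
class MetricsSummary:
    """Aggregated per-method and per-method-per-variable Monte-Carlo metrics."""

    scenario: str
    n: int
    m: int
    per_method: pd.DataFrame  # index method: rmse_y, complexity, ...
    per_variable: pd.DataFrame  # index (method, variable)
    metadata: dict = field(default_factory=dict)

    def method_table(self) -> pd.DataFrame:
        return self.per_method

    def wrong_sign_table(self, as_percent: bool = True) -> pd.DataFrame:
        """Wrong-sign percentage with the exclusion percentage in parentheses."""
        f = 100.0 if as_percent else 1.0
        pv = self.per_variable
        rows = {}
        for method in pv.index.get_level_values(0).unique():
            sub = pv.loc[method]
            rows[method] = [
                f"{f * ws:.1f} ({f * ns:.1f})" if np.isfinite(ws) else f"- ({f * ns:.1f})"
                for ws, ns in zip(sub["wrong_sign_pct"], sub["not_selected_pct"])
            ]
        first = pv.index.get_level_values(0).unique()[0]
        return pd.DataFrame(rows, index=pv.loc[first].index)

    def complexity_table(self) -> pd.DataFrame:
        cols = ["complexity", "complexity_nuisance"]
        return self.per_method[cols]

    def tuning_table(self) -> pd.DataFrame:
        cols = [c for c in self.per_method.columns if c.startswith("lambda")]
        return self.per_method[cols].dropna(how="all")

    def tidy(self) -> pd.DataFrame:
        """Long-format per-variable metrics with scenario and n attached."""
        df = self.per_variable.reset_index()
        df.insert(0, "scenario", self.scenario)
        df.insert(1, "n", self.n)
        return df


def summarize(
    records_by_method: dict[str, list[ReplicateRecord]],
    spec: ScenarioSpec,
    metadata: dict | None = None,
) -> MetricsSummary:
    """Aggregate replicate records for several methods into one summary."""
    per_method_rows = {}
    per_var_frames = []
    m = 0
    for method, recs in records_by_method.items():
        m = max(m, len(recs))
        total, nuisance = model_complexity(recs, spec.noise_indices)
        row = {
            "rmse_y": prediction_rmse(recs),
            "complexity": total,
            "complexity_nuisance": nuisance,
            "mean_rss": float(np.mean([r.fit.rss for r in recs])),
        }
        row.update(_tuning_quartiles(recs))
        per_method_rows[method] = row
        cm = coefficient_metrics(recs, spec)
        cm.index = pd.MultiIndex.from_product([[method], cm.index], names=["method", "variable"])
        per_var_frames.append(cm)
    return MetricsSummary(
        scenario=spec.name,
        n=spec.n,
        m=m,
        per_method=pd.DataFrame(per_method_rows).T,
        per_variable=pd.concat(per_var_frames),
        metadata=metadata or {},
    )
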
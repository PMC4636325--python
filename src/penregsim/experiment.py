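"""Orchestration of the full simulation study.

A :class:`StudyConfig` names the scenarios, sample sizes, methods,
replicate count and master seed; :func:`run_study` loops over every
(scenario, n) cell, generates a fresh training set and an independent
evaluation set per replicate, fits every configured method and aggregates
the replicate records through :mod:`penregsim.evaluation`.

Seeds for each replicate are derived deterministically from the master
seed, the cell and the replicate id (via ``numpy.random.SeedSequence``
spawn keys), so any single replicate can be re-run in isolation and
replicate-level ordering never changes results.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import PenaltySpec, fit_ols, fit_penalized
from .evaluation import MetricsSummary, ReplicateRecord, summarize
from .scenarios import ScenarioSpec, generate_dataset, scenario
from .selection import stepwise_backward
from .tuning import tune

__all__ = ["StudyConfig", "run_study", "ALL_METHODS", "replicate_seeds", "records_to_frame"]

ALL_METHODS = ("OLS", "sAIC", "sBIC", "Ridge", "LASSO", "Enet1", "Enet2", "Enet3")
_TUNED = {"Ridge", "LASSO", "Enet1", "Enet2", "Enet3"}

log = logging.getLogger("penregsim")


@dataclass
class StudyConfig:
    """Configuration of one simulation study run."""

    scenarios: tuple = ("A", "B", "C")
    sample_sizes: tuple = (50, 110, 500)
    replicates: int = 500
    methods: tuple = ALL_METHODS
    K: int = 10
    master_seed: int = 0
    eval_size: int = 1000
    sigma_overrides: tuple | None = None  # optional sigma values (sensitivity runs)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def resolve_scenarios(self) -> list[ScenarioSpec]:
        out = []
        for s in self.scenarios:
            out.append(s if isinstance(s, ScenarioSpec) else scenario(str(s)))
        return out

    def to_dict(self) -> dict:
        return {
            "scenarios": [s.name if isinstance(s, ScenarioSpec) else s for s in self.scenarios],
            "sample_sizes": list(self.sample_sizes),
            "replicates": self.replicates,
            "methods": list(self.methods),
            "K": self.K,
            "master_seed": self.master_seed,
            "eval_size": self.eval_size,
            "sigma_overrides": list(self.sigma_overrides) if self.sigma_overrides else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(
            scenarios=tuple(d.get("scenarios", ("A", "B", "C"))),
            sample_sizes=tuple(d.get("sample_sizes", (50, 110, 500))),
            replicates=int(d.get("replicates", 500)),
            methods=tuple(d.get("methods", ALL_METHODS)),
            K=int(d.get("K", 10)),
            master_seed=int(d.get("master_seed", 0)),
            eval_size=int(d.get("eval_size", 1000)),
            sigma_overrides=tuple(d["sigma_overrides"]) if d.get("sigma_overrides") else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def replicate_seeds(master_seed: int, cell_key: tuple, replicate_id: int) -> tuple[int, int, int]:
    """Deterministic (data, folds, eval) seeds for one replicate of one cell.

    ``cell_key`` is (scenario_index, n).  Each seed is below 2^31 so it can
    be reused as a plain RNG seed anywhere.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(cell_key[0]), int(cell_key[1]), int(replicate_id))
    )
    s = ss.generate_state(3, dtype=np.uint32) >> 1  # keep below 2^31
    return int(s[0]), int(s[1]), int(s[2])


def _fit_method(method: str, ds, K: int, folds_seed: int):
    labels = ds.spec.labels
    if method == "OLS":
        return fit_ols(ds)
    if method == "sAIC":
        return stepwise_backward(ds, "aic")
    if method == "sBIC":
        return stepwise_backward(ds, "bic")
    tr = tune(method, ds, K=K, folds_seed=folds_seed)
    fr = fit_penalized(ds, tr.penalty)
    fr.method = method
    fr.labels = labels
    return fr


def _run_cell(spec: ScenarioSpec, n: int, cfg: StudyConfig, cell_key: tuple):
    spec_n = spec.with_n(n)
    records = {mth: [] for mth in cfg.methods}
    for rep in range(cfg.replicates):
        data_seed, folds_seed, eval_seed = replicate_seeds(cfg.master_seed, cell_key, rep)
        ds = generate_dataset(spec_n, data_seed)
        ev = generate_dataset(spec_n, eval_seed, n=cfg.eval_size)
        for method in cfg.methods:
            try:
                fr = _fit_method(method, ds, cfg.K, folds_seed)
            except Exception:
                log.exception(
                    "replicate %d of cell %s/%d failed for method %s",
                    rep, spec.name, n, method,
                )
                raise
            resid = ev.y - fr.predict(ev.X)
            records[method].append(
                ReplicateRecord(
                    replicate_id=rep,
                    method=method,
                    fit=fr,
                    test_error=float(resid @ resid) / cfg.eval_size,
                    insample_mse=fr.rss / ds.n,
                )
            )
    return records


def records_to_frame(records_by_method: dict, labels) -> pd.DataFrame:
    """Flatten replicate records to a wide frame (one row per replicate x method)."""
    rows = []
    for method, recs in records_by_method.items():
        for r in recs:
            row = {
                "replicate": r.replicate_id,
                "method": method,
                "intercept": r.fit.intercept,
                "rss": r.fit.rss,
                "test_error": r.test_error,
                "lambda1": r.fit.penalty.lambda1 if r.fit.penalty else np.nan,
                "lambda2": r.fit.penalty.lambda2 if r.fit.penalty else np.nan,
            }
            row.update({f"coef_{l}": b for l, b in zip(labels, r.fit.coefficients)})
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig, outdir=None) -> dict[tuple, MetricsSummary]:
    """Run every (scenario, n) cell of the study; optionally write outputs.

    Returns a mapping from (scenario name, n) to :class:`MetricsSummary`.
    With ``outdir`` set, per-cell replicate records, summary tables and a
    machine-readable run manifest are written as CSV/JSON.
    """
    results: dict[tuple, MetricsSummary] = {}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    specs = cfg.resolve_scenarios()
    for si, base_spec in enumerate(specs):
        sigmas = [None]
        if cfg.sigma_overrides and base_spec.name == "A":
            sigmas = [None, *cfg.sigma_overrides]
        for sigma in sigmas:
            spec = base_spec if sigma is None else base_spec.with_sigma(sigma)
            tag = spec.name if sigma is None else f"{spec.name}_sigma{sigma}"
            for n in cfg.sample_sizes:
                cell_key = (si, n)
                log.info("running cell scenario=%s n=%d m=%d", tag, n, cfg.replicates)
                try:
                    records = _run_cell(spec, n, cfg, cell_key)
                except Exception:
                    # abort only this cell; completed cells stay written
                    log.exception("cell scenario=%s n=%d aborted", tag, n)
                    continue
                summary = summarize(
                    records,
                    spec.with_n(n),
                    metadata={
                        "master_seed": cfg.master_seed,
                        "K": cfg.K,
                        "eval_size": cfg.eval_size,
                        "prediction_error": "independent evaluation set per replicate",
                    },
                )
                results[(tag, n)] = summary
                if outdir is not None:
                    stem = f"{tag}_n{n}"
                    records_to_frame(records, spec.labels).to_csv(
                        outdir / f"records_{stem}.csv", index=False
                    )
                    summary.per_method.to_csv(outdir / f"methods_{stem}.csv")
                    summary.tidy().to_csv(outdir / f"variables_{stem}.csv", index=False)
                    summary.wrong_sign_table().to_csv(outdir / f"wrong_sign_{stem}.csv")
    if outdir is not None:
        manifest = {
            "config": cfg.to_dict(),
            "package_version": __version__,
            "versions": _library_versions(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _library_versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
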
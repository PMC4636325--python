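"""Simulation scenarios and dataset generation.

Three built-in scenarios emulate the statistical structure of a clinical
insulin-sensitivity study in which the response (log-transformed insulin
sensitivity index) is regressed on correlated metabolic predictors:

* **A** — k = 20 predictors with high multicollinearity: grouped OGTT
  summaries (glucose, insulin, C-peptide, proinsulin, amylin; each with
  fasting, 120-minute and AUC values), age, anthropometry (BMI, waist, hip)
  and one orthogonal noise variable ``h``.  True effects are heterogeneous,
  sigma = 0.4, intercept 1.45.
* **B** — k = 9 serially correlated glucose-curve time points with small
  unidirectional effects (all beta = -0.025), sigma = 0.3, intercept 1.45.
* **C** — as B but with four of the nine coefficients (i.2, i.3, i.8, i.9)
  set to zero (correlated nuisance variables) and sigma = 0.15.

Predictors are standard normal with a correlation structure calibrated so
that each variable's variance inflation factor matches the scenario's
target; the response is linear-Gaussian.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .correlation import synthesize_correlation, validate_correlation, vif_from_correlation
from .exceptions import DegreesOfFreedomError

__all__ = [
    "ScenarioSpec",
    "Dataset",
    "scenario",
    "generate_dataset",
    "population_adjusted_r2",
    "SCENARIO_A_LABELS",
    "SCENARIO_A_BETA",
    "SCENARIO_A_VIF",
    "SCENARIO_A_GROUPS",
    "SCENARIO_B_LABELS",
    "SCENARIO_B_VIF",
]

SCENARIO_A_LABELS = (
    "a.1", "a.2", "a.3", "b.1", "b.2", "b.3", "c.1", "c.2", "c.3", "d.1",
    "d.2", "d.3", "e.1", "e.2", "e.3", "f.1", "g.1", "g.2", "g.3", "h",
)
SCENARIO_A_BETA = (
    0.03, -0.11, -0.09, 0.15, -0.12, -0.20, -0.27, 0.30, -0.12, 0.01,
    -0.02, 0.04, 0.04, -0.18, 0.15, 0.08, -0.03, -0.09, -0.06, 0.00,
)
SCENARIO_A_VIF = (
    2.57, 4.69, 4.87, 7.27, 18.9, 14.2, 10.9, 33.3, 27.0, 4.99,
    25.3, 32.1, 2.79, 8.70, 12.0, 1.40, 11.0, 6.24, 6.84, 1.00,
)
# Assay groups: within-group correlation is strong (same analyte measured at
# several points of the glucose tolerance test); h is orthogonal noise.
SCENARIO_A_GROUPS = (
    "a", "a", "a", "b", "b", "b", "c", "c", "c", "d",
    "d", "d", "e", "e", "e", "f", "g", "g", "g", "h",
)

SCENARIO_B_LABELS = ("i.1", "i.2", "i.3", "i.4", "i.5", "i.6", "i.7", "i.8", "i.9")
SCENARIO_B_VIF = (3.06, 3.94, 4.99, 6.57, 7.61, 7.06, 4.36, 4.51, 2.76)
_SCENARIO_C_ZERO = ("i.2", "i.3", "i.8", "i.9")

_INTERCEPT = 1.45


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative definition of one simulation scenario.

    Predictors are multivariate normal with zero mean, unit variance and
    the given correlation matrix; the response is
    ``y = intercept + X beta + N(0, sigma^2)``.
    """

    name: str
    beta: tuple
    intercept: float
    sigma: float
    correlation: np.ndarray
    labels: tuple
    n: int = 110
    noise_indices: tuple = field(default=None)

    def __post_init__(self):
        R = validate_correlation(self.correlation)
        object.__setattr__(self, "correlation", R)
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "beta", beta)
        if len(beta) != R.shape[0]:
            raise ValueError("beta length must equal correlation dimension")
        if len(self.labels) != len(beta):
            raise ValueError("labels length must equal beta length")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        derived = tuple(j for j, b in enumerate(beta) if b == 0.0)
        if self.noise_indices is None:
            object.__setattr__(self, "noise_indices", derived)
        else:
            ni = tuple(sorted(int(j) for j in self.noise_indices))
            if ni != derived:
                raise ValueError(
                    "noise_indices must be exactly the positions where beta is zero"
                )
            object.__setattr__(self, "noise_indices", ni)

    @property
    def k(self) -> int:
        return len(self.beta)

    def with_n(self, n: int) -> "ScenarioSpec":
        return replace(self, n=int(n))

    def with_sigma(self, sigma: float) -> "ScenarioSpec":
        return replace(self, sigma=float(sigma))

    @property
    def vifs(self) -> np.ndarray:
        return vif_from_correlation(self.correlation)

    def signal_variance(self) -> float:
        """Population variance of the linear predictor, beta' Sigma beta."""
        b = np.asarray(self.beta)
        return float(b @ self.correlation @ b)

    def population_r2(self) -> float:
        """Population R^2 = signal variance / (signal variance + sigma^2)."""
        s = self.signal_variance()
        return s / (s + self.sigma**2)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": list(self.labels),
            "beta": list(self.beta),
            "intercept": self.intercept,
            "sigma": self.sigma,
            "n": self.n,
            "correlation": [[float(v) for v in row] for row in self.correlation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            beta=tuple(d["beta"]),
            intercept=float(d.get("intercept", _INTERCEPT)),
            sigma=float(d["sigma"]),
            correlation=np.asarray(d["correlation"], dtype=float),
            labels=tuple(d["labels"]),
            n=int(d.get("n", 110)),
        )

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def correlation_csv(self) -> str:
        """Correlation matrix as CSV with a header row of variable labels."""
        df = pd.DataFrame(self.correlation, columns=self.labels)
        return df.to_csv(index=False)


@dataclass(frozen=True)
class Dataset:
    """One simulated design matrix and response.

    Regenerating with the same spec and seed reproduces X and y
    bit-identically.
    """

    X: np.ndarray
    y: np.ndarray
    spec: ScenarioSpec
    seed: int

    def __post_init__(self):
        if self.X.shape != (len(self.y), self.spec.k):
            raise ValueError("X shape inconsistent with spec and y")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.spec.labels)
        df["y"] = self.y
        return df

    def to_csv(self, path=None):
        df = self.to_frame()
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)


@functools.lru_cache(maxsize=None)
def _builtin_correlation(name: str) -> np.ndarray:
    if name == "A":
        R = synthesize_correlation(
            SCENARIO_A_VIF, "grouped-block", tolerance=0.5, seed=0, groups=SCENARIO_A_GROUPS
        )
    else:  # B and C share the glucose-curve structure
        R = synthesize_correlation(SCENARIO_B_VIF, "banded-serial", tolerance=0.5, seed=0)
    R.setflags(write=False)
    return R


def scenario(name: str, n: int = 110, sigma: float | None = None) -> ScenarioSpec:
    """Return a built-in scenario spec (``"A"``, ``"B"`` or ``"C"``).

    ``sigma`` overrides the scenario's default error SD (used for the
    scenario-A sensitivity runs with sigma in {0.2, 0.6, 0.8}).
    """
    name = name.upper()
    if name == "A":
        spec = ScenarioSpec(
            name="A",
            beta=SCENARIO_A_BETA,
            intercept=_INTERCEPT,
            sigma=0.4,
            correlation=np.array(_builtin_correlation("A")),
            labels=SCENARIO_A_LABELS,
            n=n,
        )
    elif name == "B":
        spec = ScenarioSpec(
            name="B",
            beta=(-0.025,) * 9,
            intercept=_INTERCEPT,
            sigma=0.3,
            correlation=np.array(_builtin_correlation("B")),
            labels=SCENARIO_B_LABELS,
            n=n,
        )
    elif name == "C":
        beta = tuple(
            0.0 if lab in _SCENARIO_C_ZERO else -0.025 for lab in SCENARIO_B_LABELS
        )
        spec = ScenarioSpec(
            name="C",
            beta=beta,
            intercept=_INTERCEPT,
            sigma=0.15,
            correlation=np.array(_builtin_correlation("B")),
            labels=SCENARIO_B_LABELS,
            n=n,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; expected A, B or C")
    if sigma is not None:
        spec = spec.with_sigma(sigma)
    return spec


def generate_dataset(spec: ScenarioSpec, seed: int, n: int | None = None) -> Dataset:
    """Draw one dataset from a scenario.

    X is multivariate normal (zero mean, unit variances, correlation
    ``spec.correlation``) sampled via the Cholesky factor; the response is
    ``y = intercept + X beta + eps`` with ``eps ~ N(0, sigma^2)``.
    Deterministic given ``seed``.
    """
    n = spec.n if n is None else int(n)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(spec.correlation)
    X = rng.standard_normal((n, spec.k)) @ L.T
    eps = rng.standard_normal(n) * spec.sigma
    y = spec.intercept + X @ np.asarray(spec.beta) + eps
    return Dataset(X=X, y=y, spec=spec, seed=int(seed))


def population_adjusted_r2(
    spec: ScenarioSpec, n: int | None = None, replicates: int = 200, seed: int = 0
) -> float:
    """Monte-Carlo mean of the OLS adjusted R^2 over fresh replicates.

    Characterizes a scenario's explained variation at a given sample size:
    ``adj R^2 = 1 - (RSS / (n - k - 1)) / (TSS / (n - 1))`` averaged over
    ``replicates`` independently generated datasets.
    """
    n = spec.n if n is None else int(n)
    k = spec.k
    if n <= k + 1:
        raise DegreesOfFreedomError(f"need n > k + 1 = {k + 1}, got n = {n}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(9001,))
    seeds = ss.generate_state(replicates)
    vals = np.empty(replicates)
    for i, s in enumerate(seeds):
        ds = generate_dataset(spec, int(s), n=n)
        Xc = ds.X - ds.X.mean(axis=0)
        yc = ds.y - ds.y.mean()
        coef, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        rss = float(np.sum((yc - Xc @ coef) ** 2))
        tss = float(yc @ yc)
        vals[i] = 1.0 - (rss / (n - k - 1)) / (tss / (n - 1))
    return float(vals.mean())
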
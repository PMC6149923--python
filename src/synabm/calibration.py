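"""Two-stage parameter estimation against dose-inhibition data.

Stage one fits the linear dose-mortality coefficients
``theta = (theta0, theta1, theta2)`` to the measured inhibition
fractions by gradient descent on the half-mean-squared-error loss
``J(theta) = 1/(2m) sum (Mcrate_j - Merate_j)^2``; the converged fit is
required to agree with the closed-form least-squares solution.  Stage
two runs a global-best particle swarm over ``(c1, c2, lambda)``,
scoring each candidate by the weighted squared gap between the
simulator's replicate-averaged endpoint mortality and the experimental
inhibition, with per-pair weights ``(1 / max Merate)^2``.

Triplicate inhibition measurements are stabilized by a bootstrap mean
before fitting.  Validation reports the held-out relative error
``RE = (Msrate - Merate) / Merate`` and a paired two-sample test
between simulated and experimental series.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseTable", "LocalFit", "GlobalFit", "CVResult",
    "CollinearDesignError", "bootstrap_mean", "merate_from_absorbance",
    "fit_local", "particle_swarm", "eq16_weight", "fit_global",
    "crossvalidate", "significance_test",
]


class CollinearDesignError(ValueError):
    """The dose design does not identify all three coefficients."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

class DoseResponseTable:
    """Dose combinations with replicate inhibition fractions for one pair.

    Wraps a DataFrame with columns ``pair, dose1_uM, dose2_uM, rep1..repK``.
    Inhibition is stored as fractions in [0, 1]; CSV input whose values
    exceed 1.5 is taken to be in percent and normalized on read.
    """

    def __init__(self, frame: pd.DataFrame, label: str | None = None,
                 truth: dict | None = None) -> None:
        required = {"dose1_uM", "dose2_uM"}
        if not required.issubset(frame.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        self.rep_cols = [c for c in frame.columns if c.startswith("rep")]
        if not self.rep_cols:
            raise ValueError("table needs at least one repN column")
        frame = frame.reset_index(drop=True)
        if label is None:
            label = str(frame["pair"].iloc[0]) if "pair" in frame else "pair"
        self.label = label
        self.frame = frame
        #: generator ground truth, when the table is synthetic
        self.truth = truth or {}
        self._validate()

    def _validate(self) -> None:
        if (self.doses < 0).any():
            raise ValueError("doses must be >= 0")
        reps = self.replicates
        if np.any(reps < 0) or np.any(reps > 1):
            raise ValueError("inhibition fractions must lie in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.frame)

    @property
    def doses(self) -> np.ndarray:
        """(m, 2) array of dose1, dose2 in uM."""
        return self.frame[["dose1_uM", "dose2_uM"]].to_numpy(float)

    @property
    def replicates(self) -> np.ndarray:
        """(m, K) array of replicate inhibition fractions."""
        return self.frame[self.rep_cols].to_numpy(float)

    def replicate_means(self) -> np.ndarray:
        return self.replicates.mean(axis=1)

    def bootstrap_means(self, B: int = 1000, seed: int | None = None) -> np.ndarray:
        """Row-wise bootstrap means (the ``Merate`` used for fitting)."""
        rng = np.random.default_rng(seed)
        return np.array([bootstrap_mean(row, B=B, rng=rng)
                         for row in self.replicates])

    def subset(self, index: Sequence[int]) -> "DoseResponseTable":
        return DoseResponseTable(self.frame.iloc[list(index)], self.label,
                                 truth=self.truth)

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        out = self.frame.copy()
        if "pair" not in out:
            out.insert(0, "pair", self.label)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase,
                 label: str | None = None) -> "DoseResponseTable":
        frame = pd.read_csv(path)
        rep_cols = [c for c in frame.columns if c.startswith("rep")]
        if rep_cols and np.nanmax(frame[rep_cols].to_numpy(float)) > 1.5:
            # values look like percentages; store as fractions
            frame[rep_cols] = frame[rep_cols] / 100.0
        return cls(frame, label)

    @classmethod
    def read_pairs(cls, path: str | Path) -> Dict[str, "DoseResponseTable"]:
        """Read a multi-pair CSV, splitting on the ``pair`` column."""
        frame = pd.read_csv(path)
        if "pair" not in frame:
            return {"pair": cls.from_csv(path)}
        out = {}
        for label, sub in frame.groupby("pair", sort=False):
            rep_cols = [c for c in sub.columns if c.startswith("rep")]
            sub = sub.copy()
            if np.nanmax(sub[rep_cols].to_numpy(float)) > 1.5:
                sub[rep_cols] = sub[rep_cols] / 100.0
            out[str(label)] = cls(sub, str(label))
        return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bootstrap_mean(samples: Sequence[float], B: int = 1000,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> float:
    """Mean of ``B`` bootstrap resample means (resampling with
    replacement at the original sample size)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    return float(x[idx].mean(axis=1).mean())


def merate_from_absorbance(avg_drug: float, avg_control: float) -> float:
    """Experimental mortality ``Merate = 1 - Avg_drug / CAvg_drug``.

    Stored as a fraction; reports render it as a percentage.
    """
    if avg_control <= 0:
        raise ValueError("control absorbance must be > 0")
    if avg_drug < 0:
        raise ValueError("drug-group absorbance must be >= 0")
    return 1.0 - avg_drug / avg_control


# ---------------------------------------------------------------------------
# stage one: local gradient-descent fit of theta
# ---------------------------------------------------------------------------

@dataclass
class LocalFit:
    theta: np.ndarray
    loss: float
    p_value: float
    n_iter: int
    converged: bool

    def mcrate(self, dose1, dose2):
        """Unclamped linear prediction at the given doses."""
        t0, t1, t2 = self.theta
        return t0 + t1 * np.asarray(dose1) + t2 * np.asarray(dose2)


def _loss(X: np.ndarray, y: np.ndarray, theta: np.ndarray) -> float:
    r = X @ theta - y
    return float(r @ r / (2 * len(y)))


def fit_local(table: DoseResponseTable, merate: np.ndarray | None = None,
              init_theta: Sequence[float] = (0.0, 0.0, 0.0),
              learning_rate: float | None = None, max_iter: int = 50_000,
              tol: float = 1e-12) -> LocalFit:
    """Gradient descent on ``J(theta)``; must land on the least-squares
    optimum.

    The dose columns are standardized internally (the raw design with
    doses up to 100 uM is badly conditioned for plain gradient descent);
    the returned coefficients are on the original uM scale.  The
    p-value is the overall regression F-test of the fitted model.

    Raises :class:`CollinearDesignError` when the design matrix is rank
    deficient — e.g. a table whose doses are all zero identifies only
    the intercept.
    """
    if table.m < 3:
        raise ValueError("need at least 3 dose combinations")
    y = table.replicate_means() if merate is None else np.asarray(merate, float)
    d = table.doses
    X = np.column_stack([np.ones(table.m), d])
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearDesignError(
            "dose design is collinear; theta1/theta2 are not identifiable "
            f"(intercept-only mean Merate = {y.mean():.4f})")

    # standardize the dose columns for conditioning
    mu, sd = d.mean(axis=0), d.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(table.m), (d - mu) / sd])
    A = Xs.T @ Xs / table.m
    b = Xs.T @ y / table.m
    if learning_rate is None:
        learning_rate = 1.0 / float(np.linalg.eigvalsh(A).max())

    # map the initial guess into the standardized basis
    th0 = np.asarray(init_theta, dtype=float).copy()
    ths = np.array([th0[0] + th0[1] * mu[0] + th0[2] * mu[1],
                    th0[1] * sd[0], th0[2] * sd[1]])
    converged = False
    n_iter = max_iter
    for it in range(max_iter):
        grad = A @ ths - b
        ths -= learning_rate * grad
        if it % 50 == 0 and float(grad @ grad) < tol ** 2:
            converged, n_iter = True, it + 1
            break
    if not converged:
        warnings.warn("gradient descent did not converge; returning the "
                      "best iterate", RuntimeWarning, stacklevel=2)

    theta = np.array([ths[0] - ths[1] * mu[0] / sd[0] - ths[2] * mu[1] / sd[1],
                      ths[1] / sd[0], ths[2] / sd[1]])
    loss = _loss(X, y, theta)

    resid = X @ theta - y
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = 2, table.m - 3
    if sse <= 0 or df_resid <= 0:
        p_value = 0.0 if sst > 0 else 1.0
    else:
        F = ((sst - sse) / df_model) / (sse / df_resid)
        p_value = float(stats.f.sf(F, df_model, df_resid))
    return LocalFit(theta=theta, loss=loss, p_value=p_value,
                    n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# stage two: global-best particle swarm over (c1, c2, lambda)
# ---------------------------------------------------------------------------

@dataclass
class GlobalFit:
    c1: float
    c2: float
    lam: float
    objective: float
    history: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def theta_vector(self) -> Tuple[float, float, float]:
        return (self.c1, self.c2, self.lam)


def particle_swarm(objective: Callable[[np.ndarray], float],
                   bounds: Sequence[Tuple[float, float]],
                   swarm_size: int = 15, iters: int = 60,
                   seed: int | None = None, w: float = 0.72,
                   c_cog: float = 1.49, c_soc: float = 1.49,
                   vmax_frac: float = 0.2) -> Tuple[np.ndarray, float, np.ndarray]:
    """Global-best PSO: inertia ``w`` plus cognitive and social pulls.

    Velocities are clamped to ``vmax_frac`` of each bound's range and
    positions are clipped to the bounds.  Returns the best position,
    its objective, and the per-iteration global-best history (which is
    non-increasing by construction).
    """
    if not bounds:
        raise ValueError("bounds must be non-empty")
    if swarm_size < 1 or iters < 0:
        raise ValueError("swarm_size must be >= 1 and iters >= 0")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy lo < hi")
    ndim = len(bounds)
    vmax = vmax_frac * (hi - lo)

    x = rng.uniform(lo, hi, size=(swarm_size, ndim))
    v = rng.uniform(-vmax, vmax, size=(swarm_size, ndim))
    f = np.array([objective(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(iters):
        r1 = rng.random((swarm_size, ndim))
        r2 = rng.random((swarm_size, ndim))
        v = (w * v + c_cog * r1 * (pbest_x - x)
             + c_soc * r2 * (gbest_x - x))
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = np.array([objective(xi) for xi in x])
        better = f < pbest_f
        pbest_x[better], pbest_f[better] = x[better], f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        history.append(gbest_f)
    return gbest_x, gbest_f, np.asarray(history)


def eq16_weight(merate: np.ndarray) -> float:
    """Per-pair weight ``(1 / max Merate)^2`` of the global objective."""
    mx = float(np.max(merate))
    if mx <= 0:
        raise ValueError("pair has no positive Merate; weight undefined")
    return (1.0 / mx) ** 2


#: default search box: c1, c2 in [0, 1]; lambda in [0, 2] per hour
DEFAULT_BOUNDS: Tuple[Tuple[float, float], ...] = ((0.0, 1.0), (0.0, 1.0),
                                                   (0.0, 2.0))

Simulator = Callable[[float, float, float, float, float], float]


def build_global_objective(tables: Mapping[str, DoseResponseTable] | DoseResponseTable,
                           simulators: Mapping[str, Simulator] | Simulator,
                           merates: Mapping[str, np.ndarray] | None = None,
                           floor_at_zero: bool = True,
                           ) -> Callable[[np.ndarray], float]:
    """Weighted squared-error objective over one or more drug pairs.

    ``simulators`` maps each pair label to a replicate-averaged
    endpoint-Msrate callable ``f(c1, c2, lam, d1, d2)`` with that
    pair's theta and half-lives already bound.

    Msrate is negative under net population growth, while the measured
    inhibition it is compared against is floored at zero; by default
    simulated values are floored the same way so growth regimes score
    as zero inhibition rather than as huge spurious residuals.
    """
    if isinstance(tables, DoseResponseTable):
        tables = {tables.label: tables}
    if callable(simulators):
        simulators = {label: simulators for label in tables}
    prepared = []
    for label, table in tables.items():
        y = (merates[label] if merates is not None
             else table.replicate_means())
        prepared.append((simulators[label], table.doses, np.asarray(y, float),
                         eq16_weight(y)))

    def objective(params: np.ndarray) -> float:
        c1, c2, lam = (float(p) for p in params)
        total = 0.0
        for sim, doses, y, weight in prepared:
            for (d1, d2), target in zip(doses, y):
                ms = sim(c1, c2, lam, d1, d2)
                if floor_at_zero and ms < 0.0:
                    ms = 0.0
                total += weight * (ms - target) ** 2
        return total

    return objective


def fit_global(tables: Mapping[str, DoseResponseTable] | DoseResponseTable,
               simulators: Mapping[str, Simulator] | Simulator,
               merates: Mapping[str, np.ndarray] | None = None,
               bounds: Sequence[Tuple[float, float]] = DEFAULT_BOUNDS,
               swarm_size: int = 10, iters: int = 20,
               seed: int | None = None, **pso_kwargs) -> GlobalFit:
    """Particle-swarm estimate of ``(c1, c2, lambda)`` (Loewe stage two)."""
    objective = build_global_objective(tables, simulators, merates)
    best, best_f, history = particle_swarm(
        objective, bounds, swarm_size=swarm_size, iters=iters, seed=seed,
        **pso_kwargs)
    return GlobalFit(c1=float(best[0]), c2=float(best[1]),
                     lam=float(best[2]), objective=best_f,
                     history=history, seed=seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    label: str
    relative_errors: np.ndarray
    mean_abs_re: float
    n_excluded: int
    train_index: List[int]
    test_index: List[int]


def _thirds_split(m: int) -> Tuple[List[int], List[int]]:
    """Every third row trains (spanning the dose range); the rest test."""
    train = list(range(0, m, 3))
    test = [i for i in range(m) if i not in train]
    return train, test


def crossvalidate(tables: Mapping[str, DoseResponseTable] | Sequence[DoseResponseTable],
                  fit: Callable[[DoseResponseTable], object],
                  predict: Callable[[object, float, float], float],
                  protocol: str = "thirds",
                  merate_fn: Callable[[DoseResponseTable], np.ndarray] | None = None,
                  ) -> Dict[str, CVResult]:
    """Held-out relative error per pair.

    ``protocol="thirds"`` (default) trains on one third of each pair's
    rows and tests on the remaining two thirds; ``protocol="loocv"``
    leaves one row out at a time.  ``fit`` maps a training table to a
    model; ``predict`` maps (model, dose1, dose2) to a simulated
    mortality.  Test rows with ``Merate = 0`` are excluded (the
    relative error is undefined there) with a warning.
    """
    if not isinstance(tables, Mapping):
        tables = {t.label: t for t in tables}
    if merate_fn is None:
        merate_fn = lambda t: t.replicate_means()
    results: Dict[str, CVResult] = {}
    for label, table in tables.items():
        y = np.asarray(merate_fn(table), float)
        if protocol == "thirds":
            train_idx, test_idx = _thirds_split(table.m)
            model = fit(table.subset(train_idx))
            pairs = [(model, i) for i in test_idx]
        elif protocol == "loocv":
            train_idx, test_idx = [], list(range(table.m))
            pairs = []
            for i in test_idx:
                rest = [j for j in range(table.m) if j != i]
                pairs.append((fit(table.subset(rest)), i))
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        res, excluded = [], 0
        doses = table.doses
        for model, i in pairs:
            if y[i] == 0:
                warnings.warn(f"{label}: held-out row {i} has Merate = 0; "
                              "excluded from RE", RuntimeWarning, stacklevel=2)
                excluded += 1
                continue
            ms = predict(model, doses[i, 0], doses[i, 1])
            res.append((ms - y[i]) / y[i])
        res = np.asarray(res)
        results[label] = CVResult(
            label=label, relative_errors=res,
            mean_abs_re=float(np.mean(np.abs(res))) if res.size else float("nan"),
            n_excluded=excluded, train_index=train_idx, test_index=test_idx)
    return results


def significance_test(simulated: Sequence[float],
                      experimental: Sequence[float],
                      method: str = "wilcoxon") -> float:
    """Two-sided paired test between simulated and experimental series.

    Wilcoxon signed-rank by default (paired t-test with
    ``method="ttest"``); a p-value above 0.1 is read as no significant
    difference between simulation and experiment.
    """
    sim = np.asarray(simulated, float)
    exp = np.asarray(experimental, float)
    if sim.shape != exp.shape:
        raise ValueError("series must have equal length")
    diff = sim - exp
    if method == "wilcoxon":
        if np.all(diff == 0):
            return 1.0
        return float(stats.wilcoxon(sim, exp).pvalue)
    if method == "ttest":
        if np.all(diff == 0):
            return 1.0
        return float(stats.ttest_rel(sim, exp).pvalue)
    raise ValueError(f"unknown method {method!r}")
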
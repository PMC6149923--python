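"""Loewe-additivity combination index: iso-dose search and classification.

The combination index of a dose pair ``(d1, d2)`` producing the target
effect (by default 50% simulated mortality) is

    CI = d1 / D_X,1 + d2 / D_X,2

where ``D_X,i`` is the single-agent dose of drug i producing the same
effect.  CI near 1 means the combination behaves like a drug combined
with itself (Loewe additivity); below 1, less total drug was needed
(synergy); above 1, more (antagonism).  Categories follow the
thresholds: antagonism at CI >= 1.1, additive in [0.9, 1.1), synergism
in [0.3, 0.9), strong synergism below 0.3.

Effect curves coming from the stochastic simulator are replicate
averages and need not be monotone draw by draw; before inversion they
are smoothed by isotonic regression over a dose grid, which guards the
root search against Monte-Carlo wiggles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "IsoDoseError", "SynergyCall", "find_iso_dose", "combination_index",
    "classify_ci", "synergy_report",
]

EffectFn = Callable[[float], float]
EffectFn2D = Callable[[float, float], float]

CATEGORIES = ("antagonism", "additive", "synergism", "strong synergism")


class IsoDoseError(ValueError):
    """The target effect is not bracketed by the dose bounds."""

    def __init__(self, msg: str, effect_range: Tuple[float, float] | None = None):
        super().__init__(msg)
        self.effect_range = effect_range


@dataclass
class SynergyCall:
    """One row of a synergy report: a ratio's iso-effective combination."""

    drug1: str
    drug2: str
    ratio: str
    d1_uM: float
    d2_uM: float
    Dx1_uM: float
    Dx2_uM: float
    CI: float
    category: str


def _smoothed_inverse(effect_fn: EffectFn, target: float,
                      dose_bounds: Tuple[float, float],
                      n_grid: int) -> float:
    """Invert a noisy effect curve: grid-evaluate, isotonic-smooth,
    interpolate the target crossing."""
    lo, hi = dose_bounds
    grid = np.linspace(lo, hi, n_grid)
    raw = np.array([effect_fn(float(d)) for d in grid])
    smooth = IsotonicRegression(increasing=True).fit_transform(grid, raw)
    if target < smooth[0] or target > smooth[-1]:
        raise IsoDoseError(
            f"target effect {target:.3f} outside achieved range "
            f"[{smooth[0]:.3f}, {smooth[-1]:.3f}] on bounds {dose_bounds}",
            effect_range=(float(smooth[0]), float(smooth[-1])))
    return float(np.interp(target, smooth, grid))


def find_iso_dose(effect_fn: EffectFn, X: float = 50.0,
                  dose_bounds: Tuple[float, float] = (0.0, 100.0),
                  tol: float = 0.01, smooth: bool = False,
                  n_grid: int = 12) -> float:
    """Single-agent dose ``D_X`` at which the effect reaches ``X`` percent.

    For a deterministic, monotone ``effect_fn`` (mapping dose in uM to
    an effect fraction) the crossing is bracketed and found by
    bisection to ``|effect - X/100| <= tol``.  With ``smooth=True`` —
    for replicate-averaged stochastic curves — the curve is first
    isotonic-regressed on an ``n_grid``-point dose grid and the target
    is found on the smoothed interpolant.
    """
    if not 0 < X < 100:
        raise ValueError("X must be in (0, 100) percent")
    lo, hi = dose_bounds
    if not 0 <= lo < hi:
        raise ValueError("dose bounds must satisfy 0 <= lo < hi")
    target = X / 100.0
    if smooth:
        return _smoothed_inverse(effect_fn, target, dose_bounds, n_grid)
    f_lo, f_hi = effect_fn(lo), effect_fn(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        raise IsoDoseError(
            f"target effect {target:.3f} not bracketed: effect spans "
            f"[{f_lo:.3f}, {f_hi:.3f}] on bounds {dose_bounds}",
            effect_range=(f_lo, f_hi))
    dose = brentq(lambda d: effect_fn(d) - target, lo, hi, xtol=1e-9)
    achieved = effect_fn(dose)
    if abs(achieved - target) > tol:
        raise IsoDoseError(
            f"bisection landed at effect {achieved:.3f}, off target by "
            f"more than tol={tol}", effect_range=(f_lo, f_hi))
    return float(dose)


def combination_index(d1: float, d2: float, Dx1: float, Dx2: float) -> float:
    """Loewe combination index ``d1/D_X,1 + d2/D_X,2``."""
    if Dx1 <= 0 or Dx2 <= 0:
        raise ValueError("iso-effective doses must be > 0")
    if d1 < 0 or d2 < 0:
        raise ValueError("combination doses must be >= 0")
    return d1 / Dx1 + d2 / Dx2


def classify_ci(ci: float) -> str:
    """Map a CI value to its interaction category.

    ``ci >= 1.1`` antagonism; ``[0.9, 1.1)`` additive; ``[0.3, 0.9)``
    synergism; ``[0, 0.3)`` strong synergism.  The published interval
    bounds leave exactly 0.9 unassigned; it is placed with the additive
    band so the partition has no gap.
    """
    if ci < 0:
        raise ValueError("CI must be >= 0")
    if ci >= 1.1:
        return "antagonism"
    if ci >= 0.9:
        return "additive"
    if ci >= 0.3:
        return "synergism"
    return "strong synergism"


def _parse_ratio(ratio: str | Tuple[float, float]) -> Tuple[float, float, str]:
    if isinstance(ratio, str):
        a_s, b_s = ratio.split(":")
        a, b = float(a_s), float(b_s)
        label = ratio
    else:
        a, b = ratio
        label = f"{a:g}:{b:g}"
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError(f"invalid ratio {label}")
    return a, b, label


def synergy_report(effect_fn: EffectFn2D, drug_names: Tuple[str, str],
                   ratios: Sequence[str | Tuple[float, float]],
                   X: float = 50.0,
                   dose_bounds: Tuple[float, float] = (0.0, 100.0),
                   tol: float = 0.01, smooth: bool = False,
                   n_grid: int = 12) -> pd.DataFrame:
    """Combination-index table for a drug pair across mixing ratios.

    ``effect_fn(d1, d2)`` maps a dose pair (uM) to a mortality
    fraction.  For each ratio ``a:b`` the total dose ``s`` with
    ``effect(s*a/(a+b), s*b/(a+b)) = X%`` is located on the line of
    constant ratio, and its CI is computed against the two single-agent
    iso-doses.  Ratios on which the target effect is unreachable within
    the dose bounds are flagged (``category="unreachable"``, NaN CI)
    rather than dropped, so the report always has one row per ratio.
    """
    d1name, d2name = drug_names
    Dx1 = find_iso_dose(lambda d: effect_fn(d, 0.0), X, dose_bounds, tol,
                        smooth=smooth, n_grid=n_grid)
    Dx2 = find_iso_dose(lambda d: effect_fn(0.0, d), X, dose_bounds, tol,
                        smooth=smooth, n_grid=n_grid)
    rows: List[SynergyCall] = []
    for ratio in ratios:
        a, b, label = _parse_ratio(ratio)
        fa, fb = a / (a + b), b / (a + b)
        try:
            s = find_iso_dose(lambda t: effect_fn(fa * t, fb * t), X,
                              dose_bounds, tol, smooth=smooth, n_grid=n_grid)
        except IsoDoseError:
            rows.append(SynergyCall(d1name, d2name, label, math.nan,
                                    math.nan, Dx1, Dx2, math.nan,
                                    "unreachable"))
            continue
        d1, d2 = fa * s, fb * s
        ci = combination_index(d1, d2, Dx1, Dx2)
        rows.append(SynergyCall(d1name, d2name, label, d1, d2, Dx1, Dx2,
                                ci, classify_ci(ci)))
    return pd.DataFrame([r.__dict__ for r in rows])
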
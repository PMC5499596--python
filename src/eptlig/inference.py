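"""Rate-constant estimation from time-course data.

The estimators mirror the lab workflow: band intensities from a denaturing
gel give the remaining-acceptor fraction C/C0 at each time point; ln(C/C0)
is regressed on time through the origin (C/C0 = 1 at t = 0 by
normalization), and the apparent first-order constant k_app is the negated
slope. The default analysis window keeps the initial-velocity regime
(product <= 50%) because real ligation curves plateau below 100%, and
fitting the plateau as first order would bias k_app downward. The same
estimator applied to active-electrophile decay yields hydrolytic
half-lives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, UndefinedYieldError
from .kinetics import TimeCourse

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FitResult:
    """A first-order rate estimate with diagnostics.

    half_life is ln2/k_app (infinite when k_app = 0); r_squared is the
    coefficient of determination of the through-origin log-linear fit.
    """

    k_app: float
    stderr: float
    half_life: float
    r_squared: float
    n_points_used: int
    window: tuple[float, float]
    free_intercept: bool = False
    intercept: float = 0.0

    @property
    def half_life_hours(self) -> float:
        return self.half_life / 60.0

    def __str__(self) -> str:
        return (
            f"k_app = {self.k_app:.4g} min^-1 (se {self.stderr:.2g}), "
            f"t1/2 = {self.half_life:.4g} min, R^2 = {self.r_squared:.4f}, "
            f"n = {self.n_points_used}"
        )


def _log_linear_fit(t: np.ndarray, frac: np.ndarray, window, free_intercept: bool) -> FitResult:
    usable = frac > 0
    dropped = int(np.sum(~usable))
    if dropped:
        warnings.warn(f"excluded {dropped} point(s) with fraction <= 0 from log fit")
    t, frac = t[usable], frac[usable]
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, frac = t[keep], frac[keep]
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 usable points, got {len(t)}")
    if np.all(frac >= 1.0):
        return FitResult(
            k_app=0.0,
            stderr=0.0,
            half_life=np.inf,
            r_squared=1.0,
            n_points_used=len(t),
            window=(float(t.min()), float(t.max())),
            free_intercept=free_intercept,
        )
    y = np.log(frac)
    if free_intercept:
        X = np.column_stack([t, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        slope, intercept = coef
        resid = y - X @ coef
        dof = max(len(t) - 2, 1)
        # variance of the slope from the normal equations
        cov = np.linalg.inv(X.T @ X) * (resid @ resid / dof)
        se = math.sqrt(cov[0, 0])
    else:
        intercept = 0.0
        sxx = float(t @ t)
        if sxx == 0:
            raise InsufficientDataError("all points at t = 0; rate not identifiable")
        slope = float(t @ y) / sxx
        resid = y - slope * t
        dof = max(len(t) - 1, 1)
        se = math.sqrt(float(resid @ resid) / dof / sxx)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    k = max(-float(slope), 0.0)
    return FitResult(
        k_app=k,
        stderr=se,
        half_life=np.inf if k == 0 else LN2 / k,
        r_squared=r2,
        n_points_used=len(t),
        window=(float(t.min()), float(t.max())),
        free_intercept=free_intercept,
        intercept=float(intercept),
    )


def fit_first_order(
    tc: TimeCourse,
    window: tuple[float, float] | None = None,
    free_intercept: bool = False,
) -> FitResult:
    """Estimate k_app from a ligation time course.

    Regresses ln(C/C0) on t through the origin. ``window`` restricts the
    fit to an explicit (t_min, t_max); by default the initial-velocity
    window is used - points where the product fraction is at most 0.5.
    Points with C/C0 <= 0 are excluded with a warning.
    """
    if tc.frac_amino_remaining is None:
        raise DomainError("time course has no frac_amino_remaining data")
    t = tc.times
    frac = tc.frac_amino_remaining
    if len(t) == 0 or t[0] != 0:
        raise DomainError("time course must include the t = 0 point")
    if window is None:
        product = tc.frac_product if tc.frac_product is not None else 1.0 - frac
        in_regime = product <= 0.5
        if in_regime.sum() >= 3:
            window = (0.0, float(t[in_regime].max()))
    return _log_linear_fit(t, frac, window, free_intercept)


def fit_half_life(tc: TimeCourse, window=None, free_intercept: bool = False) -> FitResult:
    """Estimate a decay half-life from the active-electrophile trace.

    Same log-linear estimator as :func:`fit_first_order` applied to
    frac_ept_active; the whole curve is used by default (a pure decay has
    no plateau). Returns half-life in minutes (``half_life_hours`` for
    hours).
    """
    if tc.frac_ept_active is None:
        raise DomainError("time course has no frac_ept_active data")
    return _log_linear_fit(tc.times, tc.frac_ept_active, window, free_intercept)


def yield_from_intensities(i_remaining: float, i_product: float) -> float:
    """Ligation yield from gel band intensities.

    yield = i_product / (i_remaining + i_product): the product band as a
    fraction of total fluorescence in the lane.
    """
    if i_remaining < 0 or i_product < 0:
        raise DomainError("band intensities must be non-negative")
    total = i_remaining + i_product
    if total == 0:
        raise UndefinedYieldError("both band intensities are zero; yield undefined")
    return i_product / total


def compare_rates(fits: list[FitResult], labels: list[str] | None = None) -> pd.DataFrame:
    """Pairwise rate ratios with propagated standard errors.

    Returns a long-form table with one row per ordered pair (numerator,
    denominator); se(ratio) = ratio * sqrt((se_a/k_a)^2 + (se_b/k_b)^2).
    Pairs with a zero-rate denominator are flagged ``undefined``.
    """
    if len(fits) < 2:
        raise InsufficientDataError("need at least two fits to compare")
    if labels is None:
        labels = [f"fit{i}" for i in range(len(fits))]
    if len(labels) != len(fits):
        raise DomainError("labels must match fits in length")
    rows = []
    for (i, fa), (j, fb) in permutations(list(enumerate(fits)), 2):
        if fb.k_app == 0:
            rows.append(
                {"numerator": labels[i], "denominator": labels[j], "ratio": np.nan,
                 "stderr": np.nan, "undefined": True}
            )
            continue
        ratio = fa.k_app / fb.k_app
        rel = 0.0
        if fa.k_app > 0:
            rel = (fa.stderr / fa.k_app) ** 2 + (fb.stderr / fb.k_app) ** 2
        rows.append(
            {"numerator": labels[i], "denominator": labels[j], "ratio": ratio,
             "stderr": ratio * math.sqrt(rel), "undefined": False}
        )
    return pd.DataFrame(rows)
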
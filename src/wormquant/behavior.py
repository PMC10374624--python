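"""Behavioral indices, speed-dependence fits, and dose–response IC50.

Choice assays place trained or naïve animals between a pathogenic (PA14)
and a control (OP50) bacterial spot; olfactory-adaptation assays use an
odorant vs diluent spot.  The indices are standard count contrasts:

    choice index      CI = (N_PA14 - N_OP50) / (N_PA14 + N_OP50)
    learning index    LI = CI_naive - CI_trained
    chemotaxis index  CTX = (N_odor - N_ctrl) / (N_odor + N_ctrl)

so a positive CI is an innate preference for PA14 and a positive LI is a
learned aversion to it.  Speed dependence of learning is summarized by an
ordinary least-squares line of learning index against locomotion speed, and
two point sets are compared with the extra-sum-of-squares F-test (one
shared line for the pooled data vs separate lines per set).  Chemogenetic
silencing dose–response curves are fit with a four-parameter logistic to
estimate the half-maximal inhibitory concentration (IC50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError, NumericalError


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceCounts:
    n_pa14: int
    n_op50: int

    def __post_init__(self):
        if self.n_pa14 < 0 or self.n_op50 < 0:
            raise ValidationError("counts", "must be non-negative")
        if self.n_pa14 + self.n_op50 <= 0:
            raise ValidationError("counts", "total must be > 0")


@dataclass(frozen=True)
class ChemotaxisCounts:
    n_odor: int
    n_ctrl: int

    def __post_init__(self):
        if self.n_odor < 0 or self.n_ctrl < 0:
            raise ValidationError("counts", "must be non-negative")
        if self.n_odor + self.n_ctrl <= 0:
            raise ValidationError("counts", "total must be > 0")


@dataclass(frozen=True)
class LearningResult:
    ci_naive: float
    ci_trained: float
    learning_index: float


def choice_index(c: ChoiceCounts) -> float:
    """(N_PA14 - N_OP50) / total; +1 means every animal chose PA14."""
    return (c.n_pa14 - c.n_op50) / (c.n_pa14 + c.n_op50)


def learning_index(ci_naive: float, ci_trained: float) -> float:
    """CI_naive - CI_trained; positive for learned aversion to PA14."""
    for name, v in (("ci_naive", ci_naive), ("ci_trained", ci_trained)):
        if not -1.0 <= v <= 1.0:
            raise ValidationError(name, "must be in [-1, 1]")
    return ci_naive - ci_trained


def learning_result(naive: ChoiceCounts, trained: ChoiceCounts,
                    ) -> LearningResult:
    ci_n = choice_index(naive)
    ci_t = choice_index(trained)
    return LearningResult(ci_naive=ci_n, ci_trained=ci_t,
                          learning_index=learning_index(ci_n, ci_t))


def chemotaxis_index(c: ChemotaxisCounts) -> float:
    """(N_odor - N_ctrl) / total; +1 means every animal at the odorant."""
    return (c.n_odor - c.n_ctrl) / (c.n_odor + c.n_ctrl)


# --------------------------------------------------------------------------
# speed-learning fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedLearningPoint:
    speed: float            # um / s
    learning_index: float


@dataclass(frozen=True)
class LinFit:
    slope: float
    intercept: float
    rss: float
    n: int


@dataclass(frozen=True)
class FitComparison:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def _xy(points) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.speed for p in points], dtype=float)
    y = np.array([p.learning_index for p in points], dtype=float)
    return x, y


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, residual sum of squares."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValidationError("speeds", "need >= 2 distinct speed values")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    return slope, intercept, float(resid @ resid)


def fit_line(points) -> LinFit:
    """Ordinary least-squares line of learning index on speed."""
    x, y = _xy(points)
    if x.size < 3:
        raise ValidationError("points", "need at least 3 points")
    slope, intercept, rss = _ols(x, y)
    return LinFit(slope=slope, intercept=intercept, rss=rss, n=int(x.size))


def compare_fits(a_points, b_points, slope_only: bool = False,
                 ) -> FitComparison:
    """Extra-sum-of-squares F-test: one line for both sets vs separate lines.

    Default compares slope and intercept jointly (2 numerator df).  With
    ``slope_only`` the null model shares the slope but allows separate
    intercepts (1 numerator df).
    """
    xa, ya = _xy(a_points)
    xb, yb = _xy(b_points)
    if xa.size < 3 or xb.size < 3:
        raise ValidationError("points",
                              "each set needs >= 3 points for separate fits")
    _, _, rss_a = _ols(xa, ya)
    _, _, rss_b = _ols(xb, yb)
    rss_sep = rss_a + rss_b
    n = xa.size + xb.size
    df_den = n - 4

    if slope_only:
        # shared slope, separate intercepts (ANCOVA-style null)
        x = np.concatenate([xa, xb])
        y = np.concatenate([ya, yb])
        g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
        design = np.column_stack([np.ones(n), g, x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss_null = float(resid @ resid)
        df_num = 1
    else:
        x = np.concatenate([xa, xb])
        y = np.concatenate([ya, yb])
        _, _, rss_null = _ols(x, y)
        df_num = 2

    if df_den <= 0:
        raise ValidationError("points", "too few points for the F-test")
    if rss_sep == 0:
        f = 0.0 if rss_null <= rss_sep else math.inf
    else:
        f = max((rss_null - rss_sep) / df_num / (rss_sep / df_den), 0.0)
    p = float(stats.f.sf(f, df_num, df_den)) if math.isfinite(f) else 0.0
    return FitComparison(f_stat=float(f), df_num=df_num, df_den=df_den,
                         p_value=p)


# --------------------------------------------------------------------------
# dose-response
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    r_squared: float
    good_fit: bool


def _hill(dose, top, bottom, ic50, hill):
    dose = np.asarray(dose, dtype=float)
    ratio = np.where(dose > 0, (dose / np.abs(ic50)) ** hill, 0.0)
    return bottom + (top - bottom) / (1 + ratio)


def fit_ic50(doses_mM, responses, r2_threshold: float = 0.8) -> HillFit:
    """Four-parameter logistic fit of an inhibition dose–response curve.

    Initialization is deterministic: top = mean response at dose 0,
    bottom = minimum response (clamped at 0), IC50 = the dose whose response
    is closest to the midpoint (geometric mean of positive doses if tied or
    absent), Hill coefficient 1.  Non-monotone data still fit but are
    flagged (``good_fit`` False) when R² falls below ``r2_threshold``.
    """
    doses = np.asarray(doses_mM, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if doses.shape != resp.shape:
        raise ValidationError("responses", "length must match doses")
    if np.unique(doses).size < 4:
        raise ValidationError("doses_mM", "need >= 4 distinct doses")
    if not np.any(doses == 0):
        raise ValidationError("doses_mM", "must include dose 0")
    if np.any(resp < 0):
        raise ValidationError("responses", "must be non-negative")

    top0 = float(resp[doses == 0].mean())
    bottom0 = max(float(resp.min()), 0.0)
    mid = (top0 + bottom0) / 2.0
    pos = doses > 0
    ic50_0 = float(doses[pos][np.argmin(np.abs(resp[pos] - mid))])
    if ic50_0 <= 0:
        ic50_0 = float(np.exp(np.log(doses[pos]).mean()))
    p0 = [top0, bottom0, ic50_0, 1.0]

    try:
        popt, _ = optimize.curve_fit(
            _hill, doses, resp, p0=p0, maxfev=20000,
            bounds=([0, 0, 1e-9, 0.05], [np.inf, np.inf, np.inf, 20.0]))
    except RuntimeError as exc:
        raise NumericalError(f"IC50 fit failed to converge: {exc}") from exc

    pred = _hill(doses, *popt)
    ss_res = float(((resp - pred) ** 2).sum())
    ss_tot = float(((resp - resp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HillFit(top=float(popt[0]), bottom=float(popt[1]),
                   ic50=float(popt[2]), hill=float(popt[3]),
                   r_squared=r2, good_fit=r2 >= r2_threshold)
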
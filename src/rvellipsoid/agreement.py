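"""Bias and agreement statistics for method comparison against a reference.

Agreement of each estimator with the 3-D reference is quantified on
body-weight-indexed volumes by

* the median of paired differences with a distribution-free 95% CI from
  binomial order statistics (a nonzero median whose CI excludes 0 is a
  systematic bias);
* Lin's concordance correlation coefficient (CCC), the product of the
  Pearson correlation and a bias-correction factor, with a Fisher-z CI;
* Bland-Altman analysis: mean difference, 1.96-SD limits of agreement with
  t-based CIs, and an OLS regression of differences on pairwise means whose
  slope CI detects proportional bias.

All intervals are two-sided at alpha = 0.05 by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import REFERENCE_LABEL

logger = logging.getLogger(__name__)

#: Header of the per-method agreement summary CSV.
AGREEMENT_COLUMNS = [
    "method", "phase", "n",
    "median_diff", "median_lo", "median_hi",
    "ccc", "ccc_lo", "ccc_hi", "band",
    "pearson_r", "bias_correction",
    "mean_diff", "loa_lo", "loa_hi",
    "slope", "slope_lo", "slope_hi", "slope_p",
    "systematic_bias", "proportional_bias",
]

BA_POINT_COLUMNS = ["method", "phase", "dog_id", "mean", "diff"]


def median_with_ci(differences, alpha: float = 0.05):
    """Sample median with a distribution-free confidence interval.

    The CI is the exact binomial order-statistic interval: with sorted
    values x_(1..n), the interval [x_(l), x_(n+1-l)] where l is the largest
    rank with Binom(n, 1/2) lower tail <= alpha/2, guaranteeing coverage of
    at least 1 - alpha without interpolation.  For n < 6 no such interval
    exists at 95%, so the whole sample range is returned with a warning.
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = d.size
    if n == 0:
        raise ValueError("median_with_ci requires at least one value")
    med = float(np.median(d))
    # largest l >= 1 with P(X < l) <= alpha/2, X ~ Binom(n, 1/2)
    l = int(stats.binom.ppf(alpha / 2, n, 0.5))
    while l >= 1 and stats.binom.cdf(l - 1, n, 0.5) > alpha / 2:
        l -= 1
    if l < 1:
        warnings.warn(
            f"n={n} too small for a {100 * (1 - alpha):.0f}% order-statistic CI; "
            "returning the whole sample range", stacklevel=2)
        return med, (float(d[0]), float(d[-1]))
    return med, (float(d[l - 1]), float(d[n - l]))


@dataclass
class CCCResult:
    ccc: float
    ci: tuple
    pearson_r: float
    bias_correction: float
    n: int
    degenerate_ci: bool = False


def lin_ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a 95% CI.

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2) with population
    (divisor-n) moments, following Lin's original definition; the CI uses
    the Fisher z-transform with Lin's asymptotic standard error.  The
    decomposition ccc = r * C_b (Pearson correlation times bias-correction
    factor) is also returned.

    Constant series make the CI (and for both-constant, the coefficient)
    degenerate; this is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("lin_ccc requires n >= 3")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("both series are constant and identical; CCC undefined")
    ccc = 2 * sxy / denom
    ccc = float(np.clip(ccc, -1.0, 1.0))  # guard rounding at perfect (anti)concordance
    if sx2 > 0 and sy2 > 0:
        r = sxy / math.sqrt(sx2 * sy2)
        u = (mx - my) / (sx2 * sy2) ** 0.25  # scale shift relative to the spreads
        cb = ccc / r if r != 0 else float("nan")
    else:
        r = float("nan")
        u = float("nan")
        cb = float("nan")
    # Fisher z CI with Lin's variance (corrected form)
    degenerate = (
        not np.isfinite(r) or r == 0 or abs(ccc) >= 1.0 or abs(r) >= 1.0
    )
    if degenerate:
        ci = (ccc, ccc)
    else:
        z = np.arctanh(ccc)
        se2 = (
            (1 - r ** 2) * ccc ** 2 / ((1 - ccc ** 2) * r ** 2)
            + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - ccc ** 2) ** 2)
            - ccc ** 4 * u ** 4 / (2 * r ** 2 * (1 - ccc ** 2) ** 2)
        ) / (n - 2)
        se = math.sqrt(max(se2, 0.0))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return CCCResult(float(ccc), ci, float(r), float(cb), n, degenerate)


#: CCC agreement bands (internal boundaries belong to the higher band).
def classify_ccc(ccc: float) -> str:
    """Agreement band for a CCC: <0.90 poor, 0.90-0.95 moderate,
    0.95-0.99 substantial, >0.99 almost perfect."""
    if not -1 <= ccc <= 1:
        raise ValueError(f"ccc must lie in [-1, 1], got {ccc}")
    if ccc < 0.90:
        return "poor"
    if ccc < 0.95:
        return "moderate"
    if ccc <= 0.99:
        return "substantial"
    return "almost_perfect"


@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    mean_diff_ci: tuple
    loa: tuple
    loa_ci_low: tuple
    loa_ci_high: tuple
    slope: float
    intercept: float
    slope_ci: tuple
    slope_p: float
    slope_undefined: bool
    points: pd.DataFrame = field(repr=False, default=None)


def bland_altman(x, y, alpha: float = 0.05, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman analysis of paired series ``x`` (method) and ``y`` (reference).

    Differences d_i = x_i - y_i and pairwise means m_i = (x_i + y_i)/2 give
    the mean difference, the limits of agreement mean_diff +/- 1.96*SD(d)
    (sample SD), t-based CIs for the mean difference (SE = SD/sqrt(n)) and
    for each limit (SE = SD*sqrt(3/n), the large-sample Bland-Altman
    approximation), and an OLS regression of d on m (t-test on the slope,
    df = n - 2) to detect proportional bias.  The (m_i, d_i) coordinates are
    returned for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("bland_altman requires n >= 3")
    d = x - y
    m = (x + y) / 2.0
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    se_mean = sd / math.sqrt(n)
    mean_ci = (mean_diff - tcrit * se_mean, mean_diff + tcrit * se_mean)
    lo = mean_diff - loa_multiplier * sd
    hi = mean_diff + loa_multiplier * sd
    se_loa = sd * math.sqrt(3.0 / n)
    loa_ci_low = (lo - tcrit * se_loa, lo + tcrit * se_loa)
    loa_ci_high = (hi - tcrit * se_loa, hi + tcrit * se_loa)

    slope_undefined = bool(np.ptp(m) == 0)
    if slope_undefined:
        if np.ptp(d) == 0:
            slope, intercept, slope_ci, slope_p = 0.0, mean_diff, (0.0, 0.0), 1.0
        else:
            logger.warning("zero variance in pairwise means; regression slope undefined")
            slope = intercept = slope_p = float("nan")
            slope_ci = (float("nan"), float("nan"))
    elif np.ptp(d) == 0:
        # constant differences: flat regression line, exact fit
        slope, intercept, slope_ci, slope_p = 0.0, mean_diff, (0.0, 0.0), 1.0
        slope_undefined = False
    else:
        fit = stats.linregress(m, d)
        slope, intercept = float(fit.slope), float(fit.intercept)
        t2 = stats.t.ppf(1 - alpha / 2, n - 2)
        slope_ci = (slope - t2 * fit.stderr, slope + t2 * fit.stderr)
        slope_p = float(fit.pvalue)
    points = pd.DataFrame({"mean": m, "diff": d})
    return BlandAltmanResult(n, mean_diff, sd, mean_ci, (lo, hi), loa_ci_low,
                             loa_ci_high, slope, intercept, slope_ci, slope_p,
                             slope_undefined, points)


def ci_overlap_significant(ci_a, ci_b) -> bool:
    """True iff two confidence intervals are disjoint (a shared endpoint
    counts as overlap, i.e. not significant) — the conservative visual rule
    used when comparing methods on forest plots."""
    for ci in (ci_a, ci_b):
        lo, hi = ci
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"malformed interval {ci}")
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def paired_indexed_series(volumes: pd.DataFrame, method: str, reference: str, phase: str):
    """Pairwise-complete indexed-volume series for one method vs the
    reference at one phase, joined on (dog_id, session)."""
    sub = volumes[volumes["phase"] == phase]
    a = sub[sub["method"] == method].set_index(["dog_id", "session"])["indexed_ml_per_kg"]
    b = sub[sub["method"] == reference].set_index(["dog_id", "session"])["indexed_ml_per_kg"]
    joined = pd.concat({"method": a, "reference": b}, axis=1, join="inner").dropna()
    return joined


def run_agreement(volumes: pd.DataFrame, reference: str = REFERENCE_LABEL,
                  alpha: float = 0.05, min_n: int = 3):
    """Agreement of every non-reference method against the reference,
    per phase, on indexed volumes.

    Returns ``(summary, ba_points)``: a per-(method, phase) DataFrame with
    the columns in :data:`AGREEMENT_COLUMNS` and a long table of
    Bland-Altman coordinates.  Methods with fewer than ``min_n``
    pairwise-complete cases are skipped with a logged reason.
    """
    methods = [m for m in volumes["method"].unique() if m != reference]
    if reference not in set(volumes["method"]):
        raise ValueError(f"reference method {reference!r} not present in the volume table")
    rows, points = [], []
    for phase in sorted(volumes["phase"].unique()):
        for method in methods:
            joined = paired_indexed_series(volumes, method, reference, phase)
            n = len(joined)
            if n < min_n:
                logger.warning("skipping %s/%s: only %d complete pairs (< %d)",
                               method, phase, n, min_n)
                continue
            xv = joined["method"].to_numpy()
            yv = joined["reference"].to_numpy()
            diffs = xv - yv
            med, med_ci = median_with_ci(diffs, alpha)
            ccc = lin_ccc(xv, yv, alpha)
            ba = bland_altman(xv, yv, alpha)
            rows.append({
                "method": method, "phase": phase, "n": n,
                "median_diff": med, "median_lo": med_ci[0], "median_hi": med_ci[1],
                "ccc": ccc.ccc, "ccc_lo": ccc.ci[0], "ccc_hi": ccc.ci[1],
                "band": classify_ccc(ccc.ccc),
                "pearson_r": ccc.pearson_r, "bias_correction": ccc.bias_correction,
                "mean_diff": ba.mean_diff, "loa_lo": ba.loa[0], "loa_hi": ba.loa[1],
                "slope": ba.slope, "slope_lo": ba.slope_ci[0], "slope_hi": ba.slope_ci[1],
                "slope_p": ba.slope_p,
                "systematic_bias": not (med_ci[0] <= 0 <= med_ci[1]),
                "proportional_bias": (not ba.slope_undefined
                                      and not (ba.slope_ci[0] <= 0 <= ba.slope_ci[1])),
            })
            pts = ba.points.copy()
            pts.insert(0, "dog_id", [i[0] for i in joined.index])
            pts.insert(0, "phase", phase)
            pts.insert(0, "method", method)
            points.append(pts)
    summary = pd.DataFrame(rows, columns=AGREEMENT_COLUMNS)
    ba_points = (pd.concat(points, ignore_index=True)[BA_POINT_COLUMNS]
                 if points else pd.DataFrame(columns=BA_POINT_COLUMNS))
    return summary, ba_points
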
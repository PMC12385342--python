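"""Within-day reproducibility statistics for paired repeat sessions.

Each subject is measured in two same-day sessions (k = 2).  Reproducibility
of each estimator is summarised on indexed volumes by

* the within-subject coefficient of variation,
  CoV = 100 * wsSD / grand mean, where wsSD is the root-mean-square
  within-subject SD (for k = 2, sqrt(mean(d^2 / 2)) over subjects);
* the intraclass correlation ICC(A,1): two-way random-effects ANOVA,
  absolute agreement, single measures, with the standard F-based CI;
* the 95% reproducibility coefficient RC = 1.96 * SD of the session
  differences, the span expected to contain 95% of repeat differences,
  with a chi-square CI on the underlying SD.

Methods are compared by CI overlap (disjoint intervals = significant).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import ci_overlap_significant

logger = logging.getLogger(__name__)

REPRO_COLUMNS = [
    "method", "phase", "n",
    "cov_percent",
    "icc", "icc_lo", "icc_hi", "icc_band",
    "rc", "rc_lo", "rc_hi",
]


def _paired_arrays(session1, session2):
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("session arrays must be 1-D and of equal length")
    if not (np.isfinite(s1).all() and np.isfinite(s2).all()):
        raise ValueError("session values must be finite")
    return s1, s2


def within_subject_cov(session1, session2) -> float:
    """Within-subject coefficient of variation in percent.

    wsSD is pooled as the root mean square of per-subject sample SDs; with
    two sessions the per-subject sample variance is d^2/2 for difference d,
    so wsSD = sqrt(mean(d^2) / 2).  The denominator is the grand mean of
    all observations, which must be positive.
    """
    s1, s2 = _paired_arrays(session1, session2)
    if s1.size < 2:
        raise ValueError("within_subject_cov requires n >= 2 subjects")
    grand_mean = float(np.concatenate([s1, s2]).mean())
    if grand_mean <= 0:
        raise ValueError("CoV undefined: grand mean must be positive")
    ws_sd = math.sqrt(float(np.mean((s1 - s2) ** 2)) / 2.0)
    return 100.0 * ws_sd / grand_mean


def _two_way_anova(values: np.ndarray):
    """Mean squares of the two-way (subjects x sessions) ANOVA on an
    n x k matrix with one observation per cell."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_single(session1, session2, alpha: float = 0.05):
    """ICC(A,1): two-way random model, absolute agreement, single measures.

    From the ANOVA mean squares with n subjects and k = 2 sessions,

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with the F-based confidence interval of the standard two-way
    absolute-agreement construction (Satterthwaite degrees of freedom for
    the session term).  Returns ``(icc, (lo, hi))``; a table with zero
    total variance is degenerate and raises ``ValueError``.
    """
    s1, s2 = _paired_arrays(session1, session2)
    n = s1.size
    if n < 3:
        raise ValueError("icc_absolute_single requires n >= 3 subjects")
    values = np.column_stack([s1, s2])
    k = 2
    if np.ptp(values) == 0:
        raise ValueError("zero total variance: ICC undefined")
    msr, msc, mse = _two_way_anova(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measures)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
    if not np.isfinite(a) or mse == 0:
        return float(icc), (float(icc), float(icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f1 * mse)) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = (n * (f2 * msr - mse)) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), (float(lower), float(upper))


def classify_icc(icc: float) -> str:
    """Reproducibility band for an ICC: <0.5 poor, 0.5-0.75 moderate,
    0.75-0.90 good, >0.90 excellent."""
    if icc > 1:
        raise ValueError(f"icc cannot exceed 1, got {icc}")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def reproducibility_coefficient(session1, session2, alpha: float = 0.05):
    """95% reproducibility coefficient RC = 1.96 * SD of session differences.

    The CI rescales the chi-square interval on the SD of the differences by
    the same 1.96 multiplier.  Returns ``(rc, (lo, hi))``.
    """
    s1, s2 = _paired_arrays(session1, session2)
    n = s1.size
    if n < 2:
        raise ValueError("reproducibility_coefficient requires n >= 2 subjects")
    d = s1 - s2
    sd = float(d.std(ddof=1))
    rc = 1.96 * sd
    lo = 1.96 * sd * math.sqrt((n - 1) / stats.chi2.ppf(1 - alpha / 2, n - 1))
    hi = 1.96 * sd * math.sqrt((n - 1) / stats.chi2.ppf(alpha / 2, n - 1))
    return rc, (lo, hi)


def paired_sessions(volumes: pd.DataFrame, method: str, phase: str) -> pd.DataFrame:
    """Per-subject indexed volumes with both sessions present for one
    method and phase (columns ``s1``, ``s2`` indexed by dog_id)."""
    sub = volumes[(volumes["method"] == method) & (volumes["phase"] == phase)]
    wide = sub.pivot_table(index="dog_id", columns="session",
                           values="indexed_ml_per_kg", aggfunc="first")
    if 1 not in wide.columns or 2 not in wide.columns:
        return pd.DataFrame(columns=["s1", "s2"])
    wide = wide[[1, 2]].dropna()
    wide.columns = ["s1", "s2"]
    return wide


def run_reproducibility(volumes: pd.DataFrame, alpha: float = 0.05, min_n: int = 3):
    """Within-day reproducibility for every method x phase in a volume
    table containing sessions 1 and 2.

    Returns ``(summary, overlap)``: a per-(method, phase) DataFrame with
    the columns in :data:`REPRO_COLUMNS`, and a long-format pairwise
    CI-overlap significance table (one row per method pair per phase per
    quantity in {icc, rc}).  Methods with fewer than ``min_n`` paired
    subjects are skipped with a logged reason.
    """
    sessions = set(volumes["session"].unique())
    if not {1, 2} <= sessions:
        raise ValueError("volume table must contain sessions 1 and 2")
    rows = []
    cis = {}
    for phase in sorted(volumes["phase"].unique()):
        for method in volumes["method"].unique():
            wide = paired_sessions(volumes, method, phase)
            n = len(wide)
            if n < min_n:
                logger.warning("skipping %s/%s: only %d paired subjects (< %d)",
                               method, phase, n, min_n)
                continue
            s1, s2 = wide["s1"].to_numpy(), wide["s2"].to_numpy()
            cov = within_subject_cov(s1, s2)
            try:
                icc, icc_ci = icc_absolute_single(s1, s2, alpha)
            except ValueError:
                icc, icc_ci = 1.0, (1.0, 1.0)  # duplicated constant sessions
            rc, rc_ci = reproducibility_coefficient(s1, s2, alpha)
            rows.append({
                "method": method, "phase": phase, "n": n,
                "cov_percent": cov,
                "icc": icc, "icc_lo": icc_ci[0], "icc_hi": icc_ci[1],
                "icc_band": classify_icc(icc),
                "rc": rc, "rc_lo": rc_ci[0], "rc_hi": rc_ci[1],
            })
            cis[(phase, method)] = {"icc": icc_ci, "rc": rc_ci}
    summary = pd.DataFrame(rows, columns=REPRO_COLUMNS)
    overlap_rows = []
    for phase in summary["phase"].unique():
        methods = summary.loc[summary["phase"] == phase, "method"].tolist()
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                for quantity in ("icc", "rc"):
                    sig = ci_overlap_significant(cis[(phase, ma)][quantity],
                                                 cis[(phase, mb)][quantity])
                    overlap_rows.append({"phase": phase, "quantity": quantity,
                                         "method_a": ma, "method_b": mb,
                                         "significant": sig})
    overlap = pd.DataFrame(overlap_rows,
                           columns=["phase", "quantity", "method_a", "method_b", "significant"])
    return summary, overlap
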
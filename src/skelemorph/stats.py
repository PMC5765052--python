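"""Two-group study statistics.

The study design compares wild-type (WT) and achondroplastic (Ach)
littermates at 3 and 6 weeks of age, measurement by measurement:

* two-tailed unpaired t-tests with Welch's correction per measurement/age;
* Holm-Sidak step-down adjustment for families of tests (e.g. body-weight
  timelines across timepoints);
* chi-square goodness of fit for birth genotype/sex ratios;
* mean +/- SEM summaries with the conventional significance stars
  (* 0.01<p<0.05, ** 0.001<p<0.01, *** 0.0001<p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .voxgrid import StudyTable

__all__ = [
    "GroupComparison",
    "welch_t",
    "holm_sidak",
    "chi_square_gof",
    "significance_stars",
    "summarize_groups",
    "timeline_comparisons",
]


@dataclass
class GroupComparison:
    measurement_name: str
    age_weeks: int
    n_wt: int
    n_ach: int
    mean_wt: float
    mean_ach: float
    sem_wt: float
    sem_ach: float
    t_stat: float
    df_welch: float
    p_value: float
    stars: str


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test (two-tailed): returns (t, df, p).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom (not rounded).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    With ascending p_(1) <= ... <= p_(m), the adjusted value at rank k is
    max_{j<=k} [1 - (1 - p_(j))^(m - j + 1)], clipped to 1; the running
    maximum enforces monotonicity and adjusted p never falls below raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def chi_square_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Chi-square goodness of fit: returns (chi2, df, upper-tail p)."""
    obs = np.asarray(observed, dtype=float)
    prop = np.asarray(expected_proportions, dtype=float)
    if (obs < 0).any():
        raise ValueError("observed counts must be >= 0")
    if abs(prop.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    exp = obs.sum() * prop
    if (exp == 0).any():
        raise ValueError("zero expected count in a cell")
    chi2, p = sps.chisquare(obs, exp)
    return float(chi2), len(obs) - 1, float(p)


def significance_stars(p: float) -> str:
    """Star band for a p-value; boundary values fall to the less
    significant band (strict inequalities)."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def summarize_groups(table: StudyTable) -> list[GroupComparison]:
    """One WT-vs-Ach Welch comparison per (measurement, age).

    Groups with fewer than 2 animals are skipped with a warning.  Results
    carry mean +/- SEM per group, the Welch t, df and two-tailed p, and
    the significance stars.
    """
    out: list[GroupComparison] = []
    df = table.df
    for (meas, age), sub in df.groupby(["measurement", "age_weeks"], sort=True):
        wt = sub.loc[sub["genotype"] == "WT", "value"].to_numpy(dtype=float)
        ach = sub.loc[sub["genotype"] == "Ach", "value"].to_numpy(dtype=float)
        if len(wt) < 2 or len(ach) < 2:
            warnings.warn(
                f"skipping {meas!r} at {age} weeks: group with n < 2"
            )
            continue
        t, dof, p = welch_t(wt, ach)
        out.append(
            GroupComparison(
                measurement_name=str(meas),
                age_weeks=int(age),
                n_wt=len(wt),
                n_ach=len(ach),
                mean_wt=float(wt.mean()),
                mean_ach=float(ach.mean()),
                sem_wt=_sem(wt),
                sem_ach=_sem(ach),
                t_stat=t,
                df_welch=dof,
                p_value=p,
                stars=significance_stars(p),
            )
        )
    if not out:
        warnings.warn("no comparable groups found")
    return out


def timeline_comparisons(
    comparisons: Sequence[GroupComparison],
) -> list[GroupComparison]:
    """Holm-Sidak-adjust a family of per-timepoint Welch comparisons.

    Intended for repeated measurements over time (e.g. body-weight
    timelines): each timepoint's Welch p is adjusted across the family and
    the stars re-derived from the adjusted p.
    """
    if not comparisons:
        return []
    adj = holm_sidak([c.p_value for c in comparisons])
    out = []
    for c, pa in zip(comparisons, adj):
        out.append(
            GroupComparison(
                **{**c.__dict__, "p_value": float(pa), "stars": significance_stars(float(pa))}
            )
        )
    return out
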
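"""Cohort-level statistics and the summary/validation table.

Three validation tests are applied across sessions:

* one-sample t test of the light-reflex amplitude against 0 (two-sided),
* one-sample t test of the cognitive difference against 0 (two-sided),
* Wilcoxon signed-rank test of the velocity ratio against 1, one-sided
  (greater), using the normal approximation
  z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24) without continuity
  correction.

Effect sizes are one-sample Cohen's d = (mean − mu0)/sd with the n−1
standard deviation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError
from .metrics import SessionMetrics


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t test: returns (t, df, two-sided p).

    t = (mean − mu0) / (sd / sqrt(n)) with the n−1 sample SD.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 2:
        raise InsufficientDataError("t test needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance")
    t, df = t_from_summary(v.mean(), sd, n, mu0)
    return t, df, 2.0 * sps.t.sf(abs(t), df)


def t_from_summary(mean: float, sd: float, n: int, mu0: float = 0.0) -> tuple[float, int]:
    """t statistic and df from summary statistics (mean, n−1 SD, n)."""
    if n < 2:
        raise InsufficientDataError("t test needs n >= 2")
    if sd <= 0:
        raise DegenerateDataError("sd must be positive")
    return (mean - mu0) / (sd / np.sqrt(n)), n - 1


def cohens_d_one_sample(values: Sequence[float], mu0: float = 0.0) -> float:
    """Cohen's d = (mean − mu0) / sd; equals t/sqrt(n)."""
    v = np.asarray(values, float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance")
    return float((v.mean() - mu0) / sd)


def d_from_summary(mean: float, sd: float, mu0: float = 0.0) -> float:
    if sd <= 0:
        raise DegenerateDataError("sd must be positive")
    return (mean - mu0) / sd


def wilcoxon_signed_rank(
    values: Sequence[float],
    mu0: float = 1.0,
    alternative: str = "greater",
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Signed-rank test against ``mu0`` via the normal approximation.

    Ranks |value − mu0| with average ranks for ties (exact-zero differences
    are dropped, per the standard procedure), sums the positive ranks W+,
    and standardises:

        z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)

    Returns (z, p) for the requested alternative. The optional continuity
    correction shrinks the numerator by 0.5 toward zero.
    """
    v = np.asarray(values, float)
    d = v - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all values equal mu0")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    sd_w = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    num = w_plus - mean_w
    if continuity_correction and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / sd_w
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def wilcoxon_exact_p(values: Sequence[float], mu0: float = 1.0) -> float:
    """Exact one-sided (greater) signed-rank p by enumerating sign patterns.

    Reference implementation for small n (2^n patterns); used to check the
    normal approximation.
    """
    v = np.asarray(values, float)
    d = v - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all values equal mu0")
    if n > 16:
        raise ValueError("exact enumeration limited to n <= 16")
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for pattern in range(2**n):
        w = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


#: Metric extractors for the cohort table: name -> (label, getter).
_METRIC_FIELDS = [
    ("plr_amplitude_mm", lambda m: m.plr.amplitude_mm),
    ("cognitive_difference_mm", lambda m: m.cognitive.difference_mm),
    ("velocity_ratio", lambda m: m.velocity_ratio),
    ("dark_mean_mm", lambda m: m.plr.dark_mean_mm),
    ("bright_mean_mm", lambda m: m.plr.bright_mean_mm),
    ("constriction_pct", lambda m: m.plr.constriction_pct),
    ("peak_constriction_velocity_mm_s", lambda m: m.plr.peak_constriction_velocity_mm_s),
    ("low_mean_mm", lambda m: m.cognitive.low_mean_mm),
    ("high_mean_mm", lambda m: m.cognitive.high_mean_mm),
    ("percent_change", lambda m: m.cognitive.percent_change),
    ("peak_dilation_velocity_mm_s", lambda m: m.cognitive.peak_dilation_velocity_mm_s),
]

#: Tests applied in the validation rows: metric -> (test, mu0, alternative).
_VALIDATION_TESTS = {
    "plr_amplitude_mm": ("t", 0.0),
    "cognitive_difference_mm": ("t", 0.0),
    "velocity_ratio": ("wilcoxon", 1.0),
}


@dataclass
class CohortSummary:
    """Per-metric descriptives and validation tests for a cohort."""

    table: pd.DataFrame  # one row per metric
    n_sessions: int
    n_excluded: int

    def validation_table(self) -> pd.DataFrame:
        """The three validation rows in the published layout."""
        rows = self.table[self.table["metric"].isin(_VALIDATION_TESTS)].copy()
        rows["mean_sd"] = rows.apply(lambda r: f"{r['mean']:.2f} ({r['sd']:.2f})", axis=1)
        rows["range"] = rows.apply(lambda r: f"{r['min']:.2f}-{r['max']:.2f}", axis=1)

        def stat(r):
            if r["test"] == "t":
                return f"t({int(r['df'])})={r['statistic']:.2f}"
            return f"Z={r['statistic']:.2f}"

        rows["test_statistic"] = rows.apply(stat, axis=1)
        rows["effect_size_d"] = rows["d"]
        return rows[["metric", "mean_sd", "range", "test_statistic", "p", "effect_size_d"]]


def cohort_summary(metrics: Sequence[SessionMetrics]) -> CohortSummary:
    """Summarise a cohort, dropping QC-excluded sessions.

    Each metric row carries n, mean, n−1 SD, min, max; the validation
    metrics additionally carry their test statistic, df (t only), p value
    and Cohen's d. Degenerate inputs (zero variance) leave the test fields
    NaN with ``test`` set to ``"degenerate"``.
    """
    usable = [m for m in metrics if not m.excluded]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"cohort summary needs >= 2 usable sessions, got {len(usable)}"
        )
    rows = []
    for name, get in _METRIC_FIELDS:
        v = np.array([get(m) for m in usable], float)
        row = {
            "metric": name,
            "n": len(v),
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "min": v.min(),
            "max": v.max(),
            "test": "",
            "statistic": np.nan,
            "df": np.nan,
            "p": np.nan,
            "d": np.nan,
        }
        if name in _VALIDATION_TESTS:
            kind, mu0 = _VALIDATION_TESTS[name]
            try:
                if kind == "t":
                    t, df, p = one_sample_t(v, mu0)
                    row.update(test="t", statistic=t, df=df, p=p, d=cohens_d_one_sample(v, mu0))
                else:
                    z, p = wilcoxon_signed_rank(v, mu0, alternative="greater")
                    row.update(test="wilcoxon", statistic=z, p=p)
            except DegenerateDataError:
                row["test"] = "degenerate"
        rows.append(row)
    table = pd.DataFrame(rows)
    return CohortSummary(table, n_sessions=len(metrics), n_excluded=len(metrics) - len(usable))
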
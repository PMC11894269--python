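"""Cohort statistics for fitted sphere radii.

Implements the descriptive and inferential analyses run on a cohort of
per-subject Monson-sphere radii: mean ± SD with a t-based 95% CI of the
mean, a one-sample t-test of the cohort against the classical four-inch
sphere (101.6 mm), and a Mann–Whitney U test between sexes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "GroupSummary",
    "THEORETICAL_RADIUS_MM",
    "summarize",
    "one_sample_t",
    "one_sample_t_summary",
    "mann_whitney_u",
    "compare_cohort",
    "read_cohort",
    "write_cohort",
    "InsufficientDataError",
    "DegenerateDataError",
]

#: Monson's classical four-inch sphere: 4 in x 25.4 mm/in exactly.
THEORETICAL_RADIUS_MM = 4 * 25.4

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    sex: str  # "M" | "F"
    radius: float  # mm

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


@dataclass
class GroupSummary:
    """Descriptive summary: n, mean, n-1 SD, median, t-based 95% CI."""

    n: int
    mean: float
    sd: float
    median: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return asdict(self)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class MannWhitneyResult(NamedTuple):
    u: float
    p: float


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD, median and t-based 95% CI of the mean.

    The median uses the midpoint convention for even n; the CI is
    ``mean ± t(0.975, n-1) * sd / sqrt(n)``.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"summary needs n >= 2, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(1 - ALPHA / 2, n - 1) * sd / np.sqrt(n)
    return GroupSummary(
        n=n,
        mean=mean,
        sd=sd,
        median=float(np.median(x)),
        ci_low=mean - float(half),
        ci_high=mean + float(half),
    )


def one_sample_t_summary(mean: float, sd: float, n: int, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test from summary statistics:
    ``t = (mean - mu0) / (sd / sqrt(n))`` on n-1 degrees of freedom."""
    if n < 2:
        raise InsufficientDataError(f"t-test needs n >= 2, got {n}")
    if sd <= 0:
        raise DegenerateDataError("t-test undefined for sd <= 0")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=min(p, 1.0))


def one_sample_t(values: Sequence[float], mu0: float) -> TTestResult:
    """Two-sided one-sample t-test on raw data."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise InsufficientDataError(f"t-test needs n >= 2, got {len(x)}")
    if x.std(ddof=1) == 0:
        raise DegenerateDataError("t-test undefined for zero-variance data")
    return one_sample_t_summary(float(x.mean()), float(x.std(ddof=1)), len(x), mu0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U between two groups.

    U is computed from rank sums with midranks for ties.  The p-value is
    by exact enumeration when ``n_a + n_b <= 20`` and the pooled sample
    is tie-free, otherwise by the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    small = len(x) + len(y) <= 20
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue))


def compare_cohort(
    records: Iterable[CohortRecord],
    theoretical_radius: float = THEORETICAL_RADIUS_MM,
) -> dict:
    """Full cohort report: per-sex and pooled summaries, male-minus-female
    mean difference, Mann–Whitney U between sexes, and a one-sample t of
    the pooled radii against the theoretical sphere radius."""
    recs = list(records)
    males = [r.radius for r in recs if r.sex == "M"]
    females = [r.radius for r in recs if r.sex == "F"]
    if len(males) < 2 or len(females) < 2:
        raise InsufficientDataError(
            f"need >= 2 records per sex, got {len(males)} male / "
            f"{len(females)} female"
        )
    pooled = males + females
    sum_m = summarize(males)
    sum_f = summarize(females)
    sum_all = summarize(pooled)
    mw = mann_whitney_u(males, females)
    try:
        tt = one_sample_t(pooled, theoretical_radius)
        t_report = {"t": tt.t, "df": tt.df, "p": tt.p}
    except DegenerateDataError:
        # zero-variance cohort: the test statistic is undefined
        t_report = {"t": None, "df": len(pooled) - 1, "p": None}
    return {
        "schema_version": 1,
        "theoretical_radius_mm": theoretical_radius,
        "males": sum_m.to_dict(),
        "females": sum_f.to_dict(),
        "total": sum_all.to_dict(),
        "mean_difference_mm": sum_m.mean - sum_f.mean,
        "mann_whitney": {"u": mw.u, "p": mw.p},
        "one_sample_t_vs_theoretical": t_report,
        "alpha": ALPHA,
    }


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a ``subject_id,sex,radius_mm`` CSV with sex in {M, F}."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["subject_id", "sex", "radius_mm"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    return [
        CohortRecord(str(r.subject_id), str(r.sex), float(r.radius_mm))
        for r in df.itertuples(index=False)
    ]


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    recs = list(records)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recs],
            "sex": [r.sex for r in recs],
            "radius_mm": [r.radius for r in recs],
        }
    ).to_csv(path, index=False, float_format="%.17g")
    return path
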
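"""Intrarater reliability: single-measures intraclass correlation.

The repeatability design is a two-way table of n models rated in two
sessions by the same operator.  From the subjects-by-sessions ANOVA
decomposition the Shrout–Fleiss single-measures coefficients follow:

* **ICC(3,1)** (two-way mixed, consistency):
  ``(MSB - MSE) / (MSB + (k-1) MSE)`` — insensitive to a session-wide
  shift, appropriate when the sessions are the fixed raters of interest.
* **ICC(2,1)** (two-way random, absolute agreement):
  ``(MSB - MSE) / (MSB + (k-1) MSE + k (MSC - MSE) / n)`` — penalizes
  systematic between-session offsets.

Confidence intervals are the exact F-based Shrout–Fleiss intervals; the
p-value is the one-sided between-subjects F test of ICC = 0.  The
default form is the consistency coefficient, matching a same-operator
repeat-measurement design.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatedRadii",
    "ICCResult",
    "icc_single_measures",
    "read_repeated_radii",
    "write_repeated_radii",
    "table1_fixture_path",
    "InsufficientDataError",
    "DegenerateDataError",
]


class InsufficientDataError(ValueError):
    """Too few models/sessions for the requested analysis."""


class DegenerateDataError(ValueError):
    """Zero variance makes the statistic undefined."""


@dataclass
class RepeatedRadii:
    """Paired repeat radius measurements, one row per scanned model."""

    model_ids: tuple[str, ...]
    r1: np.ndarray  # mm
    r2: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, float)
        self.r2 = np.asarray(self.r2, float)
        if not (len(self.model_ids) == len(self.r1) == len(self.r2)):
            raise ValueError("model_ids, r1, r2 must have equal length")
        vals = np.concatenate([self.r1, self.r2])
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("all radii must be finite and positive")

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    @property
    def n_sessions(self) -> int:
        return 2

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.r1, self.r2])


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    p_value: float
    form: str  # "ICC(3,1)" or "ICC(2,1)"
    anova_table: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _anova_two_way(X: np.ndarray) -> dict:
    """Mean squares of the subjects x sessions decomposition (no
    replication, so the interaction is the error term)."""
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_sessions = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_error = ss_total - ss_between - ss_sessions
    return {
        "ms_between_subjects": ss_between / (n - 1),
        "ms_between_sessions": ss_sessions / (k - 1),
        "ms_error": ss_error / ((n - 1) * (k - 1)),
        "df_between_subjects": n - 1,
        "df_between_sessions": k - 1,
        "df_error": (n - 1) * (k - 1),
    }


def icc_single_measures(data: RepeatedRadii, form: str = "ICC(3,1)") -> ICCResult:
    """Single-measures ICC of the requested form with exact F-based 95% CI.

    Parameters
    ----------
    data
        The paired repeat measurements; at least 3 models required.
    form
        ``"ICC(3,1)"`` (consistency, default) or ``"ICC(2,1)"``
        (absolute agreement).
    """
    if data.n_models < 3:
        raise InsufficientDataError(
            f"ICC needs >= 3 models, got {data.n_models}"
        )
    X = data.matrix()
    n, k = X.shape
    if np.ptp(X) == 0.0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    a = _anova_two_way(X)
    msb, msc, mse = (
        a["ms_between_subjects"],
        a["ms_between_sessions"],
        a["ms_error"],
    )

    if form not in ("ICC(3,1)", "ICC(2,1)"):
        raise ValueError(f"unknown ICC form {form!r}")

    if mse == 0.0:
        # Perfect within-subject agreement (e.g. identical sessions):
        # the variance-ratio F is unbounded and the ICC is exact.
        if form == "ICC(3,1)":
            icc = 1.0
        else:
            icc = msb / (msb + k * msc / n) if (msb + k * msc / n) > 0 else 1.0
        return ICCResult(
            icc=float(icc),
            ci_low=float(icc),
            ci_high=float(icc),
            f_value=float("inf"),
            p_value=0.0,
            form=form,
            anova_table=a,
        )

    if form == "ICC(3,1)":
        icc = (msb - mse) / (msb + (k - 1) * mse)
        # Exact interval from F = MSB/MSE with (n-1, (n-1)(k-1)) df.
        F = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = F / stats.f.ppf(0.975, df1, df2)
        fu = F * stats.f.ppf(0.975, df2, df1)
        ci_low = (fl - 1.0) / (fl + k - 1.0)
        ci_high = (fu - 1.0) / (fu + k - 1.0)
        p = float(stats.f.sf(F, df1, df2))
    elif form == "ICC(2,1)":
        icc = (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
        F = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        p = float(stats.f.sf(F, df1, df2))
        # Shrout–Fleiss approximate interval via the Fj = MSC/MSE route.
        fj = msc / mse
        vn = (k - 1.0) * (n - 1.0) * (
            (k * icc * fj + n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2
        )
        vd = (n - 1.0) * (k**2) * (icc**2) * (fj**2) + (
            (n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2
        )
        v = vn / vd
        f_low = stats.f.ppf(0.975, n - 1, v)
        f_up = stats.f.ppf(0.975, v, n - 1)
        ci_low = n * (msb - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msb
        )
        ci_high = n * (f_up * msb - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msb
        )

    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        f_value=float(F),
        p_value=p,
        form=form,
        anova_table=a,
    )


def read_repeated_radii(path: str | Path) -> RepeatedRadii:
    """Read a ``model_id,r1_mm,r2_mm`` CSV."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["model_id", "r1_mm", "r2_mm"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    return RepeatedRadii(
        model_ids=tuple(str(m) for m in df["model_id"]),
        r1=df["r1_mm"].to_numpy(float),
        r2=df["r2_mm"].to_numpy(float),
    )


def write_repeated_radii(data: RepeatedRadii, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"model_id": data.model_ids, "r1_mm": data.r1, "r2_mm": data.r2}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def table1_fixture_path() -> Path:
    """Path to the packaged 15-model repeatability table."""
    return Path(
        resources.files("monsonsphere").joinpath("data/table1_repeated_radii.csv")
    )
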
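"""Clinical validation statistics for blood-pressure estimators.

Implements the standard device-validation suite: mean error (ME), mean
absolute error (MAE), root-mean-square error (RMSE), error SD and mean
relative error (MRE); BHS grading from the cumulative frequency of absolute
errors under 5/10/15 mmHg; the AAMI criterion (|ME| <= 5 mmHg and
SD < 8 mmHg); Bland-Altman limits of agreement (mean difference
+/- 1.96 SD); and regression statistics (Pearson r, R^2, OLS line) between
predicted and reference pressures.

Conventions: SD is the sample standard deviation (n-1); Bland-Altman
differences are predicted - reference; BHS cumulative frequencies count
strict inequalities |error| < threshold and are compared to the grade
thresholds with >=.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricsReport", "BHSResult", "AAMIResult", "BlandAltman",
           "compute_metrics", "bhs_grade", "aami_check", "bland_altman",
           "regression_stats", "BHS_THRESHOLDS"]

# grade -> required cumulative percentages at |e| < 5, 10, 15 mmHg
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0),
                  "B": (50.0, 75.0, 90.0),
                  "C": (40.0, 65.0, 85.0)}


@dataclass
class MetricsReport:
    me: float        # mmHg, mean(true - predicted)
    mae: float       # mmHg
    rmse: float      # mmHg
    sd_error: float  # mmHg, sample SD (n-1) of the errors
    mre: float       # percent
    n: int

    def to_series(self) -> pd.Series:
        return pd.Series({"me": self.me, "mae": self.mae, "rmse": self.rmse,
                          "sd": self.sd_error, "mre": self.mre, "n": self.n})


@dataclass
class BHSResult:
    cum5: float      # percent of |errors| < 5 mmHg
    cum10: float
    cum15: float
    grade: str       # "A" | "B" | "C" | "ungraded"


@dataclass
class AAMIResult:
    me: float
    sd: float
    pass_flag: bool


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    pairs: pd.DataFrame  # columns: average, difference


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """ME / MAE / RMSE / SD / MRE of predictions against reference values.

    ME = mean(y - yhat); MRE = mean(|y - yhat| / y) * 100 (requires
    positive reference values).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    if np.any(y_true <= 0):
        raise ValueError("reference values must be positive for MRE")
    err = y_true - y_pred
    n = err.size
    sd = float(err.std(ddof=1)) if n > 1 else 0.0
    return MetricsReport(
        me=float(err.mean()),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err ** 2).mean())),
        sd_error=sd,
        mre=float((np.abs(err) / y_true).mean() * 100.0),
        n=int(n))


def bhs_grade(errors: np.ndarray) -> BHSResult:
    """BHS cumulative-frequency grading of absolute errors (mmHg).

    The grade is the best one whose three thresholds are all met; the
    printed cumulative percentages are compared with >= to the required
    60/85/95 (A), 50/75/90 (B), 40/65/85 (C).
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error vector")
    a = np.abs(errors)
    cums = tuple(float((a < t).mean() * 100.0) for t in (5.0, 10.0, 15.0))
    grade = "ungraded"
    for g in ("C", "B", "A"):   # best grade met wins
        if all(c >= t for c, t in zip(cums, BHS_THRESHOLDS[g])):
            grade = g
    return BHSResult(cum5=cums[0], cum10=cums[1], cum15=cums[2], grade=grade)


def grade_from_cumulative(cum5: float, cum10: float,
                          cum15: float) -> str:
    """Grade a printed (cum5, cum10, cum15) percentage triple."""
    grade = "ungraded"
    for g in ("C", "B", "A"):
        if all(c >= t for c, t in zip((cum5, cum10, cum15),
                                      BHS_THRESHOLDS[g])):
            grade = g
    return grade


def aami_check(me: float, sd: float) -> AAMIResult:
    """AAMI device criterion: mean error within +/-5 mmHg (inclusive) and
    error SD strictly below 8 mmHg."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return AAMIResult(me=float(me), sd=float(sd),
                      pass_flag=bool(abs(me) <= 5.0 and sd < 8.0))


def bland_altman(y_true: np.ndarray, y_pred: np.ndarray) -> BlandAltman:
    """Agreement analysis: differences (pred - true) vs pair averages,
    with limits of agreement = mean difference +/- 1.96 x sample SD."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need at least 2 paired values")
    diff = y_pred - y_true
    avg = 0.5 * (y_pred + y_true)
    sd = float(diff.std(ddof=1))
    mean = float(diff.mean())
    return BlandAltman(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pairs=pd.DataFrame({"average": avg, "difference": diff}))


def regression_stats(y_true: np.ndarray,
                     y_pred: np.ndarray) -> Tuple[float, float, float, float]:
    """(r, R^2, slope, intercept) of the OLS fit of predictions on truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("zero-variance input")
    res = stats.linregress(y_true, y_pred)
    return (float(res.rvalue), float(res.rvalue ** 2),
            float(res.slope), float(res.intercept))


def save_plots(y_true: np.ndarray, y_pred: np.ndarray, out_dir,
               label: str = "BP") -> list:
    """Write the standard validation plots (scatter + fit, error box,
    error histogram, Bland-Altman) as PNG files; returns the paths.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y_pred - y_true
    paths = []

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y_true, y_pred, s=6, alpha=0.5)
    r, r2, slope, intercept = regression_stats(y_true, y_pred)
    xs = np.linspace(y_true.min(), y_true.max(), 2)
    ax.plot(xs, slope * xs + intercept, "r-",
            label=f"r={r:.2f}, $R^2$={r2:.2f}")
    ax.set_xlabel(f"reference {label} (mmHg)")
    ax.set_ylabel(f"predicted {label} (mmHg)")
    ax.legend()
    paths.append(out_dir / f"{label.lower()}_scatter.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(3, 4))
    ax.boxplot(err, tick_labels=[label])
    ax.set_ylabel("error (mmHg)")
    paths.append(out_dir / f"{label.lower()}_box.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(err, bins=30, density=True)
    ax.set_xlabel("error (mmHg)")
    ax.set_ylabel("density")
    paths.append(out_dir / f"{label.lower()}_hist.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    ba = bland_altman(y_true, y_pred)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(ba.pairs["average"], ba.pairs["difference"], s=6, alpha=0.5)
    for y, style in ((ba.mean_diff, "r-"), (ba.loa_low, "r--"),
                     (ba.loa_high, "r--")):
        ax.axhline(y, ls=style[1:], color="r")
    ax.set_xlabel(f"average {label} (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    paths.append(out_dir / f"{label.lower()}_bland_altman.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths


def metrics_table(y_true_sbp, y_pred_sbp, y_true_dbp,
                  y_pred_dbp) -> pd.DataFrame:
    """Combined SBP/DBP report as a tidy frame (for CSV / text export)."""
    rows = {}
    for name, yt, yp in (("SBP", y_true_sbp, y_pred_sbp),
                         ("DBP", y_true_dbp, y_pred_dbp)):
        m = compute_metrics(yt, yp)
        b = bhs_grade(np.asarray(yt) - np.asarray(yp))
        a = aami_check(m.me, m.sd_error)
        rows[name] = {"me": m.me, "mae": m.mae, "rmse": m.rmse,
                      "sd": m.sd_error, "mre": m.mre, "n": m.n,
                      "bhs_cum5": b.cum5, "bhs_cum10": b.cum10,
                      "bhs_cum15": b.cum15, "bhs_grade": b.grade,
                      "aami_pass": a.pass_flag}
    return pd.DataFrame(rows).T
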
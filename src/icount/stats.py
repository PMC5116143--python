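"""Validation and assay statistics.

Three independent concerns live here:

* calibration of automatic counts against a manual reference via
  ordinary least squares on the linear model ``Y = a + b x`` (Y =
  estimated count, x = manual count), with the usual t-test on the
  slope;
* error metrics of a counting method against known ground truth
  (absolute and percent error, exact-match fraction);
* dual-choice oviposition assays: egg numbers transformed to
  percentages per replicate and compared between arms with Welch's
  unequal-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConsistencyError, StatisticsError

Pair = tuple[float, float]  # (manual/reference count, estimated count)


class _Counted(Protocol):
    image_id: str
    total_estimate: int


class _Truth(Protocol):
    image_id: str
    total_eggs: int


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of estimated counts on manual counts."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        half = sps.t.ppf(0.5 + level / 2, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


@dataclass(frozen=True)
class ErrorMetrics:
    """Counting accuracy against ground truth, averaged over images.

    Images whose true count is zero have no defined percent error; they
    are excluded from ``mean_pct_error`` and tallied separately in
    ``n_undefined_pct``.
    """

    mean_abs_error: float
    mean_pct_error: float
    exact_match_fraction: float
    n_images: int
    n_undefined_pct: int = 0


@dataclass(frozen=True)
class ChoiceSummary:
    """Welch comparison of egg-laying percentages between two arms."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float


def fit_calibration(pairs: Sequence[Pair]) -> CalibrationFit:
    """Ordinary least squares of estimated on manual counts.

    Requires at least 3 pairs and non-constant manual counts.  The
    p-value is the two-sided t-test of slope != 0 on n - 2 degrees of
    freedom; R^2 = 1 - SSres/SStot.
    """
    if len(pairs) < 3:
        raise StatisticsError(
            f"calibration needs >= 3 (manual, estimated) pairs, got {len(pairs)}"
        )
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise StatisticsError("manual counts are all identical; slope undefined")
    res = sps.linregress(x, y)
    return CalibrationFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(pairs),
        slope_stderr=float(res.stderr),
    )


def fit_calibration_stratified(
    pairs: Sequence[Pair], split: float = 100.0
) -> dict[str, CalibrationFit | None]:
    """Separate fits for low- and high-density images.

    Counting degrades as crowding (and hence egg overlap) increases, so
    the calibration is fitted separately for manual counts <= ``split``
    and > ``split`` (default 100 eggs per image).  A stratum with fewer
    than 3 pairs, or constant manual counts, yields ``None``.
    """
    out: dict[str, CalibrationFit | None] = {}
    for name, sel in (
        ("low", [p for p in pairs if p[0] <= split]),
        ("high", [p for p in pairs if p[0] > split]),
    ):
        try:
            out[name] = fit_calibration(sel)
        except StatisticsError:
            out[name] = None
    return out


def evaluate_against_truth(
    results: Sequence[_Counted], truths: Sequence[_Truth]
) -> ErrorMetrics:
    """Per-image |auto - true| and percent errors, averaged over a batch.

    ``results`` and ``truths`` are aligned by ``image_id``; a mismatch in
    the id sets is an error.
    """
    by_id = {t.image_id: t for t in truths}
    if {r.image_id for r in results} != set(by_id) or len(results) != len(by_id):
        raise ConsistencyError(
            "results and truths must cover the same image_ids exactly"
        )
    abs_errors, pct_errors = [], []
    n_exact = 0
    n_undefined = 0
    for res in results:
        true = by_id[res.image_id].total_eggs
        err = abs(res.total_estimate - true)
        abs_errors.append(err)
        if err == 0:
            n_exact += 1
        if true > 0:
            pct_errors.append(100.0 * err / true)
        elif res.total_estimate != 0:
            n_undefined += 1
    return ErrorMetrics(
        mean_abs_error=float(np.mean(abs_errors)),
        mean_pct_error=float(np.mean(pct_errors)) if pct_errors else 0.0,
        exact_match_fraction=n_exact / len(results),
        n_images=len(results),
        n_undefined_pct=n_undefined,
    )


def choice_percent(eggs_choice: int, total_eggs: int) -> float:
    """Percentage of a replicate's eggs laid in one arm:
    100 * eggs(choice) / total eggs."""
    if total_eggs <= 0:
        raise StatisticsError(
            f"total_eggs must be positive, got {total_eggs}"
        )
    if not (0 <= eggs_choice <= total_eggs):
        raise StatisticsError(
            f"eggs_choice must lie in [0, total_eggs], got "
            f"{eggs_choice} of {total_eggs}"
        )
    return 100.0 * eggs_choice / total_eggs


def welch_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> ChoiceSummary:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degrees of freedom follow Welch–Satterthwaite.  Equals Student's t
    when both groups share size and sample variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of any difference
            return ChoiceSummary(
                tuple(a), tuple(b), float(np.mean(a)), float(np.mean(b)),
                t_statistic=0.0, df=float(len(a) + len(b) - 2), p_value=1.0,
            )
        raise StatisticsError("zero variance in both groups; t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return ChoiceSummary(
        group_a=tuple(a),
        group_b=tuple(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def plot_calibration(
    pairs: Sequence[Pair], fit: CalibrationFit, path: str | Path
) -> None:
    """Scatter of (manual, estimated) pairs with the fitted line, to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.6, label="images")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(
        xs, fit.intercept + fit.slope * xs, "r-",
        label=f"Y = {fit.slope:.2f}x + {fit.intercept:.2f}  "
              f"(R² = {fit.r_squared:.3f})",
    )
    ax.set_xlabel("manual count (reference)")
    ax.set_ylabel("estimated count")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
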
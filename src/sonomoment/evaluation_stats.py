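"""Prediction-quality metrics and the study's statistical comparison protocol.

The regression loss is the mean squared residual between the ground-truth
net plantarflexion moment and the CNN-based prediction; RMSE is its square
root; N-RMSE normalizes RMSE by the individual's peak ground-truth moment so
subjects with different moment magnitudes can be compared.  The coefficient
of determination is, by default, the squared Pearson correlation between
truth and prediction (both series' means enter the formula); the residual
form 1 - SS_res/SS_tot is available via ``form="residual"`` — the two
coincide when the prediction-vs-truth fit is near the identity line.

Group comparisons follow a normality-gated branch: Shapiro–Wilk per
condition decides between the parametric track (repeated-measures ANOVA +
Tukey HSD, or a paired t-test for two conditions) and the nonparametric
track (Friedman + Tukey-style mean-rank post hoc, or a Wilcoxon signed-rank
test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EvalSeries",
    "EvalReport",
    "StatsReport",
    "regression_loss",
    "rmse",
    "n_rmse",
    "r_squared",
    "linear_fit",
    "evaluate_series",
    "compare_groups",
]

ALPHA = 0.05
SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class EvalSeries:
    """Paired ground-truth / prediction moment vectors.

    ``peak_moment`` is the peak ground-truth moment used to normalize RMSE;
    by convention it is the max of truth over a subject's prediction cycles.
    """

    y: np.ndarray
    yhat: np.ndarray
    peak_moment: float | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        yhat = np.asarray(self.yhat, dtype=float)
        if y.ndim != 1 or yhat.ndim != 1:
            raise ValueError("y and yhat must be 1-D")
        if y.shape != yhat.shape:
            raise ValueError(
                f"length mismatch: |y|={y.size} vs |yhat|={yhat.size}"
            )
        if y.size < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
            raise ValueError("non-finite values in series")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "yhat", yhat)
        if self.peak_moment is None:
            object.__setattr__(self, "peak_moment", float(np.max(np.abs(y))))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.yhat


def regression_loss(series: EvalSeries) -> float:
    """Quadratic loss: mean over samples of (y_i - yhat_i)^2."""
    return float(np.mean(series.residuals**2))


def rmse(series: EvalSeries) -> float:
    """Root mean square error, in the label's units (Nm)."""
    return float(np.sqrt(regression_loss(series)))


def n_rmse(series: EvalSeries) -> float:
    """RMSE normalized by the peak ground-truth moment (dimensionless)."""
    if series.peak_moment is None or series.peak_moment <= 0:
        raise ZeroDivisionError("peak_moment must be positive for N-RMSE")
    return rmse(series) / series.peak_moment


def r_squared(
    series: EvalSeries, form: Literal["correlation", "residual"] = "correlation"
) -> float:
    """Coefficient of determination between truth and prediction.

    ``correlation`` (default): squared Pearson correlation coefficient.
    ``residual``: 1 - SS_res / SS_tot with truth as the reference.
    """
    y, yhat = series.y, series.yhat
    if np.ptp(y) == 0:
        raise ValueError("ground truth is constant; R^2 undefined")
    if form == "correlation":
        if np.ptp(yhat) == 0:
            raise ValueError("prediction is constant; R^2 undefined")
        r = np.corrcoef(y, yhat)[0, 1]
        return float(r * r)
    if form == "residual":
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R^2 form: {form!r}")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    r2: float


def linear_fit(series: EvalSeries) -> LinearFit:
    """OLS of prediction on ground truth; the reference is the 45-degree line.

    Standard errors and p-values come from the usual t-statistics of the
    two-parameter fit.
    """
    import statsmodels.api as sm

    if series.n < 3:
        raise ValueError("linear fit needs at least 3 samples")
    y = series.y
    if np.ptp(y) == 0:
        raise ValueError("constant ground truth: design matrix is rank-deficient")
    X = sm.add_constant(y)
    res = sm.OLS(series.yhat, X).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        slope_p=float(res.pvalues[1]),
        intercept_p=float(res.pvalues[0]),
        r2=float(res.rsquared),
    )


@dataclass
class EvalReport:
    """All scalar metrics for one truth/prediction pairing."""

    loss: float
    rmse: float
    n_rmse: float
    r2: float
    fit: LinearFit | None = None
    per_fold: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "loss": self.loss,
            "rmse": self.rmse,
            "n_rmse": self.n_rmse,
            "r2": self.r2,
        }
        if self.fit is not None:
            d["linear_fit"] = vars(self.fit).copy()
        if self.per_fold:
            d["per_fold"] = self.per_fold
        return d


def evaluate_series(series: EvalSeries, with_fit: bool = True) -> EvalReport:
    """Bundle loss, RMSE, N-RMSE, R^2 and (optionally) the linear fit."""
    return EvalReport(
        loss=regression_loss(series),
        rmse=rmse(series),
        n_rmse=n_rmse(series),
        r2=r_squared(series),
        fit=linear_fit(series) if with_fit and series.n >= 3 else None,
    )


# ---------------------------------------------------------------------------
# Normality-gated group comparisons
# ---------------------------------------------------------------------------


@dataclass
class PairwiseResult:
    pair: tuple[int, int]
    statistic: float
    p_value: float

    @property
    def flags(self) -> str:
        """Asterisk convention: * p<.05, ** p<.01, *** p<.001."""
        return "*" * sum(self.p_value < a for a in SIGNIFICANCE_LEVELS)


@dataclass
class StatsReport:
    normality_p: list[float]
    branch: Literal["parametric", "nonparametric"]
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult]

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple[int, int]]:
        return [p.pair for p in self.pairwise if p.p_value < alpha]


def _friedman_rank_posthoc(data: np.ndarray) -> list[PairwiseResult]:
    """Tukey-style studentized-range comparison of Friedman mean ranks.

    Within-subject ranks are averaged per condition; the difference of mean
    ranks for conditions i, j is referred to the studentized range
    distribution with scale sqrt(k(k+1)/(12 n)).
    """
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    scale = np.sqrt(k * (k + 1) / (12.0 * n))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / scale
            p = float(sps.studentized_range.sf(q, k, np.inf))
            out.append(PairwiseResult((i, j), float(q), p))
    return out


def compare_groups(
    metric_matrix: np.ndarray | Sequence[Sequence[float]],
    paired: bool = True,
    alpha: float = ALPHA,
) -> StatsReport:
    """Compare metric values across conditions (columns) over subjects (rows).

    Shapiro–Wilk per condition gates the branch: the parametric track is
    taken iff every condition passes normality at alpha.  With 3+
    conditions the omnibus is a one-way repeated-measures ANOVA (parametric)
    or a Friedman test, each followed by Tukey-HSD-style pairwise
    comparisons; with exactly 2 conditions a paired t-test or a Wilcoxon
    signed-rank test is used directly.
    """
    data = np.asarray(metric_matrix, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D subjects x conditions matrix with >= 2 conditions")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not paired:
        raise NotImplementedError("only the paired/repeated-measures design is supported")
    n, k = data.shape

    norm_p = []
    for c in range(k):
        col = data[:, c]
        # identical values make SW degenerate; treat as non-normal evidence-free pass
        if np.ptp(col) == 0:
            norm_p.append(1.0)
        else:
            norm_p.append(float(sps.shapiro(col).pvalue))
    branch: Literal["parametric", "nonparametric"] = (
        "parametric" if all(p >= alpha for p in norm_p) else "nonparametric"
    )

    if k == 2:
        d = data[:, 0] - data[:, 1]
        if branch == "parametric":
            if np.ptp(d) == 0:
                stat, p = 0.0, 1.0
            else:
                t = sps.ttest_rel(data[:, 0], data[:, 1])
                stat, p = float(t.statistic), float(t.pvalue)
            name = "paired t-test"
        else:
            if np.ptp(d) == 0 and np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                w = sps.wilcoxon(data[:, 0], data[:, 1])
                stat, p = float(w.statistic), float(w.pvalue)
            name = "Wilcoxon signed-rank"
        return StatsReport(norm_p, branch, name, stat, p,
                           [PairwiseResult((0, 1), stat, p)])

    if branch == "parametric":
        from statsmodels.stats.anova import AnovaRM
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "condition": np.tile(np.arange(k), n),
                "value": data.ravel(),
            }
        )
        if np.ptp(data) == 0:
            stat, p = 0.0, 1.0
            pairwise = [
                PairwiseResult((i, j), 0.0, 1.0)
                for i in range(k)
                for j in range(i + 1, k)
            ]
        else:
            aov = AnovaRM(long, "value", "subject", within=["condition"]).fit()
            stat = float(aov.anova_table["F Value"].iloc[0])
            p = float(aov.anova_table["Pr > F"].iloc[0])
            hsd = pairwise_tukeyhsd(long["value"], long["condition"], alpha=alpha)
            pairwise = [
                PairwiseResult(
                    (int(hsd._results_table.data[r + 1][0]),
                     int(hsd._results_table.data[r + 1][1])),
                    float(hsd._results_table.data[r + 1][2]),
                    float(hsd.pvalues[r]),
                )
                for r in range(len(hsd.pvalues))
            ]
        return StatsReport(norm_p, branch, "RM-ANOVA + Tukey HSD", stat, p, pairwise)

    fr = sps.friedmanchisquare(*[data[:, c] for c in range(k)])
    pairwise = _friedman_rank_posthoc(data)
    return StatsReport(
        norm_p,
        branch,
        "Friedman + mean-rank Tukey",
        float(fr.statistic),
        float(fr.pvalue),
        pairwise,
    )
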
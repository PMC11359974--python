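"""Between-session reliability statistics: ICC(2,1), SEM and classification.

The unit of analysis is an n-subjects x 2-sessions matrix of one
aggregated outcome. The model is the two-way random-effects ANOVA with one
observation per cell,

    x_ij = mu + r_i + c_j + e_ij,

subjects (rows) and sessions (columns) both random. The single-measure
absolute-agreement intraclass correlation is

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with MSR/MSC/MSE the row, column and residual mean squares, n subjects and
k = 2 sessions. Absolute agreement charges systematic session shifts to the
error term (the MSC enters the denominator), which is the appropriate form
for test-retest studies where the second session should reproduce the
first's value, not merely its ranking.

The 95% confidence interval uses the F-based procedure of McGraw & Wong
(1996) for the single-measure absolute-agreement coefficient, with the
Satterthwaite degrees of freedom for the mixture of mean squares in the
denominator. SEM defaults to sqrt(MSE), the within-subject error SD of the
same ANOVA; SEM% = 100 * SEM / grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .types import Aggregation, OutcomeMatrix, TrialOutcomes

__all__ = [
    "AnovaDecomposition",
    "ReliabilityResult",
    "ReliabilityClass",
    "aggregate_trials",
    "shapiro_wilk",
    "maybe_log_transform",
    "two_way_anova",
    "icc21",
    "sem_and_pct",
    "classify",
    "analyze_matrix",
    "reliability_table",
    "OUTCOME_COLUMNS",
]

logger = logging.getLogger(__name__)

#: tidy per-trial outcome table columns -> report outcome names
OUTCOME_COLUMNS = {
    "mvc_n": "MVC (N)",
    "rfd200_n_per_s": "RFD200ms (N/s)",
    "t90_s": "Time to 90% MVC (s)",
    "peak_emg_rms_v": "TA EMG (V)",
}


class ReliabilityClass(str, Enum):
    """Reliability bands applied to the ICC point estimate and CI lower bound."""

    EXCELLENT = "excellent"  # >= 0.90
    GOOD = "good"  # 0.75 - 0.89
    MODERATE = "moderate"  # 0.50 - 0.74
    POOR = "poor"  # < 0.50


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way, one-observation-per-cell ANOVA."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass(frozen=True)
class ReliabilityResult:
    """One row of the reliability report."""

    outcome_name: str
    aggregation: Aggregation
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    sem_pct: float
    grand_mean: float
    mean_session1: float
    mean_session2: float
    sd_session1: float
    sd_session2: float
    n: int
    log_transformed: bool
    class_point: ReliabilityClass
    class_lower: ReliabilityClass

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("confidence interval must bracket the ICC point estimate")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def aggregate_trials(
    outcomes: Sequence[TrialOutcomes], method: Aggregation | str
) -> dict[str, float | None]:
    """Reduce one session's trials to one scalar per outcome.

    ``mean3`` is the arithmetic mean; ``best3`` takes the max for MVC,
    RFD200 and peak EMG but the *min* for time-to-90% (the fastest rise is
    the best performance). Ties resolve to the same value either way.
    Missing EMG in any trial makes the session's EMG outcome missing.
    """
    if len(outcomes) == 0:
        raise ValueError("cannot aggregate zero trials")
    method = Aggregation(method)

    def agg(values: list[float], best: str) -> float:
        if method is Aggregation.MEAN3:
            return float(np.mean(values))
        return float(min(values) if best == "min" else max(values))

    result: dict[str, float | None] = {
        "mvc_n": agg([o.mvc_n for o in outcomes], "max"),
        "rfd200_n_per_s": agg([o.rfd200_n_per_s for o in outcomes], "max"),
        "t90_s": agg([o.t90_s for o in outcomes], "min"),
    }
    emg = [o.peak_emg_rms_v for o in outcomes]
    result["peak_emg_rms_v"] = None if any(v is None for v in emg) else agg(emg, "max")
    return result


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    res = scipy.stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def maybe_log_transform(matrix: OutcomeMatrix, alpha: float = 0.05) -> tuple[OutcomeMatrix, bool]:
    """Natural-log transform the matrix if either session fails normality.

    Each session column is screened with Shapiro-Wilk; p < ``alpha`` in
    either triggers a log of every cell. ``alpha = 0`` disables the
    transform.
    """
    if alpha < 0 or alpha >= 1:
        raise ValueError("alpha must be in [0, 1)")
    if alpha == 0:
        return matrix, False
    triggered = any(shapiro_wilk(matrix.values[:, j])[1] < alpha for j in range(2))
    if not triggered:
        return matrix, False
    if np.any(matrix.values <= 0):
        raise ValueError(
            f"{matrix.outcome_name}: log transform triggered but the matrix "
            "contains non-positive values"
        )
    return matrix.with_values(np.log(matrix.values)), True


def two_way_anova(matrix: OutcomeMatrix | np.ndarray) -> AnovaDecomposition:
    """Row/column/residual mean squares of the n x k one-obs-per-cell design."""
    x = matrix.values if isinstance(matrix, OutcomeMatrix) else np.asarray(matrix, float)
    if x.ndim != 2:
        raise ValueError("need an n x k matrix")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = x.mean()
    ss_rows = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ss_err = max(ss_err, 0.0)  # guard float cancellation in degenerate cases
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc21(a: AnovaDecomposition, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1) absolute agreement with its (1 - alpha) confidence interval.

    Returns ``(icc, ci_low, ci_high)``. The interval is the McGraw-Wong
    F-based one: the lower/upper bounds invert an F test whose denominator
    mean square is the Satterthwaite-weighted mixture of MSC and MSE, with
    effective degrees of freedom ``v``. Bounds are clipped to [-1, 1].
    """
    msr, msc, mse = a.ms_rows, a.ms_cols, a.ms_error
    n, k = a.n, a.k
    numer = msr - mse
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        if numer == 0:
            raise ValueError("degenerate: no variance in the outcome matrix")
        # the estimator diverges (e.g. perfectly anti-correlated sessions);
        # report the clipped limit with a collapsed interval
        icc = -1.0 if numer < 0 else 1.0
        return icc, icc, icc
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement: the interval collapses to the point
        return icc, icc, icc

    if mse == 0:
        v = float(k - 1)  # limit of the Satterthwaite df as MSC/MSE -> inf
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
    f_upper = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_upper * mse) / (f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_lower * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    lo, hi = float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))
    icc = float(np.clip(icc, -1.0, 1.0))
    return icc, min(lo, icc), max(hi, icc)


def sem_and_pct(
    a: AnovaDecomposition,
    matrix: OutcomeMatrix,
    *,
    formula: str = "mse",
    icc: float | None = None,
) -> tuple[float, float]:
    """Standard error of measurement and its percentage of the grand mean.

    ``formula="mse"`` (default): SEM = sqrt(MSE), the within-subject error
    SD of the absolute-agreement ANOVA. ``formula="sd1micc"``: the classic
    pooled-SD x sqrt(1 - ICC) alternative (requires ``icc``).
    """
    if formula == "mse":
        sem = float(np.sqrt(a.ms_error))
    elif formula == "sd1micc":
        if icc is None:
            raise ValueError("sd1micc formula requires the ICC estimate")
        sd_pooled = float(np.std(matrix.values, ddof=1))
        sem = sd_pooled * float(np.sqrt(max(0.0, 1.0 - icc)))
    else:
        raise ValueError(f"unknown SEM formula {formula!r}")
    grand = float(matrix.values.mean())
    if grand == 0:
        raise ValueError("grand mean is zero; SEM% undefined")
    return sem, 100.0 * sem / grand


def classify(icc: float, ci_low: float) -> tuple[ReliabilityClass, ReliabilityClass]:
    """Band the ICC point estimate and CI lower bound.

    excellent >= 0.90; good 0.75-0.89; moderate 0.50-0.74; poor < 0.50.
    """

    def band(v: float) -> ReliabilityClass:
        if v >= 0.90:
            return ReliabilityClass.EXCELLENT
        if v >= 0.75:
            return ReliabilityClass.GOOD
        if v >= 0.50:
            return ReliabilityClass.MODERATE
        return ReliabilityClass.POOR

    return band(icc), band(ci_low)


def analyze_matrix(
    matrix: OutcomeMatrix,
    *,
    alpha_normality: float = 0.05,
    sem_formula: str = "mse",
    log_transform: bool = True,
) -> ReliabilityResult:
    """Full reliability analysis of one outcome matrix.

    Normality screening (optional log transform), two-way ANOVA, ICC(2,1)
    with 95% CI, SEM, SEM% and classification. When the log transform
    fires, ICC/CI/SEM/SEM% are on the log (analysis) scale and the flag is
    set; session means and SDs are reported on the raw scale for
    readability.
    """
    raw = matrix
    if log_transform:
        matrix, flag = maybe_log_transform(matrix, alpha_normality)
    else:
        flag = False
    a = two_way_anova(matrix)
    icc, lo, hi = icc21(a)
    sem, sem_pct = sem_and_pct(a, matrix, formula=sem_formula, icc=icc)
    point, lower = classify(icc, lo)
    return ReliabilityResult(
        outcome_name=matrix.outcome_name,
        aggregation=matrix.aggregation,
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        sem=sem,
        sem_pct=sem_pct,
        grand_mean=float(matrix.values.mean()),
        mean_session1=float(raw.values[:, 0].mean()),
        mean_session2=float(raw.values[:, 1].mean()),
        sd_session1=float(raw.values[:, 0].std(ddof=1)),
        sd_session2=float(raw.values[:, 1].std(ddof=1)),
        n=matrix.n,
        log_transformed=flag,
        class_point=point,
        class_lower=lower,
    )


def outcome_matrix_from_table(
    table: pd.DataFrame,
    outcome: str,
    aggregation: Aggregation | str,
) -> OutcomeMatrix:
    """Build an n x 2 matrix for one outcome from a tidy per-trial table.

    `table` needs columns subject, session, trial plus the outcome columns
    of :data:`OUTCOME_COLUMNS`. Trials are aggregated per (subject,
    session); subjects missing either session, or missing the outcome
    (e.g. no EMG), are dropped listwise and logged.
    """
    aggregation = Aggregation(aggregation)
    rows: dict[str, dict[int, float]] = {}
    best = "min" if outcome == "t90_s" else "max"
    for (subj, sess), grp in table.groupby(["subject", "session"], sort=True):
        vals = grp[outcome].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        if vals.size < len(grp):
            logger.warning(
                "%s: subject %s session %s aggregated over %d of %d trials",
                outcome, subj, sess, vals.size, len(grp),
            )
        if aggregation is Aggregation.MEAN3:
            v = float(vals.mean())
        else:
            v = float(vals.min() if best == "min" else vals.max())
        rows.setdefault(str(subj), {})[int(sess)] = v

    subject_ids, values = [], []
    for subj in sorted(rows):
        if set(rows[subj]) >= {1, 2}:
            subject_ids.append(subj)
            values.append([rows[subj][1], rows[subj][2]])
        else:
            logger.info("%s: subject %s dropped (missing a session)", outcome, subj)
    if len(values) < 2:
        raise ValueError(f"{outcome}: fewer than 2 complete subjects")
    return OutcomeMatrix(
        np.asarray(values), OUTCOME_COLUMNS.get(outcome, outcome), aggregation, subject_ids
    )


def reliability_table(
    table: pd.DataFrame,
    *,
    aggregations: Iterable[Aggregation | str] = (Aggregation.MEAN3, Aggregation.BEST3),
    alpha_normality: float = 0.05,
    sem_formula: str = "mse",
    log_transform: bool = True,
) -> list[ReliabilityResult]:
    """Reliability report rows for every outcome x aggregation pair.

    With all four outcomes present and both aggregations requested this
    yields 8 rows. Outcomes whose column is entirely missing (e.g. no EMG
    recorded anywhere) are skipped with a log message.
    """
    results: list[ReliabilityResult] = []
    for outcome in OUTCOME_COLUMNS:
        if outcome not in table.columns or table[outcome].dropna().empty:
            logger.info("outcome %s absent from the table; skipped", outcome)
            continue
        for agg in aggregations:
            try:
                matrix = outcome_matrix_from_table(table, outcome, agg)
                results.append(
                    analyze_matrix(
                        matrix,
                        alpha_normality=alpha_normality,
                        sem_formula=sem_formula,
                        log_transform=log_transform,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{outcome} [{Aggregation(agg).value}]: {exc}") from exc
    return results
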
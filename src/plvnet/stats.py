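"""Statistical layer: increase maps, group contrasts, FDR, behavior, regression.

All functions here are pure (no hidden randomness).  Group contrasts use
the Mann-Whitney U test with a tie-corrected normal approximation for the
Z score and the effect size r = |Z| / sqrt(N); multiple comparisons are
controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "SignificanceMap",
    "PerformanceSummary",
    "RegressionResult",
    "pointwise_increase_map",
    "mann_whitney_compare",
    "fdr_adjust",
    "behavioral_summary",
    "efficiency_rt_regression",
    "chi_square_proportions",
]

#: Open-interval reaction-time filter, ms after S2: boundary values excluded.
RT_BOUNDS = (150.0, 1500.0)


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney contrast with medians, IQRs and effect size."""

    median: dict[str, float]
    iqr: dict[str, float]
    n: dict[str, int]
    u: float
    z: float
    p: float
    r: float
    p_fdr: float | None = None


@dataclass
class SignificanceMap:
    """−log10(p) of the across-subject increase test, connections x samples."""

    values: np.ndarray
    times: np.ndarray
    connection_names: tuple[str, ...] = ()


@dataclass
class PerformanceSummary:
    """Behavioral performance of one subject after RT filtering."""

    subject_id: str
    median_rt: dict[str, float]
    mean_rt: dict[str, float]
    accuracy_pct: float
    anticipatory_count: int
    n_valid_rt: int
    valid: bool = True


@dataclass
class RegressionResult:
    """Simple OLS of an outcome on global efficiency."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p: float
    df: tuple[int, int]
    p_fdr: float | None = None


def pointwise_increase_map(
    values: np.ndarray,
    times: np.ndarray,
    connection_names: tuple[str, ...] = (),
) -> SignificanceMap:
    """Pointwise one-sample increase test across subjects.

    ``values`` is ``subjects x connections x samples`` of rPLV; at every
    connection and sample, a one-sided one-sample t-test of mean > 0 across
    subjects is converted to −log10(p).  Degenerate cells (zero
    across-subject variance) get p = 1, i.e. a map value of 0.
    """
    arr = np.asarray(values, float)
    if arr.ndim != 3:
        raise ValueError("expected subjects x connections x samples")
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    with np.errstate(all="ignore"):
        res = sps.ttest_1samp(arr, 0.0, axis=0, alternative="greater")
        p = np.asarray(res.pvalue)
    degenerate = np.ptp(arr, axis=0) == 0
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    return SignificanceMap(
        values=-np.log10(p), times=np.asarray(times),
        connection_names=tuple(connection_names),
    )


def _tie_corrected_sigma(all_values: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return float(np.sqrt(var))


def mann_whitney_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    groups: tuple[str, str] = ("TS", "CO"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U contrast between two groups.

    U is reported for the first group; Z is the tie-corrected normal
    approximation (no continuity correction) and r = |Z| / sqrt(n1 + n2).
    The p-value is scipy's (exact for small tie-free samples, asymptotic
    with tie correction otherwise).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    sigma = _tie_corrected_sigma(np.concatenate([a, b]), n1, n2)
    z = 0.0 if sigma == 0 else (u - mu) / sigma
    return GroupComparison(
        median={groups[0]: float(np.median(a)), groups[1]: float(np.median(b))},
        iqr={
            groups[0]: float(np.subtract(*np.percentile(a, [75, 25]))),
            groups[1]: float(np.subtract(*np.percentile(b, [75, 25]))),
        },
        n={groups[0]: n1, groups[1]: n2},
        u=u,
        z=z,
        p=float(res.pvalue),
        r=abs(z) / np.sqrt(n1 + n2),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def behavioral_summary(record) -> PerformanceSummary:
    """Per-subject behavioral metrics with the standard RT filter.

    Reaction times outside the open interval (150, 1500) ms are excluded
    from the RT statistics (anticipatory and excessively delayed presses);
    accuracy is the percentage of correct trials over all trials, and the
    anticipatory count tallies presses between S1 and S2.
    """
    trials: pd.DataFrame = record.trials
    rt = trials["rt_ms"].to_numpy(float)
    ok = np.isfinite(rt) & (rt > RT_BOUNDS[0]) & (rt < RT_BOUNDS[1])
    median_rt, mean_rt = {}, {}
    for side in ("left", "right"):
        m = ok & (trials["side"] == side).to_numpy()
        median_rt[side] = float(np.median(rt[m])) if m.any() else float("nan")
        mean_rt[side] = float(np.mean(rt[m])) if m.any() else float("nan")
    n_total = len(trials)
    accuracy = 100.0 * trials["correct"].mean() if n_total else float("nan")
    return PerformanceSummary(
        subject_id=record.subject_id,
        median_rt=median_rt,
        mean_rt=mean_rt,
        accuracy_pct=float(accuracy),
        anticipatory_count=int(trials["anticipatory"].sum()),
        n_valid_rt=int(ok.sum()),
        valid=bool(ok.any()),
    )


def efficiency_rt_regression(e_glob, outcome) -> RegressionResult:
    """OLS of a behavioral outcome on per-subject global efficiency."""
    x = np.asarray(e_glob, float)
    y = np.asarray(outcome, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched subjects")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    if np.ptp(y) == 0:
        # constant outcome: no association by definition
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            f_stat=0.0, p=1.0, df=(1, x.size - 2),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p=float(model.f_pvalue),
        df=(int(model.df_model), int(model.df_resid)),
    )


def chi_square_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Chi-square test (no continuity correction) for two proportions.

    Worked-example utility for demographics tables, e.g. 16/20 vs 16/20
    males gives chi-square = 0.0, p = 1.0.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative and k <= n")
    if k1 / n1 == k2 / n2:
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
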
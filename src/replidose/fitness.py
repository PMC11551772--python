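"""Growth, fitness, expression and survival estimators.

Small closed-form estimators used throughout the battery:

* :func:`growth_metrics` — Vmax as the maximum sliding-window OLS slope
  of OD versus time, and the raw trapezoidal AUC;
* :func:`relative_fitness` — competition-assay fitness
  ``w = ln(Nf,untagged/Ni,untagged) / ln(Nf,tagged/Ni,tagged)``, the
  ratio of log fold-changes of the query strain over the tagged
  reference;
* :func:`fold_change_ddct` — qPCR relative expression ``2**(-ddCt)``;
* :func:`survival_summary` — kill-curve survival fractions and log10
  reductions with a censoring rule at the plating detection limit;
* :func:`event_frequency` — CFU-based frequencies (e.g. transformation
  frequency) with exact binomial confidence intervals;
* :func:`endpoint_compare` — unpaired t-test / one-way ANOVA endpoint
  comparisons, with Benjamini–Hochberg adjustment in batch mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .kinetics import KineticSeries
from .simulate import CompetitionCount, KillCurve

__all__ = [
    "GrowthMetrics",
    "CtRecord",
    "growth_metrics",
    "relative_fitness",
    "fold_change_ddct",
    "survival_summary",
    "event_frequency",
    "EndpointTest",
    "endpoint_compare",
    "endpoint_compare_batch",
]


@dataclass(frozen=True)
class GrowthMetrics:
    vmax: float  # OD/min
    auc: float  # OD·min
    vmax_window: tuple[float, float]  # (t_start, t_end) of the maximizing window


def growth_metrics(series: KineticSeries, slope_window_points: int = 5) -> GrowthMetrics:
    """Vmax and AUC of a growth curve.

    Vmax is the maximum over sliding windows of ``slope_window_points``
    consecutive readings of the least-squares slope of OD on time; the
    first maximizing window is reported on ties.  AUC is the trapezoid
    of the raw OD over the full horizon (no baseline subtraction).
    """
    if slope_window_points < 2:
        raise ValueError("slope_window_points must be >= 2")
    t, v = series.time_min, series.values
    n = t.size
    if n < slope_window_points:
        raise ValueError(
            f"need at least {slope_window_points} readings, got {n}"
        )
    w = slope_window_points
    best_slope, best_i = -np.inf, 0
    for i in range(n - w + 1):
        x = t[i : i + w]
        y = v[i : i + w]
        xm, ym = x.mean(), y.mean()
        slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
        if slope > best_slope:
            best_slope, best_i = slope, i
    auc = float(np.trapezoid(v, t))
    return GrowthMetrics(
        vmax=best_slope,
        auc=auc,
        vmax_window=(float(t[best_i]), float(t[best_i + w - 1])),
    )


def relative_fitness(c: CompetitionCount) -> float:
    """Relative fitness of the untagged competitor.

    ``w = ln(Nf,untagged / Ni,untagged) / ln(Nf,tagged / Ni,tagged)``.
    All four counts must be positive and the tagged reference must have
    grown (or shrunk): equal initial and final tagged counts make the
    denominator zero.
    """
    counts = (
        c.n_initial_untagged,
        c.n_final_untagged,
        c.n_initial_tagged,
        c.n_final_tagged,
    )
    if any(x <= 0 for x in counts):
        raise ValueError("fitness undefined: all four counts must be > 0")
    denom = np.log(c.n_final_tagged / c.n_initial_tagged)
    if denom == 0.0:
        raise ValueError("reference did not grow: tagged final equals tagged initial")
    return float(np.log(c.n_final_untagged / c.n_initial_untagged) / denom)


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles for a target gene and the housekeeping reference
    in one strain/condition."""

    condition: str
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def fold_change_ddct(sample: CtRecord, control: CtRecord) -> float:
    """Relative expression by the threshold-cycle method: ``2**(-ddCt)``
    with ``ddCt = dCt(sample) - dCt(control)`` and
    ``dCt = Ct(target) - Ct(reference)``."""
    if (
        sample.target_gene != control.target_gene
        or sample.reference_gene != control.reference_gene
    ):
        raise ValueError("sample and control records measure different genes")
    return float(2.0 ** (-(sample.delta_ct - control.delta_ct)))


def survival_summary(
    k: KillCurve, detection_limit_cfu_per_ml: float = 10.0
) -> pd.DataFrame:
    """Per-timepoint survival fractions and log10 reductions.

    ``fraction = cfu_t / cfu_0`` per replicate; ``log10_reduction =
    -log10(fraction)``.  A replicate hitting zero CFU is censored at the
    plating detection limit: its reduction is reported as
    ``log10(cfu_0 / detection_limit)`` with ``censored=True`` (the true
    reduction is at least this).  Returns one row per (timepoint,
    replicate) plus replicate mean ± sd columns merged per timepoint.
    """
    t = k.timepoints_h
    c = k.cfu_per_ml
    if np.any(c[:, 0] <= 0):
        raise ValueError("zero CFU at t0: survival fractions undefined")
    rows = []
    for r in range(c.shape[0]):
        c0 = c[r, 0]
        for j in range(t.size):
            if c[r, j] > 0:
                frac = c[r, j] / c0
                red = -np.log10(frac)
                cens = False
            else:
                frac = 0.0
                red = np.log10(c0 / detection_limit_cfu_per_ml)
                cens = True
            rows.append(
                {
                    "time_h": t[j],
                    "replicate": r,
                    "fraction": frac,
                    "log10_reduction": red,
                    "censored": cens,
                }
            )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("time_h")["log10_reduction"]
        .agg(mean_log10_reduction="mean", sd_log10_reduction="std")
        .reset_index()
    )
    return df.merge(agg, on="time_h")


def event_frequency(
    selected_count: int, total_count: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Frequency of selected events (e.g. transformants over total CFU)
    with an exact (Clopper–Pearson) binomial confidence interval.

    Returns ``(frequency, ci_low, ci_high)``.  With zero selected events
    the frequency is 0 and the interval is one-sided from 0.
    """
    if total_count <= 0:
        raise ValueError("total_count must be > 0")
    if not 0 <= selected_count <= total_count:
        raise ValueError("selected_count must be in [0, total_count]")
    lo, hi = proportion_confint(selected_count, total_count, alpha=alpha, method="beta")
    lo = 0.0 if selected_count == 0 else float(lo)
    return selected_count / total_count, lo, float(hi)


@dataclass(frozen=True)
class EndpointTest:
    test: str  # "t" or "anova"
    statistic: float
    pvalue: float
    pvalue_adjusted: float | None = None


def endpoint_compare(groups: list[np.ndarray]) -> EndpointTest:
    """Compare endpoint replicate measurements across groups.

    Two groups: unpaired two-sided t-test (equal variances).  Three or
    more: one-way ANOVA.  Groups with identical values throughout give a
    degenerate variance and are rejected.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("need at least two replicates per group")
    pooled_var = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    if pooled_var == 0.0:
        means = {float(g.mean()) for g in gs}
        if len(means) == 1:
            # all observations identical: no evidence of difference
            return EndpointTest("t" if len(gs) == 2 else "anova", 0.0, 1.0)
        raise ValueError("degenerate within-group variance")
    if len(gs) == 2:
        res = stats.ttest_ind(gs[0], gs[1], equal_var=True)
        return EndpointTest("t", float(res.statistic), float(res.pvalue))
    res = stats.f_oneway(*gs)
    return EndpointTest("anova", float(res.statistic), float(res.pvalue))


def endpoint_compare_batch(batches: list[list[np.ndarray]]) -> list[EndpointTest]:
    """Run :func:`endpoint_compare` on many endpoints and attach
    Benjamini–Hochberg adjusted p-values."""
    tests = [endpoint_compare(groups) for groups in batches]
    if not tests:
        return []
    _, p_adj, _, _ = multipletests([t.pvalue for t in tests], method="fdr_bh")
    return [
        EndpointTest(t.test, t.statistic, t.pvalue, float(p))
        for t, p in zip(tests, p_adj)
    ]
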
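"""Time-course proportion estimation and reference-timepoint comparisons.

Per-cell phenotype labels are aggregated into per-timepoint counts and
percentages; the counting floor (at least 500 cells scored per
timepoint) is checked and under-powered points are flagged rather than
dropped.  Uncertainty on a single proportion uses the Wilson score
interval.  Timepoints are compared to a chosen reference (AP for the
starvation arm, Q for the re-supplementation arm) with two-sample
t-tests on donor-level percentages, Bonferroni-corrected over the family
of non-reference timepoints, and starred with the usual
0.05 / 0.01 / 0.001 convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .phenotypes import ALL_STATES, STRESS_STATES, Phenotype

MIN_CELLS = 500

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclasses.dataclass
class TimecoursePoint:
    """Phenotype counts for one timepoint."""

    label: str
    counts: dict[Phenotype, int]
    n_fields: int = 1

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def underpowered(self) -> bool:
        return self.n_total < MIN_CELLS

    def percentage(self, phenotype: Phenotype) -> float:
        return 100.0 * self.counts.get(phenotype, 0) / self.n_total

    def percentages(self) -> dict[Phenotype, float]:
        return {s: self.percentage(s) for s in ALL_STATES}

    @property
    def sa_b_gal_positive_pct(self) -> float:
        """Percentage in any SA-β-gal-positive state."""
        return sum(self.percentage(s) for s in STRESS_STATES)


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    reference: str
    target: str
    phenotype: Phenotype
    statistic: float
    p_raw: float
    p_adj: float
    stars: str


@dataclasses.dataclass(frozen=True)
class MinCellsVerdict:
    label: str
    n_total: int
    passed: bool
    shortfall: int


def estimate_proportions(
    cells: pd.DataFrame,
    group_by: str = "timepoint",
    phenotype_col: str = "phenotype",
) -> list[TimecoursePoint]:
    """Aggregate a classified per-cell table into per-timepoint counts."""
    if group_by not in cells.columns or phenotype_col not in cells.columns:
        raise ValueError(f"table must carry {group_by!r} and {phenotype_col!r} columns")
    points = []
    for label, group in cells.groupby(group_by, sort=False):
        if len(group) == 0:
            raise ValueError(f"timepoint {label!r} has no cells")
        observed = group[phenotype_col].value_counts()
        counts = {s: int(observed.get(s.value, observed.get(s, 0))) for s in ALL_STATES}
        n_fields = group["field_id"].nunique() if "field_id" in group else 1
        points.append(TimecoursePoint(label=str(label), counts=counts, n_fields=n_fields))
    if not points:
        raise ValueError("empty per-cell table")
    return points


def proportion_ci(count: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 <= count <= n or n < 1:
        raise ValueError("need 0 <= count <= n with n >= 1")
    lo, hi = proportion_confint(count, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def stars_for(p_adj: float) -> str:
    for threshold, symbol in STAR_THRESHOLDS:
        if p_adj < threshold:
            return symbol
    return "ns"


def compare_to_reference(
    points: pd.DataFrame,
    reference: str,
    phenotype: Phenotype,
    *,
    value_col: str = "percentage",
    anova_gate: bool = False,
) -> list[ComparisonResult]:
    """Compare each timepoint to a reference on donor-level percentages.

    ``points`` carries one row per (timepoint, donor) with the phenotype
    percentage in ``value_col``; columns ``timepoint`` and ``donor`` are
    required.  Each non-reference timepoint is tested against the
    reference with a pooled-variance two-sample t-test; Bonferroni
    correction spans the family of non-reference timepoints.  With
    ``anova_gate=True`` pairwise tests are only starred when the omnibus
    one-way ANOVA across timepoints is itself significant at 0.05.
    """
    required = {"timepoint", "donor", value_col}
    if not required.issubset(points.columns):
        raise ValueError(f"points table must carry columns {sorted(required)}")
    labels = list(dict.fromkeys(points["timepoint"]))
    if reference not in labels:
        raise ValueError(f"reference timepoint {reference!r} not present")
    groups = {lab: points.loc[points["timepoint"] == lab, value_col].to_numpy()
              for lab in labels}
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"timepoint {lab!r} has a single replicate; need >= 2 donors"
            )

    gate_open = True
    if anova_gate:
        gate_open = sps.f_oneway(*groups.values()).pvalue < 0.05

    targets = [lab for lab in labels if lab != reference]
    m = len(targets)
    results = []
    for lab in targets:
        t_res = sps.ttest_ind(groups[lab], groups[reference], equal_var=True)
        p_raw = float(t_res.pvalue)
        p_adj = min(1.0, m * p_raw)
        results.append(
            ComparisonResult(
                reference=reference,
                target=lab,
                phenotype=phenotype,
                statistic=float(t_res.statistic),
                p_raw=p_raw,
                p_adj=p_adj,
                stars=stars_for(p_adj) if gate_open else "ns",
            )
        )
    return results


def check_min_cells(point: TimecoursePoint) -> MinCellsVerdict:
    """Verdict on the >=500-cells counting rule for one timepoint."""
    n = point.n_total
    return MinCellsVerdict(
        label=point.label,
        n_total=n,
        passed=n >= MIN_CELLS,
        shortfall=max(0, MIN_CELLS - n),
    )


def timecourse_table(points: list[TimecoursePoint], level: float = 0.95) -> pd.DataFrame:
    """Long-format report: one row per (timepoint, phenotype) with CI."""
    rows = []
    for point in points:
        for state in ALL_STATES:
            count = point.counts.get(state, 0)
            lo, hi = proportion_ci(count, point.n_total, level)
            rows.append(
                {
                    "timepoint": point.label,
                    "phenotype": state.value,
                    "count": count,
                    "n_total": point.n_total,
                    "percentage": point.percentage(state),
                    "ci_low_pct": 100 * lo,
                    "ci_high_pct": 100 * hi,
                    "underpowered": point.underpowered,
                }
            )
    return pd.DataFrame(rows)


def plot_timecourse(points: list[TimecoursePoint], phenotypes=None, ax=None):
    """Line plot of phenotype percentages along the time course."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    phenotypes = phenotypes or ALL_STATES
    labels = [p.label for p in points]
    for state in phenotypes:
        values = [p.percentage(state) for p in points]
        if max(values) > 0:
            ax.plot(labels, values, marker="o", label=state.value)
    ax.set_ylabel("% of scored cells")
    ax.set_xlabel("timepoint")
    ax.legend(fontsize=8)
    return ax
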
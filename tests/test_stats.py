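"""Proportion estimation, Wilson intervals, reference comparisons, counting rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from quiescore.phenotypes import ALL_STATES, Phenotype
from quiescore.stats import (
    TimecoursePoint,
    check_min_cells,
    compare_to_reference,
    estimate_proportions,
    proportion_ci,
    stars_for,
    timecourse_table,
)


def _point(label="AP", **counts):
    full = dict.fromkeys(ALL_STATES, 0)
    for k, v in counts.items():
        full[Phenotype[k]] = v
    return TimecoursePoint(label=label, counts=full)


def test_sa_b_gal_positive_percentage_arithmetic():
    point = _point(STRESSED=200, PRE_SENESCENT=50, SENESCENT=20, CYCLING=230)
    assert point.n_total == 500
    assert point.sa_b_gal_positive_pct == pytest.approx(54.0)


def test_single_phenotype_gives_100_percent():
    point = _point(G0=400)
    assert point.percentage(Phenotype.G0) == 100.0
    assert all(
        point.percentage(s) == 0.0 for s in ALL_STATES if s is not Phenotype.G0
    )


def test_percentages_sum_to_100_per_timepoint():
    cells = pd.DataFrame(
        {
            "timepoint": ["AP"] * 600 + ["Q"] * 700,
            "phenotype": (
                ["cycling"] * 300 + ["g0"] * 300 + ["g0"] * 400 + ["g0_alert"] * 300
            ),
        }
    )
    points = estimate_proportions(cells)
    for point in points:
        assert sum(point.percentages().values()) == pytest.approx(100.0)
    report = timecourse_table(points)
    assert report.groupby("timepoint")["percentage"].sum().round(9).eq(100.0).all()


def test_estimate_proportions_rejects_empty_or_malformed_input():
    with pytest.raises(ValueError):
        estimate_proportions(pd.DataFrame({"timepoint": [], "phenotype": []}))
    with pytest.raises(ValueError):
        estimate_proportions(pd.DataFrame({"phenotype": ["g0"]}))


def _wilson_by_inversion(count, n, level):
    """Independent oracle: invert the score test numerically."""
    phat = count / n
    z = sps.norm.ppf(0.5 + level / 2)

    def score(p, sign):
        return (phat - p) / np.sqrt(p * (1 - p) / n) - sign * z

    lo = 0.0 if count == 0 else optimize.brentq(score, 1e-12, phat, args=(1,))
    hi = 1.0 if count == n else optimize.brentq(score, phat, 1 - 1e-12, args=(-1,))
    return lo, hi


@pytest.mark.parametrize("count,n", [(240, 500), (1, 50), (499, 500), (270, 500)])
def test_wilson_interval_matches_score_test_inversion(count, n):
    got = proportion_ci(count, n, 0.95)
    want = _wilson_by_inversion(count, n, 0.95)
    assert got == pytest.approx(want, abs=1e-6)


def test_wilson_interval_edge_cases_and_monotonicity():
    lo, hi = proportion_ci(0, 100)
    assert lo == pytest.approx(0.0, abs=1e-12) and hi > 0.0
    lo, hi = proportion_ci(100, 100)
    assert hi == pytest.approx(1.0, abs=1e-12)
    w_small = np.diff(proportion_ci(30, 100))
    w_large = np.diff(proportion_ci(300, 1000))
    assert w_large < w_small
    with pytest.raises(ValueError):
        proportion_ci(5, 4)


def _replicates(values_by_tp):
    rows = [
        {"timepoint": tp, "donor": i, "percentage": v}
        for tp, values in values_by_tp.items()
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


def test_t_statistic_matches_pooled_variance_formula():
    ref, tgt = [10.0, 12.0, 11.0], [15.0, 14.0, 16.0]
    points = _replicates({"AP": ref, "Q": tgt})
    (res,) = compare_to_reference(points, "AP", Phenotype.G0)
    m1, m2 = np.mean(tgt), np.mean(ref)
    sp2 = (np.var(tgt, ddof=1) * 2 + np.var(ref, ddof=1) * 2) / 4
    t_hand = (m1 - m2) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)


def test_identical_groups_are_not_significant():
    points = _replicates({"AP": [10.0, 12.0, 14.0], "Q": [10.0, 12.0, 14.0]})
    (res,) = compare_to_reference(points, "AP", Phenotype.CYCLING)
    assert res.p_raw == pytest.approx(1.0)
    assert res.stars == "ns"


def test_bonferroni_adjustment_and_stars():
    values = {
        "AP": [40.0, 42.0, 41.0],
        "S1": [30.0, 31.0, 29.0],
        "S2": [20.0, 21.0, 19.5],
        "S3": [10.0, 11.0, 9.0],
        "Q": [2.0, 3.0, 2.5],
    }
    results = compare_to_reference(_replicates(values), "AP", Phenotype.CYCLING)
    assert len(results) == 4  # family = non-reference timepoints
    for res in results:
        assert res.p_adj >= res.p_raw
        assert res.p_adj == pytest.approx(min(1.0, 4 * res.p_raw))
        assert res.stars == stars_for(res.p_adj)


def test_star_thresholds_follow_the_caption_convention():
    assert stars_for(0.04) == "*"
    assert stars_for(0.009) == "**"
    assert stars_for(0.0009) == "***"
    assert stars_for(0.05) == "ns"  # strict inequality


def test_single_replicate_raises_naming_the_timepoint():
    points = _replicates({"AP": [40.0, 41.0], "Q": [3.0]})
    with pytest.raises(ValueError, match="Q"):
        compare_to_reference(points, "AP", Phenotype.CYCLING)


def test_missing_reference_raises():
    points = _replicates({"Q": [1.0, 2.0], "T1": [3.0, 4.0]})
    with pytest.raises(ValueError, match="AP"):
        compare_to_reference(points, "AP", Phenotype.CYCLING)


@pytest.mark.parametrize(
    "n,passed,shortfall", [(500, True, 0), (499, False, 1), (0, False, 500)]
)
def test_minimum_cell_counting_rule(n, passed, shortfall):
    point = _point(G0=n)
    verdict = check_min_cells(point)
    assert verdict.passed is passed
    assert verdict.shortfall == shortfall
    assert point.underpowered is (not passed)
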
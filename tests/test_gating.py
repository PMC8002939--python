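"""Mixture gating: threshold placement, degeneracy, calls and monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from quiescore.gating import (
    GateModel,
    GatingError,
    GatingMethod,
    InputSchemaError,
    apply_gates,
    fit_gate,
    fit_gate_with_fallback,
    robust_fence_gate,
)
from quiescore.phenotypes import marker_truth, Phenotype
from quiescore.pipeline import fit_gates


def _mixture_sample(rng, n, locs, scales, weights):
    comp = rng.random(n) < weights[1]
    log_x = np.where(
        comp, rng.normal(locs[1], scales[1], n), rng.normal(locs[0], scales[0], n)
    )
    return np.exp(log_x)


def _grid_equal_density_point(locs, scales, weights):
    """Independent oracle: equal-weighted-density point by brute-force grid."""
    grid = np.linspace(locs[0], locs[1], 20001)
    d0 = weights[0] * sps.norm.pdf(grid, locs[0], scales[0])
    d1 = weights[1] * sps.norm.pdf(grid, locs[1], scales[1])
    return grid[np.argmin(np.abs(d0 - d1))]


def test_symmetric_mixture_thresholds_at_midpoint(rng):
    x = _mixture_sample(rng, 4000, (1.0, 3.0), (0.3, 0.3), (0.5, 0.5))
    gate = fit_gate(x, "ki67")
    assert gate.method is GatingMethod.TWO_COMPONENT_MIXTURE
    assert np.log(gate.threshold) == pytest.approx(2.0, abs=0.1)


def test_threshold_matches_grid_search_oracle(rng):
    locs, scales, weights = (1.0, 3.2), (0.40, 0.30), (0.3, 0.7)
    x = _mixture_sample(rng, 20000, locs, scales, weights)
    gate = fit_gate(x, "prps6")
    oracle = _grid_equal_density_point(locs, scales, weights)
    assert np.log(gate.threshold) == pytest.approx(oracle, abs=0.1)
    mp = gate.mix_params
    assert mp.weight_neg + mp.weight_pos == pytest.approx(1.0, abs=1e-9)
    assert mp.loc_neg < np.log(gate.threshold) < mp.loc_pos


def test_single_population_raises_gating_failure(rng):
    x = np.exp(rng.normal(2.0, 0.3, 1000))
    with pytest.raises(GatingError):
        fit_gate(np.concatenate([x, x]), "sabgal")


def test_fallback_fence_calls_almost_nothing_positive(rng):
    x = np.exp(rng.normal(2.0, 0.3, 2000))
    gate = fit_gate_with_fallback(x, "sabgal")
    assert gate.method is GatingMethod.FIXED
    assert gate.call(x).mean() < 0.01


def test_quantile_and_fixed_methods(rng):
    x = np.exp(rng.normal(2.0, 0.3, 200))
    q_gate = fit_gate(x, "ki67", method=GatingMethod.QUANTILE, quantile=0.5)
    assert q_gate.threshold == pytest.approx(np.median(x))
    f_gate = fit_gate(x, "ki67", method=GatingMethod.FIXED, threshold=5.0)
    assert f_gate.threshold == 5.0


def test_gate_requires_enough_positive_intensities(rng):
    with pytest.raises(ValueError):
        fit_gate(np.ones(10), "ki67")
    bad = np.exp(rng.normal(2.0, 0.3, 100))
    bad[0] = -1.0
    with pytest.raises(ValueError):
        fit_gate(bad, "ki67")


def test_tie_at_threshold_calls_negative():
    gate = GateModel(marker="ki67", threshold=10.0, method=GatingMethod.FIXED)
    calls = gate.call([9.999, 10.0, 10.001])
    assert list(calls) == [False, False, True]


def test_apply_gates_alignment_and_schema():
    cells = pd.DataFrame(
        {
            "ki67_intensity": [100.0, 1.0],
            "prps6_intensity": [100.0, 1.0],
            "sabgal_intensity": [100.0, 1.0],
        },
        index=[7, 3],
    )
    gates = {
        m: GateModel(marker=m, threshold=10.0, method=GatingMethod.FIXED)
        for m in ("ki67", "prps6", "sabgal")
    }
    profiles = apply_gates(cells, gates)
    assert list(profiles.index) == [7, 3]
    assert profiles.loc[7].tolist() == [True, True, True]
    assert profiles.loc[3].tolist() == [False, False, False]
    with pytest.raises(InputSchemaError):
        apply_gates(cells.drop(columns=["prps6_intensity"]), gates)


def test_calls_match_generator_truth_on_separated_populations(sen3_cells):
    gates = fit_gates(sen3_cells)
    profiles = apply_gates(sen3_cells, gates)
    truth = [
        marker_truth(Phenotype(s), sub or None)
        for s, sub in zip(sen3_cells["truth_state"], sen3_cells["truth_subcode"])
    ]
    for col, attr in (("ki67", "ki67"), ("prps6", "prps6"), ("sa_b_gal", "sa_b_gal")):
        expected = np.array([getattr(t, attr) for t in truth])
        agreement = (profiles[col].to_numpy() == expected).mean()
        assert agreement >= 0.99, f"{col} call agreement {agreement:.3f}"


@settings(max_examples=50, derandomize=True)
@given(
    threshold=st.floats(0.5, 100.0),
    values=st.lists(st.floats(0.01, 1000.0), min_size=2, max_size=20),
)
def test_gating_is_monotone_in_intensity(threshold, values):
    """Raising a cell's intensity never flips a positive call to negative."""
    gate = GateModel(marker="ki67", threshold=threshold, method=GatingMethod.FIXED)
    x = np.sort(np.asarray(values))
    calls = gate.call(x).astype(int)
    assert np.all(np.diff(calls) >= 0)


def test_robust_fence_scales_with_population_location(rng):
    x = np.exp(rng.normal(2.0, 0.3, 1000))
    g1 = robust_fence_gate(x, "sabgal")
    g2 = robust_fence_gate(x * 10, "sabgal")
    assert np.log(g2.threshold) - np.log(g1.threshold) == pytest.approx(
        np.log(10), abs=0.05
    )
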
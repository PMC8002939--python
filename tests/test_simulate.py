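"""State sampling, intensity emission and experiment-bundle generation."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from quiescore.phenotypes import Phenotype, marker_truth
from quiescore.presets import build_preset
from quiescore.simulate import (
    ValidationError,
    generate_experiment,
    sample_intensities,
    sample_states,
)


def test_sampled_g0_fraction_matches_preset_within_3_se():
    preset = build_preset("Q")
    n = 100_000
    states = sample_states(preset, n, seed=5)
    frac = sum(s is Phenotype.G0 for s in states) / n
    p = preset.state_props[Phenotype.G0]
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_degenerate_preset_yields_single_state():
    import dataclasses

    preset = build_preset("AP")
    props = dict.fromkeys(preset.state_props, 0.0)
    props[Phenotype.CYCLING] = 1.0
    pure = dataclasses.replace(preset, state_props=props)
    states = sample_states(pure, 500, seed=0)
    assert all(s is Phenotype.CYCLING for s in states)


def test_sampling_is_reproducible_for_a_fixed_seed():
    preset = build_preset("SEN2")
    assert sample_states(preset, 1000, seed=42) == sample_states(preset, 1000, seed=42)
    states = sample_states(preset, 200, seed=1)
    t1 = sample_intensities(states, preset, seed=9)
    t2 = sample_intensities(states, preset, seed=9)
    assert t1.equals(t2)


def test_zero_noise_intensities_sit_exactly_at_component_locations():
    preset = build_preset("Q")
    params = preset.intensity_params
    table = sample_intensities(
        [Phenotype.G0, Phenotype.CYCLING], preset, seed=0, zero_noise=True
    )
    # quiescent: all three markers at the negative location
    g0 = table.iloc[0]
    for marker in ("ki67", "prps6", "sabgal"):
        assert g0[f"{marker}_intensity"] == pytest.approx(
            np.exp(params.for_marker(marker).neg_loc)
        )
    # cycling: Ki67 and pRPS6 positive, SA-β-gal negative
    cyc = table.iloc[1]
    assert cyc["ki67_intensity"] == pytest.approx(np.exp(params.ki67.pos_loc))
    assert cyc["prps6_intensity"] == pytest.approx(np.exp(params.prps6.pos_loc))
    assert cyc["sabgal_intensity"] == pytest.approx(np.exp(params.sabgal.neg_loc))


def test_presenescent_cells_split_between_the_two_marker_routes():
    preset = build_preset("SEN5")
    states = [Phenotype.PRE_SENESCENT] * 2000
    table = sample_intensities(states, preset, seed=3)
    subcodes = set(table["truth_subcode"])
    assert subcodes == {"early", "late_entry"}
    # early route emits positive Ki67, late-entry negative
    early = table[table["truth_subcode"] == "early"]
    late = table[table["truth_subcode"] == "late_entry"]
    assert early["ki67_intensity"].median() > late["ki67_intensity"].median() * 3


def test_truth_states_match_marker_populations(sen3_cells, sen3_preset):
    """Each state's median intensities sit at the populations its row implies."""
    params = sen3_preset.intensity_params
    for state_value, group in sen3_cells.groupby("truth_state"):
        if state_value == Phenotype.PRE_SENESCENT.value:
            continue  # mixed Ki67 routes, covered separately
        truth = marker_truth(Phenotype(state_value))
        for marker, positive in zip(
            ("ki67", "prps6", "sabgal"), (truth.ki67, truth.prps6, truth.sa_b_gal)
        ):
            model = params.for_marker(marker)
            expected = model.pos_loc if positive else model.neg_loc
            observed = np.log(group[f"{marker}_intensity"]).median()
            assert observed == pytest.approx(expected, abs=3 * model.log_scale)


def test_experiment_rosters_and_counting_floor(tmp_path):
    with pytest.raises(ValidationError, match="500"):
        generate_experiment("starvation", n_cells_per_timepoint=499, seed=0)
    bundle = generate_experiment(
        "stress", n_cells_per_timepoint=120, seed=0, allow_undersized=True
    )
    assert list(bundle.cells) == ["AP", "SEN1", "SEN2", "SEN3", "SEN4", "SEN5"]
    assert bundle.manifest["timepoints"] == list(bundle.cells)


def _bundle_hashes(outdir: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.glob("cells_*.csv"))
    }


def test_fixed_seed_gives_byte_identical_tables(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_experiment("starvation", n_cells_per_timepoint=500, seed=7, outdir=a)
    generate_experiment("starvation", n_cells_per_timepoint=500, seed=7, outdir=b)
    hashes_a, hashes_b = _bundle_hashes(a), _bundle_hashes(b)
    assert len(hashes_a) == 9
    assert hashes_a == hashes_b


def test_timepoint_streams_are_independent_of_bundle_context():
    full = generate_experiment("stress", 500, seed=3)
    # regenerating a single timepoint with its own stream reproduces it
    solo = generate_experiment("stress", 500, seed=3).cells["SEN4"]
    assert full.cells["SEN4"].equals(solo)


def test_rendered_fields_conserve_cell_count(small_layout):
    bundle = generate_experiment(
        "stress",
        n_cells_per_timepoint=40,
        seed=2,
        render_fields=1,
        field_layout=small_layout,
        allow_undersized=True,
    )
    for label, fields in bundle.fields.items():
        assert len(fields) == 1
        n_rendered = min(40, small_layout.max_cells)
        assert len(fields[0].truth) == n_rendered
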
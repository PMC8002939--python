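"""Per-cell synthetic data: ground-truth states, marker intensities, bundles.

Cells are drawn i.i.d. from a preset's state proportions; each cell then
emits log-normal intensities from the negative or positive population of
each marker according to what its state implies (a senescent cell, for
instance, emits positive-population pRPS6 and SA-β-gal and
negative-population Ki67).  Pre-senescent cells split between the early
(Ki67+) and late-entry (Ki67−) routes.

``generate_experiment`` assembles the full desk-scale experiment: one
per-cell table, one DNA-content event list and (optionally) rendered
pseudo-micrograph fields per timepoint of a design, with a manifest.
Seeding is hierarchical — one master seed, per-timepoint streams derived
by fixed offsets — so any timepoint is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dna import simulate_dna_events
from .phenotypes import (
    ALL_STATES,
    PRESEN_EARLY,
    PRESEN_LATE_ENTRY,
    Phenotype,
    marker_truth,
)
from .presets import ConditionPreset, Design, build_preset, design_timepoints
from .render import FieldImage, FieldLayout, render_field

#: Counting floor: phenotype percentages are only considered adequately
#: powered when scored on at least this many cells per timepoint.
MIN_CELLS_PER_TIMEPOINT = 500

CELL_TABLE_COLUMNS = (
    "cell_id",
    "field_id",
    "ki67_intensity",
    "prps6_intensity",
    "sabgal_intensity",
    "dapi_intensity",
    "truth_state",
    "truth_subcode",
)


class ValidationError(ValueError):
    """Configuration violates a documented constraint."""


def sample_states(preset: ConditionPreset, n_cells: int, seed) -> list[Phenotype]:
    """Draw i.i.d. ground-truth states from the preset's proportions."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([preset.state_props[s] for s in ALL_STATES])
    idx = rng.choice(len(ALL_STATES), size=n_cells, p=probs / probs.sum())
    return [ALL_STATES[i] for i in idx]


def sample_intensities(
    states: list[Phenotype],
    preset: ConditionPreset,
    seed,
    *,
    cells_per_field: int = 250,
    zero_noise: bool = False,
    presen_early_prob: float = 0.5,
) -> pd.DataFrame:
    """Emit the per-cell intensity table for a list of ground-truth states.

    Each marker intensity is log-normal around the location its state
    implies; ``zero_noise=True`` collapses every draw onto the component
    location exactly (useful for degenerate-case tests).  Cells are
    assigned to fields in chunks of ``cells_per_field``.
    """
    if not states:
        raise ValueError("states must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(states)
    params = preset.intensity_params

    subcodes = np.where(
        np.array([s is Phenotype.PRE_SENESCENT for s in states]),
        np.where(
            rng.random(n) < presen_early_prob, PRESEN_EARLY, PRESEN_LATE_ENTRY
        ),
        None,
    )

    rows: dict[str, np.ndarray] = {
        "cell_id": np.arange(n),
        "field_id": np.arange(n) // cells_per_field,
    }
    for marker in ("ki67", "prps6", "sabgal"):
        model = params.for_marker(marker)
        positive = np.array(
            [
                getattr(
                    marker_truth(s, subcodes[i]),
                    {"ki67": "ki67", "prps6": "prps6", "sabgal": "sa_b_gal"}[marker],
                )
                for i, s in enumerate(states)
            ]
        )
        loc = np.where(positive, model.pos_loc, model.neg_loc)
        scale = 0.0 if zero_noise else model.log_scale
        rows[f"{marker}_intensity"] = np.exp(rng.normal(loc, scale))
    dapi_scale = 0.0 if zero_noise else params.dapi_scale
    rows["dapi_intensity"] = np.exp(rng.normal(params.dapi_loc, dapi_scale, n))
    rows["truth_state"] = np.array([s.value for s in states])
    rows["truth_subcode"] = np.array(["" if c is None else c for c in subcodes])
    return pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS))


def simulate_timepoint(
    label: str,
    n_cells: int,
    seed,
    *,
    preset: ConditionPreset | None = None,
    **intensity_kwargs,
) -> pd.DataFrame:
    """Sample states then intensities for one timepoint (one rng stream)."""
    preset = preset or build_preset(label)
    states = sample_states(preset, n_cells, seed)
    # distinct child stream so state and intensity draws do not interleave
    return sample_intensities(states, preset, [seed, 1], **intensity_kwargs)


@dataclasses.dataclass
class ExperimentBundle:
    """In-memory result of one simulated experiment."""

    design: Design
    seed: int
    cells: dict[str, pd.DataFrame]
    dna_events: dict[str, np.ndarray]
    fields: dict[str, list[FieldImage]]
    manifest: dict


def _timepoint_seed(master_seed: int, index: int) -> list[int]:
    # fixed-offset child streams: independent and individually reproducible
    return [int(master_seed), 7919 * (index + 1)]


def generate_experiment(
    design: Design | str,
    n_cells_per_timepoint: int = 2000,
    seed: int = 0,
    *,
    outdir: str | Path | None = None,
    n_dna_events: int = 5000,
    dna_cv: float = 0.05,
    render_fields: int = 0,
    field_layout: FieldLayout | None = None,
    allow_undersized: bool = False,
) -> ExperimentBundle:
    """Simulate a full design: tables, DNA events and optional fields.

    Enforces the >=500-cells-per-timepoint counting floor unless
    ``allow_undersized`` is set.  With ``outdir`` given, the bundle is
    written to disk (CSV tables, per-field multi-page TIFF + truth JSON,
    manifest JSON); tables are byte-stable for a fixed seed.
    """
    design = Design(design)
    if n_cells_per_timepoint < MIN_CELLS_PER_TIMEPOINT and not allow_undersized:
        raise ValidationError(
            f"{n_cells_per_timepoint} cells/timepoint is below the counting "
            f"floor of {MIN_CELLS_PER_TIMEPOINT} cells scored per timepoint; "
            "pass allow_undersized=True to override"
        )
    cells: dict[str, pd.DataFrame] = {}
    dna_events: dict[str, np.ndarray] = {}
    fields: dict[str, list[FieldImage]] = {}
    for i, label in enumerate(design_timepoints(design)):
        preset = build_preset(label)
        tp_seed = _timepoint_seed(seed, i)
        table = simulate_timepoint(label, n_cells_per_timepoint, tp_seed, preset=preset)
        cells[label] = table
        dna_events[label] = simulate_dna_events(
            preset.cycle_fractions, n_dna_events, dna_cv, tp_seed + [2]
        )
        field_list: list[FieldImage] = []
        if render_fields > 0:
            layout = field_layout or FieldLayout()
            for j in range(render_fields):
                sub = table[table["field_id"] == j]
                sub = sub.iloc[: layout.max_cells]
                if len(sub) == 0:
                    break
                field_list.append(render_field(sub, layout, seed=tp_seed + [3, j]))
        fields[label] = field_list

    manifest = {
        "package_version": __version__,
        "design": design.value,
        "seed": int(seed),
        "n_cells_per_timepoint": int(n_cells_per_timepoint),
        "n_dna_events": int(n_dna_events),
        "dna_cv": float(dna_cv),
        "timepoints": list(design_timepoints(design)),
        "render_fields": int(render_fields),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()

    bundle = ExperimentBundle(
        design=design,
        seed=seed,
        cells=cells,
        dna_events=dna_events,
        fields=fields,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ExperimentBundle, outdir: str | Path) -> None:
    """Write an experiment bundle to disk in the documented layout."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, list[str]] = {}
    for label, table in bundle.cells.items():
        cells_path = outdir / f"cells_{label}.csv"
        table.to_csv(cells_path, index=False, float_format="%.6f")
        dna_path = outdir / f"dna_{label}.csv"
        pd.DataFrame({"dna_content": bundle.dna_events[label]}).to_csv(
            dna_path, index=False, float_format="%.6f"
        )
        tp_files = [cells_path.name, dna_path.name]
        for j, field in enumerate(bundle.fields.get(label, [])):
            tiff_path = outdir / f"field_{label}_{j}.tiff"
            tifffile.imwrite(
                tiff_path, field.channels.astype(np.float32),
                photometric="minisblack",
            )
            truth_path = outdir / f"field_{label}_{j}.truth.json"
            truth_path.write_text(json.dumps(field.truth_as_json(), indent=1))
            tp_files += [tiff_path.name, truth_path.name]
        files[label] = tp_files
    manifest = dict(bundle.manifest)
    manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
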
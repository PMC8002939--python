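"""End-to-end helpers: gate → classify → count on tables or presets.

These functions wire the module surfaces together the way the command
line and the reproduction script use them: fit one gate per marker on a
per-cell table (mixture gating with robust-fence fallback for unimodal
markers), call every cell, classify the triples, and aggregate.
"""

from __future__ import annotations

import pandas as pd

from .gating import (
    MARKERS,
    GateModel,
    GatingMethod,
    apply_gates,
    fit_gate,
    fit_gate_with_fallback,
)
from .phenotypes import classify_profile, MarkerProfile
from .presets import build_preset
from .simulate import simulate_timepoint
from .stats import TimecoursePoint, estimate_proportions


def fit_gates(
    cells: pd.DataFrame,
    method: GatingMethod = GatingMethod.TWO_COMPONENT_MIXTURE,
    **kwargs,
) -> dict[str, GateModel]:
    """Fit one gate per marker on a per-cell table.

    Mixture gating falls back to the robust negative-control fence for
    markers whose intensity distribution is unimodal (no positive
    population present); other methods are passed through as-is.
    """
    gates = {}
    for marker in MARKERS:
        intensities = cells[f"{marker}_intensity"].to_numpy()
        if method is GatingMethod.TWO_COMPONENT_MIXTURE:
            gates[marker] = fit_gate_with_fallback(intensities, marker, **kwargs)
        else:
            gates[marker] = fit_gate(intensities, marker, method=method, **kwargs)
    return gates


def classify_cells(
    cells: pd.DataFrame,
    gates: dict[str, GateModel] | None = None,
    with_subcode: bool = False,
) -> pd.DataFrame:
    """Gate and classify every cell; returns the table plus call columns.

    Adds boolean ``ki67/prps6/sa_b_gal`` columns and a ``phenotype``
    column (enum values as strings); ``with_subcode=True`` adds the
    pre-senescent route sub-code.
    """
    gates = gates or fit_gates(cells)
    profiles = apply_gates(cells, gates)
    out = cells.copy()
    for col in profiles.columns:
        out[col] = profiles[col]
    labels = []
    subcodes = []
    for k, r, b in zip(profiles["ki67"], profiles["prps6"], profiles["sa_b_gal"]):
        phen, sub = classify_profile(MarkerProfile(k, r, b), with_subcode=True)
        labels.append(phen.value)
        subcodes.append(sub or "")
    out["phenotype"] = labels
    if with_subcode:
        out["phenotype_subcode"] = subcodes
    return out


def run_timepoint(
    label: str, n_cells: int = 2000, seed: int = 1, **simulate_kwargs
) -> TimecoursePoint:
    """Simulate one preset and push it through gate → classify → count."""
    cells = simulate_timepoint(label, n_cells, seed, **simulate_kwargs)
    classified = classify_cells(cells)
    classified["timepoint"] = label
    return estimate_proportions(classified)[0]


def classify_experiment(cells_by_timepoint: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Classify every timepoint table of a bundle into one long table."""
    frames = []
    for label, table in cells_by_timepoint.items():
        classified = classify_cells(table)
        classified["timepoint"] = label
        frames.append(classified)
    return pd.concat(frames, ignore_index=True)
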
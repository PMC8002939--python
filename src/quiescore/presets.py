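"""Built-in experimental-condition presets.

Two designs are modelled, matching serum-starvation/re-supplementation of
bone-marrow mesenchymal stromal cells (MSCs) and an acute oxidative-stress
time course:

* **STARVATION** — asynchronously proliferating cells (AP) are serum
  starved for 36 h (sampled at S1, S2, S3 and the quiescence endpoint Q),
  then serum is re-supplemented for 36 h (sampled at T1, T2, T3 and the
  proliferative endpoint P).
* **STRESS** — proliferating cells (AP) receive a 0.5 h pulse of 300 µM
  H₂O₂ and are sampled at 0.5, 1, 24, 48 and 64 h (SEN1–SEN5).

Each preset carries the ground-truth state proportions, the per-marker
intensity-distribution parameters, and the paired DNA-content cycle
fractions.  Published percentages are anchored exactly; the remaining
probability mass is filled by a deterministic completion rule
(interpolation between the nearest anchored timepoints for that state,
uniform share for states never anchored, rescaled to the unanchored
mass).  Unanchored entries are plausible but are not measured quantities.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .dna import CycleFractions
from .phenotypes import ALL_STATES, HEALTHY_STATES, STRESS_STATES, Phenotype


class Design(str, enum.Enum):
    STARVATION = "starvation"
    STRESS = "stress"


STARVATION_TIMEPOINTS = ("AP", "S1", "S2", "S3", "Q", "T1", "T2", "T3", "P")
STRESS_TIMEPOINTS = ("AP", "SEN1", "SEN2", "SEN3", "SEN4", "SEN5")
ALL_TIMEPOINTS = STARVATION_TIMEPOINTS + STRESS_TIMEPOINTS[1:]


class UnknownTimepointError(ValueError):
    def __init__(self, label: str):
        super().__init__(
            f"unknown timepoint {label!r}; valid labels: {sorted(set(ALL_TIMEPOINTS))}"
        )


@dataclasses.dataclass(frozen=True)
class MarkerIntensityModel:
    """Log-normal negative/positive populations for one marker.

    Locations and scale are on natural-log intensity (arbitrary
    fluorescence / optical-density units).  Defaults give a 2.0-log
    separation at 0.35 log-scale — populations a scorer would call
    cleanly by eye.
    """

    neg_loc: float
    pos_loc: float
    log_scale: float = 0.35


@dataclasses.dataclass(frozen=True)
class IntensityParams:
    ki67: MarkerIntensityModel = MarkerIntensityModel(4.0, 6.0)
    prps6: MarkerIntensityModel = MarkerIntensityModel(4.2, 6.2)
    sabgal: MarkerIntensityModel = MarkerIntensityModel(3.6, 5.6)
    dapi_loc: float = 5.3
    dapi_scale: float = 0.20

    def for_marker(self, marker: str) -> MarkerIntensityModel:
        return getattr(self, marker)


@dataclasses.dataclass(frozen=True)
class ConditionPreset:
    """Ground truth for one experimental timepoint."""

    label: str
    design: Design
    state_props: dict[Phenotype, float]
    intensity_params: IntensityParams
    cycle_fractions: CycleFractions
    schedule_meta: str

    def __post_init__(self) -> None:
        total = sum(self.state_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state proportions sum to {total}, not 1")
        if any(v < 0 for v in self.state_props.values()):
            raise ValueError("state proportions must be non-negative")
        if self.label in STARVATION_TIMEPOINTS:
            for s in STRESS_STATES:
                if self.state_props.get(s, 0.0) != 0.0:
                    raise ValueError(
                        f"healthy-design preset {self.label} has nonzero {s} mass"
                    )
            g0_like = sum(
                self.state_props[s]
                for s in (Phenotype.G0_ENTRY, Phenotype.G0, Phenotype.G0_ALERT)
            )
            if g0_like > self.cycle_fractions.g1_g0 + 1e-9:
                raise ValueError(
                    f"preset {self.label}: G0-entry+G0+G0-alert ({g0_like:.3f}) "
                    f"exceeds the G1/G0 fraction ({self.cycle_fractions.g1_g0:.3f})"
                )

    @property
    def sa_b_gal_positive(self) -> float:
        """Total mass of SA-β-gal-positive states."""
        return sum(self.state_props[s] for s in STRESS_STATES)


# ---------------------------------------------------------------------------
# Anchored (published) state proportions; everything else is completed.
# ---------------------------------------------------------------------------

_HEALTHY_ANCHORS: dict[str, dict[Phenotype, float]] = {
    "AP": {Phenotype.CYCLING: 0.420, Phenotype.G0: 0.160},
    "Q": {Phenotype.CYCLING: 0.027, Phenotype.G0: 0.479, Phenotype.G0_ALERT: 0.133},
    "T1": {Phenotype.G0_ALERT: 0.524},
    "P": {Phenotype.CYCLING: 0.369},
}

# SA-β-gal-positive totals along the stress time course (fractions).
_SABGAL_TOTAL_ANCHORS = {"AP": 0.0, "SEN1": 0.540, "SEN2": 0.300, "SEN5": 0.630}

# Authored split of the SA-β-gal-positive mass (stressed, pre-sen, senescent
# shares): acute stress dominates at first, senescence programs take over by
# 64 h.  Not measured quantities.
_SABGAL_SPLIT = {
    "SEN1": (0.85, 0.10, 0.05),
    "SEN2": (0.70, 0.20, 0.10),
    "SEN3": (0.45, 0.35, 0.20),
    "SEN4": (0.25, 0.45, 0.30),
    "SEN5": (0.10, 0.45, 0.45),
}

# Authored split of the SA-β-gal-negative remainder in the stress design
# (cycling, G0-entry, G0, G0-alert shares).
_STRESS_HEALTHY_SPLIT = (0.55, 0.15, 0.20, 0.10)

# Cycle fractions (g1_g0, s, g2m).  Printed values: AP (0.730, 0.190),
# S1 s=0.043, P s=0.153; S-phase doubles around T3 and collapses at Q.
# The G1/G0 entries at unanchored timepoints are set to respect the
# "G0-like states never exceed the G1/G0 peak" constraint.
_CYCLE_TABLE: dict[str, tuple[float, float, float]] = {
    "AP": (0.730, 0.190, 0.080),
    "S1": (0.880, 0.043, 0.077),
    "S2": (0.910, 0.025, 0.065),
    "S3": (0.930, 0.012, 0.058),
    "Q": (0.978, 0.004, 0.018),
    "T1": (0.950, 0.010, 0.040),
    "T2": (0.940, 0.020, 0.040),
    "T3": (0.900, 0.040, 0.060),
    "P": (0.780, 0.153, 0.067),
    # Stress design: G2/M spikes right after the insult (SEN1), the S
    # fraction dips then transiently recovers (SEN2-3) and falls again.
    "SEN1": (0.620, 0.050, 0.330),
    "SEN2": (0.660, 0.120, 0.220),
    "SEN3": (0.680, 0.140, 0.180),
    "SEN4": (0.720, 0.080, 0.200),
    "SEN5": (0.740, 0.050, 0.210),
}

_SCHEDULE_META = {
    "AP": "asynchronously proliferating MSCs, passage 3, ~70% confluence",
    "S1": "1 h serum starvation (0.1% FBS)",
    "S2": "nominal 6 h serum starvation (0.1% FBS)",
    "S3": "nominal 18 h serum starvation (0.1% FBS)",
    "Q": "36 h serum starvation (0.1% FBS); quiescence endpoint",
    "T1": "1 h after serum re-supplementation (10% FBS)",
    "T2": "nominal 6 h after serum re-supplementation (10% FBS)",
    "T3": "18 h after serum re-supplementation (10% FBS)",
    "P": "36 h after serum re-supplementation (10% FBS)",
    "SEN1": "0.5 h after 300 uM H2O2 (0.5 h pulse)",
    "SEN2": "1 h after 300 uM H2O2 (0.5 h pulse)",
    "SEN3": "24 h after 300 uM H2O2 (0.5 h pulse)",
    "SEN4": "48 h after 300 uM H2O2 (0.5 h pulse)",
    "SEN5": "64 h after 300 uM H2O2 (0.5 h pulse)",
}


def _complete(
    order: tuple[str, ...],
    anchors: dict[str, dict[Phenotype, float]],
    states: tuple[Phenotype, ...],
    label: str,
    total_mass: float = 1.0,
) -> dict[Phenotype, float]:
    """Deterministic completion of a partially anchored proportion vector.

    Anchored values are fixed.  Each unanchored state gets a provisional
    weight by linear interpolation of its anchors over the timepoint index
    (nearest-anchor extrapolation at the ends); a state with no anchor
    anywhere in the design gets the uniform share of the unanchored mass.
    Provisional weights are then rescaled so the vector sums to
    ``total_mass``.
    """
    idx = order.index(label)
    anchored_here = anchors.get(label, {})
    props = {s: anchored_here.get(s) for s in states}
    remaining = total_mass - sum(v for v in props.values() if v is not None)
    if remaining < -1e-9:
        raise ValueError(f"anchors at {label} exceed available mass")
    unanchored = [s for s in states if props[s] is None]
    if not unanchored:
        return {s: float(v) for s, v in props.items()}

    provisional: dict[Phenotype, float | None] = {}
    for s in unanchored:
        xs = [order.index(t) for t in order if s in anchors.get(t, {})]
        ys = [anchors[t][s] for t in order if s in anchors.get(t, {})]
        provisional[s] = float(np.interp(idx, xs, ys)) if xs else None
    uniform_share = remaining / len(unanchored)
    weights = {s: (v if v is not None else uniform_share) for s, v in provisional.items()}
    wsum = sum(weights.values())
    for s in unanchored:
        props[s] = remaining * weights[s] / wsum if wsum > 0 else 0.0
    return {s: float(v) for s, v in props.items()}


def _healthy_props(label: str) -> dict[Phenotype, float]:
    props = dict.fromkeys(ALL_STATES, 0.0)
    props.update(
        _complete(STARVATION_TIMEPOINTS, _HEALTHY_ANCHORS, HEALTHY_STATES, label)
    )
    return props


def _stress_props(label: str) -> dict[Phenotype, float]:
    if label == "AP":
        return _healthy_props("AP")
    xs = [STRESS_TIMEPOINTS.index(t) for t in STRESS_TIMEPOINTS if t in _SABGAL_TOTAL_ANCHORS]
    ys = [_SABGAL_TOTAL_ANCHORS[t] for t in STRESS_TIMEPOINTS if t in _SABGAL_TOTAL_ANCHORS]
    positive_total = float(np.interp(STRESS_TIMEPOINTS.index(label), xs, ys))
    split = _SABGAL_SPLIT[label]
    props = dict.fromkeys(ALL_STATES, 0.0)
    for state, share in zip(STRESS_STATES, split):
        props[state] = positive_total * share
    healthy_total = 1.0 - positive_total
    for state, share in zip(HEALTHY_STATES, _STRESS_HEALTHY_SPLIT):
        props[state] = healthy_total * share
    return props


def build_preset(
    label: str, intensity_params: IntensityParams | None = None
) -> ConditionPreset:
    """Build the built-in preset for one timepoint label.

    ``AP`` belongs to both designs with identical (healthy) composition
    and is returned as a STARVATION preset.
    """
    if label not in _CYCLE_TABLE:
        raise UnknownTimepointError(label)
    if label in STARVATION_TIMEPOINTS:
        design = Design.STARVATION
        props = _healthy_props(label)
    else:
        design = Design.STRESS
        props = _stress_props(label)
    g1, s, g2m = _CYCLE_TABLE[label]
    return ConditionPreset(
        label=label,
        design=design,
        state_props=props,
        intensity_params=intensity_params or IntensityParams(),
        cycle_fractions=CycleFractions(g1_g0=g1, s=s, g2m=g2m),
        schedule_meta=_SCHEDULE_META[label],
    )


def design_timepoints(design: Design) -> tuple[str, ...]:
    return STARVATION_TIMEPOINTS if design is Design.STARVATION else STRESS_TIMEPOINTS
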
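"""Intensity gating: turning continuous marker intensities into +/− calls.

Positivity of an immunofluorescence or chromogenic stain is classically
scored by eye.  Here the same decision is made by a reproducible rule: a
two-component Gaussian mixture is fitted to the log intensities of a
marker across cells, and the threshold is placed where the two weighted
component densities cross (the posterior-0.5 boundary).  When the two
components are not separable — an all-negative or all-positive
population — the fit is declared degenerate and a fallback rule applies.

Calls are made as ``intensity > threshold``; a cell exactly at the
threshold is called negative, the conservative choice that avoids
inflating positivity.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .phenotypes import MarkerProfile

#: Marker keys in panel order; ``<marker>_intensity`` are the table columns.
MARKERS = ("ki67", "prps6", "sabgal")

#: Per-cell table columns the gating step consumes.
INTENSITY_COLUMNS = tuple(f"{m}_intensity" for m in MARKERS)

#: Profile-column names emitted by :func:`apply_gates` (match MarkerProfile).
PROFILE_COLUMNS = ("ki67", "prps6", "sa_b_gal")

MIN_CELLS_FOR_GATE = 50
DEFAULT_MIN_SEPARATION_SD = 1.0


class GatingMethod(str, enum.Enum):
    TWO_COMPONENT_MIXTURE = "two_component_mixture"
    FIXED = "fixed"
    QUANTILE = "quantile"


class GatingError(RuntimeError):
    """Degenerate gate fit; caller should fall back to a non-mixture rule."""


class InputSchemaError(ValueError):
    """A required column is missing from a per-cell table."""


@dataclasses.dataclass(frozen=True)
class MixtureParams:
    """Two-component location/scale/weight fit on log intensity.

    Component 1 is the negative (lower-location) population.
    """

    loc_neg: float
    scale_neg: float
    weight_neg: float
    loc_pos: float
    scale_pos: float
    weight_pos: float

    def __post_init__(self) -> None:
        if abs(self.weight_neg + self.weight_pos - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def pooled_sd(self) -> float:
        return float(
            np.sqrt(
                self.weight_neg * self.scale_neg**2
                + self.weight_pos * self.scale_pos**2
            )
        )

    @property
    def separation_sd(self) -> float:
        return (self.loc_pos - self.loc_neg) / self.pooled_sd


@dataclasses.dataclass(frozen=True)
class GateModel:
    """A fitted positivity gate for one marker.

    ``threshold`` is on the original intensity scale; the mixture (when
    present) lives on the log scale.
    """

    marker: str
    threshold: float
    method: GatingMethod
    mix_params: MixtureParams | None = None

    def __post_init__(self) -> None:
        if self.method is GatingMethod.TWO_COMPONENT_MIXTURE:
            if self.mix_params is None:
                raise ValueError("mixture gate requires mix_params")
            log_thr = np.log(self.threshold)
            if not (self.mix_params.loc_neg < log_thr < self.mix_params.loc_pos):
                raise ValueError(
                    "mixture threshold must lie strictly between component locations"
                )

    def call(self, intensities) -> np.ndarray:
        """Positivity calls; ties at the threshold are negative."""
        return np.asarray(intensities, dtype=float) > self.threshold


def _check_intensities(intensities: np.ndarray) -> np.ndarray:
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < MIN_CELLS_FOR_GATE:
        raise ValueError(
            f"need at least {MIN_CELLS_FOR_GATE} cells to fit a gate, got {x.size}"
        )
    if not np.all(x > 0):
        raise ValueError("intensities must be strictly positive")
    return x


def _crossing_threshold(mix: MixtureParams) -> float:
    """Log-threshold where the weighted component densities are equal.

    Searched between the two component locations (the decision boundary of
    interest always lies there for a separable pair).
    """

    def density_gap(x: float) -> float:
        return mix.weight_neg * stats.norm.pdf(
            x, mix.loc_neg, mix.scale_neg
        ) - mix.weight_pos * stats.norm.pdf(x, mix.loc_pos, mix.scale_pos)

    grid = np.linspace(mix.loc_neg, mix.loc_pos, 512)
    gap = np.array([density_gap(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(gap)) != 0)[0]
    if sign_change.size == 0:
        raise GatingError(
            "no density crossing between component locations; "
            "fall back to a quantile or fixed gate"
        )
    i = sign_change[0]
    return float(optimize.brentq(density_gap, grid[i], grid[i + 1]))


def fit_gate(
    intensities,
    marker: str,
    method: GatingMethod = GatingMethod.TWO_COMPONENT_MIXTURE,
    *,
    quantile: float = 0.5,
    threshold: float | None = None,
    min_separation_sd: float = DEFAULT_MIN_SEPARATION_SD,
    random_state: int = 0,
) -> GateModel:
    """Fit a positivity gate for one marker.

    ``TWO_COMPONENT_MIXTURE`` fits a 2-component Gaussian mixture on log
    intensity and thresholds at the equal-weighted-density point.  A fit
    whose components are closer than ``min_separation_sd`` pooled standard
    deviations is degenerate and raises :class:`GatingError` — the caller
    should fall back to ``QUANTILE`` or a fixed negative-control fence
    (see :func:`robust_fence_gate`).

    ``QUANTILE`` thresholds at the given quantile of the raw intensities;
    ``FIXED`` uses the supplied ``threshold``.
    """
    if method is GatingMethod.FIXED:
        if threshold is None or threshold <= 0:
            raise ValueError("FIXED gating requires a positive threshold")
        return GateModel(marker=marker, threshold=float(threshold), method=method)

    x = _check_intensities(intensities)

    if method is GatingMethod.QUANTILE:
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        return GateModel(
            marker=marker, threshold=float(np.quantile(x, quantile)), method=method
        )

    log_x = np.log(x)[:, None]
    gm = GaussianMixture(
        n_components=2, covariance_type="diag", n_init=3, random_state=random_state
    ).fit(log_x)
    # A single Gaussian split in half by the 2-component fit passes a naive
    # separation check (each half gets a small scale); require the
    # 2-component model to beat 1 component on BIC before trusting it.
    gm1 = GaussianMixture(
        n_components=1, covariance_type="diag", random_state=random_state
    ).fit(log_x)
    if gm1.bic(log_x) <= gm.bic(log_x):
        raise GatingError(
            f"intensity distribution for {marker!r} is better described by a "
            "single component; fall back to a quantile or fixed gate"
        )
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    weights = weights / weights.sum()
    mix = MixtureParams(
        loc_neg=float(means[0]),
        scale_neg=float(sds[0]),
        weight_neg=float(weights[0]),
        loc_pos=float(means[1]),
        scale_pos=float(sds[1]),
        weight_pos=float(weights[1]),
    )
    if mix.separation_sd < min_separation_sd:
        raise GatingError(
            f"mixture components for {marker!r} separated by "
            f"{mix.separation_sd:.2f} pooled SD "
            f"(< {min_separation_sd}); population looks unimodal — "
            "fall back to a quantile or fixed gate"
        )
    log_threshold = _crossing_threshold(mix)
    return GateModel(
        marker=marker,
        threshold=float(np.exp(log_threshold)),
        method=GatingMethod.TWO_COMPONENT_MIXTURE,
        mix_params=mix,
    )


def robust_fence_gate(intensities, marker: str, n_sigma: float = 3.0) -> GateModel:
    """Negative-control-style gate for a unimodal marker.

    Thresholds at ``median + n_sigma`` robust standard deviations
    (1.4826·MAD) on log intensity — the standard cytometry fence that calls
    only upper outliers positive when no positive population is present.
    """
    x = _check_intensities(intensities)
    log_x = np.log(x)
    med = np.median(log_x)
    sigma = 1.4826 * np.median(np.abs(log_x - med))
    return GateModel(
        marker=marker,
        threshold=float(np.exp(med + n_sigma * sigma)),
        method=GatingMethod.FIXED,
    )


def fit_gate_with_fallback(intensities, marker: str, **kwargs) -> GateModel:
    """Mixture gate with automatic fallback to the robust fence.

    This is the pipeline's default policy: markers with a genuine
    negative/positive split are gated by the mixture crossing; markers
    with a single (all-negative) population are gated by the outlier
    fence so that essentially no cell is called positive.
    """
    try:
        return fit_gate(intensities, marker, **kwargs)
    except GatingError:
        return robust_fence_gate(intensities, marker)


def apply_gates(cells: pd.DataFrame, gates: dict[str, GateModel]) -> pd.DataFrame:
    """Call every marker for every cell.

    ``cells`` must carry the ``<marker>_intensity`` columns; ``gates`` one
    :class:`GateModel` per marker in :data:`MARKERS`.  Returns a boolean
    frame with columns ``ki67, prps6, sa_b_gal``, row-aligned with the
    input (same index).
    """
    missing = [c for c in INTENSITY_COLUMNS if c not in cells.columns]
    if missing:
        raise InputSchemaError(f"per-cell table missing columns: {missing}")
    absent = [m for m in MARKERS if m not in gates]
    if absent:
        raise ValueError(f"no gate supplied for markers: {absent}")
    out = pd.DataFrame(index=cells.index)
    for marker, profile_col in zip(MARKERS, PROFILE_COLUMNS):
        out[profile_col] = gates[marker].call(cells[f"{marker}_intensity"].to_numpy())
    return out


def profiles_to_tuples(profiles: pd.DataFrame) -> list[MarkerProfile]:
    """Row-wise conversion of a boolean call frame to MarkerProfile tuples."""
    return [
        MarkerProfile(bool(k), bool(r), bool(b))
        for k, r, b in zip(
            profiles["ki67"], profiles["prps6"], profiles["sa_b_gal"]
        )
    ]
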
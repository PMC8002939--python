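"""Pseudo-micrograph rendering of synthetic cell fields.

Four channels are drawn, mimicking the stains of the assay: DAPI (nuclear
counterstain), Ki67 (nuclear immunofluorescence), pRPS6 (perinuclear /
cytoplasmic immunofluorescence, drawn as an annulus around the nucleus)
and SA-β-gal (chromogenic X-Gal precipitate, represented as a diffuse
cytoplasmic blob on an inverted-brightfield optical-density channel).
Nuclei are randomly oriented ellipses, lightly blurred; Poisson shot
noise and Gaussian read noise are added unless disabled.  Per-cell ground
truth (centroid, outline, state, emitted intensities) rides along with
the image.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse

CHANNEL_NAMES = ("dapi", "ki67", "prps6", "sabgal")


class LayoutError(RuntimeError):
    """Requested cells cannot be placed in the field."""


@dataclasses.dataclass(frozen=True)
class FieldLayout:
    """Geometry and noise settings of one rendered field of view."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.65
    nucleus_radius_um: tuple[float, float] = (5.0, 9.0)
    annulus_px: int = 5  # width of the rendered perinuclear band
    cyto_extra_px: int = 8  # radial extent of the SA-β-gal blob
    blur_sigma: float = 0.6
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    max_cells: int = 200
    placement_attempts: int = 200
    touch_factor: float = 0.95  # centre distance >= factor * (r1 + r2)


@dataclasses.dataclass
class CellTruth:
    cell_id: int
    centroid: tuple[float, float]  # (row, col), 0-based pixels
    radii: tuple[float, float]  # (row, col) semi-axes in pixels
    rotation: float  # radians
    state: str
    subcode: str
    intensities: dict[str, float]


@dataclasses.dataclass
class FieldImage:
    """A rendered 4-channel field plus its ground truth."""

    channels: np.ndarray  # (4, H, W) float, order per CHANNEL_NAMES
    pixel_size_um: float
    truth: list[CellTruth]

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError("channels must be a (4, H, W) array")
        h, w = self.channels.shape[1:]
        for t in self.truth:
            r, c = t.centroid
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"cell {t.cell_id} centroid outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]

    def truth_as_json(self) -> list[dict]:
        return [dataclasses.asdict(t) for t in self.truth]


def _place_centroids(
    radii_px: np.ndarray, shape: tuple[int, int], margin: np.ndarray, rng, layout
) -> np.ndarray:
    """Rejection-sample non-overlapping centroids; raise on packing failure."""
    n = len(radii_px)
    h, w = shape
    centroids = np.zeros((n, 2))
    rmax = radii_px.max(axis=1)
    for i in range(n):
        for _ in range(layout.placement_attempts):
            r = rng.uniform(margin[i], h - margin[i])
            c = rng.uniform(margin[i], w - margin[i])
            if i == 0:
                centroids[i] = (r, c)
                break
            dists = np.hypot(centroids[:i, 0] - r, centroids[:i, 1] - c)
            if np.all(dists >= layout.touch_factor * (rmax[:i] + rmax[i])):
                centroids[i] = (r, c)
                break
        else:
            raise LayoutError(
                f"could not place cell {i + 1}/{n}: field too crowded for "
                f"{n} nuclei of this size"
            )
    return centroids


def render_field(
    cells: pd.DataFrame, layout: FieldLayout | None = None, seed=0
) -> FieldImage:
    """Render one field of view from a per-cell intensity table.

    ``cells`` uses the standard per-cell schema (``<marker>_intensity``
    columns, optional ``truth_state``/``truth_subcode``).  Cell count must
    be positive and at most ``layout.max_cells``.
    """
    layout = layout or FieldLayout()
    n = len(cells)
    if n == 0:
        raise ValueError("cannot render an empty field")
    if n > layout.max_cells:
        raise LayoutError(
            f"{n} cells exceed the configured maximum of {layout.max_cells} per field"
        )
    rng = np.random.default_rng(seed)
    h, w = layout.shape
    r_lo, r_hi = (r / layout.pixel_size_um for r in layout.nucleus_radius_um)
    radii = rng.uniform(r_lo, r_hi, size=(n, 2))
    rotations = rng.uniform(0, np.pi, size=n)
    margin = radii.max(axis=1) + layout.annulus_px + layout.cyto_extra_px + 2
    if np.any(2 * margin >= min(h, w)):
        raise LayoutError("nuclei too large for the configured field shape")
    centroids = _place_centroids(radii, (h, w), margin, rng, layout)

    channels = np.zeros((len(CHANNEL_NAMES), h, w))
    truth: list[CellTruth] = []
    records = cells.reset_index(drop=True)
    for i in range(n):
        row = records.iloc[i]
        rr, rc = radii[i]
        cr, cc = centroids[i]
        rot = rotations[i]
        nuc = ellipse(cr, cc, rr, rc, shape=(h, w), rotation=rot)
        outer = ellipse(
            cr, cc, rr + layout.annulus_px, rc + layout.annulus_px,
            shape=(h, w), rotation=rot,
        )
        inner = ellipse(
            cr, cc, max(rr - 1, 1), max(rc - 1, 1), shape=(h, w), rotation=rot
        )
        blob = ellipse(
            cr, cc, rr + layout.cyto_extra_px, rc + layout.cyto_extra_px,
            shape=(h, w), rotation=rot,
        )
        channels[0][nuc] += row["dapi_intensity"]
        channels[1][nuc] += row["ki67_intensity"]
        # perinuclear band extends 1 px into the nucleus so that blurring
        # does not hollow out its inner edge
        band = np.zeros((h, w), dtype=bool)
        band[outer] = True
        band[inner] = False
        channels[2][band] += row["prps6_intensity"]
        channels[3][blob] += row["sabgal_intensity"]
        truth.append(
            CellTruth(
                cell_id=int(row.get("cell_id", i)),
                centroid=(float(cr), float(cc)),
                radii=(float(rr), float(rc)),
                rotation=float(rot),
                state=str(row.get("truth_state", "")),
                subcode=str(row.get("truth_subcode", "")),
                intensities={
                    m: float(row[f"{m}_intensity"])
                    for m in ("ki67", "prps6", "sabgal")
                } | {"dapi": float(row["dapi_intensity"])},
            )
        )

    if layout.blur_sigma > 0:
        for k in range(channels.shape[0]):
            channels[k] = ndimage.gaussian_filter(channels[k], layout.blur_sigma)
    if layout.shot_noise:
        channels = rng.poisson(np.clip(channels, 0, None)).astype(float)
    if layout.read_noise_sd > 0:
        channels = channels + rng.normal(0, layout.read_noise_sd, channels.shape)
    return FieldImage(
        channels=channels, pixel_size_um=layout.pixel_size_um, truth=truth
    )
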
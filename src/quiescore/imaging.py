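"""Nucleus segmentation and per-cell intensity measurement.

The DAPI channel is smoothed, thresholded (Otsu) and split into nuclei by
a distance-transform watershed; border-touching and size-outlier nuclei
are flagged and excluded from counting by default.  Per cell, Ki67 and
DAPI are measured over the (slightly eroded) nucleus mask, while pRPS6
and SA-β-gal — cytoplasmic/perinuclear signals — are measured over a thin
annulus obtained by dilating the nucleus; the per-cell statistic is the
median, which is robust to boundary partial-volume pixels and to
spill-over from neighbouring cells.  The per-channel
background (median of non-cell pixels) is subtracted and floored at a
small positive epsilon, so the output table feeds straight into gating.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion, remove_small_objects
from skimage.segmentation import relabel_sequential, watershed

from .render import CHANNEL_NAMES, FieldImage

BACKGROUND_EPSILON = 1e-3


class SegmentationError(RuntimeError):
    """The DAPI channel cannot be segmented."""


@dataclasses.dataclass
class SegmentationResult:
    """Labelled nuclei plus per-cell quality-control flags."""

    labels: np.ndarray  # integer raster, 0 = background
    qc: pd.DataFrame  # cell_id, area, centroid, border_touch, size_ok

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def kept_ids(self) -> np.ndarray:
        keep = (~self.qc["border_touch"]) & self.qc["size_ok"]
        return self.qc.loc[keep, "cell_id"].to_numpy()


def _dapi_channel(image) -> np.ndarray:
    if isinstance(image, FieldImage):
        return image.channel("dapi")
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        return arr[0]
    return arr


def segment_nuclei(
    image,
    *,
    smooth_sigma: float = 2.0,
    min_area_px: int = 60,
    max_area_px: int | None = None,
    peak_min_distance: int = 7,
) -> SegmentationResult:
    """Segment nuclei from the DAPI channel of a field.

    Accepts a :class:`~quiescore.render.FieldImage` or a raw array (first
    plane treated as DAPI).  Raises :class:`SegmentationError` on a blank
    (zero-dynamic-range) channel.
    """
    dapi = _dapi_channel(image)
    if float(dapi.max() - dapi.min()) <= 0:
        raise SegmentationError("DAPI channel has no dynamic range")
    smoothed = gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        raise SegmentationError("no foreground after thresholding")

    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros_like(distance, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    labels, _, _ = relabel_sequential(labels)

    h, w = labels.shape
    areas = np.array([p.area for p in regionprops(labels)])
    if max_area_px is None:
        max_area_px = int(np.median(areas) * 4) if len(areas) else 10**9
    rows = []
    for prop in regionprops(labels):
        rmin, cmin, rmax, cmax = prop.bbox
        border = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        rows.append(
            {
                "cell_id": prop.label,
                "area": int(prop.area),
                "centroid_r": float(prop.centroid[0]),
                "centroid_c": float(prop.centroid[1]),
                "border_touch": bool(border),
                "size_ok": bool(min_area_px <= prop.area <= max_area_px),
            }
        )
    qc = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "area", "centroid_r", "centroid_c", "border_touch", "size_ok",
        ],
    )
    return SegmentationResult(labels=labels, qc=qc)


def measure_cells(
    image,
    seg: SegmentationResult,
    *,
    annulus_width: int = 3,
    epsilon: float = BACKGROUND_EPSILON,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Measure per-cell marker intensities given a segmentation.

    Returns the standard per-cell table (``cell_id``, centroid,
    ``<marker>_intensity`` columns) with background subtracted and floored
    at ``epsilon``.  Cells whose annulus collides with the image border
    are flagged and (by default) excluded, as are segmentation QC
    failures.
    """
    if isinstance(image, FieldImage):
        channels = image.channels
    else:
        channels = np.asarray(image, dtype=float)
        if channels.ndim != 3:
            raise ValueError("expected a (4, H, W) channel stack")
    if channels.shape[1:] != seg.labels.shape:
        raise ValueError("segmentation does not match image shape")

    h, w = seg.labels.shape
    background = {
        name: float(np.median(channels[k][seg.labels == 0]))
        for k, name in enumerate(CHANNEL_NAMES)
    }
    keep = set(seg.kept_ids()) if exclude_flagged else set(seg.qc["cell_id"])
    selem = disk(annulus_width)
    rows = []
    for prop in regionprops(seg.labels):
        if prop.label not in keep:
            continue
        rmin, cmin, rmax, cmax = prop.bbox
        pad = annulus_width + 1
        r0, c0 = max(rmin - pad, 0), max(cmin - pad, 0)
        r1, c1 = min(rmax + pad, h), min(cmax + pad, w)
        nuc = seg.labels[r0:r1, c0:c1] == prop.label
        other = (seg.labels[r0:r1, c0:c1] > 0) & ~nuc
        dilated = dilation(nuc, selem)
        annulus = dilated & ~nuc & ~other
        if exclude_flagged and (
            rmin - annulus_width < 0
            or cmin - annulus_width < 0
            or rmax + annulus_width > h
            or cmax + annulus_width > w
        ):
            continue  # annulus collides with the border
        core = erosion(nuc, disk(1))
        if not core.any():
            core = nuc

        def mean_over(channel_name: str, mask) -> float:
            # median, not mean: robust to boundary partial-volume pixels and
            # to spill-over from a neighbouring cell's cytoplasmic signal
            k = CHANNEL_NAMES.index(channel_name)
            if not mask.any():
                return epsilon
            value = float(np.median(channels[k][r0:r1, c0:c1][mask]))
            return max(value - background[channel_name], epsilon)

        rows.append(
            {
                "cell_id": prop.label,
                "field_id": 0,
                "centroid_r": float(prop.centroid[0]),
                "centroid_c": float(prop.centroid[1]),
                "area": int(prop.area),
                "ki67_intensity": mean_over("ki67", core),
                "prps6_intensity": mean_over("prps6", annulus),
                "sabgal_intensity": mean_over("sabgal", annulus),
                "dapi_intensity": mean_over("dapi", core),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "field_id", "centroid_r", "centroid_c", "area",
            "ki67_intensity", "prps6_intensity", "sabgal_intensity",
            "dapi_intensity",
        ],
    )


def match_to_truth(measured: pd.DataFrame, field: FieldImage) -> pd.DataFrame:
    """Attach ground truth to measured cells by nearest-centroid matching.

    Each measured cell is matched to the closest truth centroid within
    one nucleus diameter; unmatched rows are dropped.  Used for
    round-trip validation of the render → segment → measure path.
    """
    if not len(measured):
        return measured.assign(truth_state=[], truth_subcode=[])
    truth_xy = np.array([t.centroid for t in field.truth])
    states = [t.state for t in field.truth]
    subcodes = [t.subcode for t in field.truth]
    max_radius = max(max(t.radii) for t in field.truth)
    rows = []
    for _, row in measured.iterrows():
        d = np.hypot(
            truth_xy[:, 0] - row["centroid_r"], truth_xy[:, 1] - row["centroid_c"]
        )
        j = int(np.argmin(d))
        if d[j] <= 2 * max_radius:
            rec = dict(row)
            rec["truth_state"] = states[j]
            rec["truth_subcode"] = subcodes[j]
            rec["truth_ki67"] = field.truth[j].intensities["ki67"]
            rec["truth_prps6"] = field.truth[j].intensities["prps6"]
            rec["truth_sabgal"] = field.truth[j].intensities["sabgal"]
            rec["truth_dapi"] = field.truth[j].intensities["dapi"]
            rows.append(rec)
    return pd.DataFrame(rows)
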
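"""Arena-photograph processing: segmentation, centroids, calibration.

Turns a grayscale chamber photograph into a calibrated set of fly
centroids.  The pipeline is deliberately minimal — global threshold,
connected components within an arena mask, area filtering, and an optional
distance-transform watershed to split merged (touching) flies — which is
sufficient to reproduce the within-four-body-lengths statistic from
images.

Physical calibration uses either an explicit ``px_per_mm`` scale or the
median detected body length, anchored to the 2.5 mm adult fly body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .arena import (
    ArenaGeometry,
    PointConfig,
    DEFAULT_BODY_LENGTH_MM,
    transform_for_arena,
)

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "CentroidSet",
    "segment_flies",
    "extract_centroids",
    "to_physical",
    "detect_flies",
    "match_detections",
    "arena_mask_polygon",
]

#: A component this many times larger than the median blob is treated as
#: merged flies and split by watershed (when splitting is enabled).
MERGED_AREA_FACTOR = 1.6


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation configuration.

    ``threshold`` is either the tag ``"otsu"`` (automatic) or a fixed
    intensity in the image's value range.  ``mask`` is an optional polygon
    of (x, y) pixel vertices restricting detection to the chamber
    interior; pixels outside it are ignored (the arena border would
    otherwise segment as foreground).
    """

    threshold: str | float = "otsu"
    min_area: float = 40.0
    max_area: float = 5000.0
    split_merged: bool = True
    mask: np.ndarray | None = None
    polarity: str = "dark"  # flies darker ("dark") or brighter ("bright")

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a fixed value")


@dataclass
class SegmentationResult:
    """Labeled fly regions plus per-region split provenance."""

    labels: np.ndarray                      # 0 = background
    split_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.split_flags)


@dataclass
class CentroidSet:
    """Image-derived fly detections with shape attributes.

    Coordinates are pixels: x = column, y = row, 0-based, origin top-left.
    ``estimated_body_length`` is the median major-axis length over unsplit
    detections (NaN, with ``body_length_defined = False``, when empty).
    """

    centroids: np.ndarray                   # (n, 2) of (x, y) px
    areas: np.ndarray
    major_axes: np.ndarray
    minor_axes: np.ndarray
    orientations: np.ndarray
    split_flags: np.ndarray
    estimated_body_length: float
    source: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)

    @property
    def n_detections(self) -> int:
        return len(self.centroids)

    @property
    def body_length_defined(self) -> bool:
        return np.isfinite(self.estimated_body_length)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_px": self.centroids[:, 0],
                "y_px": self.centroids[:, 1],
                "area": self.areas,
                "major": self.major_axes,
                "minor": self.minor_axes,
                "orientation": self.orientations,
                "split_flag": self.split_flags,
            }
        )


def arena_mask_polygon(
    arena: ArenaGeometry,
    px_per_mm: float,
    pad_mm: float = 2.0,
    shrink_mm: float = 1.0,
) -> np.ndarray:
    """Pixel polygon of the chamber interior, shrunk to exclude the border."""
    shrunk = ArenaGeometry(arena.vertices, margin=shrink_mm)
    tf = transform_for_arena(arena, px_per_mm, pad_mm)
    return tf.mm_to_px(shrunk.eroded_vertices if shrink_mm > 0 else arena.vertices)


def _mask_array(shape: tuple[int, int], mask_poly: np.ndarray | None) -> np.ndarray:
    if mask_poly is None:
        return np.ones(shape, dtype=bool)
    poly = np.asarray(mask_poly, dtype=float)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def segment_flies(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> SegmentationResult:
    """Threshold, label and area-filter fly blobs inside the arena mask.

    Components are 8-connected.  With ``split_merged`` enabled, any
    component larger than 1.6x the median component area is divided by a
    distance-transform watershed seeded at local distance maxima.

    An empty mask or an image with no foreground yields an empty
    result (zero regions), not an exception.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    img = img.astype(float)
    mask = _mask_array(img.shape, params.mask)
    if not mask.any():
        return SegmentationResult(labels=np.zeros(img.shape, dtype=int))

    if params.threshold == "otsu":
        thr = threshold_otsu(img[mask])
        # the returned value is a histogram bin centre: nudge by half a bin
        # so values in the boundary bin stay on the foreground side
        thr += np.ptp(img[mask]) / 512.0 if params.polarity == "dark" else 0.0
    else:
        thr = float(params.threshold)
    fg = (img <= thr) if params.polarity == "dark" else (img > thr)
    fg &= mask
    if not fg.any():
        return SegmentationResult(labels=np.zeros(img.shape, dtype=int))

    labels = cc_label(fg, connectivity=2)
    regions = regionprops(labels)
    keep = [r for r in regions if params.min_area <= r.area <= params.max_area]
    if not keep:
        return SegmentationResult(labels=np.zeros(img.shape, dtype=int))

    out = np.zeros(img.shape, dtype=int)
    split_flags: dict[int, bool] = {}
    next_label = 1
    median_area = float(np.median([r.area for r in keep]))

    for r in keep:
        region_mask = labels == r.label
        if params.split_merged and r.area > MERGED_AREA_FACTOR * median_area:
            pieces = _watershed_split(region_mask, params.min_area, median_area)
            if len(pieces) > 1:
                for piece in pieces:
                    out[piece] = next_label
                    split_flags[next_label] = True
                    next_label += 1
                continue
        out[region_mask] = next_label
        split_flags[next_label] = False
        next_label += 1
    return SegmentationResult(labels=out, split_flags=split_flags)


def _watershed_split(
    region_mask: np.ndarray, min_area: float, median_area: float
) -> list[np.ndarray]:
    """Split one merged blob at distance-transform maxima; may return [mask].

    The number of seeds is capped at the blob area divided by the median
    single-fly area, so a merged pair yields two pieces rather than one
    piece per ridge plateau.
    """
    dist = ndi.distance_transform_edt(region_mask)
    n_expected = max(2, int(round(region_mask.sum() / median_area)))
    min_sep = max(3, int(round(np.sqrt(median_area) / 2)))
    peaks = peak_local_max(
        dist, min_distance=min_sep, num_peaks=n_expected,
        labels=region_mask, exclude_border=False,
    )
    if len(peaks) < 2:
        return [region_mask]
    markers = np.zeros(region_mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    ws = watershed(-dist, markers, mask=region_mask)
    pieces = [ws == lab for lab in range(1, len(peaks) + 1)]
    pieces = [p for p in pieces if p.sum() >= min_area]
    return pieces if len(pieces) > 1 else [region_mask]


def extract_centroids(seg: SegmentationResult, source: str = "") -> CentroidSet:
    """Binary centroids and moment-based shape attributes per region.

    The body-length estimate is the median major-axis length over regions
    that did not come from splitting a merged blob (split halves are
    foreshortened); if every region was split, all regions are used.
    """
    regions = regionprops(seg.labels)
    if not regions:
        empty = np.empty(0)
        return CentroidSet(
            centroids=np.empty((0, 2)), areas=empty, major_axes=empty,
            minor_axes=empty, orientations=empty,
            split_flags=np.empty(0, dtype=bool),
            estimated_body_length=float("nan"), source=source,
        )
    cents = np.array([(r.centroid[1], r.centroid[0]) for r in regions])
    areas = np.array([r.area for r in regions], dtype=float)
    majors = np.array([r.axis_major_length for r in regions])
    minors = np.array([r.axis_minor_length for r in regions])
    orients = np.array([r.orientation for r in regions])
    flags = np.array([seg.split_flags.get(r.label, False) for r in regions])
    unsplit = majors[~flags]
    body = float(np.median(unsplit if unsplit.size else majors))
    return CentroidSet(
        centroids=cents, areas=areas, major_axes=majors, minor_axes=minors,
        orientations=orients, split_flags=flags,
        estimated_body_length=body, source=source,
    )


def to_physical(
    cs: CentroidSet | PointConfig,
    px_per_mm: float | None = None,
    arena: ArenaGeometry | None = None,
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM,
) -> PointConfig:
    """Convert pixel detections to a mm-space point configuration.

    With an explicit ``px_per_mm`` that scale is used; otherwise the scale
    is calibrated so the estimated body length equals ``body_length_mm``
    (2.5 mm by default, making four body lengths = 1 cm).  Passing an
    already-physical :class:`PointConfig` is a no-op, so calibration is
    idempotent.
    """
    if isinstance(cs, PointConfig):
        return cs
    if px_per_mm is None:
        if not cs.body_length_defined:
            raise ValueError(
                "cannot calibrate: no explicit px_per_mm and no usable "
                "body-length estimate (empty detection set); provide "
                "px_per_mm or a non-empty CentroidSet"
            )
        px_per_mm = cs.estimated_body_length / body_length_mm
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be > 0")
    return PointConfig(
        coords=cs.centroids / px_per_mm,
        arena=arena,
        body_length=body_length_mm,
        label=cs.source,
        meta={"px_per_mm": px_per_mm, "n_split": int(cs.split_flags.sum()) if cs.n_detections else 0},
    )


def match_detections(
    detected: np.ndarray,
    truth: np.ndarray,
    gate: float = 5.0,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one nearest-pair matching within a distance gate.

    Pairs (detected index, truth index, distance) are claimed in order of
    ascending distance; unmatched ground truth counts as a miss.  Used to
    score detections against render ground truth.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if not len(detected) or not len(truth):
        return []
    d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_d, used_t, matches = set(), set(), []
    for i, j in order:
        if d[i, j] > gate:
            break
        if i in used_d or j in used_t:
            continue
        matches.append((int(i), int(j), float(d[i, j])))
        used_d.add(int(i))
        used_t.add(int(j))
    return matches


def detect_flies(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    source: str = "",
) -> CentroidSet:
    """Segment an image and extract its centroid set in one call."""
    return extract_centroids(segment_flies(image, params), source=source)
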
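"""End-to-end analysis: images in, per-angle metrics out.

One pass over an arc series performs preprocessing, ball-bearing and field
edge detection per image and then computes every mechanical metric; a
single delivery therefore characterises imager sag, gantry sag, SDD
variation, skew, tilt and carriage sag simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ArcSagError, DetectionError, ReferenceFrameError
from .geometry_metrics import ArcMetrics, compute_arc_metrics
from .imaging_io import ArcSeries
from .marker_detection import (
    PhantomGeometry,
    conservative_smooth,
    detect_field_edges,
    detect_markers,
    preprocess,
)

log = logging.getLogger(__name__)

#: an arc is analysable while at least this fraction of images is usable
MIN_USABLE_FRACTION = 0.8


@dataclass
class ImageFailure:
    index: int
    gantry_angle_deg: float
    error: str


@dataclass
class SeriesResult:
    metrics: ArcMetrics
    failures: list[ImageFailure] = field(default_factory=list)


def analyze_series(
    series: ArcSeries,
    geometry: PhantomGeometry | None = None,
) -> SeriesResult:
    """Detect markers and edges in every frame and compute all metrics.

    Individual frames whose detection fails are reported and skipped as
    long as at least 80% of the series (and the reference frame) remain
    usable; otherwise the per-image error is re-raised.
    """
    geometry = geometry or PhantomGeometry()
    angles, marker_sets, edge_sets, failures = [], [], [], []
    for i, image in enumerate(series.images):
        try:
            smoothed = conservative_smooth(image)
            markers = detect_markers(smoothed, geometry)
            edges = detect_field_edges(smoothed, geometry, markers)
        except ArcSagError as exc:
            if i == series.reference_index:
                raise ReferenceFrameError(
                    f"reference frame (gantry {image.gantry_angle_deg:.1f} deg) "
                    f"unusable: {exc}"
                ) from exc
            failures.append(
                ImageFailure(i, image.gantry_angle_deg, f"{type(exc).__name__}: {exc}")
            )
            log.warning(
                "image %d (gantry %.1f deg) skipped: %s", i, image.gantry_angle_deg, exc
            )
            continue
        log.info(
            "image %d gantry %+7.2f deg scores %s",
            i,
            image.gantry_angle_deg,
            {k: round(v, 2) for k, v in markers.detection_score.items()},
        )
        angles.append(image.gantry_angle_deg)
        marker_sets.append(markers)
        edge_sets.append(edges)

    usable = len(angles) / len(series.images)
    if usable < MIN_USABLE_FRACTION:
        raise DetectionError(
            f"only {len(angles)}/{len(series.images)} images usable "
            f"({usable:.0%} < {MIN_USABLE_FRACTION:.0%}); aborting",
            count=len(angles),
        )

    metrics = compute_arc_metrics(
        angles, marker_sets, edge_sets, series.sdd0_mm, geometry
    )
    metrics.meta.update(
        direction=series.direction,
        collimator_setting_deg=series.collimator_setting_deg,
        replicate_id=series.replicate_id,
    )
    return SeriesResult(metrics=metrics, failures=failures)
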
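"""Whole-well fluorescent colony counting and classification.

Implements a thresholding macro for two-channel (Nanog-GFP / mCherry) well
scans: grayscale-opening background subtraction, per-channel intensity
thresholds set at the mean of reporter-negative colonies plus 5 standard
deviations, connected-component segmentation, and per-colony classification
by comparing colony-mean intensities against the channel thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .errors import InputError, ParameterError

CLASS_NAMES = ("NanogGFP+", "mCherry+", "double", "negative")


@dataclass(frozen=True)
class ChannelThreshold:
    """Positivity threshold for one channel: T = mean + 5*SD of negatives."""

    channel: str
    mean: float
    sd: float
    multiplier: float = 5.0

    @property
    def threshold(self) -> float:
        return self.mean + self.multiplier * self.sd


def subtract_background(image: np.ndarray, radius: int) -> np.ndarray:
    """White-tophat background subtraction with a disk structuring element.

    result = image - opening(image, disk(radius)), clipped at 0. The radius
    must exceed the largest expected colony radius so colonies survive while
    slowly varying background (including flat offsets) is removed.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("expected a 2-D single-channel image")
    footprint = morphology.disk(radius, decomposition="sequence")
    opened = morphology.opening(img, footprint)
    return np.clip(img - opened, 0.0, None)


def estimate_threshold(
    negative_intensities, channel: str = "", multiplier: float = 5.0
) -> ChannelThreshold:
    """Threshold from reporter-negative colony intensities: mean + 5*SD.

    Sample SD uses the n-1 denominator. Requires >= 2 reference values.
    """
    vals = np.asarray(list(negative_intensities), dtype=float)
    if vals.size < 2:
        raise InputError("need >= 2 negative reference intensities")
    return ChannelThreshold(
        channel=channel,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        multiplier=multiplier,
    )


def segment_colonies(
    image: np.ndarray,
    detection_threshold: float,
    min_area: int = 50,
    connectivity: int = 8,
) -> np.ndarray:
    """Label connected components of {pixel > detection_threshold}.

    Components smaller than ``min_area`` pixels are removed; surviving
    components are relabeled 1..K. Connectivity 8 (or 4) is pixel adjacency.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    img = np.asarray(image, dtype=float)
    conn = 1 if connectivity == 4 else 2
    mask = img > detection_threshold
    if min_area > 1:
        # keep components with area >= min_area (max_size removes area <= value)
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=conn)
    return measure.label(mask, connectivity=conn)


def classify_and_count(
    labels: np.ndarray,
    channels: dict[str, np.ndarray],
    thresholds: dict[str, ChannelThreshold],
    large_percentile: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-colony table and class counts from a label map and channel images.

    A colony is positive for a channel iff its mean intensity in that
    channel strictly exceeds the channel threshold. Classes: GFP+ only →
    NanogGFP+, mCherry+ only → mCherry+, both → double, neither → negative.
    ``large_percentile`` optionally flags colonies whose area is at or above
    that percentile of the well's colony areas (the size criterion for
    "large" colonies is a free parameter).
    """
    lab = np.asarray(labels)
    for name, img in channels.items():
        if np.asarray(img).shape != lab.shape:
            raise InputError(f"channel {name!r} shape does not match label map")
    for name in ("gfp", "mcherry"):
        if name not in channels or name not in thresholds:
            raise InputError(f"channel {name!r} image and threshold are required")

    n = int(lab.max())
    counts = {c: 0 for c in CLASS_NAMES}
    if n == 0:
        empty = pd.DataFrame(
            columns=[
                "label", "centroid_y", "centroid_x", "area",
                "mean_gfp", "mean_mcherry", "colony_class",
            ]
        )
        return empty, counts

    props = measure.regionprops(lab)
    ids = np.array([p.label for p in props])
    areas = np.array([p.area for p in props], dtype=int)
    cents = np.array([p.centroid for p in props], dtype=float)
    means = {
        name: np.array(
            [np.asarray(img, dtype=float)[lab == i].mean() for i in ids]
        )
        for name, img in channels.items()
    }
    gfp_pos = means["gfp"] > thresholds["gfp"].threshold
    mch_pos = means["mcherry"] > thresholds["mcherry"].threshold
    cls = np.where(
        gfp_pos & mch_pos, "double",
        np.where(gfp_pos, "NanogGFP+", np.where(mch_pos, "mCherry+", "negative")),
    )
    table = pd.DataFrame(
        {
            "label": ids,
            "centroid_y": cents[:, 0],
            "centroid_x": cents[:, 1],
            "area": areas,
            "mean_gfp": means["gfp"],
            "mean_mcherry": means["mcherry"],
            "colony_class": cls,
        }
    )
    if large_percentile is not None:
        cutoff = np.percentile(areas, large_percentile)
        table["large"] = areas >= cutoff
    for c in cls:
        counts[str(c)] += 1
    return table, counts


def quantify_well(
    channels: dict[str, np.ndarray],
    negative_references: dict[str, np.ndarray],
    background_radius: int,
    detection_threshold: float,
    min_area: int = 50,
    connectivity: int = 8,
    threshold_multiplier: float = 5.0,
    large_percentile: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, ChannelThreshold]]:
    """End-to-end well quantification.

    Channels are background-subtracted, segmented on their pixel-wise
    maximum (so reporter-negative colonies with autofluorescence are still
    detected), and classified against thresholds estimated from the supplied
    per-channel negative-reference colony intensities.
    """
    subtracted = {
        name: subtract_background(img, background_radius) for name, img in channels.items()
    }
    thresholds = {
        name: estimate_threshold(vals, channel=name, multiplier=threshold_multiplier)
        for name, vals in negative_references.items()
    }
    detect = np.maximum.reduce(list(subtracted.values()))
    labels = segment_colonies(detect, detection_threshold, min_area, connectivity)
    table, counts = classify_and_count(labels, subtracted, thresholds, large_percentile)
    return table, counts, thresholds
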
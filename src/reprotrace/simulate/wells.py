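"""Synthetic whole-well fluorescence images with planted colonies.

Two channels (GFP reporter and mCherry transgene reporter) share colony
geometry: every colony carries a base autofluorescence level in both
channels plus class-specific offsets, so reporter-negative colonies remain
detectable while classification depends on the channel thresholds. The
image model is background + linear gradient + colony disks + Gaussian pixel
noise, clipped to the 16-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, PlacementError
from ..rng import rng_from_seed

CHANNELS = ("gfp", "mcherry")
COLONY_CLASSES = ("NanogGFP+", "mCherry+", "double", "negative")

DEFAULT_OFFSETS = {
    "NanogGFP+": {"gfp": 1200.0, "mcherry": 0.0},
    "mCherry+": {"gfp": 0.0, "mcherry": 1200.0},
    "double": {"gfp": 1200.0, "mcherry": 1200.0},
    "negative": {"gfp": 0.0, "mcherry": 0.0},
}

U16_MAX = 65535.0


@dataclass
class WellSimConfig:
    image_shape: tuple[int, int] = (256, 256)
    background_level: float = 200.0
    gradient_amplitude: float = 20.0
    noise_sd: float = 5.0
    n_colonies: Mapping[str, int] = field(
        default_factory=lambda: {"NanogGFP+": 8, "mCherry+": 8, "double": 4, "negative": 5}
    )
    colony_radius_range: tuple[int, int] = (5, 9)
    colony_base_intensity: float = 400.0
    class_offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OFFSETS.items()}
    )
    radial_falloff: bool = False
    non_overlap: bool = True
    min_separation: float = 4.0
    border_margin: int = 4
    max_attempts: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if min(self.image_shape) < 16:
            raise ConfigurationError("image too small")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.n_colonies) - set(COLONY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown colony classes: {sorted(unknown)}")
        if any(v < 0 for v in self.n_colonies.values()):
            raise ConfigurationError("colony counts must be >= 0")
        lo, hi = self.colony_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid colony_radius_range")
        peak = (
            self.background_level
            + self.gradient_amplitude
            + self.colony_base_intensity
            + max(
                (sum(offs.values()) for offs in self.class_offsets.values()),
                default=0.0,
            )
        )
        if peak > U16_MAX:
            raise ConfigurationError("configured intensities exceed the 16-bit range")


def _place_colonies(cfg: WellSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    h, w = cfg.image_shape
    lo, hi = cfg.colony_radius_range
    order: list[str] = []
    for cls in COLONY_CLASSES:
        order.extend([cls] * int(cfg.n_colonies.get(cls, 0)))
    placed: list[tuple[float, float, float, str]] = []
    for cls in order:
        r = float(rng.uniform(lo, hi))
        for _ in range(cfg.max_attempts):
            cy = float(rng.uniform(cfg.border_margin + r, h - cfg.border_margin - r))
            cx = float(rng.uniform(cfg.border_margin + r, w - cfg.border_margin - r))
            if not cfg.non_overlap:
                break
            ok = all(
                np.hypot(cy - py, cx - px) >= r + pr + cfg.min_separation
                for py, px, pr, _ in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place {len(placed) + 1} non-overlapping colonies "
                f"in {cfg.max_attempts} attempts"
            )
        placed.append((cy, cx, r, cls))
    return pd.DataFrame(placed, columns=["centroid_y", "centroid_x", "radius", "colony_class"])


def gen_well_image(cfg: WellSimConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate one two-channel well.

    Returns (channels, truth): ``channels`` maps channel name to a float64
    image already clipped to [0, 65535]; ``truth`` lists each planted
    colony's centroid, radius, pixel area, class and per-channel planted
    intensity (base + class offset, excluding background).
    """
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    h, w = cfg.image_shape
    truth = _place_colonies(cfg, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    gradient = cfg.gradient_amplitude * (xx / max(w - 1, 1))
    images = {ch: cfg.background_level + gradient.copy() for ch in CHANNELS}

    areas = []
    for row in truth.itertuples():
        dist2 = (yy - row.centroid_y) ** 2 + (xx - row.centroid_x) ** 2
        mask = dist2 <= row.radius**2
        areas.append(int(mask.sum()))
        if cfg.radial_falloff:
            profile = np.where(mask, 1.0 - 0.5 * np.sqrt(dist2) / row.radius, 0.0)
        else:
            profile = mask.astype(float)
        offs = cfg.class_offsets.get(row.colony_class, {})
        for ch in CHANNELS:
            amp = cfg.colony_base_intensity + float(offs.get(ch, 0.0))
            images[ch] += amp * profile
    truth["area"] = areas
    for ch in CHANNELS:
        offs = [
            cfg.colony_base_intensity + float(cfg.class_offsets.get(cls, {}).get(ch, 0.0))
            for cls in truth["colony_class"]
        ]
        truth[f"intensity_{ch}"] = offs

    for ch in CHANNELS:
        if cfg.noise_sd > 0:
            images[ch] = images[ch] + rng.normal(0.0, cfg.noise_sd, size=(h, w))
        images[ch] = np.clip(images[ch], 0.0, U16_MAX)
    return images, truth
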
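"""Flow-cytometry event analysis: MFI, gates, quadrants, bimodality.

Events arrive as a rectangular table of per-cell linear fluorescence
intensities. Gates are single-channel thresholds; positivity is strict
(">"), so events at the gate count as negative, consistent with the
colony-classification convention. Bimodality detection runs a Gaussian KDE
(Silverman bandwidth) on log-transformed intensities and requires both a
minimum minor-mode mass and a minimum valley depth, so a wiggle in the
density tail does not count as a second population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class Gate:
    channel: str
    threshold: float
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError("gate threshold must be > 0")


@dataclass(frozen=True)
class QuadrantResult:
    """Fractions of the gated parent population in each quadrant."""

    dn: float          # X- Y-
    x_pos: float       # X+ Y-
    y_pos: float       # X- Y+
    dp: float          # X+ Y+
    n_events: int

    def as_dict(self) -> dict[str, float]:
        return {"DN": self.dn, "X+Y-": self.x_pos, "X-Y+": self.y_pos, "DP": self.dp}


def _channel(events: pd.DataFrame, channel: str) -> np.ndarray:
    if channel not in events.columns:
        raise InputError(f"channel {channel!r} not in event table")
    return events[channel].to_numpy(dtype=float)


def mfi(events: pd.DataFrame, channel: str) -> float:
    """Median fluorescence intensity on linear scale.

    For an even number of events this is the mean of the central pair.
    """
    vals = _channel(events, channel)
    if vals.size == 0:
        raise InputError("no events")
    return float(np.median(vals))


def positive_gate(
    control_events: pd.DataFrame, channel: str, percentile: float = 99.5
) -> Gate:
    """Gate at a percentile of a negative-control channel distribution."""
    if not 0 <= percentile <= 100:
        raise ParameterError("percentile must be in [0, 100]")
    vals = _channel(control_events, channel)
    if vals.size == 0:
        raise InputError("empty control event table")
    return Gate(
        channel=channel,
        threshold=float(np.percentile(vals, percentile)),
        provenance=f"control p{percentile:g}",
    )


def positive_fraction(events: pd.DataFrame, gate: Gate) -> float:
    """Fraction of events strictly above the gate."""
    vals = _channel(events, gate.channel)
    if vals.size == 0:
        raise InputError("no events")
    return float((vals > gate.threshold).mean())


def quadrant_proportions(events: pd.DataFrame, gate_x: Gate, gate_y: Gate) -> QuadrantResult:
    """DN / X+Y- / X-Y+ / DP proportions over all events."""
    x = _channel(events, gate_x.channel)
    y = _channel(events, gate_y.channel)
    if x.size == 0:
        raise InputError("no events")
    xp = x > gate_x.threshold
    yp = y > gate_y.threshold
    n = x.size
    return QuadrantResult(
        dn=float((~xp & ~yp).sum() / n),
        x_pos=float((xp & ~yp).sum() / n),
        y_pos=float((~xp & yp).sum() / n),
        dp=float((xp & yp).sum() / n),
        n_events=n,
    )


def detect_bimodality(
    events: pd.DataFrame,
    channel: str,
    min_fraction: float = 0.05,
    depth_fraction: float = 0.1,
    grid_size: int = 512,
) -> tuple[bool, float | None]:
    """Detect a bimodal marker distribution on log scale.

    Returns (is_bimodal, valley) where ``valley`` is the linear-scale
    intensity of the density minimum between the two largest modes (None
    when unimodal). Bimodal requires at least two KDE local maxima such
    that the minor side of the valley holds >= ``min_fraction`` of the
    probability mass and the valley density is at least ``depth_fraction``
    below the lower of the two peaks.
    """
    vals = _channel(events, channel)
    if vals.size < 100:
        raise InputError("need >= 100 events for bimodality detection")
    logv = np.log10(np.clip(vals, np.finfo(float).tiny, None))
    if np.ptp(logv) == 0:
        return False, None
    kde = gaussian_kde(logv, bw_method="silverman")
    pad = 0.5
    grid = np.linspace(logv.min() - pad, logv.max() + pad, grid_size)
    dens = kde(grid)

    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_max]
    if len(peaks) < 2:
        return False, None
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo_i, hi_i = int(top2.min()), int(top2.max())
    valley_rel = int(np.argmin(dens[lo_i : hi_i + 1]))
    valley_i = lo_i + valley_rel

    step = grid[1] - grid[0]
    mass_left = float(dens[: valley_i + 1].sum() * step)
    mass_right = float(dens[valley_i:].sum() * step)
    total = float(dens.sum() * step)
    minor_mass = min(mass_left, mass_right) / total
    lower_peak = min(dens[lo_i], dens[hi_i])
    deep_enough = dens[valley_i] <= (1.0 - depth_fraction) * lower_peak
    if minor_mass >= min_fraction and deep_enough:
        return True, float(10 ** grid[valley_i])
    return False, None
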
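"""Synthetic Sanger-style chromatogram peak-height tables.

A control trace is built from a random nucleotide sequence: at each
position the called base carries a large peak and the other three bases a
small background peak. An edited trace models a mixed PCR amplicon over an
indel spectrum {k: f_k}: upstream of the cut site it equals the control;
from the cut site on it is the frequency-weighted sum of copies of the
control shifted by each indel size k (insertions shift downstream signal
right, deletions left), optionally scaled and perturbed by multiplicative
noise. This is exactly the linear mixture model the decomposition stage
inverts, so noise-free recovery is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..rng import rng_from_seed

BASES = ("A", "C", "G", "T")


@dataclass
class TraceSignal:
    """Four per-base peak-height series over positions 0..L-1 (0-based).

    ``cut_site`` indexes the first base downstream of the blunt cut.
    """

    heights: pd.DataFrame  # columns A, C, G, T; index = position
    cut_site: int

    def __post_init__(self) -> None:
        if list(self.heights.columns) != list(BASES):
            raise ConfigurationError(f"trace columns must be {BASES}")
        if (self.heights.to_numpy() < 0).any():
            raise ConfigurationError("peak heights must be >= 0")
        if not 0 <= self.cut_site < len(self.heights):
            raise ConfigurationError("cut_site outside trace")

    @property
    def length(self) -> int:
        return len(self.heights)

    def array(self) -> np.ndarray:
        return self.heights.to_numpy(dtype=float)


@dataclass
class TraceSimConfig:
    length: int = 300
    cut_site: int = 120
    spectrum: Mapping[int, float] = field(default_factory=lambda: {0: 0.7, -3: 0.3})
    window: int = 10
    peak_height: float = 1000.0
    background_fraction: float = 0.03
    noise_sd: float = 0.0  # multiplicative, as a fraction of each height
    edited_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.length < 60:
            raise ConfigurationError("trace too short")
        if not 20 <= self.cut_site < self.length - 20:
            raise ConfigurationError("cut_site must leave room on both sides")
        if self.noise_sd < 0 or self.peak_height <= 0 or self.edited_scale <= 0:
            raise ConfigurationError("invalid intensity parameters")
        freqs = np.array(list(self.spectrum.values()), dtype=float)
        if (freqs < 0).any():
            raise ConfigurationError("spectrum frequencies must be >= 0")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"spectrum frequencies sum to {freqs.sum()}, expected 1")
        for k in self.spectrum:
            if abs(int(k)) > self.window:
                raise ConfigurationError(
                    f"indel size {k} outside decomposition window +/-{self.window}"
                )


def shift_trace(control: np.ndarray, k: int, cut_site: int) -> np.ndarray:
    """Control trace with its signal shifted by indel size k downstream of the cut.

    Positions < cut_site are untouched; position p >= cut_site reads
    control[p - k] (out-of-range source positions give 0). Positive k models
    an insertion pushing downstream peaks right.
    """
    out = control.copy()
    L = control.shape[0]
    pos = np.arange(cut_site, L)
    src = pos - k
    valid = (src >= 0) & (src < L)
    out[pos] = 0.0
    out[pos[valid]] = control[src[valid]]
    return out


def gen_traces(cfg: TraceSimConfig) -> tuple[TraceSignal, TraceSignal]:
    """Simulate (control, edited) traces for one target site."""
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    seq = rng.integers(0, 4, size=cfg.length)
    called = cfg.peak_height * rng.uniform(0.8, 1.2, size=cfg.length)
    bg = cfg.peak_height * cfg.background_fraction * rng.uniform(0.0, 1.0, size=(cfg.length, 4))
    control = bg
    control[np.arange(cfg.length), seq] = called

    edited = np.zeros_like(control)
    for k, f in cfg.spectrum.items():
        edited += float(f) * shift_trace(control, int(k), cfg.cut_site)
    edited *= cfg.edited_scale
    if cfg.noise_sd > 0:
        edited = edited * (1.0 + rng.normal(0.0, cfg.noise_sd, size=edited.shape))
        edited = np.clip(edited, 0.0, None)

    idx = pd.RangeIndex(cfg.length, name="pos")
    return (
        TraceSignal(pd.DataFrame(control, index=idx, columns=list(BASES)), cfg.cut_site),
        TraceSignal(pd.DataFrame(edited, index=idx, columns=list(BASES)), cfg.cut_site),
    )
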
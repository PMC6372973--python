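"""Synthetic flow-cytometry event tables from log-normal mixtures.

Channels are simulated on linear scale, matching cytometry convention where
log transforms are applied only for display and gating. Each channel is an
independent mixture of log-normal components; component labels are returned
per event so gating/bimodality stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..rng import rng_from_seed


@dataclass(frozen=True)
class LogNormalComponent:
    """One mixture component: exp(Normal(location, scale)), median exp(location)."""

    location: float
    scale: float
    weight: float


@dataclass
class FlowSimConfig:
    channels: Mapping[str, Sequence[LogNormalComponent]] = field(
        default_factory=lambda: {
            # TROP2-like bimodal marker: negative and positive modes
            "TROP2": (
                LogNormalComponent(np.log(150.0), 0.45, 0.5),
                LogNormalComponent(np.log(4000.0), 0.45, 0.5),
            )
        }
    )
    n_events: int = 10000
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        if not self.channels:
            raise ConfigurationError("at least one channel required")
        for name, comps in self.channels.items():
            if not comps:
                raise ConfigurationError(f"channel {name!r} has no components")
            total = float(sum(c.weight for c in comps))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"channel {name!r} component weights sum to {total}, expected 1"
                )
            if any(c.weight < 0 or c.scale < 0 for c in comps):
                raise ConfigurationError(f"channel {name!r} has invalid components")


def gen_flow_events(cfg: FlowSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an event table plus per-event component labels per channel."""
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    values: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for name, comps in cfg.channels.items():
        weights = np.array([c.weight for c in comps], dtype=float)
        idx = rng.choice(len(comps), size=cfg.n_events, p=weights)
        loc = np.array([c.location for c in comps])[idx]
        scale = np.array([c.scale for c in comps])[idx]
        values[name] = np.exp(rng.normal(loc, scale)) if cfg.n_events else np.empty(0)
        labels[name] = idx
    events = pd.DataFrame(values)
    comp = pd.DataFrame(labels)
    return events, comp
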
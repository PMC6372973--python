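"""Synthetic arrayed CRISPR-interference screen readouts.

Emulates a candidate screen in which each gene is targeted by several
independent sgRNAs and two flow-cytometry proportions are read out per
sgRNA (%mCherry+ intermediates and %TROP2+ cells), alongside no-sgRNA
control replicates. Control readouts are Normal(mean, SD); a targeting
sgRNA's readout is shifted by its gene's planted effect (in percentage
points). Values are clipped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..rng import rng_from_seed

READOUTS = ("pct_mCherry_pos", "pct_TROP2_pos")
CONTROL_GENE = "sgRNA-"


@dataclass
class ScreenSimConfig:
    n_control_sgrnas: int = 10
    sgrnas_per_gene: int = 5
    control_mean: Mapping[str, float] = field(
        default_factory=lambda: {"pct_mCherry_pos": 40.0, "pct_TROP2_pos": 50.0}
    )
    control_sd: Mapping[str, float] = field(
        default_factory=lambda: {"pct_mCherry_pos": 2.0, "pct_TROP2_pos": 2.0}
    )
    # gene -> readout -> shift in percentage points
    gene_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Trp53": {"pct_mCherry_pos": 37.5, "pct_TROP2_pos": 0.0},
            "Tacstd2": {"pct_mCherry_pos": 0.0, "pct_TROP2_pos": -27.5},
            "Ovol1": {"pct_mCherry_pos": 15.0, "pct_TROP2_pos": -15.0},
            "Fut9": {"pct_mCherry_pos": 0.0, "pct_TROP2_pos": 0.0},
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.sgrnas_per_gene < 1:
            raise ConfigurationError("sgrnas_per_gene must be >= 1")
        if self.n_control_sgrnas < 2:
            raise ConfigurationError("need >= 2 control replicates")
        for r in READOUTS:
            if r not in self.control_mean or r not in self.control_sd:
                raise ConfigurationError(f"missing control parameters for {r}")
            if self.control_sd[r] <= 0:
                raise ConfigurationError("control SD must be > 0")
        for gene, effects in self.gene_effects.items():
            unknown = set(effects) - set(READOUTS)
            if unknown:
                raise ConfigurationError(f"gene {gene!r}: unknown readouts {sorted(unknown)}")


def gen_screen_dataset(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Simulate per-sgRNA readouts (long format).

    Columns: gene, sgrna_id, readout_type, value, is_control. Control rows
    use gene = ``"sgRNA-"``.
    """
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    rows = []
    for rep in range(1, cfg.n_control_sgrnas + 1):
        for readout in READOUTS:
            v = rng.normal(cfg.control_mean[readout], cfg.control_sd[readout])
            rows.append((CONTROL_GENE, f"{CONTROL_GENE}_{rep}", readout, float(np.clip(v, 0, 100)), True))
    for gene in cfg.gene_effects:
        for k in range(1, cfg.sgrnas_per_gene + 1):
            for readout in READOUTS:
                shift = float(cfg.gene_effects[gene].get(readout, 0.0))
                v = rng.normal(cfg.control_mean[readout] + shift, cfg.control_sd[readout])
                rows.append((gene, f"{gene}-kd{k}", readout, float(np.clip(v, 0, 100)), False))
    return pd.DataFrame(rows, columns=["gene", "sgrna_id", "readout_type", "value", "is_control"])
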
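"""Arrayed CRISPR screen hit calling with control-derived thresholds.

Hit calling follows a simple, transparent rule: compute the mean and sample
SD of the no-sgRNA control readouts, draw screening thresholds at
mean ± 3·SD, flag each targeting sgRNA as above / below / within, and call
a gene a hit for a readout direction when enough of its sgRNAs (all of
them, by default) are flagged consistently in that direction. With five
sgRNAs per gene the all-of-five rule has a per-gene false-call probability
of about Φ(-3)^5 ≈ 4.5e-15 per direction under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

READOUTS = ("pct_mCherry_pos", "pct_TROP2_pos")


@dataclass(frozen=True)
class ReadoutStats:
    mean: float
    sd: float
    n: int
    multiplier: float = 3.0

    @property
    def upper(self) -> float:
        return self.mean + self.multiplier * self.sd

    @property
    def lower(self) -> float:
        return self.mean - self.multiplier * self.sd


@dataclass
class ControlStats:
    per_readout: dict[str, ReadoutStats]


@dataclass(frozen=True)
class HitCall:
    gene: str
    readout: str
    direction: str  # "up" | "down" | "none"
    n_consistent: int
    n_sgrnas: int
    rule: str


def control_stats(dataset: pd.DataFrame, multiplier: float = 3.0) -> ControlStats:
    """Per-readout control mean/SD (n-1) and mean ± multiplier·SD bounds."""
    ctrl = dataset[dataset["is_control"]]
    out: dict[str, ReadoutStats] = {}
    for readout, grp in ctrl.groupby("readout_type"):
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise InputError(f"need >= 2 control replicates for {readout!r}")
        out[str(readout)] = ReadoutStats(
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            n=int(vals.size),
            multiplier=multiplier,
        )
    if not out:
        raise InputError("dataset contains no control rows")
    return ControlStats(out)


def flag_sgrnas(dataset: pd.DataFrame, stats: ControlStats) -> pd.DataFrame:
    """Flag every targeting sgRNA readout as above / below / within.

    Strict inequalities: a value exactly at a bound is 'within'.
    """
    targ = dataset[~dataset["is_control"]].copy()
    flags = np.full(len(targ), "within", dtype=object)
    for readout, st in stats.per_readout.items():
        m = (targ["readout_type"] == readout).to_numpy()
        v = targ["value"].to_numpy(dtype=float)
        flags[m & (v > st.upper)] = "above"
        flags[m & (v < st.lower)] = "below"
    targ["flag"] = flags
    return targ


def call_hits(
    flags: pd.DataFrame, min_consistent: int | None = None
) -> list[HitCall]:
    """Gene-level hit calls per readout and direction.

    A gene is a hit (direction up/down) for a readout when at least
    ``min_consistent`` of its sgRNAs are flagged above/below. The default
    requires every sgRNA of the gene to agree — the "consistent across all
    guides" rule.
    """
    calls: list[HitCall] = []
    for (gene, readout), grp in flags.groupby(["gene", "readout_type"], sort=True):
        n = len(grp)
        k = n if min_consistent is None else min_consistent
        if k > n:
            raise ParameterError(f"min_consistent={k} exceeds {n} sgRNAs for {gene}")
        n_above = int((grp["flag"] == "above").sum())
        n_below = int((grp["flag"] == "below").sum())
        if n_above >= k:
            direction, n_cons = "up", n_above
        elif n_below >= k:
            direction, n_cons = "down", n_below
        else:
            direction, n_cons = "none", max(n_above, n_below)
        calls.append(
            HitCall(
                gene=str(gene),
                readout=str(readout),
                direction=direction,
                n_consistent=n_cons,
                n_sgrnas=n,
                rule=f">={k} of {n}",
            )
        )
    return calls


def hits_table(calls: list[HitCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def call_hits_table(flags: pd.DataFrame, min_consistent: int | None = None) -> pd.DataFrame:
    """Vectorized gene x readout call table (for large simulated screens).

    Same rule as :func:`call_hits`; returns columns gene, readout_type,
    n_sgrnas, n_above, n_below, direction.
    """
    tab = (
        flags.groupby(["gene", "readout_type"], sort=True)["flag"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["above", "below", "within"], fill_value=0)
        .reset_index()
    )
    n = tab[["above", "below", "within"]].sum(axis=1)
    k = n if min_consistent is None else min_consistent
    if np.any(k > n):
        raise ParameterError("min_consistent exceeds the sgRNA count for some gene")
    direction = np.where(
        tab["above"] >= k, "up", np.where(tab["below"] >= k, "down", "none")
    )
    return pd.DataFrame(
        {
            "gene": tab["gene"],
            "readout_type": tab["readout_type"],
            "n_sgrnas": n,
            "n_above": tab["above"],
            "n_below": tab["below"],
            "direction": direction,
        }
    )
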
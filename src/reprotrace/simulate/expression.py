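"""Synthetic two-condition reprogramming expression time courses.

Emulates a microarray-style design: log2 normalized intensities for a
low-KLF4 and a high-KLF4 reprogramming series sampled over several days with
replicate cultures, plus terminal reference samples (MEF, mESC, iPSC,
keratinocyte). Genes are planted in classes whose temporal templates encode
the biology the downstream analyses must recover:

fibroblast            high in MEF, silenced during reprogramming
sustained_MET         induced in both conditions, stays on in iPSC/mESC
                      (EpCAM/Cdh1-like core epithelial genes)
transient_MET         induced from ~day 4 only under high KLF4, retained in
                      late intermediates, silenced in iPSC; keratinocyte-
                      expressed (peripheral epithelial genes). A configurable
                      fraction is additionally mESC-elevated below the day-8
                      peak, which exercises the triple-intersection rescue
                      rule downstream.
esc_specific          high only in mESC/iPSC
keratinocyte_specific high only in keratinocytes
background            flat

Noise is additive Gaussian in log2 space. All draws are deterministic given
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..expression import ExpressionMatrix
from ..rng import rng_from_seed

GENE_CLASSES = (
    "fibroblast",
    "sustained_MET",
    "transient_MET",
    "esc_specific",
    "keratinocyte_specific",
    "background",
)

DEFAULT_PROPORTIONS = {
    "background": 0.55,
    "fibroblast": 0.10,
    "sustained_MET": 0.10,
    "transient_MET": 0.10,
    "esc_specific": 0.075,
    "keratinocyte_specific": 0.075,
}


@dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    days: Sequence[float] = (0, 2, 4, 6, 8, 18)
    n_replicates: int = 2
    log2_effect: float = 2.0
    noise_sd: float = 0.25
    baseline: float = 6.0
    # fraction of transient_MET genes that are also mESC-elevated (rescue rule)
    rescue_fraction: float = 24 / 200
    # their mESC level as a fraction of log2_effect; must put them >2-fold over
    # MEF yet below the day-8 high-KLF4 peak
    rescue_level_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be >= 0")
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ConfigurationError("rescue_fraction must be in [0, 1]")
        if not 0.0 < self.rescue_level_fraction < 1.0:
            raise ConfigurationError("rescue_level_fraction must be in (0, 1)")
        if len(self.days) < 2:
            raise ConfigurationError("need at least 2 sampling days")


def _class_counts(cfg: ExpressionSimConfig) -> dict[str, int]:
    """Largest-remainder apportionment so counts are exact for clean fractions."""
    classes = [c for c in GENE_CLASSES if cfg.class_proportions.get(c, 0) > 0]
    raw = {c: cfg.class_proportions[c] * cfg.n_genes for c in classes}
    counts = {c: int(np.floor(raw[c])) for c in classes}
    short = cfg.n_genes - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _induction_ramp(day: np.ndarray) -> np.ndarray:
    """0 through day 2, linear rise to 1 at day 8, then held (retained late)."""
    return np.clip((day - 2.0) / 6.0, 0.0, 1.0)


def _silencing_ramp(day: np.ndarray) -> np.ndarray:
    """Fibroblast program: 1 at day 0 decaying to 0 by day 8."""
    return np.clip(1.0 - day / 8.0, 0.0, 1.0)


def _template(
    cls: str, condition: str, day: float | None, effect: float, rescue: bool, rescue_level: float
) -> float:
    """Log2 offset over baseline for one class in one sample."""
    d = np.array([day if day is not None else np.nan])
    if cls == "background":
        return 0.0
    if cls == "fibroblast":
        if condition == "MEF":
            return effect
        if condition in ("lowKLF4", "highKLF4"):
            return effect * float(_silencing_ramp(d)[0])
        return 0.0
    if cls == "sustained_MET":
        if condition in ("lowKLF4", "highKLF4"):
            return effect * float(_induction_ramp(d)[0])
        if condition in ("mESC", "iPSC", "keratinocyte"):
            return effect
        return 0.0
    if cls == "transient_MET":
        if condition == "highKLF4":
            return effect * float(_induction_ramp(d)[0])
        if condition == "keratinocyte":
            return effect
        if condition == "mESC" and rescue:
            return rescue_level
        return 0.0  # lowKLF4, MEF, iPSC, (mESC non-rescue)
    if cls == "esc_specific":
        return effect if condition in ("mESC", "iPSC") else 0.0
    if cls == "keratinocyte_specific":
        return effect if condition == "keratinocyte" else 0.0
    raise ConfigurationError(f"unknown class {cls!r}")


def _sample_plan(cfg: ExpressionSimConfig) -> pd.DataFrame:
    rows = []
    for cond in ("lowKLF4", "highKLF4"):
        for day in cfg.days:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"{cond}_d{day:g}_r{rep}", cond, float(day), rep))
    for cond in ("MEF", "mESC", "iPSC", "keratinocyte"):
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((f"{cond}_r{rep}", cond, np.nan, rep))
    df = pd.DataFrame(rows, columns=["sample", "condition", "day", "replicate"])
    return df.set_index("sample")


def gen_expression(cfg: ExpressionSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an expression matrix with planted ground-truth gene classes.

    Returns (matrix, truth) where truth is a per-gene DataFrame with columns
    ``gene_class`` and ``esc_elevated`` (the rescue-rule subset of the
    transient class).
    """
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    counts = _class_counts(cfg)
    samples = _sample_plan(cfg)

    classes: list[str] = []
    for c in GENE_CLASSES:
        classes.extend([c] * counts.get(c, 0))
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    rescue_level = cfg.rescue_level_fraction * cfg.log2_effect

    n_trans = counts.get("transient_MET", 0)
    n_rescue = int(round(cfg.rescue_fraction * n_trans))
    trans_idx = [i for i, c in enumerate(classes) if c == "transient_MET"]
    rescue_set = set(trans_idx[:n_rescue])

    clean = np.empty((cfg.n_genes, len(samples)), dtype=float)
    template_cache: dict[tuple[str, bool], np.ndarray] = {}
    meta = list(samples.itertuples())
    for key in {(c, i in rescue_set) for i, c in enumerate(classes)}:
        cls, rescue = key
        template_cache[key] = np.array(
            [
                cfg.baseline
                + _template(
                    cls,
                    m.condition,
                    None if np.isnan(m.day) else m.day,
                    cfg.log2_effect,
                    rescue,
                    rescue_level,
                )
                for m in meta
            ]
        )
    for i, c in enumerate(classes):
        clean[i] = template_cache[(c, i in rescue_set)]

    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape) if cfg.noise_sd > 0 else clean
    values = pd.DataFrame(noisy, index=pd.Index(genes, name="gene"), columns=samples.index)
    truth = pd.DataFrame(
        {
            "gene_class": classes,
            "esc_elevated": [i in rescue_set for i in range(cfg.n_genes)],
        },
        index=values.index,
    )
    return ExpressionMatrix(values, samples), truth


def dynamics_truth(truth: pd.DataFrame) -> pd.Series:
    """Map planted gene classes to the expected dynamics call."""
    mapping = {
        "transient_MET": "transient",
        "sustained_MET": "sustained",
    }
    return truth["gene_class"].map(lambda c: mapping.get(c, "not_induced")).rename("dynamics_class")


def gen_annotation(
    truth: pd.DataFrame,
    n_random_terms: int = 20,
    term_size: int = 50,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene→term annotation (GMT-style dict) with class-derived and random terms.

    Each planted class becomes a term containing exactly its genes, so
    over-representation of e.g. the keratinocyte program in a derived gene
    set is testable against ground truth; random terms provide the null.
    """
    rng = rng_from_seed(seed)
    ann: dict[str, list[str]] = {}
    for cls in GENE_CLASSES:
        members = truth.index[truth["gene_class"] == cls]
        if len(members):
            ann[f"CLASS_{cls.upper()}"] = list(members)
    genes = np.asarray(truth.index)
    for i in range(n_random_terms):
        k = min(term_size, len(genes))
        ann[f"RANDOM_{i:02d}"] = list(rng.choice(genes, size=k, replace=False))
    return ann


@dataclass
class AnticorrSimConfig:
    """Design for the anti-correlation recovery simulation.

    A transient-MET-like reference profile is sampled over ``days`` under one
    condition; ``n_planted`` genes are negative affine transforms of the
    reference with per-gene noise calibrated so the population Pearson r
    equals ``target_r``; ``n_background`` genes carry uncorrelated noise.
    """

    days: Sequence[float] = (0, 2, 4, 6, 8, 10, 12, 14, 18)
    n_planted: int = 500
    n_background: int = 500
    target_r: float = -0.95
    n_replicates: int = 2
    baseline: float = 6.0
    log2_effect: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 < self.target_r < 0.0:
            raise ConfigurationError("target_r must be in (-1, 0)")
        if len(self.days) < 3:
            raise ConfigurationError("need >= 3 days")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


def gen_anticorrelated(cfg: AnticorrSimConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate a high-KLF4 series with planted anti-correlated genes.

    Returns (matrix, truth) where truth marks planted genes True. The
    reference gene is named ``REF``. Noise for planted genes is calibrated
    from the design variance of the reference profile: for target population
    correlation rho, Var(noise) = b^2 * Var(x) * (1/rho^2 - 1), applied to
    the replicate-averaged profile (per-replicate draws are scaled by
    sqrt(n_replicates)).
    """
    cfg.validate()
    rng = rng_from_seed(cfg.seed)
    days = np.asarray(cfg.days, dtype=float)
    x = cfg.log2_effect * _induction_ramp(days)
    x = np.where(days > 8, cfg.log2_effect * np.exp(-(days - 8) / 20.0), x)
    var_x = x.var(ddof=1)
    rho = abs(cfg.target_r)
    sd_eff = np.sqrt(var_x * (1.0 / rho**2 - 1.0))

    n_pts = len(days)
    samples = pd.DataFrame(
        [
            (f"highKLF4_d{d:g}_r{rep}", "highKLF4", float(d), rep)
            for d in days
            for rep in range(1, cfg.n_replicates + 1)
        ],
        columns=["sample", "condition", "day", "replicate"],
    ).set_index("sample")

    b = rng.uniform(0.5, 2.0, size=cfg.n_planted)
    a = cfg.baseline + b * x.max()  # keeps planted profiles positive
    planted = a[:, None] - b[:, None] * x[None, :]
    noise = rng.normal(0.0, 1.0, size=(cfg.n_planted, n_pts, cfg.n_replicates))
    noise *= (b * sd_eff)[:, None, None] * np.sqrt(cfg.n_replicates)
    planted_rep = planted[:, :, None] + noise

    bg = cfg.baseline + rng.normal(0.0, 0.5, size=(cfg.n_background, n_pts, cfg.n_replicates))
    ref = np.broadcast_to((cfg.baseline + x)[:, None], (n_pts, cfg.n_replicates))

    stack = np.concatenate([ref[None], planted_rep, bg], axis=0)
    values = pd.DataFrame(
        stack.reshape(stack.shape[0], -1),
        index=pd.Index(
            ["REF"]
            + [f"NEG{i:04d}" for i in range(cfg.n_planted)]
            + [f"BG{i:04d}" for i in range(cfg.n_background)],
            name="gene",
        ),
        columns=samples.index,
    )
    truth = pd.Series(
        [False] + [True] * cfg.n_planted + [False] * cfg.n_background,
        index=values.index,
        name="planted_anticorrelated",
    )
    return ExpressionMatrix(values, samples), truth
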
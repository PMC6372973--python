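"""Gene-set derivation from reprogramming expression time courses.

The analyses here reproduce a fold-change-based workflow for dissecting
mesenchymal-to-epithelial transition (MET) dynamics during iPSC
reprogramming under two KLF4 stoichiometries:

* crosswise >2-fold comparisons between day-8 reprogramming intermediates
  (high- vs low-KLF4), keratinocytes vs MEFs, and mESCs vs MEFs;
* a three-way Venn partition of the resulting up-regulated gene sets;
* extraction of the *transient*-MET gene set: genes shared by the high-KLF4
  and keratinocyte comparisons but absent from the mESC comparison, plus a
  rescue rule re-admitting triple-intersection genes whose day-8 expression
  transiently exceeds the mESC level;
* per-gene dynamics classification (transient / sustained / not induced);
* hypergeometric term over-representation;
* Pearson anti-correlation screening against a reference gene over the
  ordered reprogramming time course.

All expression values are log2 normalized intensities; replicates are
averaged in log2 space before any ratio is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError, SelectorError

TERMINAL_CONDITIONS = ("MEF", "mESC", "iPSC", "keratinocyte")
TIMECOURSE_CONDITIONS = ("lowKLF4", "highKLF4")
CONDITIONS = TIMECOURSE_CONDITIONS + TERMINAL_CONDITIONS

REQUIRED_SAMPLE_FIELDS = ("condition", "day", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix with per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``condition``
    (one of :data:`CONDITIONS`), ``day`` (float; NaN for terminal samples
    such as mESC/iPSC/keratinocyte/MEF reference cultures) and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InputError(f"duplicate gene identifier: {dup!r}")
        missing = [c for c in REQUIRED_SAMPLE_FIELDS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample metadata missing fields: {missing}")
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise InputError("sample metadata does not match matrix columns")
            self.samples = self.samples.loc[self.values.columns]
        if self.samples["condition"].isna().any() or self.samples["replicate"].isna().any():
            raise InputError("incomplete sample metadata")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise InputError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def select(self, condition: str | None = None, day: float | None = None) -> list[str]:
        """Sample ids matching a (condition, day) filter; day=None matches any."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if day is not None:
            mask &= self.samples["day"] == day
        return list(self.samples.index[mask])

    def group_mean(self, sample_ids: Sequence[str]) -> pd.Series:
        """Replicate-averaged log2 expression over a sample group."""
        if len(sample_ids) == 0:
            raise SelectorError("empty sample group")
        return self.values[list(sample_ids)].mean(axis=1)

    def timecourse(
        self, condition: str, prepend: str | None = None
    ) -> tuple[pd.DataFrame, list[float]]:
        """Replicate-averaged profiles over the ordered days of ``condition``.

        Returns (genes x points DataFrame, day labels). When ``prepend`` names
        a terminal condition (e.g. ``"MEF"``), its replicate mean is inserted
        as the first point of the series.
        """
        days = sorted(self.samples.loc[self.samples["condition"] == condition, "day"].dropna().unique())
        if not days:
            raise SelectorError(f"no time-course samples for condition {condition!r}")
        cols, labels = [], []
        if prepend is not None:
            ids = self.select(condition=prepend)
            if not ids:
                raise SelectorError(f"no samples for baseline condition {prepend!r}")
            cols.append(self.group_mean(ids))
            labels.append(-1.0)
        for d in days:
            cols.append(self.group_mean(self.select(condition=condition, day=d)))
            labels.append(float(d))
        return pd.concat(cols, axis=1, keys=range(len(cols))), labels


@dataclass(frozen=True)
class ComparisonSpec:
    """A crosswise comparison: linear fold change of group A over group B."""

    group_a: Mapping[str, object] | Sequence[str]
    group_b: Mapping[str, object] | Sequence[str]
    fold_threshold: float = 2.0


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class VennPartition:
    """The 7 disjoint regions of three gene sets (HK, KER, ESC)."""

    regions: dict[str, frozenset[str]]

    REGION_NAMES = (
        "HK_only",
        "KER_only",
        "ESC_only",
        "HK_KER",
        "HK_ESC",
        "KER_ESC",
        "HK_KER_ESC",
    )

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


@dataclass
class CorrelationResult:
    reference_gene: str
    r: pd.Series
    band: tuple[float, float]
    selected: frozenset[str]
    excluded_zero_variance: frozenset[str] = field(default_factory=frozenset)


def _resolve_group(matrix: ExpressionMatrix, selector) -> list[str]:
    if isinstance(selector, Mapping):
        ids = matrix.select(**dict(selector))
    else:
        ids = list(selector)
        unknown = [s for s in ids if s not in matrix.samples.index]
        if unknown:
            raise SelectorError(f"unknown sample ids: {unknown}")
    if not ids:
        raise SelectorError(f"selector matched no samples: {selector!r}")
    return ids


def normalize(raw: pd.DataFrame, method: str = "quantile-log2") -> pd.DataFrame:
    """Normalize a raw (linear-scale) genes x samples intensity matrix.

    ``quantile-log2`` (default): rank-based quantile normalization across
    samples — every column is forced onto the mean empirical distribution —
    followed by log2. ``log2``: log transform only. Any monotone
    normalization is acceptable upstream of the fold-change analyses; these
    are the provided defaults for matrices that arrive unnormalized.
    Non-positive intensities are clipped to the smallest positive value
    before the log.
    """
    vals = raw.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise InputError("raw intensities must be finite")
    if method == "quantile-log2":
        order = np.argsort(vals, axis=0, kind="stable")
        ranked = np.sort(vals, axis=0)
        mean_dist = ranked.mean(axis=1)
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            out[order[:, j], j] = mean_dist
    elif method == "log2":
        out = vals.copy()
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    positive = out[out > 0]
    if positive.size == 0:
        raise InputError("no positive intensities to log-transform")
    out = np.log2(np.clip(out, positive.min(), None))
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def fold_change(matrix: ExpressionMatrix, spec: ComparisonSpec) -> pd.Series:
    """Per-gene linear fold change 2**(mean log2 A - mean log2 B).

    Replicate means are taken in log2 space before the ratio is formed, so
    the result is the ratio of geometric-mean intensities.
    """
    a = _resolve_group(matrix, spec.group_a)
    b = _resolve_group(matrix, spec.group_b)
    if set(a) & set(b):
        raise SelectorError("comparison groups overlap")
    return (2.0 ** (matrix.group_mean(a) - matrix.group_mean(b))).rename("fold_change")


def upregulated_set(
    fc: pd.Series, threshold: float = 2.0, name: str = "up", provenance: str = ""
) -> GeneSet:
    """Genes with fold change strictly greater than ``threshold``.

    Strict ">" mirrors a 'more than N-fold' rule: ties at the threshold are
    excluded.
    """
    if threshold <= 0:
        raise ParameterError(f"fold threshold must be > 0, got {threshold}")
    return GeneSet(name, frozenset(fc.index[fc > threshold]), provenance or f"FC > {threshold}")


def venn_partition(hk: GeneSet, ker: GeneSet, esc: GeneSet) -> VennPartition:
    """Partition three gene sets into their 7 disjoint Venn regions."""
    h, k, e = hk.members, ker.members, esc.members
    return VennPartition(
        regions={
            "HK_only": frozenset(h - k - e),
            "KER_only": frozenset(k - h - e),
            "ESC_only": frozenset(e - h - k),
            "HK_KER": frozenset((h & k) - e),
            "HK_ESC": frozenset((h & e) - k),
            "KER_ESC": frozenset((k & e) - h),
            "HK_KER_ESC": frozenset(h & k & e),
        }
    )


def transient_met_genes(
    partition: VennPartition,
    matrix: ExpressionMatrix,
    day: float = 8.0,
    condition: str = "highKLF4",
    esc_condition: str = "mESC",
) -> GeneSet:
    """Transient-MET gene set with the triple-intersection rescue rule.

    Core set: genes up in the high-KLF4 and keratinocyte comparisons but not
    the mESC comparison (HK ∩ KER − ESC). Rescue: triple-intersection genes
    whose replicate-mean day-8 high-KLF4 expression strictly exceeds the mESC
    mean are re-admitted — their induction transiently overshoots the
    embryonic-stem-cell level even though they are mESC-expressed.
    """
    core = set(partition.regions["HK_KER"])
    triple = partition.regions["HK_KER_ESC"]
    rescued: set[str] = set()
    if triple:
        day8_ids = matrix.select(condition=condition, day=day)
        esc_ids = matrix.select(condition=esc_condition)
        if not day8_ids or not esc_ids:
            raise SelectorError(
                f"rescue rule needs day-{day:g} {condition} and {esc_condition} samples"
            )
        genes = sorted(triple)
        day8 = matrix.group_mean(day8_ids).loc[genes]
        escm = matrix.group_mean(esc_ids).loc[genes]
        rescued = set(day8.index[day8 > escm])
    return GeneSet(
        "transient_MET",
        frozenset(core | rescued),
        provenance=f"(HK∩KER−ESC) ∪ rescue({len(rescued)} of {len(triple)} triple)",
    )


def classify_dynamics_table(
    matrix: ExpressionMatrix,
    fold_threshold: float = 2.0,
    condition: str = "highKLF4",
    baseline_condition: str = "MEF",
    silenced_condition: str = "iPSC",
) -> pd.Series:
    """Vectorized transient/sustained/not_induced call for every gene.

    A gene is *induced* when its replicate-mean expression at some day of the
    reprogramming course exceeds the baseline (MEF) mean by more than
    log2(fold_threshold). Induced genes are *transient* when the iPSC level
    returns to within log2(fold_threshold) of baseline (the silencing
    tolerance is symmetric with the induction criterion), *sustained* when
    the iPSC level itself is induced over baseline.
    """
    if fold_threshold <= 0:
        raise ParameterError("fold_threshold must be > 0")
    delta = np.log2(fold_threshold)
    base_ids = matrix.select(condition=baseline_condition)
    sil_ids = matrix.select(condition=silenced_condition)
    if not base_ids:
        raise SelectorError(f"no {baseline_condition} samples")
    if not sil_ids:
        raise SelectorError(f"no {silenced_condition} samples")
    course, _ = matrix.timecourse(condition)
    baseline = matrix.group_mean(base_ids)
    silenced_level = matrix.group_mean(sil_ids)
    induced = course.max(axis=1) - baseline > delta
    sil = (silenced_level - baseline).abs() < delta
    ind_ipsc = silenced_level - baseline > delta
    out = pd.Series("not_induced", index=matrix.genes, name="dynamics_class")
    out[induced & ind_ipsc] = "sustained"
    out[induced & sil] = "transient"
    return out


def classify_dynamics(matrix: ExpressionMatrix, gene: str, **kwargs) -> str:
    """Dynamics class for a single gene (see :func:`classify_dynamics_table`)."""
    if gene not in matrix.genes:
        raise SelectorError(f"gene {gene!r} not in matrix")
    sub = ExpressionMatrix(matrix.values.loc[[gene]], matrix.samples)
    return str(classify_dynamics_table(sub, **kwargs).loc[gene])


def enrich_terms(
    gene_set: GeneSet | Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    p_cutoff: float = 1.0e-3,
    fdr: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation terms.

    For each term, p = P(X >= overlap) with X ~ Hypergeom(universe, term
    members in universe, set size). Terms are ranked by ascending p; the
    ``reported`` column marks terms passing ``p_cutoff`` (applied to the BH
    q-value instead when ``fdr`` is set — off by default, matching raw-p
    reporting with a fixed cutoff).
    """
    members = frozenset(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    universe_set = frozenset(universe)
    if not members <= universe_set:
        stray = sorted(members - universe_set)[:3]
        raise InputError(f"gene set not a subset of the universe (e.g. {stray})")
    m_univ, n_set = len(universe_set), len(members)
    rows = []
    for term, term_genes in annotation.items():
        tset = frozenset(term_genes) & universe_set
        overlap = len(tset & members)
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, len(tset), n_set))
        rows.append((term, overlap, len(tset), n_set, m_univ, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "set_size", "universe_size", "p"]
    ).sort_values(["p", "term"], kind="stable", ignore_index=True)
    if fdr and len(df):
        df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
        df["reported"] = df["q"] < p_cutoff
    else:
        df["reported"] = df["p"] < p_cutoff
    return df


def anticorrelated_genes(
    matrix: ExpressionMatrix,
    reference_gene: str,
    band: tuple[float, float] = (-1.0, -0.9),
    condition: str = "highKLF4",
    include_baseline: bool | str = "auto",
) -> CorrelationResult:
    """Genes whose time-course Pearson r with a reference falls in a band.

    Profiles are replicate-averaged samples of ``condition`` ordered by day;
    when MEF samples exist (or ``include_baseline=True``) the MEF mean is
    prepended as the pre-induction point. The reference gene is excluded from
    its own result; zero-variance profiles are excluded with a warning.
    """
    lo, hi = band
    if not (-1.0 <= lo <= hi <= 1.0):
        raise ParameterError(f"invalid correlation band {band}")
    if reference_gene not in matrix.genes:
        raise SelectorError(f"reference gene {reference_gene!r} not in matrix")
    if include_baseline == "auto":
        include_baseline = bool(matrix.select(condition="MEF"))
    prepend = "MEF" if include_baseline else None
    course, _ = matrix.timecourse(condition, prepend=prepend)
    if course.shape[1] < 3:
        raise SelectorError("need at least 3 time-course points for correlation")
    x = course.loc[reference_gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InputError("reference gene has a constant profile")
    y = course.to_numpy(dtype=float)
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc**2).sum(axis=1))
    zero_var = denom_y == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (denom_y * np.sqrt(xc @ xc))
    r = pd.Series(r, index=matrix.genes, name="pearson_r").drop(reference_gene)
    zero_names = frozenset(matrix.genes[zero_var]) - {reference_gene}
    if zero_names:
        warnings.warn(
            f"{len(zero_names)} zero-variance profiles excluded from correlation",
            stacklevel=2,
        )
        r = r.drop(list(zero_names))
    selected = frozenset(r.index[(r >= lo) & (r <= hi)])
    return CorrelationResult(reference_gene, r, (lo, hi), selected, zero_names)


def t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t test, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("t test needs at least 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
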
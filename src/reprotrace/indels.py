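"""Indel-spectrum estimation from mixed Sanger traces (TIDE-style).

A mixed amplicon's chromatogram downstream of the Cas9 cut site is modeled
as a non-negative combination of copies of the control trace shifted by
each candidate indel size k in a window ±W:

    y ≈ Σ_k f_k · shift_k(control),   f_k ≥ 0

solved by non-negative least squares over the stacked four-channel signal.
The estimated spectrum is summarized into reading-frame classes (WT,
in-frame 3n+0, frameshift 3n+1 and 3n+2, with k mod 3 the mathematical
modulus into {0,1,2}), and class fractions can be compared between sorted
populations as enrichment ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import InputError, ParameterError, TraceQualityError
from .simulate.traces import TraceSignal, shift_trace

FRAME_CLASSES = ("WT", "inframe_3n0", "shift_3n1", "shift_3n2")


@dataclass(frozen=True)
class Calibration:
    """Intensity scale (multiply edited by it) and integer position offset."""

    scale: float
    offset: int
    rmse: float  # normalized upstream disagreement after calibration


@dataclass
class IndelSpectrum:
    window: int
    frequencies: dict[int, float]  # indel size -> allele frequency
    r_squared: float
    normalized: bool = False

    @property
    def wt_fraction(self) -> float:
        return self.frequencies.get(0, 0.0)

    @property
    def total(self) -> float:
        return float(sum(self.frequencies.values()))


@dataclass
class FrameClassSummary:
    fractions: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, cls: str) -> float:
        return self.fractions[cls]


@dataclass
class PopulationComparison:
    """Per-class allele fractions in two populations and their B/A ratios."""

    fractions_a: dict[str, float]
    fractions_b: dict[str, float]
    ratios: dict[str, float | None]

    def status(self, cls: str) -> str:
        r = self.ratios[cls]
        if r is None:
            return "undefined"
        return "enriched" if r > 1 else ("depleted" if r < 1 else "unchanged")


def _upstream_region(trace: TraceSignal, margin: int = 5) -> slice:
    stop = trace.cut_site - margin
    if stop - margin < 20:
        raise InputError("need >= 20 usable positions upstream of the cut site")
    return slice(margin, stop)


def calibrate(
    control: TraceSignal,
    edited: TraceSignal,
    max_offset: int = 5,
    tolerance: float = 0.2,
) -> Calibration:
    """Least-squares intensity scale and integer alignment offset.

    For each trial offset o, edited[p] is compared against control[p + o]
    over the upstream (pre-cut) region and the best-fitting scale
    a = <e, c>/<e, e> is computed; the offset minimizing the residual wins.
    A normalized RMSE above ``tolerance`` after the best calibration raises
    :class:`TraceQualityError` (unrelated traces).
    """
    if control.cut_site != edited.cut_site:
        raise InputError("control and edited traces disagree on the cut site")
    region = _upstream_region(control, margin=max_offset)
    c = control.array()
    e = edited.array()
    best: Calibration | None = None
    idx = np.arange(region.start, region.stop)
    for off in range(-max_offset, max_offset + 1):
        ee = e[idx].ravel()
        cc = c[idx + off].ravel()
        denom = float(ee @ ee)
        if denom == 0:
            continue
        a = float(ee @ cc) / denom
        if a <= 0:
            continue
        resid = a * ee - cc
        scale_ref = float(np.sqrt(np.mean(cc**2)))
        rmse = float(np.sqrt(np.mean(resid**2))) / (scale_ref or 1.0)
        if best is None or rmse < best.rmse:
            best = Calibration(scale=a, offset=off, rmse=rmse)
    if best is None:
        raise TraceQualityError("could not calibrate traces (degenerate signal)")
    if best.rmse > tolerance:
        raise TraceQualityError(
            f"upstream disagreement {best.rmse:.3f} exceeds tolerance {tolerance}"
        )
    return best


def decompose(
    control: TraceSignal,
    edited: TraceSignal,
    window: int = 10,
    decomp_region: tuple[int, int] | None = None,
    calibration: Calibration | None = None,
    renormalize: bool = False,
    quality_floor: float = 0.5,
) -> IndelSpectrum:
    """Estimate the indel spectrum by non-negative least squares.

    ``decomp_region`` is a half-open (start, stop) position range downstream
    of the cut site; by default it spans from a small buffer after the cut
    to ``window`` positions before the trace end. Frequencies are reported
    unnormalized (their shortfall from 1 is unexplained signal) unless
    ``renormalize`` is set, which rescales them to sum to 1 when the fit's
    R² is at or above ``quality_floor``.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if calibration is None:
        calibration = calibrate(control, edited)
    cut = control.cut_site
    L = control.length
    if decomp_region is None:
        decomp_region = (cut + 5, L - window)
    start, stop = decomp_region
    if start < cut:
        raise InputError("decomposition region must start at or after the cut site")
    if stop > L or stop - window < 0 or start - window < 0:
        raise InputError("decomposition region (plus window) extends past the trace")
    if stop - start < 2 * window + 1:
        raise InputError("decomposition region shorter than the shift window")

    c = control.array()
    e = edited.array() * calibration.scale
    if calibration.offset:
        e = np.roll(e, calibration.offset, axis=0)

    ks = list(range(-window, window + 1))
    cols = [shift_trace(c, k, cut)[start:stop].ravel() for k in ks]
    design = np.column_stack(cols)
    y = e[start:stop].ravel()
    f, rnorm = nnls(design, y)
    rss = float(rnorm**2)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    freqs = {k: float(v) for k, v in zip(ks, f)}
    normalized = False
    if renormalize:
        total = sum(freqs.values())
        if r2 >= quality_floor and total > 0:
            freqs = {k: v / total for k, v in freqs.items()}
            normalized = True
    return IndelSpectrum(window=window, frequencies=freqs, r_squared=r2, normalized=normalized)


def classify_frames(spectrum: IndelSpectrum) -> FrameClassSummary:
    """Summarize an indel spectrum into reading-frame classes.

    WT = f_0; in-frame = Σ f_k over k ≠ 0 with k ≡ 0 (mod 3); frameshift
    classes collect k ≡ 1 and k ≡ 2 (mod 3), the modulus mapping negative
    sizes into {0, 1, 2} (so a 1-bp deletion, k = -1, is a 3n+2 shift).
    """
    out = {c: 0.0 for c in FRAME_CLASSES}
    for k, f in spectrum.frequencies.items():
        if k == 0:
            out["WT"] += f
        elif k % 3 == 0:
            out["inframe_3n0"] += f
        elif k % 3 == 1:
            out["shift_3n1"] += f
        else:
            out["shift_3n2"] += f
    return FrameClassSummary(fractions=out)


def compare_populations(
    summary_a: FrameClassSummary, summary_b: FrameClassSummary
) -> PopulationComparison:
    """Per-class enrichment of population B over population A (ratio B/A).

    Ratios are undefined (None) for classes absent from A.
    """
    ratios: dict[str, float | None] = {}
    for cls in FRAME_CLASSES:
        a = summary_a.fractions.get(cls, 0.0)
        b = summary_b.fractions.get(cls, 0.0)
        ratios[cls] = (b / a) if a > 0 else None
    return PopulationComparison(
        fractions_a=dict(summary_a.fractions),
        fractions_b=dict(summary_b.fractions),
        ratios=ratios,
    )
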
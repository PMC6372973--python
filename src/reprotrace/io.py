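"""File formats: expression TSV, gene sets, GMT, events/screen/trace CSV, TIFF.

All text formats are UTF-8 with '.' decimal separators. Matrices travel as
TSV (genes in rows) with a sidecar sample-metadata TSV; flow events and
screen readouts as CSV; chromatograms as a 4-column peak-height CSV with
the cut site recorded on a leading comment line; annotations as GMT.
Writing then reading any object yields an equal object.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import ParseError
from .expression import ExpressionMatrix, GeneSet
from .simulate.traces import BASES, TraceSignal

_META_SUFFIX = ".samples.tsv"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(_META_SUFFIX)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    matrix.samples.to_csv(_meta_path(path), sep="\t", index_label="sample")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=path)
    meta = _meta_path(path)
    if not meta.exists():
        raise ParseError("sidecar sample metadata not found", path=meta)
    try:
        values = pd.read_csv(path, sep="\t", index_col="gene")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(str(exc), path=path) from exc
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            def _bad(v):
                try:
                    float(v)
                    return False
                except (TypeError, ValueError):
                    return True

            bad = values[col].map(_bad).to_numpy()
            line = int(np.argmax(bad)) + 2  # +1 header line, +1 1-based
            raise ParseError(f"non-numeric cell in column {col!r}", path=path, line=line)
    values.columns.name = "sample"
    samples = pd.read_csv(meta, sep="\t", index_col="sample")
    return ExpressionMatrix(values, samples)


def write_geneset(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_set.members)))


def read_geneset(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    members = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneSet(name or path.stem, frozenset(members), provenance=str(path))


def write_gmt(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            genes = "\t".join(annotation[term])
            fh.write(f"{term}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    ann: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError("GMT line needs term, description, >=1 gene", path=path, line=i)
        ann[parts[0]] = [g for g in parts[2:] if g]
    return ann


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path, required_channels: Iterable[str] = ()) -> pd.DataFrame:
    try:
        events = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(str(exc), path=path) from exc
    missing = [c for c in required_channels if c not in events.columns]
    if missing:
        raise ParseError(f"missing declared channels: {missing}", path=path, line=1)
    for col in events.columns:
        if not pd.api.types.is_numeric_dtype(events[col]):
            raise ParseError(f"non-numeric channel {col!r}", path=path)
    return events


def write_screen(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False)


def read_screen(path: str | Path, control_gene: str = "sgRNA-") -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(str(exc), path=path) from exc
    needed = {"gene", "sgrna_id", "readout_type", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}", path=path, line=1)
    if "is_control" not in df.columns:
        df["is_control"] = df["gene"] == control_gene
    return df


def write_trace(trace: TraceSignal, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cut_site={trace.cut_site}\n")
        trace.heights.to_csv(fh, index_label="pos")


def read_trace(path: str | Path) -> TraceSignal:
    path = Path(path)
    cut_site = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "cut_site=" in first:
        cut_site = int(first.split("cut_site=")[1].strip())
    if cut_site is None:
        raise ParseError("missing '# cut_site=N' header line", path=path, line=1)
    try:
        df = pd.read_csv(path, comment="#", index_col="pos")
    except Exception as exc:
        raise ParseError(str(exc), path=path) from exc
    missing = [b for b in BASES if b not in df.columns]
    if missing:
        raise ParseError(f"missing base columns: {missing}", path=path, line=2)
    return TraceSignal(df[list(BASES)].astype(float), cut_site)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Save a single-channel intensity image as 16-bit TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 65535).round().astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_results(results: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True, default=default) + "\n")


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
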
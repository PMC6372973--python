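#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes an expression time course with planted gene classes, a two-channel
well image, flow-cytometry events, an arrayed screen table and a pair of
chromatograms, all with ground-truth sidecars, under results/data/.
"""

import argparse
from pathlib import Path

from reprotrace import io
from reprotrace.rng import spawn_seeds
from reprotrace.simulate import (
    ExpressionSimConfig,
    FlowSimConfig,
    ScreenSimConfig,
    TraceSimConfig,
    WellSimConfig,
    gen_annotation,
    gen_expression,
    gen_flow_events,
    gen_screen_dataset,
    gen_traces,
    gen_well_image,
)


def main(seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    s = dict(zip(["expr", "well", "flow", "screen", "traces"], spawn_seeds(seed, 5)))

    matrix, truth = gen_expression(ExpressionSimConfig(seed=s["expr"]))
    io.write_expression(matrix, out / "expression.tsv")
    truth.to_csv(out / "expression_truth.tsv", sep="\t")
    io.write_gmt(gen_annotation(truth, seed=s["expr"]), out / "annotation.gmt")
    print(f"expression: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")
    print(truth["gene_class"].value_counts().to_string())

    images, well_truth = gen_well_image(WellSimConfig(seed=s["well"]))
    for ch, img in images.items():
        io.write_image(img, out / f"well_{ch}.tif")
    well_truth.to_csv(out / "well_truth.csv", index=False)
    print(f"well: {len(well_truth)} colonies planted")

    events, comp = gen_flow_events(FlowSimConfig(n_events=10000, seed=s["flow"]))
    io.write_events(events, out / "events.csv")
    comp.to_csv(out / "events_components.csv", index=False)
    print(f"flow: {len(events)} events")

    io.write_screen(gen_screen_dataset(ScreenSimConfig(seed=s["screen"])), out / "screen.csv")
    control, edited = gen_traces(
        TraceSimConfig(spectrum={0: 0.4, -1: 0.25, 1: 0.2, -3: 0.15}, seed=s["traces"])
    )
    io.write_trace(control, out / "trace_control.csv")
    io.write_trace(edited, out / "trace_edited.csv")
    print("screen + traces written")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    a = ap.parse_args()
    main(a.seed, a.out)
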
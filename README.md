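# reprotrace

Quantification pipeline for iPSC reprogramming experiments that compare low-
and high-KLF4 Yamanaka-factor stoichiometries. During reprogramming of mouse
embryonic fibroblasts (MEFs), cells undergo a mesenchymal-to-epithelial
transition (MET); under high KLF4, an additional set of *transient* MET genes
(keratinocyte-like, e.g. *Ovol1*, *Tacstd2*/TROP2) switches on around day 8
and off again in iPSCs, while *sustained* MET genes (*Epcam*, *Cdh1*) stay on.
This package implements the bespoke quantification steps such a study needs,
each testable against synthetic data with planted ground truth:

- **Transient-MET gene derivation** — crosswise fold-change comparisons
  (high- vs low-KLF4 at day 8; keratinocyte vs MEF; mESC vs MEF) at a strict
  `FC > 2` cutoff, a three-way Venn partition, and the rescue rule
  `(HK ∩ KER − ESC) ∪ {g ∈ HK ∩ KER ∩ ESC : day-8 expression > mESC}`,
  plus per-gene dynamics classification (transient / sustained / not induced),
  hypergeometric GO-style term enrichment (cutoff p < 10⁻³), and Pearson
  anti-correlation screening against a reference gene (band −1.0 ≤ r ≤ −0.9).
- **Colony counting** — whole-well two-channel (Nanog-GFP / mCherry) images:
  tophat background subtraction, channel thresholds at
  `mean + 5·SD` of reporter-negative colonies, connected-component
  segmentation, per-colony classification.
- **Flow gating** — median fluorescence intensity (MFI), control-percentile
  gates, DN / single-positive / DP quadrant proportions, KDE-based
  bimodality detection.
- **Screen calling** — arrayed CRISPRi screen with five sgRNAs per gene and
  two proportion readouts (%mCherry⁺, %TROP2⁺); thresholds at the no-sgRNA
  control `mean ± 3·SD`; a gene is a hit when all of its sgRNAs agree.
- **Indel decomposition** — TIDE-style non-negative least squares of an
  edited Sanger trace onto shifted copies of the control trace
  (`y ≈ Σₖ fₖ·shiftₖ(control)`, window ±10), frame classification
  (WT / 3n+0 / 3n+1 / 3n+2 by mathematical modulus), and per-class
  enrichment ratios between sorted populations.
- **Synthetic data** — generators for every input (expression time courses,
  well images, event tables, screens, chromatograms) with truth sidecars.

## Worked example

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_transient_met_genes.py
python analysis/05_screen_hits.py --seed 1
```

prints (abridged):

```
Venn region counts: {'HK_only': 0, 'KER_only': 150, 'ESC_only': 150,
                     'HK_KER': 179, 'HK_ESC': 0, 'KER_ESC': 200, 'HK_KER_ESC': 21}
transient-MET set: 200 genes (200 of 200 planted recovered)
dynamics classification agrees with planted labels for 100.0% of genes
...
hit: Ovol1 down on pct_TROP2_pos (5/5 sgRNAs)
hit: Ovol1 up on pct_mCherry_pos (5/5 sgRNAs)
hit: Tacstd2 down on pct_TROP2_pos (5/5 sgRNAs)
hit: Trp53 up on pct_mCherry_pos (5/5 sgRNAs)
```

The 200-gene transient set is the union of the 179 genes unique to the
high-KLF4 ∩ keratinocyte overlap and the 21 triple-overlap genes rescued
because their day-8 induction overshoots the mESC level (the split between
the two regions moves with the simulation seed; the planted total is always
recovered exactly at zero noise). The screen calls show the expected
pattern: knocking down the proliferation brake raises the %mCherry⁺
intermediate population, knocking down the marker gene itself lowers
%TROP2⁺, and the transient-MET regulator does both, consistently across all
five sgRNAs.

The same stages are available as a CLI for file-based inputs:

```sh
reprotrace simulate expression --seed 3 --out expr/
reprotrace genes transient --expression expr/expression.tsv --out transient.txt
reprotrace screen call --screen screen.csv --out calls.csv
reprotrace indels decompose --control c.csv --edited e.csv --out spectrum.json
reprotrace run --seed 4 --out run/          # full pipeline + manifest
```

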
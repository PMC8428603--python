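# cmapviz

Visualization and analysis of predicted protein residue–residue contact maps
and distograms, integrated with per-residue sequence annotations.

Covariance- and deep-learning-based predictors output, for a protein of
length L, a set of scored residue pairs (a contact map) or a per-pair
probability distribution over binned inter-residue distances (a distogram).
Interpreting these maps usually requires juxtaposing them with other
sequence-based predictions — secondary structure, membrane topology,
disorder, conservation — and with contacts extracted from candidate 3D
models. `cmapviz` is a headless library plus CLI for exactly this workflow,
aimed at structural bioinformaticians evaluating predictions and models:

- **Parsers** for CASP RR files (plain contacts, 3- and 5-column dialects,
  and RMODE 2 binned distances), PSIPRED `.ss2`, IUPred disorder scores,
  TOPCONS topology strings, ConSurf conservation grades, single-record FASTA
  and a simple custom-track format (`start end colour [label] [slot]`).
- **Contact extraction** from PDB models: one representative atom per residue
  (Cβ, Cα for glycine — the CASP convention), contact iff distance ≤ 8 Å.
- **Superposition** of a predicted map P and a model-derived map M: the union
  of contacts is partitioned into *matched* (P ∩ M, drawn black), *model-only*
  (M \ P, red) and *predicted-only* (P \ M, grey).
- **Model-quality scoring** by contact satisfaction: with the top-L/2
  highest-confidence predictions and long-range pairs (|i−j| ≥ 23),

  satisfaction = |matched| / |selected predictions|,

  i.e. the precision of the selected predictions with respect to the model —
  a model realizing the confident long-range predictions is more trustworthy.
- **Figure layout**: the two triangular halves of the square [1, L]² can show
  different maps of the same sequence; the conventionally blank band around
  the diagonal hosts up to **9 annotation tracks** in slots numbered −4…+4
  (slot 0 on the diagonal), with optional mirroring of slot +k into −k.
  Point mode and heatmap (distogram) mode are supported.
- **Rendering** to PNG or SVG (SVG output is byte-deterministic).

## Worked example

The built-in demo generates a fully synthetic membrane-protein scenario —
a 140-residue sequence whose model contains two helical hairpins (re-entrant
segments at residues 16–42 and 105–131, each a membrane band with a central
break), plus matching topology/secondary-structure/conservation tracks, a
predicted contact map and a model PDB — and runs the whole pipeline:

```
$ cmapviz demo --out-dir demo_out --seed 1
figure (png): demo_out/demo.png
figure (svg): demo_out/demo.svg
classification table: demo_out/classification.tsv
matched: 192  model-only: 64  predicted-only: 20
long-range top-L/2 satisfaction: 0.9487
```

Reading the numbers: of the 276 contacts in the union of the two maps (at
the display separation cut-off), 192 are present in both the predicted and
the model map (black points in the upper triangle of `demo.png`), 64 appear
only in the model (red) and 20 only in the prediction (grey). Of the 70
(= L/2) most confident predictions, the long-range ones are realized in the
model at a rate of 0.9487 — a model that satisfies its long-range
predictions this well would be considered well supported. The figure shows
the membrane track (slot 0) with its central break, helix tracks (±1),
conservation gradient (±2) and the purple re-entrant-loop segments from the
custom track (±3/±4).

Other subcommands: `plot` (one or two maps, RR or PDB, `--track
SLOT=FILE[:FORMAT][:mirror]`, optional `--config figure.yaml`), `compare`
(classification table + satisfaction), `extract` (PDB → RR), `convert`
(between RR dialects). Run `cmapviz COMMAND --help` for flags.

## Documentation

See `docs/methods.md` for the underlying conventions (contact definition,
bin layout, band geometry, satisfaction statistic), the synthetic-data
design and known limitations.
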
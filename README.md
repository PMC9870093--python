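# hepaquant

Analysis pipeline for liver-regeneration studies that combine droplet
scRNA-seq with lineage-traced fluorescence microscopy — the setting
where biliary epithelial cells (BECs) act as facultative stem cells and
convert to hepatocytes after severe hepatocyte ablation.

It provides, as a plain Python library:

- **Droplet cell calling** by the cumulative-read-fraction slope rule:
  barcodes ranked by total UMI count; the slope at rank *i* is barcode
  *i*'s share of total UMIs, the mean slope over *N* barcodes is 1/*N*,
  and a barcode is a cell iff slope ≥ 1/*N* (equivalently, total ≥ mean
  total).
- **Ambient background subtraction**: per gene, the nearest-rank 95th
  percentile of counts across background barcodes is subtracted from
  every barcode with a floor at zero, and the matrix is restricted to
  called cells.
- **Cell-state expression analytics**: log-normalization
  ln(1 + 10⁴·c/C), dot-plot statistics, one-vs-rest positive-only
  Wilcoxon marker detection with Bonferroni adjustment (p_adj < 0.05),
  ≥3-marker cluster identification, merging of indistinct clusters,
  `timepoint.celltype` cell states (e.g. `2dpa.BEC`), and heatmaps of
  state-averaged expression min-max scaled per gene row.
- **Single-cell image quantification**: Otsu cellular (GFP ∪ mCherry)
  and nuclear (DAPI) masks, an exactly-one-nucleus filter, per-cell
  area/eccentricity/intensity measurements, GFP-vs-mCherry lineage
  classification, the biliary-derived hepatocyte fraction, and
  percent-positive-nuclei time courses (mean ± SEM, rank-sum vs mock,
  Bonferroni).
- **Statistics**: a self-contained two-sided Wilcoxon rank-sum test
  (exact enumeration for pooled n ≤ 12 without ties, tie-corrected
  normal approximation otherwise), Bonferroni adjustment, mean ± SEM.
- **Synthetic data generators** with analytic ground truth for all
  three data modalities, so every stage is testable without any
  download.

## Worked example

```bash
python examples/droplet_cell_calling.py
```

```
barcodes considered : 2050
average slope (1/N) : 0.000488
called cells        : 50 (true cells: 50)
sensitivity         : 1.000
specificity         : 1.000
genes with ambient threshold > 0 : 47
corrected matrix    : 100 genes x 50 cells
```

The simulated library has 50 true cells (~2000 UMIs, 20% ambient
contamination) among 2000 empty droplets (~20 UMIs). The slope rule
calls exactly the 50 true cells; 47 of 100 genes have a non-zero
ambient threshold, and the corrected matrix keeps only the called
cells. The other scripts in `examples/` walk through marker detection,
state heatmaps, image quantification and time-course testing the same
way.

## Layout

```
src/hepaquant/
  dge.py          DGE matrix container, dense TSV + MatrixMarket I/O
  droplets.py     slope-based cell calling, ambient subtraction
  expression.py   normalization, markers, states, scaled heatmaps
  imaging.py      masks, morphometry, lineage, time-course tests
  stats.py        rank-sum test, Bonferroni, mean ± SEM
  simulate/       droplet, state-expression and image generators
  benchmarks.py   ground-truth recovery benchmarks
  pipeline.py     deterministic end-to-end demo
```

See `docs/methods.md` for the models, parameter choices and known
limitations.
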
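"""End-to-end demonstration pipeline with deterministic CSV outputs.

Runs the full chain on synthetic data — droplet simulation, cell
calling, ambient subtraction, normalization, marker detection, state
heatmap, image simulation and quantification — and writes every result
as CSV. Identical seeds yield byte-identical files, which is the
pipeline's reproducibility contract.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .droplets import preprocess_droplets
from .expression import build_states, find_markers, log_normalize, state_heatmap
from .imaging import (
    ChannelImage,
    cellular_mask,
    filter_single_nucleus,
    measure_cells,
    nuclear_mask,
)

__all__ = ["demo_droplet_spec", "demo_image_spec", "run_demo"]


def demo_droplet_spec(seed: int, n_genes: int = 80) -> simulate.DropletSimSpec:
    """A small two-cell-type droplet library over a skewed ambient soup."""
    rng = np.random.default_rng(seed)
    ambient = rng.dirichlet(np.full(n_genes, 0.3))
    type_a = rng.dirichlet(np.full(n_genes, 0.3))
    type_b = rng.dirichlet(np.full(n_genes, 0.3))
    return simulate.DropletSimSpec(
        n_cells=40,
        n_background=800,
        n_genes=n_genes,
        cell_depth_mean=2000.0,
        background_depth_mean=20.0,
        ambient_profile=ambient,
        celltype_profiles=[type_a, type_b],
        ambient_fraction=0.2,
        seed=seed,
    )


def demo_image_spec(seed: int) -> simulate.ImageSimSpec:
    """A small field of GFP and mCherry cells with one binucleate."""
    roles = {"dapi": 0, "gfp": 1, "mcherry": 2, "cfp": 3}
    cells = [
        simulate.CellSpec((30, 30), 10, 8, 0.0, 1, 3, {"gfp": 300.0, "cfp": 120.0}),
        simulate.CellSpec((30, 90), 12, 7, 0.6, 1, 3, {"mcherry": 280.0, "cfp": 150.0}),
        simulate.CellSpec((90, 40), 14, 9, 1.1, 2, 3, {"mcherry": 260.0}),
        simulate.CellSpec((90, 100), 9, 9, 0.0, 1, 3, {"gfp": 310.0}),
    ]
    return simulate.ImageSimSpec((128, 128), cells, roles, seed=seed)


def run_demo(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Run the full synthetic pipeline and write CSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- droplets: simulate, call cells, subtract ambient background
    dge, truth = simulate.simulate_droplets(demo_droplet_spec(seed))
    corrected, classification, background = preprocess_droplets(dge)
    p = outdir / "barcode_classification.csv"
    classification.to_csv(p)
    written["classification"] = p
    p = outdir / "background_thresholds.csv"
    background.to_csv(p)
    written["background"] = p

    # --- expression: normalize, markers by simulated cell type
    types = truth.barcodes.set_index("barcode")["cell_type"]
    true_cells = [b for b in corrected.barcodes if types.get(b, "") != ""]
    nm = log_normalize(corrected.select_barcodes(true_cells))
    markers = find_markers(nm, types.loc[true_cells])
    p = outdir / "markers.csv"
    markers.to_csv(p, index=False, float_format="%.6g")
    written["markers"] = p

    # --- states: a two-branch regeneration time course
    states = ["mock.BEC", "0dpa.BEC", "2dpa.BEC", "2dpa.HC", "7dpa.HC"]
    programs = {
        "biliary": (["anxa4", "krt18a.1", "alcama"],
                    {"mock.BEC": 10, "0dpa.BEC": 8, "2dpa.BEC": 5, "2dpa.HC": 3, "7dpa.HC": 1}),
        "hepatocyte": (["fabp10a", "tfa", "cp"],
                       {"mock.BEC": 0, "0dpa.BEC": 0, "2dpa.BEC": 1, "2dpa.HC": 4, "7dpa.HC": 10}),
    }
    expr, meta = simulate.simulate_state_expression(
        simulate.StateSimSpec(states, 40, programs, dispersion=2.0, seed=seed)
    )
    nm_states = log_normalize(expr)
    meta = build_states(meta.drop(columns="state"))
    hm = state_heatmap(
        nm_states, meta.set_index("cell")["state"],
        ["anxa4", "krt18a.1", "fabp10a", "tfa"], states,
    )
    p = outdir / "state_heatmap.csv"
    hm.rename_axis("gene").to_csv(p, float_format="%.6g")
    written["heatmap"] = p

    # --- imaging: render, segment, measure
    planes, img_truth = simulate.simulate_image(demo_image_spec(seed))
    img = ChannelImage(planes, {"dapi": 0, "gfp": 1, "mcherry": 2, "cfp": 3})
    cells = cellular_mask(img)
    nuclei = nuclear_mask(img)
    records = filter_single_nucleus(measure_cells(cells, nuclei, img))
    p = outdir / "cell_records.csv"
    records.to_csv(p, index=False, float_format="%.6g")
    written["cells"] = p

    return written
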
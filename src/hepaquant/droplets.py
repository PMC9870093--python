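"""Slope-based droplet cell calling and ambient background subtraction.

Barcodes are ranked by total UMI count; on the cumulative-read-fraction
curve the pointwise slope at rank i is barcode i's share of total UMIs,
and the mean slope over the N barcodes considered is exactly 1/N. A
barcode at or above the mean slope is called a cell, below it
background. The ambient background is then modelled per gene as the
95th-percentile (nearest-rank) UMI count across background barcodes,
subtracted from every barcode with a floor at zero, and the matrix is
restricted to the called cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DGEMatrix

__all__ = [
    "BarcodeClassification",
    "BackgroundModel",
    "rank_barcodes",
    "classify_barcodes",
    "fit_background_model",
    "subtract_background",
    "preprocess_droplets",
]


@dataclass
class BarcodeClassification:
    """Per-barcode cell/background call with the slopes that produced it.

    ``table`` is ordered by rank and has columns barcode, total, slope,
    label; ``average_slope`` equals 1 / (barcodes considered).
    """

    table: pd.DataFrame = field(repr=False)
    average_slope: float
    max_barcodes_used: int

    @property
    def cell_barcodes(self) -> list[str]:
        return list(self.table.loc[self.table["label"] == "cell", "barcode"])

    @property
    def background_barcodes(self) -> list[str]:
        return list(self.table.loc[self.table["label"] == "background", "barcode"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class BackgroundModel:
    """Per-gene ambient UMI thresholds (nearest-rank quantile over
    background barcodes)."""

    thresholds: pd.Series = field(repr=False)  # index: gene, integer values
    quantile_level: float
    n_background_barcodes: int

    def to_csv(self, path) -> None:
        self.thresholds.rename("threshold").rename_axis("gene").to_csv(path)


def rank_barcodes(m: DGEMatrix, max_barcodes: int | None = None) -> pd.Series:
    """Barcodes sorted by total UMI count descending, ties broken by
    barcode identifier, truncated to the top ``max_barcodes``."""
    totals = m.barcode_totals()
    if totals.sum() == 0:
        raise ValueError("matrix has no UMIs; nothing to rank")
    ranked = totals.sort_index().sort_values(ascending=False, kind="mergesort")
    if max_barcodes is not None:
        ranked = ranked.iloc[:max_barcodes]
    return ranked


def classify_barcodes(m: DGEMatrix, max_barcodes: int = 5000) -> BarcodeClassification:
    """Call cells by the cumulative-read-fraction slope rule.

    Considering the top ``max_barcodes`` ranked barcodes, the slope at
    each rank is that barcode's fraction of the considered total; the
    average slope is the mean of those slopes (1/N). Labels: ``cell``
    if slope >= average, else ``background``. Ties at the average are
    called cells so that a perfectly uniform library is kept whole.
    """
    ranked = rank_barcodes(m, max_barcodes)
    n = len(ranked)
    if n < 2:
        raise ValueError("need at least 2 barcodes to classify")
    grand_total = float(ranked.sum())
    slopes = ranked.to_numpy(dtype=float) / grand_total
    average_slope = 1.0 / n
    labels = np.where(slopes >= average_slope, "cell", "background")
    table = pd.DataFrame(
        {
            "barcode": ranked.index,
            "total": ranked.to_numpy(),
            "slope": slopes,
            "label": labels,
        }
    )
    return BarcodeClassification(table, average_slope, max_barcodes)


def fit_background_model(
    m: DGEMatrix,
    c: BarcodeClassification,
    quantile_level: float = 0.95,
) -> BackgroundModel:
    """Per-gene nearest-rank quantile of counts over background barcodes.

    The threshold for gene g is the order statistic at position
    ceil(quantile_level * n_background) of g's counts across the
    background barcodes, so thresholds stay integral.
    """
    if not (0.0 < quantile_level < 1.0):
        raise ValueError("quantile_level must lie in (0, 1)")
    background = c.background_barcodes
    if not background:
        raise ValueError(
            "no background barcodes were called; ambient subtraction is undefined"
        )
    sub = m.select_barcodes(background).counts
    k = int(np.ceil(quantile_level * sub.shape[1]))  # 1-based order statistic
    ordered = np.sort(sub, axis=1)
    thresholds = pd.Series(ordered[:, k - 1], index=m.genes)
    return BackgroundModel(thresholds, quantile_level, len(background))


def subtract_background(
    m: DGEMatrix,
    b: BackgroundModel,
    c: BarcodeClassification,
) -> DGEMatrix:
    """Floored per-gene subtraction, then restriction to called cells.

    corrected(g, bc) = max(0, count(g, bc) - threshold(g)), applied to
    every barcode; the output keeps only barcodes labelled ``cell``, in
    rank order.
    """
    if list(b.thresholds.index) != list(m.genes):
        missing = set(m.genes) - set(b.thresholds.index)
        if missing:
            raise ValueError(f"background model missing genes: {sorted(missing)[:5]}")
        b = BackgroundModel(
            b.thresholds.reindex(m.genes), b.quantile_level, b.n_background_barcodes
        )
    corrected = np.maximum(
        m.counts - b.thresholds.to_numpy(dtype=np.int64)[:, None], 0
    )
    corrected_m = DGEMatrix(list(m.genes), list(m.barcodes), corrected)
    cells = c.cell_barcodes
    if not cells:
        warnings.warn("no barcodes were called as cells; output matrix is empty")
    return corrected_m.select_barcodes(cells)


def preprocess_droplets(
    m: DGEMatrix,
    max_barcodes: int = 5000,
    quantile_level: float = 0.95,
) -> tuple[DGEMatrix, BarcodeClassification, BackgroundModel]:
    """Full chain: classify barcodes, fit the ambient model, subtract."""
    c = classify_barcodes(m, max_barcodes)
    b = fit_background_model(m, c, quantile_level)
    return subtract_background(m, b, c), c, b
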
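"""Normalization, marker detection, cell-state construction and the
row-scaled average-expression heatmaps of cluster/state analyses.

Marker finding is the classic one-vs-rest positive-only recipe: genes
passing detection-fraction and log-fold-change prefilters are tested
with a two-sided Wilcoxon rank-sum test, Bonferroni-adjusted over all
tests performed, and retained when adjusted p < 0.05 with higher mean
expression inside the cluster.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DGEMatrix
from .stats import bonferroni, rank_sum_test

__all__ = [
    "NormalizedMatrix",
    "AmbiguousClusterError",
    "log_normalize",
    "dotplot_stats",
    "find_markers",
    "identify_cluster",
    "merge_indistinct_clusters",
    "build_states",
    "parse_state",
    "state_heatmap",
    "conserved_marker_heatmap",
    "minmax_scale_rows",
]

DEFAULT_ALPHA = 0.05


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of log-transformed normalized UMI counts."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray = field(repr=False)
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


class AmbiguousClusterError(ValueError):
    """A cluster matched the marker panels of more than one cell type."""


def log_normalize(m: DGEMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """ln(1 + count / cell_total * scale_factor) per entry.

    Depth normalization to ``scale_factor`` counts per cell followed by
    log1p; every zero-total cell is an error because its expression is
    undefined.
    """
    totals = m.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {m.barcodes[zero[0]]!r} has zero total count")
    values = np.log1p(m.counts / totals[None, :] * scale_factor)
    return NormalizedMatrix(list(m.genes), list(m.barcodes), values, scale_factor)


def _labels_series(nm: NormalizedMatrix, labels) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    missing = [c for c in nm.cells if c not in s.index]
    if missing:
        raise ValueError(f"labels missing for cells: {missing[:5]}")
    return s.loc[nm.cells]


def dotplot_stats(nm: NormalizedMatrix, labels, genes) -> pd.DataFrame:
    """Per (gene, cluster): mean normalized expression and the fraction
    of the cluster's cells expressing the gene (count > 0)."""
    s = _labels_series(nm, labels)
    rows = []
    for cluster, cells in s.groupby(s, observed=True).groups.items():
        idx = [nm.cells.index(c) for c in cells]
        if not idx:
            raise ValueError(f"cluster {cluster!r} is empty")
        for gene in genes:
            vals = nm.gene_row(gene)[idx]
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "avg_expression": float(vals.mean()),
                    "fraction_expressing": float((vals > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


def _log_fold_change(in_vals: np.ndarray, out_vals: np.ndarray) -> float:
    """Natural-log fold change of depth-normalized means, consistent
    with log1p-normalized input: ln((mean(expm1(in)) + 1) /
    (mean(expm1(out)) + 1))."""
    return float(
        np.log((np.expm1(in_vals).mean() + 1.0) / (np.expm1(out_vals).mean() + 1.0))
    )


def find_markers(
    nm: NormalizedMatrix,
    labels,
    min_fraction: float = 0.1,
    min_logfc: float = 0.25,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-vs-rest positive-only marker detection per cluster.

    Prefilters: the gene must be detected in at least ``min_fraction``
    of cells on the higher-detection side, and its log fold-change in
    favour of the cluster must reach ``min_logfc``. Passing genes are
    tested with the two-sided Wilcoxon rank-sum test and Bonferroni
    adjusted with the total number of genes in the matrix as the family
    (the classic FindAllMarkers convention — correcting only over the
    post-prefilter tests would not survive the selection step, since
    the prefilter favours genes with small p-values). The family size
    is recorded in ``result.attrs["bonferroni_m"]``. Retained rows
    satisfy p_adj < alpha and mean-in > mean-in-rest.
    """
    s = _labels_series(nm, labels)
    clusters = sorted(s.unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to find markers")

    cell_idx = {c: i for i, c in enumerate(nm.cells)}
    rows = []
    for cluster in clusters:
        in_idx = np.array([cell_idx[c] for c in s.index[s == cluster]])
        out_idx = np.array([cell_idx[c] for c in s.index[s != cluster]])
        if len(in_idx) < 3:
            warnings.warn(f"cluster {cluster!r} has fewer than 3 cells; skipped")
            continue
        for gi, gene in enumerate(nm.genes):
            in_vals = nm.values[gi, in_idx]
            out_vals = nm.values[gi, out_idx]
            frac_in = float((in_vals > 0).mean())
            frac_out = float((out_vals > 0).mean())
            if max(frac_in, frac_out) < min_fraction:
                continue
            lfc = _log_fold_change(in_vals, out_vals)
            if lfc < min_logfc:  # only.pos: cluster must be the high side
                continue
            res = rank_sum_test(in_vals, out_vals)
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "mean_in": float(in_vals.mean()),
                    "mean_out": float(out_vals.mean()),
                    "log_fc": lfc,
                    "p_value": res.p_value,
                    "frac_in": frac_in,
                    "frac_out": frac_out,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene", "cluster", "mean_in", "mean_out", "log_fc",
            "p_value", "frac_in", "frac_out",
        ],
    )
    m = len(nm.genes)
    if result.empty:
        result["p_adj"] = pd.Series(dtype=float)
        result.attrs["bonferroni_m"] = m
        return result
    result["p_adj"] = bonferroni(result["p_value"], m=m)
    keep = (result["p_adj"] < alpha) & (result["mean_in"] > result["mean_out"])
    out = result.loc[keep].reset_index(drop=True)
    out.attrs["bonferroni_m"] = m
    return out


def identify_cluster(markers: pd.DataFrame, panel: dict[str, list[str]]) -> dict:
    """Assign each cluster a cell type when >= 3 of that type's panel
    genes appear among the cluster's retained markers.

    A cluster matching two or more types at the threshold is an error:
    the ambiguity is surfaced, not resolved.
    """
    for cell_type, genes in panel.items():
        if len(genes) < 3:
            raise ValueError(f"panel for {cell_type!r} lists fewer than 3 genes")
    assignments: dict = {}
    if markers.empty:
        return assignments
    for cluster, sub in markers.groupby("cluster", observed=True):
        marker_genes = set(sub["gene"])
        hits = [
            ct for ct, genes in panel.items() if len(marker_genes & set(genes)) >= 3
        ]
        if len(hits) > 1:
            raise AmbiguousClusterError(
                f"cluster {cluster!r} matches >=3 markers of multiple types: {hits}"
            )
        assignments[cluster] = hits[0] if hits else "unassigned"
    return assignments


def merge_indistinct_clusters(
    nm: NormalizedMatrix,
    labels,
    min_fraction: float = 0.1,
    min_logfc: float = 0.25,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Merge cluster pairs with no head-to-head differential genes.

    For each pair, genes passing the detection and |log fold-change|
    prefilters (either direction) are rank-sum tested and Bonferroni
    adjusted with the total gene count as the family (as in
    :func:`find_markers`); a pair with zero genes at p_adj < alpha
    is indistinct. Indistinct relations are closed transitively and
    each connected component collapses to its smallest original label.
    """
    s = _labels_series(nm, labels)
    clusters = sorted(s.unique(), key=str)
    if len(clusters) < 2:
        return s.copy()

    cell_idx = {c: i for i, c in enumerate(nm.cells)}
    parent = {c: c for c in clusters}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted([ra, rb], key=str)
            parent[hi] = lo

    for a, b in itertools.combinations(clusters, 2):
        a_idx = np.array([cell_idx[c] for c in s.index[s == a]])
        b_idx = np.array([cell_idx[c] for c in s.index[s == b]])
        p_values = []
        for gi in range(len(nm.genes)):
            va, vb = nm.values[gi, a_idx], nm.values[gi, b_idx]
            frac_a, frac_b = float((va > 0).mean()), float((vb > 0).mean())
            if max(frac_a, frac_b) < min_fraction:
                continue
            if abs(_log_fold_change(va, vb)) < min_logfc:
                continue
            p_values.append(rank_sum_test(va, vb).p_value)
        if not p_values or not np.any(bonferroni(p_values, m=len(nm.genes)) < alpha):
            union(a, b)

    return s.map({c: find(c) for c in clusters})


def build_states(meta: pd.DataFrame) -> pd.DataFrame:
    """Combine timepoint and cell-type labels into a cell-state label
    (``timepoint.celltype``, e.g. ``2dpa.BEC``)."""
    out = meta.copy()
    for col in ("timepoint", "cell_type"):
        if col not in out.columns:
            raise ValueError(f"metadata lacks a {col!r} column")
        bad = out.index[out[col].isna() | (out[col].astype(str) == "")]
        if len(bad):
            cell = out.loc[bad[0]].get("cell", bad[0])
            raise ValueError(f"cell {cell!r} is missing its {col} label")
    out["state"] = out["timepoint"].astype(str) + "." + out["cell_type"].astype(str)
    return out


def parse_state(state: str) -> tuple[str, str]:
    """Inverse of state construction: '2dpa.BEC' -> ('2dpa', 'BEC')."""
    tp, ct = state.split(".", 1)
    return tp, ct


def minmax_scale_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - min) / (max - min); constant rows map to all zeros."""
    vals = df.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(scaled, index=df.index, columns=df.columns)


def state_heatmap(
    nm: NormalizedMatrix,
    states,
    genes,
    column_order: list[str],
) -> pd.DataFrame:
    """Row-scaled heatmap of state-averaged expression.

    Columns follow ``column_order`` (e.g. mock -> 0dpa -> ... -> 7dpa
    along one branch); each row is min-max scaled to [0, 1].
    """
    if isinstance(states, pd.DataFrame):
        states = states.set_index("cell")["state"] if "cell" in states.columns else states["state"]
    s = _labels_series(nm, states)
    unknown = [g for g in genes if g not in nm.genes]
    if unknown:
        raise KeyError(f"unknown genes: {unknown}")
    for st in column_order:
        if not (s == st).any():
            raise ValueError(f"requested state {st!r} has no cells")
    avg = pd.DataFrame(index=list(genes), columns=column_order, dtype=float)
    for st in column_order:
        idx = np.flatnonzero((s == st).to_numpy())
        for g in genes:
            avg.loc[g, st] = float(nm.gene_row(g)[idx].mean())
    return minmax_scale_rows(avg)


def conserved_marker_heatmap(
    species_data: dict[str, tuple[NormalizedMatrix, "pd.Series"]],
    ortholog_table: pd.DataFrame,
    column_orders: dict[str, list[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cross-species row-scaled heatmaps over an ortholog table.

    ``ortholog_table`` has one column per species naming that species'
    gene; rows unresolvable in any species are dropped with a warning.
    Each species gets a heatmap of cluster-averaged scaled expression
    with the shared row order of the table.
    """
    keep = []
    for i, row in ortholog_table.iterrows():
        ok = all(row[sp] in species_data[sp][0].genes for sp in species_data)
        if ok:
            keep.append(i)
        else:
            warnings.warn(f"ortholog row {i} unresolvable in all species; dropped")
    table = ortholog_table.loc[keep]

    out: dict[str, pd.DataFrame] = {}
    for sp, (nm, labels) in species_data.items():
        s = _labels_series(nm, labels)
        order = (
            column_orders[sp] if column_orders else sorted(s.unique(), key=str)
        )
        genes = list(table[sp])
        hm = state_heatmap(nm, s, genes, order)
        hm.index = pd.Index(keep, name="ortholog_row")
        out[sp] = hm
    return out
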
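"""Droplet scRNA-seq simulator: true cells over an ambient background.

True cells draw a Poisson depth around ``cell_depth_mean`` and sample
genes from a mixture of their cell-type profile and the shared ambient
profile; empty (background) barcodes draw a much shallower Poisson depth
from the ambient profile alone. This reproduces the knee-shaped
barcode-rank curve that slope-based cell calling exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..dge import DGEMatrix

__all__ = ["DropletSimSpec", "DropletTruth", "simulate_droplets"]

_PROB_TOL = 1e-9


def _check_profile(p: np.ndarray, name: str, n_genes: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n_genes,):
        raise ValueError(f"{name} must have length n_genes={n_genes}, got {p.shape}")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1 (got {p.sum():.12f})")
    return p


@dataclass
class DropletSimSpec:
    """Parameters of a simulated droplet library.

    ``ambient_fraction`` is the share of each true cell's UMIs drawn
    from the ambient profile (soup contamination); background barcodes
    are pure ambient.
    """

    n_cells: int
    n_background: int
    n_genes: int
    cell_depth_mean: float
    background_depth_mean: float
    ambient_profile: np.ndarray
    celltype_profiles: list[np.ndarray]
    ambient_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_background < 0 or self.n_genes < 1:
            raise ValueError("n_cells/n_background must be >= 0, n_genes >= 1")
        if self.cell_depth_mean <= self.background_depth_mean:
            raise ValueError("cell_depth_mean must exceed background_depth_mean")
        if not (0.0 <= self.ambient_fraction < 1.0):
            raise ValueError("ambient_fraction must lie in [0, 1)")
        self.ambient_profile = _check_profile(self.ambient_profile, "ambient_profile", self.n_genes)
        if self.n_cells > 0 and not self.celltype_profiles:
            raise ValueError("at least one celltype_profile required when n_cells > 0")
        self.celltype_profiles = [
            _check_profile(p, f"celltype_profiles[{i}]", self.n_genes)
            for i, p in enumerate(self.celltype_profiles)
        ]


@dataclass
class DropletTruth:
    """Ground truth for a simulated droplet library."""

    barcodes: pd.DataFrame = field(repr=False)  # barcode, is_cell, cell_type
    celltype_profiles: list[np.ndarray] = field(repr=False)

    @property
    def is_cell(self) -> pd.Series:
        return self.barcodes.set_index("barcode")["is_cell"]


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 12) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_droplets(spec: DropletSimSpec) -> tuple[DGEMatrix, DropletTruth]:
    """Simulate a genes x barcodes UMI matrix plus per-barcode truth.

    Returns the matrix (true cells first, then background barcodes) and
    a :class:`DropletTruth` with the is-cell flag, the cell-type
    assignment (round-robin over ``celltype_profiles``), and the clean
    cell-type profiles for recovery comparisons.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    n_total = spec.n_cells + spec.n_background
    barcodes = _random_barcodes(rng, n_total)

    counts = np.zeros((spec.n_genes, n_total), dtype=np.int64)
    cell_types: list[str] = []
    k = len(spec.celltype_profiles)
    for j in range(spec.n_cells):
        t = j % k
        profile = (
            (1.0 - spec.ambient_fraction) * spec.celltype_profiles[t]
            + spec.ambient_fraction * spec.ambient_profile
        )
        depth = rng.poisson(spec.cell_depth_mean)
        counts[:, j] = rng.multinomial(depth, profile)
        cell_types.append(f"type{t}")
    for j in range(spec.n_cells, n_total):
        depth = rng.poisson(spec.background_depth_mean)
        counts[:, j] = rng.multinomial(depth, spec.ambient_profile)
        cell_types.append("")

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_cell": [j < spec.n_cells for j in range(n_total)],
            "cell_type": cell_types,
        }
    )
    return DGEMatrix(genes, barcodes, counts), DropletTruth(truth, list(spec.celltype_profiles))
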
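"""Cell-state expression simulator with gene-program structure.

Counts are negative-binomial with per-state means defined by named gene
programs (e.g. a biliary program decaying along the hepatocyte branch of
a regeneration time course, proliferation peaking mid-course). The
accompanying state table assigns each cell its timepoint.celltype state
label, mirroring how regeneration time courses are organised
(mock, 0dpa ... 7dpa x BEC / HC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..dge import DGEMatrix

__all__ = ["StateSimSpec", "simulate_state_expression"]


@dataclass
class StateSimSpec:
    """Simulation of state-structured counts.

    ``gene_programs`` maps a program name to ``(gene list, {state:
    mean})``; every gene in a program shares that program's per-state
    mean schedule. ``dispersion`` is the negative-binomial size
    parameter (variance = m + m^2 / dispersion; large values approach
    Poisson).
    """

    states: list[str]
    cells_per_state: int
    gene_programs: dict[str, tuple[list[str], dict[str, float]]]
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_state < 1:
            raise ValueError("cells_per_state must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        seen: set[str] = set()
        for name, (genes, levels) in self.gene_programs.items():
            for s, level in levels.items():
                if s not in self.states:
                    raise ValueError(f"program {name!r} references unknown state {s!r}")
                if level < 0:
                    raise ValueError(f"program {name!r} has negative level for {s!r}")
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in more than one program")
                seen.add(g)


def _split_state(state: str) -> tuple[str, str]:
    """'2dpa.BEC' -> ('2dpa', 'BEC'); states without a dot get an empty
    cell-type part."""
    if "." in state:
        tp, ct = state.split(".", 1)
        return tp, ct
    return state, ""


def simulate_state_expression(spec: StateSimSpec) -> tuple[DGEMatrix, pd.DataFrame]:
    """Simulate counts plus a state table (cell, timepoint, cell_type, state)."""
    rng = np.random.default_rng(spec.seed)
    genes: list[str] = []
    program_of: dict[str, str] = {}
    for name, (glist, _) in spec.gene_programs.items():
        for g in glist:
            genes.append(g)
            program_of[g] = name

    cells: list[str] = []
    rows = []
    state_of_cell: list[str] = []
    for s in spec.states:
        tp, ct = _split_state(s)
        for i in range(spec.cells_per_state):
            cid = f"{s}_{i:04d}"
            cells.append(cid)
            state_of_cell.append(s)
            rows.append({"cell": cid, "timepoint": tp, "cell_type": ct, "state": s})
    state_table = pd.DataFrame(rows)

    counts = np.zeros((len(genes), len(cells)), dtype=np.int64)
    theta = spec.dispersion
    for gi, g in enumerate(genes):
        levels = spec.gene_programs[program_of[g]][1]
        for s in spec.states:
            m = float(levels.get(s, 0.0))
            cols = [j for j, cs in enumerate(state_of_cell) if cs == s]
            if m <= 0.0:
                continue
            p = theta / (theta + m)
            counts[gi, cols] = rng.negative_binomial(theta, p, size=len(cols))

    return DGEMatrix(genes, cells, counts), state_table
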
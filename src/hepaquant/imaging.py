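"""Single-cell quantification of lineage-traced fluorescence images.

Mirrors a dissociated-cell measurement pipeline: a cellular mask from
the union of the GFP and mCherry reporter channels, a nuclear mask from
DAPI, an exactly-one-nucleus filter, per-cell morphology (area,
eccentricity of the moment-matched ellipse) and fluorescence means,
lineage classification, and per-animal percent-positive-nuclei time
courses tested against the mock (uninjured) group.

Thresholding is global Otsu per channel with a fixed-value override;
touching objects are not split, and cells clipped by the image border
are excluded.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects

from .stats import bonferroni, mean_sem, rank_sum_test

__all__ = [
    "ChannelImage",
    "cellular_mask",
    "nuclear_mask",
    "assign_nuclei",
    "filter_single_nucleus",
    "measure_cells",
    "export_grid",
    "classify_lineage",
    "biliary_derived_fraction",
    "positive_nuclei_fraction",
    "timecourse_test",
]

logger = logging.getLogger(__name__)

CELL_MIN_AREA = 50  # px^2
NUCLEUS_MIN_AREA = 10  # px^2


@dataclass
class ChannelImage:
    """Multi-channel 2D image with a role -> plane map
    (roles: dapi, gfp, mcherry, cfp, marker)."""

    planes: np.ndarray = field(repr=False)  # (channels, rows, cols)
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ValueError("planes must be (channels, rows, cols)")
        for role, idx in self.channel_roles.items():
            if not (0 <= idx < self.planes.shape[0]):
                raise ValueError(f"role {role!r} references missing plane {idx}")

    def plane(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(f"image has no {role!r} channel")
        return self.planes[self.channel_roles[role]]


def _foreground(plane: np.ndarray, threshold: float | None) -> np.ndarray:
    """Otsu foreground (or fixed threshold); a constant plane has none."""
    if threshold is None:
        if plane.max() == plane.min():
            return np.zeros(plane.shape, dtype=bool)
        threshold = threshold_otsu(plane)
    return plane > threshold


def _clean_label(mask: np.ndarray, min_area: int) -> np.ndarray:
    filled = ndimage.binary_fill_holes(mask)
    cleaned = remove_small_objects(filled, max_size=min_area - 1)
    return cc_label(cleaned, connectivity=2)  # 8-connectivity


def cellular_mask(
    img: ChannelImage,
    min_area: int = CELL_MIN_AREA,
    thresholds: dict[str, float] | None = None,
) -> np.ndarray:
    """Labelled cell mask from the union of GFP and mCherry foregrounds."""
    thresholds = thresholds or {}
    union = np.zeros(img.planes.shape[1:], dtype=bool)
    for role in ("gfp", "mcherry"):
        union |= _foreground(img.plane(role), thresholds.get(role))
    return _clean_label(union, min_area)


def nuclear_mask(
    img: ChannelImage,
    min_area: int = NUCLEUS_MIN_AREA,
    threshold: float | None = None,
) -> np.ndarray:
    """Labelled nuclear mask from the DAPI foreground."""
    return _clean_label(_foreground(img.plane("dapi"), threshold), min_area)


def _nucleus_centroid_cells(cells: np.ndarray, nuclei: np.ndarray) -> list[int]:
    """Cell label at each nucleus's centroid pixel (0 = no cell)."""
    owners = []
    for prop in regionprops(nuclei):
        r, c = (int(round(x)) for x in prop.centroid)
        owners.append(int(cells[r, c]))
    return owners


def assign_nuclei(cells: np.ndarray, nuclei: np.ndarray) -> dict[int, int]:
    """Per-cell nucleus count by nucleus-centroid containment."""
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nuclear masks must share shape")
    counts = {int(lbl): 0 for lbl in np.unique(cells) if lbl != 0}
    for owner in _nucleus_centroid_cells(cells, nuclei):
        if owner != 0:
            counts[owner] += 1
    return counts


def measure_cells(
    cells: np.ndarray,
    nuclei: np.ndarray,
    img: ChannelImage,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Morphology and fluorescence per segmented cell.

    Area is the pixel count; eccentricity comes from the ellipse with
    matching normalized second central moments; intensities are means
    over the cell's pixels per channel role. Cells whose mask touches
    the image border are excluded (their shape is truncated).
    """
    nucleus_counts = assign_nuclei(cells, nuclei)
    border = np.zeros(cells.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    rows = []
    n_border = 0
    for prop in regionprops(cells):
        if exclude_border and border[prop.slice][prop.image].any():
            n_border += 1
            continue
        rec = {
            "cell": int(prop.label),
            "centroid_row": float(prop.centroid[0]),
            "centroid_col": float(prop.centroid[1]),
            "area": float(prop.area),
            "eccentricity": float(prop.eccentricity),
            "nucleus_count": nucleus_counts.get(int(prop.label), 0),
        }
        mask = cells == prop.label
        for role, idx in img.channel_roles.items():
            rec[f"mean_{role}"] = float(img.planes[idx][mask].mean())
        rows.append(rec)
    if n_border:
        logger.info("excluded %d border-touching cell(s)", n_border)
    return pd.DataFrame(rows)


def filter_single_nucleus(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only cells with exactly one nucleus; log what was removed."""
    if records.empty:
        return records.copy()
    removed = records.loc[records["nucleus_count"] != 1]
    if len(removed):
        logger.info(
            "single-nucleus filter removed %d of %d cells (counts: %s)",
            len(removed),
            len(records),
            removed["nucleus_count"].value_counts().to_dict(),
        )
    return records.loc[records["nucleus_count"] == 1].reset_index(drop=True)


def export_grid(
    records: pd.DataFrame,
    img: ChannelImage,
    thumb_size: int = 32,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Tile per-cell thumbnails (cropped around centroids, zero-padded
    at the borders) row-major into one grid image per channel.

    Returns the grid (channels, H, W) and an index table mapping grid
    position to cell id and source crop origin.
    """
    if records.empty:
        raise ValueError("no cells to export")
    n = len(records)
    ncol = math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    c, h, w = img.planes.shape
    grid = np.zeros((c, nrow * thumb_size, ncol * thumb_size), dtype=img.planes.dtype)
    index_rows = []
    half = thumb_size // 2
    for k, (_, rec) in enumerate(records.iterrows()):
        r0 = int(round(rec["centroid_row"])) - half
        c0 = int(round(rec["centroid_col"])) - half
        thumb = np.zeros((c, thumb_size, thumb_size), dtype=img.planes.dtype)
        rs, re = max(r0, 0), min(r0 + thumb_size, h)
        cs, ce = max(c0, 0), min(c0 + thumb_size, w)
        thumb[:, rs - r0 : re - r0, cs - c0 : ce - c0] = img.planes[:, rs:re, cs:ce]
        gr, gc = divmod(k, ncol)
        grid[
            :,
            gr * thumb_size : (gr + 1) * thumb_size,
            gc * thumb_size : (gc + 1) * thumb_size,
        ] = thumb
        index_rows.append(
            {
                "grid_row": gr,
                "grid_col": gc,
                "cell": rec["cell"],
                "crop_row0": r0,
                "crop_col0": c0,
            }
        )
    return grid, pd.DataFrame(index_rows)


def classify_lineage(
    records: pd.DataFrame,
    gfp_threshold: float,
    mcherry_threshold: float,
) -> pd.DataFrame:
    """Call each cell gfp- or mCherry-lineage by reporter intensity.

    A cell is one lineage only when it is above that reporter's
    threshold and at or below the other's; anything else is ambiguous.
    """
    if gfp_threshold < 0 or mcherry_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    out = records.copy()
    gfp = out["mean_gfp"] > gfp_threshold
    mch = out["mean_mcherry"] > mcherry_threshold
    out["lineage"] = np.select(
        [gfp & ~mch, mch & ~gfp], ["gfp", "mcherry"], default="ambiguous"
    )
    return out


def biliary_derived_fraction(records: pd.DataFrame, cfp_threshold: float) -> float:
    """Fraction of hepatocytes (CFP-positive cells) carrying the
    mCherry lineage label, i.e. derived from biliary epithelial cells."""
    hep = records.loc[records["mean_cfp"] > cfp_threshold]
    if hep.empty:
        raise ValueError("no CFP-positive cells; biliary-derived fraction undefined")
    return float((hep["lineage"] == "mcherry").mean())


def positive_nuclei_fraction(
    images: list[ChannelImage],
    lineage_role: str = "mcherry",
    marker_role: str = "marker",
    marker_threshold: float | None = None,
    lineage_threshold: float | None = None,
) -> float:
    """Fraction of lineage-resident nuclei positive for a marker
    (e.g. PCNA / BrdU / H3P), pooled over one animal's images.

    Denominator: nuclei whose centroid lies inside a lineage-positive
    cell region (Otsu foreground of the lineage channel, cleaned like
    the cellular mask). Numerator: those whose mean marker intensity
    exceeds ``marker_threshold`` — a fixed value, or by default Otsu
    over the candidate nuclei's mean intensities for this animal.
    """
    candidate_means: list[float] = []
    for img in images:
        lineage = _clean_label(
            _foreground(img.plane(lineage_role), lineage_threshold), CELL_MIN_AREA
        )
        nuclei = nuclear_mask(img)
        marker_plane = img.plane(marker_role)
        for prop in regionprops(nuclei):
            r, c = (int(round(x)) for x in prop.centroid)
            if lineage[r, c] != 0:
                candidate_means.append(float(marker_plane[nuclei == prop.label].mean()))
    if not candidate_means:
        raise ValueError("no lineage-resident nuclei found; animal should be excluded")
    means = np.asarray(candidate_means)
    if marker_threshold is None:
        if means.max() == means.min():
            return 0.0
        marker_threshold = threshold_otsu(means)
    return float((means > marker_threshold).mean())


def timecourse_test(
    fractions: pd.DataFrame,
    reference: str = "mock",
) -> pd.DataFrame:
    """Group statistics and rank-sum tests of per-animal fractions.

    ``fractions`` has columns animal, timepoint, fraction. Per
    timepoint: mean, SEM and n over animals, plus a two-sided rank-sum
    test against the reference group, Bonferroni-adjusted over the
    number of timepoint-vs-reference comparisons.
    """
    groups = {tp: sub["fraction"].to_numpy() for tp, sub in fractions.groupby("timepoint")}
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing from data")
    for tp, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {tp!r} has fewer than 2 animals")
    ref = groups[reference]
    timepoints = [reference] + sorted(tp for tp in groups if tp != reference)
    rows = []
    p_raw = []
    for tp in timepoints:
        mean, sem = mean_sem(groups[tp])
        row = {"timepoint": tp, "mean": mean, "sem": sem, "n": len(groups[tp])}
        if tp == reference:
            row["p_value"] = np.nan
        else:
            row["p_value"] = rank_sum_test(groups[tp], ref).p_value
            p_raw.append(row["p_value"])
        rows.append(row)
    out = pd.DataFrame(rows)
    m = len(p_raw)
    out["p_adj"] = [
        np.nan if np.isnan(p) else float(bonferroni([p], m)[0]) for p in out["p_value"]
    ]
    return out
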
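"""Region assignment (periphery / invasive margin / central), compartment-
resolved densities, and composite anti-tumoral metrics.

Regions partition the slide around the tumor–host interface:

* **PERIPHERY** — a band spanning the interface: liver cells within
  ``periphery_liver_depth`` (default 100 µm) of the nearest non-liver cell,
  every peritumoral STROMA cell (the full fibrotic capsule in desmoplastic
  lesions, reactive-stroma patches otherwise), and tumor cells within
  ``periphery_tumor_depth`` (default 100 µm) of the nearest non-tumor cell
  — the "first row" of tumor cells, operationalized as a 100 µm fringe.
* **IM** (invasive margin) — tumor cells within ``im_depth`` (default
  800 µm) of the tumor margin (Measure-B distance) that are not already
  peripheral.
* **CENTRAL** — all remaining tumor cells.

Precedence for tumor cells is PERIPHERY > IM > CENTRAL, so every
non-excluded tumor cell lands in exactly one region.

Two composite metrics summarize the anti-tumoral status of the infiltrate
per sample and region, both scale-free fractions in [0, 1]:

* ``cd8_cd4_ratio`` = CD8 / (CD8 + CD4) — cytotoxic fraction of the T-cell
  infiltrate;
* ``cd8_epithelial_fraction`` = CD8_epi / (CD8_epi + CD8_stromal) — how
  much of the CD8 infiltrate reaches the tumor-gland epithelium rather
  than stalling in intratumoral stroma.

Both are NA when the denominator is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_table_io import Compartment, SampleTable, Tissue
from .phenotyping import PhenotypeAssignment
from .spatial_analysis import MEASURE_B, convex_hull_area, nearest_reference_distance

__all__ = [
    "RegionScheme",
    "REGION_KEY",
    "assign_regions",
    "region_densities",
    "cd8_cd4_ratio",
    "cd8_epithelial_fraction",
    "composite_metrics",
]

REGIONS = ("PERIPHERY", "IM", "CENTRAL")
COMPARTMENTS = ("EPITHELIAL", "STROMAL", "TOTAL")
REGION_KEY = ("sample_id", "region", "compartment", "subset")


@dataclass(frozen=True)
class RegionScheme:
    periphery_liver_depth: float = 100.0
    periphery_tumor_depth: float = 100.0
    im_depth: float = 800.0

    def __post_init__(self) -> None:
        if min(self.periphery_liver_depth, self.periphery_tumor_depth, self.im_depth) <= 0:
            raise ValueError("all region depths must be strictly positive")


def _nearest_other(df: pd.DataFrame, from_mask: np.ndarray, to_mask: np.ndarray) -> pd.Series:
    """Distance from each cell in from_mask to nearest cell in to_mask."""
    idx = df.index[from_mask]
    if len(idx) == 0 or not to_mask.any():
        return pd.Series(np.inf, index=idx, dtype=float)
    tree = cKDTree(df.loc[to_mask, ["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(df.loc[idx, ["x", "y"]].to_numpy(dtype=float), k=1)
    return pd.Series(d, index=idx)


def assign_regions(
    table: SampleTable, scheme: RegionScheme | None = None
) -> pd.Series:
    """Map each cell to PERIPHERY / IM / CENTRAL, or <NA> outside all regions.

    Requires at least one TUMOR cell (and, for the periphery band, LIVER
    cells to define the interface).
    """
    if scheme is None:
        scheme = RegionScheme()
    df = table.cells
    tumor = (df["tissue"] == Tissue.TUMOR.value).to_numpy()
    liver = (df["tissue"] == Tissue.LIVER.value).to_numpy()
    stroma = (df["tissue"] == Tissue.STROMA.value).to_numpy()
    if not tumor.any():
        raise ValueError(f"sample {table.sample_id}: no tumor cells")

    region = pd.Series(pd.NA, index=df.index, dtype="object", name="region")

    # liver side of the periphery: within depth of nearest non-liver cell
    d_liver = _nearest_other(df, liver, tumor | stroma)
    region[d_liver.index[d_liver <= scheme.periphery_liver_depth]] = "PERIPHERY"

    # the whole peritumoral stroma band is peripheral (capsule included)
    region[df.index[stroma]] = "PERIPHERY"

    # tumor cells: peripheral fringe > invasive margin > central
    d_tumor_edge = _nearest_other(df, tumor, liver | stroma)
    tumor_idx = df.index[tumor]
    fringe = d_tumor_edge <= scheme.periphery_tumor_depth
    dist_b = nearest_reference_distance(table, MEASURE_B)  # tumor cells only
    im = (dist_b.loc[tumor_idx] < scheme.im_depth) & ~fringe
    region[tumor_idx[fringe]] = "PERIPHERY"
    region[tumor_idx[im]] = "IM"
    region[tumor_idx[~fringe & ~im]] = "CENTRAL"
    return region


def region_densities(
    table: SampleTable,
    assignment: PhenotypeAssignment,
    regions: pd.Series,
) -> pd.DataFrame:
    """Count and hull-normalized density per (region, compartment, subset).

    For each region the hull is computed over all cells of that region and
    compartment; the TOTAL compartment pools epithelial + stromal (plus
    compartment-free liver cells in the periphery), so TOTAL counts equal
    the sum over cells regardless of compartment.
    """
    df = table.cells
    rows = []
    for reg in REGIONS:
        in_reg = regions == reg
        for comp in COMPARTMENTS:
            if comp == "TOTAL":
                sel = in_reg
            else:
                sel = in_reg & (df["compartment"] == comp)
            sel_idx = df.index[sel.to_numpy(dtype=bool)]
            pts = df.loc[sel_idx, ["x", "y"]].to_numpy(dtype=float)
            area = convex_hull_area(pts) if len(sel_idx) else float("nan")
            for subset in assignment.subsets:
                count = int(assignment.membership.loc[sel_idx, subset].sum())
                if np.isnan(area) or area <= 0:
                    density = float("nan")
                else:
                    density = count / area
                rows.append(
                    {
                        "sample_id": table.sample_id,
                        "region": reg,
                        "compartment": comp,
                        "subset": subset,
                        "count": count,
                        "hull_area_mm2": area,
                        "density_per_mm2": density,
                    }
                )
    return pd.DataFrame(rows)


def cd8_cd4_ratio(cd8_count: int, cd4_count: int) -> float:
    """CD8 / (CD8 + CD4); NaN when both counts are zero."""
    if cd8_count < 0 or cd4_count < 0:
        raise ValueError("counts must be non-negative")
    total = cd8_count + cd4_count
    if total == 0:
        return float("nan")
    return cd8_count / total


def cd8_epithelial_fraction(cd8_epi: int, cd8_stromal: int) -> float:
    """CD8_epithelial / (CD8_epithelial + CD8_stromal); NaN when both zero."""
    if cd8_epi < 0 or cd8_stromal < 0:
        raise ValueError("counts must be non-negative")
    total = cd8_epi + cd8_stromal
    if total == 0:
        return float("nan")
    return cd8_epi / total


def composite_metrics(
    region_table: pd.DataFrame,
    *,
    cd8_subset: str = "CD8_total",
    cd4_subset: str = "CD4_total",
) -> pd.DataFrame:
    """Per (sample, region) composite metrics from pooled region counts.

    Counts are pooled at region level (TOTAL compartment for the CD8/CD4
    ratio; epithelial vs stromal compartments for the CD8 epithelial
    fraction), giving one value per sample and region.
    """
    rows = []
    for (sid, reg), grp in region_table.groupby(["sample_id", "region"], sort=True):
        by = grp.set_index(["compartment", "subset"])["count"]

        def _count(comp: str, subset: str) -> int:
            try:
                return int(by.loc[(comp, subset)])
            except KeyError:
                return 0

        rows.append(
            {
                "sample_id": sid,
                "region": reg,
                "cd8_cd4_ratio": cd8_cd4_ratio(
                    _count("TOTAL", cd8_subset), _count("TOTAL", cd4_subset)
                ),
                "cd8_epithelial_fraction": cd8_epithelial_fraction(
                    _count("EPITHELIAL", cd8_subset), _count("STROMAL", cd8_subset)
                ),
            }
        )
    return pd.DataFrame(rows)
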
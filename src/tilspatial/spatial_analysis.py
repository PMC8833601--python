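"""Interface-referenced distances, distance zones, hull areas and densities.

The central quantification: for every cell of interest the Euclidean
distance to the nearest reference-tissue cell (of any phenotype) is
measured, distances are binned into zones, and per-zone cell counts are
normalized by the area (mm²) of the convex hull of all analysis-tissue
cells in the zone.

Two reference schemes express the ambiguity of where the tumor "starts"
when a fibrotic capsule separates tumor from liver:

* **Measure A** — reference = liver parenchyma; cells of interest live in
  the peritumoral stroma (capsule / reactive stroma) *and* tumor tissue.
  Distance is from the liver interface.
* **Measure B** — reference = liver parenchyma *and* stroma; cells of
  interest are tumor-tissue cells only.  Distance is from the tumor margin,
  so the capsule and reactive stroma are excluded from the analyzed
  population.

Since B's reference set is a superset of A's, for any tumor cell the
Measure-B distance is ≤ the Measure-A distance.

The interface is defined by cell populations, not drawn boundary curves:
distance-to-interface is literally distance to the nearest reference-class
cell.  Nearest-neighbor queries use a KD-tree but the contract is exact
equality with an all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .cell_table_io import SampleTable, Tissue
from .phenotyping import PhenotypeAssignment

__all__ = [
    "MeasureScheme",
    "MEASURE_A",
    "MEASURE_B",
    "ZoneScheme",
    "EmptyReferenceError",
    "nearest_reference_distance",
    "bin_zones",
    "convex_hull_area",
    "zone_densities",
    "ZONE_KEY",
]

UM2_PER_MM2 = 1e6

#: key columns of a zone-density table
ZONE_KEY = ("sample_id", "measure", "subset", "zone")


class EmptyReferenceError(ValueError):
    """No reference-tissue cells available for a distance measure."""


@dataclass(frozen=True)
class MeasureScheme:
    name: str
    reference_tissues: frozenset[Tissue]
    analysis_tissues: frozenset[Tissue]

    def __post_init__(self) -> None:
        if self.reference_tissues & self.analysis_tissues:
            raise ValueError("reference and analysis tissues must be disjoint")


MEASURE_A = MeasureScheme(
    "A",
    reference_tissues=frozenset({Tissue.LIVER}),
    analysis_tissues=frozenset({Tissue.STROMA, Tissue.TUMOR}),
)
MEASURE_B = MeasureScheme(
    "B",
    reference_tissues=frozenset({Tissue.LIVER, Tissue.STROMA}),
    analysis_tissues=frozenset({Tissue.TUMOR}),
)

MEASURES = {"A": MEASURE_A, "B": MEASURE_B}


@dataclass(frozen=True)
class ZoneScheme:
    """Ordered distance-band edges in µm; default four bands to 600 µm."""

    edges: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 600.0)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2:
            raise ValueError("need at least two zone edges")
        if e[0] != 0:
            raise ValueError("first zone edge must be 0")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("zone edges must be strictly increasing")

    @property
    def n_zones(self) -> int:
        return len(self.edges) - 1

    def label(self, k: int) -> str:
        return f"{self.edges[k]:g}-{self.edges[k + 1]:g}um"


def _tissue_mask(df: pd.DataFrame, tissues: frozenset[Tissue]) -> np.ndarray:
    return df["tissue"].isin([t.value for t in tissues]).to_numpy()


def nearest_reference_distance(
    table: SampleTable, scheme: MeasureScheme
) -> pd.Series:
    """Distance (µm) from each analysis-tissue cell to its nearest
    reference-tissue cell.

    Returns a float Series indexed by the cell-table row index of the
    analysis cells.  EXCLUDED cells participate on neither side.
    """
    df = table.cells
    ref = _tissue_mask(df, scheme.reference_tissues)
    ana = _tissue_mask(df, scheme.analysis_tissues)
    if not ref.any():
        raise EmptyReferenceError(
            f"sample {table.sample_id}: no reference cells for Measure {scheme.name}"
        )
    ana_idx = df.index[ana]
    if len(ana_idx) == 0:
        return pd.Series(dtype=float, name="distance_um")
    tree = cKDTree(df.loc[ref, ["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(df.loc[ana_idx, ["x", "y"]].to_numpy(dtype=float), k=1)
    return pd.Series(d, index=ana_idx, name="distance_um")


def bin_zones(distances: pd.Series, zones: ZoneScheme) -> pd.Series:
    """Map distances to half-open zone indices; ≥ last edge -> <NA>.

    Zone k covers ``edges[k] <= d < edges[k+1]``.
    """
    d = distances.to_numpy(dtype=float)
    if (d < 0).any():
        raise ValueError("negative distance")
    edges = np.asarray(zones.edges)
    idx = np.searchsorted(edges, d, side="right") - 1
    out = pd.Series(idx, index=distances.index, dtype="Int64", name="zone")
    out[(idx < 0) | (idx >= zones.n_zones)] = pd.NA
    return out


def convex_hull_area(points: np.ndarray) -> float:
    """Area (mm²) of the convex hull of 2-D points (µm); NaN if degenerate.

    Fewer than 3 points, or all points collinear, give NaN.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinate in hull input")
    if len(pts) < 3:
        return float("nan")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float("nan")  # collinear / duplicate degeneracy
    return hull.volume / UM2_PER_MM2  # 2-D "volume" is area


def zone_densities(
    table: SampleTable,
    assignment: PhenotypeAssignment,
    scheme: MeasureScheme,
    zones: ZoneScheme | None = None,
    *,
    hull_scope: str = "all",
) -> pd.DataFrame:
    """Per (subset, zone) counts, hull areas and densities for one sample.

    ``hull_scope="all"`` (default) computes each zone's hull over *all*
    analysis-tissue cells in the zone, so the area is subset-independent;
    ``hull_scope="subset"`` computes a per-subset hull instead.

    Returns a DataFrame keyed by ``(sample_id, measure, subset, zone)`` with
    columns ``zone_label, count, hull_area_mm2, density_per_mm2``.  Density
    is count/area when the area is positive, 0-count zones get density 0.0
    if the area is defined, and NaN area propagates to NaN density.
    """
    if zones is None:
        zones = ZoneScheme()
    if hull_scope not in ("all", "subset"):
        raise ValueError("hull_scope must be 'all' or 'subset'")
    dist = nearest_reference_distance(table, scheme)
    zone_of = bin_zones(dist, zones)
    df = table.cells

    rows = []
    for k in range(zones.n_zones):
        in_zone = zone_of.index[zone_of == k]
        zone_pts = df.loc[in_zone, ["x", "y"]].to_numpy(dtype=float)
        area_all = convex_hull_area(zone_pts) if len(in_zone) else float("nan")
        for subset in assignment.subsets:
            member = assignment.membership.loc[in_zone, subset]
            count = int(member.sum())
            if hull_scope == "all":
                area = area_all
            else:
                sub_pts = df.loc[in_zone[member.to_numpy(dtype=bool)], ["x", "y"]]
                area = convex_hull_area(sub_pts.to_numpy(dtype=float))
            if np.isnan(area) or area <= 0:
                density = float("nan")
            else:
                density = count / area
            rows.append(
                {
                    "sample_id": table.sample_id,
                    "measure": scheme.name,
                    "subset": subset,
                    "zone": k,
                    "zone_label": zones.label(k),
                    "count": count,
                    "hull_area_mm2": area,
                    "density_per_mm2": density,
                }
            )
    return pd.DataFrame(rows)
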
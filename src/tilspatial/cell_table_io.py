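"""Read, validate and write per-cell segmentation tables.

The pipeline consumes one tab-separated table per acquisition region: one row
per segmented cell with planar coordinates (µm), a tissue category, a tissue
compartment and boolean marker positivity columns (optionally raw intensity
columns).  This is the shape of an inForm-style cell-segmentation export.

Conventions fixed here and used everywhere downstream:

* coordinates are continuous µm in a single shared frame per sample; areas
  are reported in mm² (1 mm² = 1e6 µm²);
* three tissue categories — ``TUMOR`` (tumor tissue, containing epithelial
  glands plus intervening intratumoral stroma), ``LIVER`` (host parenchyma)
  and ``STROMA`` (the peritumoral band: fibrotic capsule in desmoplastic
  lesions, reactive-stroma patches in non-desmoplastic ones) — plus
  ``EXCLUDED`` for cells removed by artifact/necrosis masks;
* two compartments, ``EPITHELIAL`` and ``STROMAL``, with ``NONE`` allowed
  only for liver or excluded cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape

__all__ = [
    "Tissue",
    "Compartment",
    "CellRecord",
    "SampleTable",
    "ExclusionMask",
    "SchemaError",
    "ParseError",
    "GeometryError",
    "DEFAULT_TISSUE_SYNONYMS",
    "read_cell_table",
    "apply_exclusions",
    "write_table",
    "read_table",
    "read_exclusion_mask",
    "NA_SENTINEL",
]

NA_SENTINEL = "NA"

#: µm per pixel of the imaging platform (2 pixels per µm).
DEFAULT_PIXEL_SCALE = 0.5


class Tissue(str, Enum):
    TUMOR = "TUMOR"
    LIVER = "LIVER"
    STROMA = "STROMA"
    EXCLUDED = "EXCLUDED"


class Compartment(str, Enum):
    EPITHELIAL = "EPITHELIAL"
    STROMAL = "STROMAL"
    NONE = "NONE"


class SchemaError(ValueError):
    """Input table violates the declared column schema or vocabulary."""


class ParseError(ValueError):
    """A row of the input table could not be parsed."""


class GeometryError(ValueError):
    """Invalid polygon geometry (e.g. self-intersection)."""


#: Case-insensitive synonyms mapping vendor vocabulary onto the three tissue
#: categories.  User-extensible via ``read_cell_table(..., tissue_synonyms=)``.
DEFAULT_TISSUE_SYNONYMS: dict[str, Tissue] = {
    "tumor": Tissue.TUMOR,
    "tumour": Tissue.TUMOR,
    "tumor tissue": Tissue.TUMOR,
    "liver": Tissue.LIVER,
    "liver parenchyma": Tissue.LIVER,
    "parenchyma": Tissue.LIVER,
    "stroma": Tissue.STROMA,
    "capsule": Tissue.STROMA,
    "fibrotic capsule": Tissue.STROMA,
    "reactive stroma": Tissue.STROMA,
    "excluded": Tissue.EXCLUDED,
}

_COMPARTMENT_SYNONYMS: dict[str, Compartment] = {
    "epithelial": Compartment.EPITHELIAL,
    "epithelium": Compartment.EPITHELIAL,
    "tumor": Compartment.EPITHELIAL,
    "stromal": Compartment.STROMAL,
    "stroma": Compartment.STROMAL,
    "none": Compartment.NONE,
    "": Compartment.NONE,
}


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell (row view over a :class:`SampleTable`)."""

    cell_id: str
    x: float
    y: float
    tissue: Tissue
    compartment: Compartment
    markers: Mapping[str, bool]
    intensities: Mapping[str, float] | None = None


@dataclass
class SampleTable:
    """All cells of one sample plus its growth-pattern label.

    ``cells`` is a DataFrame with columns ``cell_id, x, y, tissue,
    compartment`` plus one boolean column per marker (and optional
    ``<marker>_intensity`` columns).  Coordinates are µm.
    """

    sample_id: str
    hgp: str  # "dHGP" or "ndHGP"
    cells: pd.DataFrame
    markers: list[str]
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    regions: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hgp not in ("dHGP", "ndHGP"):
            raise SchemaError(f"unknown growth-pattern label {self.hgp!r}")
        if self.pixel_scale <= 0:
            raise SchemaError("pixel_scale must be positive")
        self._validate()

    def _validate(self) -> None:
        df = self.cells
        required = ["cell_id", "x", "y", "tissue", "compartment"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table missing columns: {missing}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise ParseError(f"non-finite coordinate at row {bad}")
        valid_tissue = {t.value for t in Tissue}
        bad_tissue = set(df["tissue"].unique()) - valid_tissue
        if bad_tissue:
            raise SchemaError(f"unknown tissue labels: {sorted(bad_tissue)}")
        valid_comp = {c.value for c in Compartment}
        bad_comp = set(df["compartment"].unique()) - valid_comp
        if bad_comp:
            raise SchemaError(f"unknown compartment labels: {sorted(bad_comp)}")
        # compartment NONE only for liver/excluded cells
        none_rows = df["compartment"] == Compartment.NONE.value
        offending = none_rows & ~df["tissue"].isin(
            [Tissue.LIVER.value, Tissue.EXCLUDED.value]
        )
        if offending.any():
            raise SchemaError(
                "compartment NONE is only allowed for LIVER or EXCLUDED cells"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def included(self) -> pd.DataFrame:
        """Cells not flagged EXCLUDED (the analysis population)."""
        return self.cells[self.cells["tissue"] != Tissue.EXCLUDED.value]

    def records(self) -> Iterable[CellRecord]:
        for row in self.cells.itertuples(index=False):
            yield CellRecord(
                cell_id=row.cell_id,
                x=row.x,
                y=row.y,
                tissue=Tissue(row.tissue),
                compartment=Compartment(row.compartment),
                markers={m: bool(getattr(row, m)) for m in self.markers},
            )


@dataclass
class ExclusionMask:
    """Artifact/necrosis polygons (µm frame) whose interior cells are dropped."""

    polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.polygons):
            if not poly.is_valid:
                raise GeometryError(f"mask polygon {i} is invalid (self-intersecting?)")


# ---------------------------------------------------------------------------
# reading


def _normalize_tissue(value: str, synonyms: Mapping[str, Tissue]) -> str:
    key = str(value).strip().lower()
    if key in synonyms:
        return synonyms[key].value
    if value in {t.value for t in Tissue}:
        return value
    raise SchemaError(f"unknown tissue label {value!r}")


def _normalize_compartment(value: str) -> str:
    key = str(value).strip().lower()
    if key in _COMPARTMENT_SYNONYMS:
        return _COMPARTMENT_SYNONYMS[key].value
    if value in {c.value for c in Compartment}:
        return value
    raise SchemaError(f"unknown compartment label {value!r}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "pos", "+", "yes"):
        return True
    if s in ("0", "false", "neg", "-", "no", ""):
        return False
    try:
        return float(s) != 0.0
    except ValueError as exc:
        raise ParseError(f"cannot interpret marker value {v!r} as boolean") from exc


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    hgp: str = "dHGP",
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    coords_in_pixels: bool = False,
    markers: Sequence[str] | None = None,
    tissue_synonyms: Mapping[str, Tissue] | None = None,
    intensity_thresholds: Mapping[str, float] | None = None,
) -> SampleTable:
    """Read a tab-separated per-cell table into a validated :class:`SampleTable`.

    Parameters
    ----------
    path
        TSV file with a header row.
    schema
        Maps the canonical column roles ``id, x, y, tissue, compartment`` to
        the column names used in the file.  Defaults to the identity mapping
        ``{"id": "cell_id", "x": "x", ...}``.
    markers
        Marker column names.  If omitted, every column not claimed by the
        schema and not ending in ``_intensity`` is treated as a marker.
    coords_in_pixels
        If true, coordinates are multiplied by ``pixel_scale`` (µm/pixel,
        default 0.5 — the platform images at 2 pixels per µm).
    intensity_thresholds
        Marker-name -> cutoff map.  For any marker with no boolean column
        but a ``<marker>_intensity`` column, positivity is derived as
        intensity >= cutoff.  Exports carry only staining intensities when
        gating was not done upstream; the cutoffs themselves are a
        configuration input.
    """
    path = Path(path)
    schema = dict(schema or {})
    colmap = {
        "id": schema.get("id", "cell_id"),
        "x": schema.get("x", "x"),
        "y": schema.get("y", "y"),
        "tissue": schema.get("tissue", "tissue"),
        "compartment": schema.get("compartment", "compartment"),
    }
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty:
        raise SchemaError(f"{path}: empty cell table")
    for role, col in colmap.items():
        if col not in raw.columns:
            raise SchemaError(f"{path}: missing required column {col!r} (role {role})")

    synonyms = dict(DEFAULT_TISSUE_SYNONYMS)
    if tissue_synonyms:
        synonyms.update({k.lower(): v for k, v in tissue_synonyms.items()})

    claimed = set(colmap.values())
    thresholds = dict(intensity_thresholds or {})
    if markers is None:
        markers = [
            c
            for c in raw.columns
            if c not in claimed and not c.endswith("_intensity")
        ]
        markers += [
            m for m in thresholds
            if m not in markers and f"{m}_intensity" in raw.columns
        ]
    markers = list(markers)
    for m in markers:
        if m not in raw.columns:
            if m in thresholds and f"{m}_intensity" in raw.columns:
                continue  # gated from the intensity column below
            raise SchemaError(
                f"{path}: marker column {m!r} not found"
                + (" (no intensity threshold configured)" if f"{m}_intensity" in raw.columns else "")
            )

    def _coord(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[colmap[col]], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ParseError(
                f"{path}: non-numeric {col} coordinate at row {row}"
            )
        return vals.to_numpy(dtype=float)

    scale = pixel_scale if coords_in_pixels else 1.0
    df = pd.DataFrame(
        {
            "cell_id": raw[colmap["id"]].astype(str),
            "x": _coord("x") * scale,
            "y": _coord("y") * scale,
            "tissue": [
                _normalize_tissue(v, synonyms) for v in raw[colmap["tissue"]]
            ],
            "compartment": [
                _normalize_compartment(v if pd.notna(v) else "")
                for v in raw[colmap["compartment"]]
            ],
        }
    )
    for c in raw.columns:
        if c.endswith("_intensity"):
            vals = pd.to_numeric(raw[c], errors="coerce")
            if (vals < 0).any():
                raise ParseError(f"{path}: negative intensity in column {c!r}")
            df[c] = vals
    for m in markers:
        if m in raw.columns:
            df[m] = [_parse_bool(v) for v in raw[m]]
        else:
            df[m] = (df[f"{m}_intensity"] >= thresholds[m]).fillna(False)

    return SampleTable(
        sample_id=sample_id or path.stem,
        hgp=hgp,
        cells=df.reset_index(drop=True),
        markers=markers,
        pixel_scale=pixel_scale,
    )


def read_exclusion_mask(path: str | Path) -> ExclusionMask:
    """Read exclusion polygons from a GeoJSON file (coordinates in µm)."""
    with open(path) as fh:
        gj = json.load(fh)
    polys: list[Polygon] = []
    features = gj.get("features", [gj]) if gj.get("type") == "FeatureCollection" else [gj]
    for feat in features:
        geom = feat.get("geometry", feat)
        g = shape(geom)
        if g.geom_type == "Polygon":
            polys.append(g)
        elif g.geom_type == "MultiPolygon":
            polys.extend(g.geoms)
        else:
            raise GeometryError(f"unsupported geometry type {g.geom_type}")
    return ExclusionMask(polygons=polys)


# ---------------------------------------------------------------------------
# exclusion


def apply_exclusions(table: SampleTable, mask: ExclusionMask) -> SampleTable:
    """Flag cells strictly inside any mask polygon as EXCLUDED.

    Boundary cells are kept (strict-interior convention).  Cell count is
    preserved; the operation is idempotent.
    """
    df = table.cells.copy()
    if mask.polygons:
        inside = np.zeros(len(df), dtype=bool)
        pts = [Point(x, y) for x, y in zip(df["x"], df["y"])]
        for poly in mask.polygons:
            hits = np.fromiter(
                (poly.contains(p) for p in pts), dtype=bool, count=len(pts)
            )
            inside |= hits
        df.loc[inside, "tissue"] = Tissue.EXCLUDED.value
        df.loc[inside, "compartment"] = Compartment.NONE.value
    return SampleTable(
        sample_id=table.sample_id,
        hgp=table.hgp,
        cells=df,
        markers=table.markers,
        pixel_scale=table.pixel_scale,
        regions=table.regions,
    )


# ---------------------------------------------------------------------------
# generic result-table round-trip (ZoneDensityTable / RegionDensityTable etc.)


def write_table(df: pd.DataFrame, path: str | Path, key: Sequence[str]) -> None:
    """Write a result table as TSV with deterministic row order.

    Rows are sorted by the ``key`` columns; missing densities/areas are
    serialized as the literal ``NA``.
    """
    out = df.sort_values(list(key), kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (NA-aware)."""
    return pd.read_csv(
        path, sep="\t", na_values=[NA_SENTINEL], keep_default_na=False
    )
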
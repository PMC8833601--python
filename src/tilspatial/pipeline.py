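"""End-to-end orchestration: cohort in, result tables out.

Every stage reads and writes plain TSV files inside a cohort directory so
each intermediate is auditable and stages compose through the filesystem:

    manifest.tsv                 sample_id, hgp, cells file
    cells/<sample_id>.tsv        per-cell tables
    truth/<sample_id>_truth.tsv  synthetic ground truth (simulate only)
    phenotypes.tsv               per-cell boolean subset membership
    zones_A.tsv, zones_B.tsv     zone-density tables per measure
    regions.tsv                  region/compartment density table
    metrics.tsv                  per-sample composite metrics
    stats_*.tsv                  group comparisons
    run_manifest.json            config hash, package version, seed

Reruns with the same inputs and config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cell_table_io import (
    ExclusionMask,
    SampleTable,
    apply_exclusions,
    read_cell_table,
    read_exclusion_mask,
    write_table,
)
from .phenotyping import (
    PhenotypeAssignment,
    classify_cells,
    default_rules,
    rules_from_config,
)
from .region_metrics import (
    RegionScheme,
    assign_regions,
    composite_metrics,
    region_densities,
)
from .spatial_analysis import MEASURES, ZONE_KEY, ZoneScheme, zone_densities
from .stats import compare_groups, compare_paired_regions
from .synthetic_data import generate_cohort

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "write_cohort",
    "load_cohort",
    "run_pipeline",
]

REGION_KEY = ("sample_id", "region", "compartment", "subset")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; validated at load time."""

    cohort_dir: str = "."
    schema: dict = dataclasses.field(default_factory=dict)
    phenotype_rules: dict | None = None  # None -> shipped defaults
    zone_edges: Sequence[float] = (0.0, 100.0, 200.0, 400.0, 600.0)
    region_scheme: dict = dataclasses.field(default_factory=dict)
    measures: Sequence[str] = ("A", "B")
    hull_scope: str = "all"
    stats_adjust: str | None = None
    stats_subsets: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            self.zones = ZoneScheme(tuple(float(e) for e in self.zone_edges))
        except ValueError as exc:
            raise ConfigError(f"bad zone edges: {exc}") from exc
        for m in self.measures:
            if m not in MEASURES:
                raise ConfigError(f"unknown measure {m!r}")
        try:
            self.regions = RegionScheme(**self.region_scheme)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad region scheme: {exc}") from exc
        if self.hull_scope not in ("all", "subset"):
            raise ConfigError("hull_scope must be 'all' or 'subset'")
        self.rules = (
            default_rules()
            if self.phenotype_rules is None
            else rules_from_config(self.phenotype_rules)
        )
        known = {r.subset_name for r in self.rules}
        for s in self.stats_subsets or []:
            if s not in known:
                raise ConfigError(f"stats block names unknown subset {s!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if not isinstance(v, (ZoneScheme, RegionScheme))
        }
        payload["zone_edges"] = list(self.zone_edges)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort directories


def write_cohort(
    cohort: list, out_dir: str | Path, *, with_truth: bool = True
) -> Path:
    """Write a generated cohort (list of (SampleTable, GroundTruth)) to disk."""
    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    rows = []
    for table, truth in cohort:
        path = out / "cells" / f"{table.sample_id}.tsv"
        table.cells.to_csv(path, sep="\t", index=False)
        rows.append(
            {"sample_id": table.sample_id, "hgp": table.hgp, "cells": f"cells/{table.sample_id}.tsv"}
        )
        if with_truth and truth is not None:
            tdir = out / "truth"
            tdir.mkdir(exist_ok=True)
            sidecar = table.cells[["cell_id"]].copy()
            sidecar["true_region"] = truth.true_region.to_numpy()
            sidecar.to_csv(tdir / f"{table.sample_id}_truth.tsv", sep="\t", index=False)
            params = {
                "class_scale": truth.class_scale,
                "class_epi": truth.class_epi,
                "stroma_patch": truth.stroma_patch,
                "hgp": table.hgp,
            }
            (tdir / f"{table.sample_id}_params.json").write_text(
                json.dumps(params, indent=1, sort_keys=True)
            )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def load_cohort(
    cohort_dir: str | Path,
    schema: dict | None = None,
    exclusion_masks: dict[str, ExclusionMask] | None = None,
) -> list[SampleTable]:
    """Read every sample listed in a cohort directory's manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")
    tables = []
    for row in manifest.itertuples(index=False):
        t = read_cell_table(
            cohort_dir / row.cells,
            schema=schema,
            sample_id=row.sample_id,
            hgp=row.hgp,
        )
        if exclusion_masks and row.sample_id in exclusion_masks:
            t = apply_exclusions(t, exclusion_masks[row.sample_id])
        tables.append(t)
    return tables


# ---------------------------------------------------------------------------
# pipeline


def _phenotype_frame(table: SampleTable, assignment: PhenotypeAssignment) -> pd.DataFrame:
    out = table.cells[["cell_id"]].copy()
    out.insert(0, "sample_id", table.sample_id)
    for s in assignment.subsets:
        out[s] = assignment.membership[s].to_numpy()
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage over a cohort directory; returns the output directory.

    On any stage failure the partially written outputs are removed and the
    error is re-raised annotated with the stage and sample.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        tables = load_cohort(config.cohort_dir, schema=config.schema or None)
        hgp_labels = {t.sample_id: t.hgp for t in tables}

        pheno_frames, zone_frames, region_frames = [], {m: [] for m in config.measures}, []
        for t in tables:
            stage, sample = "phenotype", t.sample_id
            try:
                assignment = classify_cells(t, config.rules)
                pheno_frames.append(_phenotype_frame(t, assignment))
                stage = "zones"
                for m in config.measures:
                    zone_frames[m].append(
                        zone_densities(
                            t,
                            assignment,
                            MEASURES[m],
                            config.zones,
                            hull_scope=config.hull_scope,
                        )
                    )
                stage = "regions"
                regions = assign_regions(t, config.regions)
                region_frames.append(region_densities(t, assignment, regions))
            except Exception as exc:
                raise RuntimeError(f"stage {stage}, sample {sample}: {exc}") from exc

        def _write(df: pd.DataFrame, name: str, key) -> None:
            path = out / name
            write_table(df, path, key)
            written.append(path)

        _write(pd.concat(pheno_frames, ignore_index=True), "phenotypes.tsv", ("sample_id", "cell_id"))
        for m in config.measures:
            _write(
                pd.concat(zone_frames[m], ignore_index=True), f"zones_{m}.tsv", ZONE_KEY
            )
        region_table = pd.concat(region_frames, ignore_index=True)
        _write(region_table, "regions.tsv", REGION_KEY)
        _write(composite_metrics(region_table), "metrics.tsv", ("sample_id", "region"))

        for m in config.measures:
            zt = pd.concat(zone_frames[m], ignore_index=True)
            st = compare_groups(zt, hgp_labels, adjust=config.stats_adjust)
            _write(st, f"stats_zones_{m}.tsv", [c for c in ("measure", "subset", "zone") if c in st.columns])
        sr = compare_groups(region_table, hgp_labels, adjust=config.stats_adjust)
        _write(sr, "stats_regions.tsv", [c for c in ("region", "compartment", "subset") if c in sr.columns])
        sp = compare_paired_regions(region_table)
        _write(sp, "stats_paired_central_vs_periphery.tsv", ("subset",) if len(sp) else sp.columns.tolist() or ("subset",))

        manifest = {
            "package": "tilspatial",
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_samples": len(tables),
            "outputs": sorted(p.name for p in written),
        }
        mpath = out / "run_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        written.append(mpath)
        return out
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def simulate_cohort_dir(
    out_dir: str | Path,
    *,
    n_dhgp: int = 13,
    n_ndhgp: int = 9,
    scenario: str = "paper-like",
    seed: int = 0,
) -> Path:
    """Generate a synthetic cohort and write it as a cohort directory."""
    cohort = generate_cohort(n_dhgp, n_ndhgp, scenario, seed)
    return write_cohort(cohort, out_dir)
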
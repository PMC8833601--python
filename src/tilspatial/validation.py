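"""Cohort-level Monte-Carlo helpers: run the full pipeline over simulated
cohorts and summarize the group comparisons the study design asks about.

Used by the validation suite and the reproduction script.  Cohort-level
Monte-Carlo runs use a reduced structural-cell floor (the floor only sets
the resolution of the cell-defined interface, not any effect size), which
keeps repeated-cohort sweeps cheap; single-slide density-recovery checks
use the generator default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import classify_cells
from .region_metrics import assign_regions, composite_metrics, region_densities
from .spatial_analysis import MEASURE_A, MEASURE_B, zone_densities
from .stats import compare_groups, mann_whitney_u
from .synthetic_data import generate_cohort

__all__ = [
    "cohort_zone_tables",
    "evaluate_paper_like_cohort",
    "null_cohort_pvalues",
    "MC_STRUCTURAL_INTENSITY",
]

#: structural floor used for repeated-cohort Monte-Carlo sweeps (cells/mm²)
MC_STRUCTURAL_INTENSITY = 1200.0


def cohort_zone_tables(cohort, measures=(MEASURE_A, MEASURE_B)):
    """Zone-density tables (one per measure) plus growth-pattern labels."""
    labels = {}
    frames = {m.name: [] for m in measures}
    for table, _ in cohort:
        labels[table.sample_id] = table.hgp
        assignment = classify_cells(table)
        for m in measures:
            frames[m.name].append(zone_densities(table, assignment, m))
    return {k: pd.concat(v, ignore_index=True) for k, v in frames.items()}, labels


def _cohort_region_metrics(cohort):
    frames = []
    for table, _ in cohort:
        assignment = classify_cells(table)
        regions = assign_regions(table)
        frames.append(region_densities(table, assignment, regions))
    rt = pd.concat(frames, ignore_index=True)
    return rt, composite_metrics(rt)


def evaluate_paper_like_cohort(
    seed: int, structural_intensity: float = MC_STRUCTURAL_INTENSITY
) -> dict[str, tuple[float, bool]]:
    """One paper-like cohort -> {finding: (two-sided p, direction correct)}.

    Findings checked (all Mann-Whitney, desmoplastic vs non-desmoplastic):

    * ``cd8_zone0_A``     — CD8 density in the 0-100 µm zone, Measure A,
                             expected higher in dHGP;
    * ``cd4_measure_B``   — per-sample mean CD4 density over the Measure-B
                             zones, expected higher in ndHGP;
    * ``cd8_cd4_ratio_im``— CD8/(CD8+CD4) in the invasive margin, expected
                             higher in dHGP;
    * ``cd8_epi_frac_im`` — CD8 epithelial fraction in the invasive margin,
                             expected higher in dHGP.
    """
    cohort = generate_cohort(
        13, 9, "paper-like", seed=seed, structural_intensity=structural_intensity
    )
    zones, labels = cohort_zone_tables(cohort)
    hgp = pd.Series(labels)
    out = {}

    za = zones["A"]
    sel = za[(za.subset == "CD8_total") & (za.zone == 0)].set_index("sample_id")
    g1 = sel.loc[hgp[hgp == "dHGP"].index, "density_per_mm2"].dropna()
    g2 = sel.loc[hgp[hgp == "ndHGP"].index, "density_per_mm2"].dropna()
    res = mann_whitney_u(g1, g2)
    out["cd8_zone0_A"] = (res.p_value, g1.median() > g2.median())

    zb = zones["B"]
    per_sample = (
        zb[zb.subset == "CD4_total"].groupby("sample_id")["density_per_mm2"].mean()
    )
    g1 = per_sample.reindex(hgp[hgp == "dHGP"].index).dropna()
    g2 = per_sample.reindex(hgp[hgp == "ndHGP"].index).dropna()
    res = mann_whitney_u(g1, g2)
    out["cd4_measure_B"] = (res.p_value, g2.median() > g1.median())

    _, cm = _cohort_region_metrics(cohort)
    im = cm[cm.region == "IM"].set_index("sample_id")
    for key, col in (
        ("cd8_cd4_ratio_im", "cd8_cd4_ratio"),
        ("cd8_epi_frac_im", "cd8_epithelial_fraction"),
    ):
        g1 = im.loc[im.index.intersection(hgp[hgp == "dHGP"].index), col].dropna()
        g2 = im.loc[im.index.intersection(hgp[hgp == "ndHGP"].index), col].dropna()
        res = mann_whitney_u(g1, g2)
        out[key] = (res.p_value, g1.median() > g2.median())
    return out


def null_cohort_pvalues(
    seed: int, structural_intensity: float = MC_STRUCTURAL_INTENSITY
) -> np.ndarray:
    """All per-(subset, zone) Measure-A group-test p-values for one null cohort."""
    cohort = generate_cohort(
        13, 9, "null", seed=seed, structural_intensity=structural_intensity
    )
    zones, labels = cohort_zone_tables(cohort, measures=(MEASURE_A,))
    res = compare_groups(zones["A"], labels)
    return res["p_value"].to_numpy()
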
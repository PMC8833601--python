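# tilspatial

Spatial quantification of tumor-infiltrating lymphocytes (TILs) in
colorectal-cancer liver metastases (CRC-LM), stratified by histologic
growth pattern (HGP).

Liver metastases grow in two broad patterns: **desmoplastic** (dHGP),
where a fibrotic capsule separates tumor from liver parenchyma, and
**non-desmoplastic** (ndHGP), where tumor cells touch hepatocytes
directly, at most with patches of reactive stroma in between. Because the
capsule retains most of the immune infiltrate, naive "peripheral density"
comparisons between the two patterns are confounded by tissue composition.
`tilspatial` implements an interface-referenced analysis that makes the
comparison well-posed, starting from per-cell multiplex-IHC segmentation
tables (inForm-style TSV exports: coordinates in µm, tissue category,
epithelial/stromal compartment, marker positivity).

## What it computes

Given cells classified into subsets by boolean marker rules
(CD8 total/single, CD4 total/single/memory, Treg = CD4⁺FoxP3⁺, CD45RO⁺,
CD20⁺):

1. **Interface-referenced distances.** For every cell of interest, the
   Euclidean distance to the nearest reference-tissue cell, under two
   schemes — *Measure A* (reference = liver parenchyma; cells of interest
   in capsule/reactive stroma **and** tumor) and *Measure B* (reference =
   liver **and** stroma; tumor-tissue cells only, i.e. distance from the
   tumor margin). For any tumor cell, d_B ≤ d_A.
2. **Distance zones and densities.** Distances binned into half-open
   zones (default 0–100, 100–200, 200–400, 400–600 µm); per-zone counts
   normalized by the convex-hull area (mm²) of all analysis-tissue cells
   in the zone:  density = n / A_hull.
3. **Regions and compartments.** Periphery (±100 µm around the interface,
   plus the whole capsule), invasive margin (tumor within 800 µm of its
   margin), and central tumor; densities resolved by epithelial vs
   stromal compartment.
4. **Composite anti-tumoral metrics**, per sample and region:

   - CD8/CD4 ratio = CD8 / (CD8 + CD4)
   - CD8 epithelial fraction = CD8_epi / (CD8_epi + CD8_stromal)

5. **Statistics.** Mann–Whitney U (mid-ranks, exact enumeration for small
   tie-free samples, tie-corrected normal approximation otherwise) for
   dHGP-vs-ndHGP contrasts; Wilcoxon signed-rank with Pratt zero handling
   for paired central-vs-periphery contrasts; Ward hierarchical
   clustering.

A synthetic-slide generator (`tilspatial.synthetic_data`) draws
inhomogeneous-Poisson slides with known exponential density gradients
λ(d) = λ₀·e^(−d/τ) from the interface, for both growth-pattern geometries,
so every stage can be validated against closed-form ground truth.

## Worked example

```python
from tilspatial import (MEASURE_A, SyntheticSlideConfig, GradientSpec,
                        classify_cells, generate_slide, zone_densities,
                        assign_regions, region_densities, composite_metrics)

cfg = SyntheticSlideConfig(
    hgp="dHGP",
    gradients={"CD8": GradientSpec(lambda0=400, tau=150, base=20),
               "CD4": GradientSpec(lambda0=150, tau=200, base=40)},
    epithelial_fraction={"CD8": 0.4, "CD4": 0.15},
    seed=7,
)
slide, truth = generate_slide(cfg)
cells = classify_cells(slide)

zones = zone_densities(slide, cells, MEASURE_A)
print(zones[zones.subset == "CD8_total"][
    ["zone_label", "count", "hull_area_mm2", "density_per_mm2"]
].to_string(index=False))

metrics = composite_metrics(region_densities(slide, cells, assign_regions(slide)))
print(metrics.to_string(index=False))
```

Output:

```
zone_label  count  hull_area_mm2  density_per_mm2
   0-100um     36       0.133114       270.445061
 100-200um     22       0.148136       148.511716
 200-400um     31       0.281177       110.250738
 400-600um      9       0.276978        32.493538
       sample_id    region  cd8_cd4_ratio  cd8_epithelial_fraction
synthetic_dHGP_7   CENTRAL       0.481481                 0.538462
synthetic_dHGP_7        IM       0.373134                 0.320000
synthetic_dHGP_7 PERIPHERY       0.594203                 0.060976
```

The CD8 zone densities fall off from ~270 cells/mm² at the liver
interface (the analytic band mean for λ₀ = 400, τ = 150 over 0–100 µm is
292 cells/mm²; single slides scatter around it with Poisson noise) toward
the configured base rate deeper in the lesion. The composite table reads,
for each region, what fraction of T cells are cytotoxic and how much of
the CD8 infiltrate reaches the tumor-gland epithelium.

## Command line

Each stage is a subcommand operating on a cohort directory of TSV files
(`manifest.tsv` + `cells/*.tsv`), so every intermediate is auditable:

```
tilspatial simulate --out cohort/ --n-dhgp 13 --n-ndhgp 9 --scenario paper-like --seed 1
tilspatial phenotype --cohort cohort/
tilspatial zones     --cohort cohort/ --measure A
tilspatial regions   --cohort cohort/
tilspatial metrics   --cohort cohort/
tilspatial stats     --cohort cohort/ --table zones_A.tsv
tilspatial run       --config pipeline.json --out results/   # everything at once
```

Exit codes: 0 success, 2 validation error, 3 runtime error. Reruns with
the same inputs and seed are bit-identical.

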
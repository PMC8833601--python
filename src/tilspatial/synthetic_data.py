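"""Synthetic multiplex-IHC slides with known ground truth.

Each synthetic slide is a rectangular acquisition region (default
1860 × 1390 µm) stratified left-to-right along ``x``:

* a liver-parenchyma band (``0 ≤ x < liver_depth``);
* for desmoplastic (dHGP) slides, a fibrotic-capsule band of STROMA cells
  of width ``capsule_width``;
* for non-desmoplastic (ndHGP) slides, a direct liver–tumor interface with
  optional reactive-stroma patches covering ``reactive_stroma_fraction`` of
  the interface length to depth ``stroma_patch_depth``;
* tumor tissue over the remaining width.

Real lesions are curved; the flat interface is a deliberate simplification
— every downstream quantity is distance-based, and a straight interface
buys closed-form ground truth (analytic band integrals of the intensity).

Cells are drawn from inhomogeneous Poisson processes by thinning.  Every
band receives marker-negative *structural* cells at a constant floor
intensity (so reference sets and hulls are never empty), and each
lymphocyte class is laid down with intensity

    lambda(d) = base + lambda0 * exp(-d / tau)

where ``d`` is depth into the lesion measured from the liver interface
(``x - liver_depth``; zero on the liver side).  Lymphocyte classes are
*exact* marker combinations, so the generated subsets are realized
exactly: e.g. a ``CD4_mem`` class cell is CD4+CD45RO+ and nothing else,
and therefore counts toward the CD4_total, CD4_memory and CD45RO_total
analysis subsets.

Per-sample biological variability is modelled as a lognormal multiplier
(sd ``sample_sigma`` on the log scale) applied to each class's intensity,
and a logit-normal jitter on the epithelial fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell_table_io import Compartment, SampleTable, Tissue
from .phenotyping import PANEL

__all__ = [
    "GradientSpec",
    "SyntheticSlideConfig",
    "GroundTruth",
    "CLASS_MARKERS",
    "CLASS_SUBSETS",
    "generate_slide",
    "generate_cohort",
    "paper_like_params",
    "null_params",
    "analytic_band_mean",
]

#: generator cell classes -> exact marker pattern (positives; all others negative)
CLASS_MARKERS: dict[str, tuple[str, ...]] = {
    "CD8": ("CD8",),
    "CD4": ("CD4",),
    "CD4_mem": ("CD4", "CD45RO"),
    "Treg": ("CD4", "FoxP3"),
    "CD45RO": ("CD45RO",),
    "CD20": ("CD20",),
}

#: analysis subsets each class realizes under the default phenotype rules
CLASS_SUBSETS: dict[str, tuple[str, ...]] = {
    "CD8": ("CD8_total", "CD8_single"),
    "CD4": ("CD4_total", "CD4_single"),
    "CD4_mem": ("CD4_total", "CD4_memory", "CD45RO_total"),
    "Treg": ("CD4_total", "CD4_Treg"),
    "CD45RO": ("CD45RO_total",),
    "CD20": ("CD20_total",),
}


@dataclass(frozen=True)
class GradientSpec:
    """Interface-referenced exponential intensity for one cell class.

    ``lambda(d) = base + lambda0 * exp(-d/tau)`` in cells/mm² at depth
    ``d`` µm into the lesion.
    """

    lambda0: float = 0.0
    tau: float = 150.0
    base: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.base < 0 or self.tau <= 0:
            raise ValueError("intensities must be >= 0 and tau > 0")

    def at(self, depth: float | np.ndarray) -> float | np.ndarray:
        return self.base + self.lambda0 * np.exp(-np.asarray(depth, float) / self.tau)

    @property
    def peak(self) -> float:
        return self.base + self.lambda0


def analytic_band_mean(spec: GradientSpec, a: float, b: float) -> float:
    """Mean of lambda(d) over the depth band [a, b) — the expected density
    a perfect estimator would recover for that distance zone."""
    if b <= a:
        raise ValueError("need b > a")
    return spec.base + spec.lambda0 * spec.tau * (
        math.exp(-a / spec.tau) - math.exp(-b / spec.tau)
    ) / (b - a)


@dataclass(frozen=True)
class SyntheticSlideConfig:
    width: float = 1860.0
    height: float = 1390.0
    hgp: str = "dHGP"
    capsule_width: float = 250.0  # dHGP only
    reactive_stroma_fraction: float = 0.3  # ndHGP only
    stroma_patch_depth: float = 150.0  # ndHGP only
    liver_depth: float = 400.0
    structural_intensity: float = 5000.0  # marker-negative cells/mm², every band
    gradients: dict[str, GradientSpec] = field(default_factory=dict)
    epithelial_fraction: dict[str, float] = field(default_factory=dict)
    sample_sigma: float = 0.0  # lognormal sd of per-sample intensity multiplier
    epi_sigma: float = 0.0  # logit-normal sd of per-sample epithelial fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hgp not in ("dHGP", "ndHGP"):
            raise ValueError(f"unknown growth pattern {self.hgp!r}")
        if min(self.width, self.height, self.liver_depth) <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.hgp == "dHGP":
            if self.reactive_stroma_fraction != 0.0:
                object.__setattr__(self, "reactive_stroma_fraction", 0.0)
            if self.capsule_width <= 0:
                raise ValueError("dHGP slides need a positive capsule width")
            if self.liver_depth + self.capsule_width >= self.width:
                raise ValueError("capsule wider than the slide")
        else:
            if self.capsule_width != 0.0:
                object.__setattr__(self, "capsule_width", 0.0)
            if not 0.0 <= self.reactive_stroma_fraction <= 1.0:
                raise ValueError("reactive_stroma_fraction must be in [0, 1]")
            if self.liver_depth + self.stroma_patch_depth >= self.width:
                raise ValueError("stroma patch deeper than the slide")
        if self.structural_intensity < 0:
            raise ValueError("structural_intensity must be >= 0")
        for name, frac in self.epithelial_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"epithelial_fraction[{name}] outside [0, 1]")

    @property
    def interface_x(self) -> float:
        """x of the liver interface (depth origin)."""
        return self.liver_depth

    @property
    def tumor_start_x(self) -> float:
        """x where tumor tissue begins outside any stroma patch."""
        return self.liver_depth + self.capsule_width


@dataclass
class GroundTruth:
    """What the generator actually put on the slide."""

    config: SyntheticSlideConfig
    #: realized per-class intensity multipliers (per-sample lognormal draw)
    class_scale: dict[str, float]
    #: realized per-class epithelial fractions
    class_epi: dict[str, float]
    #: [y_lo, y_hi) interval of the reactive-stroma patch (ndHGP), or None
    stroma_patch: tuple[float, float] | None
    #: per-cell true region labels, aligned with the emitted cell table
    true_region: pd.Series = field(repr=False)

    def realized_gradient(self, cls: str) -> GradientSpec:
        g = self.config.gradients.get(cls, GradientSpec())
        s = self.class_scale.get(cls, 1.0)
        return replace(g, lambda0=g.lambda0 * s, base=g.base * s)

    def analytic_zone_density(self, subset: str, a: float, b: float) -> float:
        """Expected density of an analysis subset over depth band [a, b)."""
        total = 0.0
        for cls, subsets in CLASS_SUBSETS.items():
            if subset in subsets:
                total += analytic_band_mean(self.realized_gradient(cls), a, b)
        return total


# ---------------------------------------------------------------------------
# point-process machinery

UM2_PER_MM2 = 1e6


def _poisson_points(
    rng: np.random.Generator, x0: float, x1: float, y0: float, y1: float, lam: float
) -> np.ndarray:
    """Homogeneous Poisson points at lam cells/mm² in a rectangle (µm)."""
    area_mm2 = (x1 - x0) * (y1 - y0) / UM2_PER_MM2
    if area_mm2 <= 0 or lam <= 0:
        return np.empty((0, 2))
    n = rng.poisson(lam * area_mm2)
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    return np.column_stack([xs, ys])


def _thinned_gradient_points(
    rng: np.random.Generator,
    x0: float,
    x1: float,
    y0: float,
    y1: float,
    spec: GradientSpec,
    interface_x: float,
) -> np.ndarray:
    """Inhomogeneous Poisson points with intensity spec.at(x - interface_x),
    by thinning a homogeneous process at the peak intensity."""
    peak = spec.peak
    pts = _poisson_points(rng, x0, x1, y0, y1, peak)
    if len(pts) == 0:
        return pts
    lam = spec.at(np.maximum(pts[:, 0] - interface_x, 0.0))
    keep = rng.uniform(0.0, peak, len(pts)) < lam
    return pts[keep]


# ---------------------------------------------------------------------------
# slide generation


def _band_layout(cfg: SyntheticSlideConfig, rng: np.random.Generator):
    """Return (bands, stroma_patch) where bands is a list of
    (tissue, x0, x1, y0, y1) rectangles tiling the slide."""
    H, W, L = cfg.height, cfg.width, cfg.liver_depth
    bands: list[tuple[Tissue, float, float, float, float]] = [
        (Tissue.LIVER, 0.0, L, 0.0, H)
    ]
    patch = None
    if cfg.hgp == "dHGP":
        bands.append((Tissue.STROMA, L, L + cfg.capsule_width, 0.0, H))
        bands.append((Tissue.TUMOR, L + cfg.capsule_width, W, 0.0, H))
    else:
        frac = cfg.reactive_stroma_fraction
        if frac > 0:
            patch_h = frac * H
            y_lo = rng.uniform(0.0, H - patch_h)
            patch = (y_lo, y_lo + patch_h)
            d = cfg.stroma_patch_depth
            bands.append((Tissue.STROMA, L, L + d, patch[0], patch[1]))
            bands.append((Tissue.TUMOR, L + d, W, patch[0], patch[1]))
            # uncovered interface: tumor abuts liver directly
            if patch[0] > 0:
                bands.append((Tissue.TUMOR, L, W, 0.0, patch[0]))
            if patch[1] < H:
                bands.append((Tissue.TUMOR, L, W, patch[1], H))
        else:
            bands.append((Tissue.TUMOR, L, W, 0.0, H))
    return bands, patch


def _true_regions(
    cfg: SyntheticSlideConfig,
    tissue: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    patch: tuple[float, float] | None,
) -> pd.Series:
    """Geometric region labels: the region each cell would occupy if the
    interfaces were read off the generator's band layout directly."""
    L = cfg.liver_depth
    # depth of tumor start for each cell's y-column
    tumor_start = np.full_like(x, L + cfg.capsule_width)
    if cfg.hgp == "ndHGP" and patch is not None:
        covered = (y >= patch[0]) & (y < patch[1])
        tumor_start = np.where(covered, L + cfg.stroma_patch_depth, L)
    region = np.full(len(x), None, dtype=object)
    liver = tissue == Tissue.LIVER.value
    stroma = tissue == Tissue.STROMA.value
    tumor = tissue == Tissue.TUMOR.value
    region[liver & (x >= L - 100.0)] = "PERIPHERY"
    region[stroma] = "PERIPHERY"
    depth_b = x - tumor_start  # depth into tumor tissue from its margin
    region[tumor & (depth_b <= 100.0)] = "PERIPHERY"
    region[tumor & (depth_b > 100.0) & (depth_b < 800.0)] = "IM"
    region[tumor & (depth_b >= 800.0)] = "CENTRAL"
    return pd.Series(region, dtype="object", name="true_region")


def generate_slide(
    cfg: SyntheticSlideConfig, sample_id: str | None = None
) -> tuple[SampleTable, GroundTruth]:
    """Draw one synthetic slide; deterministic for a fixed config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    bands, patch = _band_layout(cfg, rng)

    # per-sample biological variability
    classes = list(CLASS_MARKERS)
    scale = {
        c: float(np.exp(rng.normal(0.0, cfg.sample_sigma))) if cfg.sample_sigma else 1.0
        for c in classes
    }
    epi = {}
    for c in classes:
        f = cfg.epithelial_fraction.get(c, 0.2)
        if cfg.epi_sigma and 0.0 < f < 1.0:
            logit = math.log(f / (1 - f)) + rng.normal(0.0, cfg.epi_sigma)
            f = 1.0 / (1.0 + math.exp(-logit))
        epi[c] = f

    xs: list[np.ndarray] = []
    tissues: list[np.ndarray] = []
    cls_of: list[np.ndarray] = []

    for tis, x0, x1, y0, y1 in bands:
        # structural marker-negative cells in every band
        pts = _poisson_points(rng, x0, x1, y0, y1, cfg.structural_intensity)
        xs.append(pts)
        tissues.append(np.full(len(pts), tis.value))
        cls_of.append(np.full(len(pts), "structural"))
        if tis == Tissue.LIVER:
            continue  # lymphocyte gradients live in the lesion only
        for c in classes:
            g = cfg.gradients.get(c)
            if g is None or (g.lambda0 == 0 and g.base == 0):
                continue
            g = replace(g, lambda0=g.lambda0 * scale[c], base=g.base * scale[c])
            pts = _thinned_gradient_points(rng, x0, x1, y0, y1, g, cfg.interface_x)
            xs.append(pts)
            tissues.append(np.full(len(pts), tis.value))
            cls_of.append(np.full(len(pts), c))

    coords = np.vstack([p for p in xs if len(p)]) if any(len(p) for p in xs) else np.empty((0, 2))
    tissue = np.concatenate(tissues) if tissues else np.array([], dtype=object)
    cls = np.concatenate(cls_of) if cls_of else np.array([], dtype=object)

    n = len(coords)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "x": coords[:, 0] if n else np.array([]),
            "y": coords[:, 1] if n else np.array([]),
            "tissue": tissue,
        }
    )
    # markers: exact realization of the class pattern
    for m in PANEL:
        df[m] = False
    for c, positives in CLASS_MARKERS.items():
        sel = cls == c
        for m in positives:
            df.loc[sel, m] = True

    # compartments: hepatocytes epithelial; capsule/reactive stroma stromal;
    # tumor-tissue cells split epithelial/stromal per class fraction
    comp = np.full(n, Compartment.STROMAL.value, dtype=object)
    comp[tissue == Tissue.LIVER.value] = Compartment.EPITHELIAL.value
    in_tumor = tissue == Tissue.TUMOR.value
    for c in ["structural", *classes]:
        sel = in_tumor & (cls == c)
        k = int(sel.sum())
        if k:
            f = epi.get(c, 0.2) if c != "structural" else 0.5
            comp[np.where(sel)[0][rng.uniform(size=k) < f]] = (
                Compartment.EPITHELIAL.value
            )
    df["compartment"] = comp

    sid = sample_id or f"synthetic_{cfg.hgp}_{cfg.seed}"
    table = SampleTable(
        sample_id=sid, hgp=cfg.hgp, cells=df, markers=list(PANEL)
    )
    truth = GroundTruth(
        config=cfg,
        class_scale=scale,
        class_epi=epi,
        stroma_patch=patch,
        true_region=_true_regions(cfg, tissue, df["x"].to_numpy(), df["y"].to_numpy(), patch),
    )
    return table, truth


# ---------------------------------------------------------------------------
# cohort scenarios


def paper_like_params(hgp: str) -> tuple[dict[str, GradientSpec], dict[str, float]]:
    """Effect structure of the 'paper-like' scenario.

    Desmoplastic lesions: CD8/CD20 piled into the outer capsule (steep
    gradient from the liver interface) and a high CD8 epithelial fraction
    in tumor tissue.  Non-desmoplastic lesions: CD4-family and CD45RO
    enrichment in reactive stroma and tumor, CD8 mostly stroma-retained.
    Intensities are cells/mm²; effect sizes are the generator's own.
    """
    if hgp == "dHGP":
        gradients = {
            "CD8": GradientSpec(lambda0=700, tau=120, base=30),
            "CD20": GradientSpec(lambda0=400, tau=100, base=10),
            "CD4": GradientSpec(lambda0=150, tau=150, base=25),
            "CD4_mem": GradientSpec(lambda0=80, tau=150, base=12),
            "Treg": GradientSpec(lambda0=50, tau=150, base=8),
            "CD45RO": GradientSpec(lambda0=120, tau=150, base=20),
        }
        epi = {c: 0.12 for c in CLASS_MARKERS}
        epi["CD8"] = 0.45
    elif hgp == "ndHGP":
        gradients = {
            "CD8": GradientSpec(lambda0=250, tau=120, base=30),
            "CD20": GradientSpec(lambda0=150, tau=100, base=10),
            "CD4": GradientSpec(lambda0=500, tau=200, base=60),
            "CD4_mem": GradientSpec(lambda0=250, tau=200, base=30),
            "Treg": GradientSpec(lambda0=120, tau=200, base=15),
            "CD45RO": GradientSpec(lambda0=400, tau=200, base=50),
        }
        epi = {c: 0.12 for c in CLASS_MARKERS}
        epi["CD8"] = 0.15
    else:
        raise ValueError(f"unknown growth pattern {hgp!r}")
    return gradients, epi


def null_params() -> tuple[dict[str, GradientSpec], dict[str, float]]:
    """Flat, group-independent intensities: no spatial gradient, identical
    parameters for both growth patterns (only the geometry differs)."""
    gradients = {
        "CD8": GradientSpec(lambda0=0, base=60),
        "CD20": GradientSpec(lambda0=0, base=30),
        "CD4": GradientSpec(lambda0=0, base=80),
        "CD4_mem": GradientSpec(lambda0=0, base=30),
        "Treg": GradientSpec(lambda0=0, base=15),
        "CD45RO": GradientSpec(lambda0=0, base=60),
    }
    epi = {c: 0.2 for c in CLASS_MARKERS}
    return gradients, epi


def generate_cohort(
    n_dhgp: int = 13,
    n_ndhgp: int = 9,
    scenario: str = "paper-like",
    seed: int = 0,
    *,
    sample_sigma: float = 0.4,
    epi_sigma: float = 0.3,
    structural_intensity: float = 5000.0,
) -> list[tuple[SampleTable, GroundTruth]]:
    """A labelled cohort of synthetic slides (defaults 13 dHGP + 9 ndHGP).

    ``scenario`` is ``"paper-like"`` (group differences as in
    :func:`paper_like_params`) or ``"null"`` (identical flat parameters for
    both groups).  Each slide gets its own RNG stream keyed by
    ``(seed, index)``.
    """
    if n_dhgp < 1 or n_ndhgp < 1:
        raise ValueError("cohort needs at least one sample per group")
    if scenario not in ("paper-like", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    out = []
    labels = ["dHGP"] * n_dhgp + ["ndHGP"] * n_ndhgp
    for i, hgp in enumerate(labels):
        if scenario == "paper-like":
            gradients, epi = paper_like_params(hgp)
        else:
            gradients, epi = null_params()
        cfg = SyntheticSlideConfig(
            hgp=hgp,
            gradients=gradients,
            epithelial_fraction=epi,
            sample_sigma=sample_sigma,
            epi_sigma=epi_sigma,
            structural_intensity=structural_intensity,
            seed=int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1)),
        )
        sid = f"{scenario.replace('-', '_')}_{hgp}_{i:02d}"
        out.append(generate_slide(cfg, sample_id=sid))
    return out
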
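import numpy as np
import pandas as pd
import pytest

from tilspatial.cell_table_io import SampleTable
from tilspatial.synthetic_data import (
    GradientSpec,
    SyntheticSlideConfig,
    generate_slide,
)


def make_table(rows, markers=("CD4", "CD8"), sample_id="toy", hgp="dHGP"):
    """Build a SampleTable from (cell_id, x, y, tissue, compartment, *marker) rows.

    Panel markers not named in ``markers`` are padded as negative so the
    shipped default phenotype rules always apply.
    """
    from tilspatial.phenotyping import PANEL

    cols = ["cell_id", "x", "y", "tissue", "compartment", *markers]
    df = pd.DataFrame(rows, columns=cols)
    full = list(markers) + [m for m in PANEL if m not in markers]
    for m in full:
        if m not in df.columns:
            df[m] = False
    return SampleTable(sample_id=sample_id, hgp=hgp, cells=df, markers=full)


@pytest.fixture
def toy_table():
    rows = [
        ("a", 0.0, 0.0, "LIVER", "NONE", False, False),
        ("b", 100.0, 0.0, "STROMA", "STROMAL", True, False),
        ("c", 300.0, 400.0, "TUMOR", "EPITHELIAL", False, True),
        ("d", 350.0, 400.0, "TUMOR", "STROMAL", True, True),
    ]
    return make_table(rows)


@pytest.fixture(scope="session")
def small_dhgp_slide():
    """One modest desmoplastic slide with a CD8 capsule gradient."""
    cfg = SyntheticSlideConfig(
        hgp="dHGP",
        structural_intensity=1500,
        gradients={
            "CD8": GradientSpec(lambda0=400, tau=150, base=20),
            "CD4": GradientSpec(lambda0=200, tau=200, base=40),
        },
        epithelial_fraction={"CD8": 0.4, "CD4": 0.15},
        seed=11,
    )
    return generate_slide(cfg)


# ---------------------------------------------------------------------------
# independent oracles (used by unit and acceptance tests)


def brute_force_distances(ref_xy: np.ndarray, qry_xy: np.ndarray) -> np.ndarray:
    """O(n*m) all-pairs nearest distances."""
    diff = qry_xy[:, None, :] - ref_xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def gift_wrap_hull_area_um2(points: np.ndarray) -> float:
    """Jarvis-march convex hull followed by the shoelace formula.

    Returns 0 for degenerate (collinear / <3 point) inputs.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(range(n), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % n
        for r in range(n):
            c = cross(pts[p], pts[q], pts[r])
            if c < 0 or (
                c == 0
                and np.hypot(*(pts[r] - pts[p])) > np.hypot(*(pts[q] - pts[p]))
            ):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > n:  # safety for fully collinear input
            return 0.0
    if len(hull) < 3:
        return 0.0
    h = pts[hull]
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
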
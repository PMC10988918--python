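import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from citegate import Assay, OmicsContainer, generate, pbmc_preset
from citegate.synthetic import ensure_clr

# ---------------------------------------------------------------------------
# independent geometry oracle: winding-number by signed-angle summation.
# Deliberately a different algorithm from the package's even-odd ray casting;
# for simple polygons the two must agree away from edges.
# ---------------------------------------------------------------------------

def winding_number_inside(points, vertices):
    pts = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    total = np.zeros(len(pts))
    for i in range(n):
        a = v[i] - pts
        b = v[(i + 1) % n] - pts
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
        total += np.arctan2(cross, dot)
    return np.abs(total) > np.pi  # ~2*pi inside, ~0 outside


def point_segment_distance(points, a, b):
    pts = np.asarray(points, dtype=float)
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def min_edge_distance(points, vertices):
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    d = np.full(len(points), np.inf)
    for i in range(n):
        d = np.minimum(d, point_segment_distance(points, v[i], v[(i + 1) % n]))
    return d


def random_simple_polygon(rng, n_min=3, n_max=12):
    """Star-shaped (hence simple) polygon: sorted angles, random radii."""
    n = int(rng.integers(n_min, n_max + 1))
    # one jittered angle per sector keeps every angular gap < pi, so each
    # edge stays inside its cone and edges cannot cross
    angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.25, 0.75, size=n)) / n
    radii = rng.uniform(0.3, 2.0, size=n)
    center = rng.uniform(-3, 3, size=2)
    return [
        (center[0] + r * np.cos(t), center[1] + r * np.sin(t))
        for r, t in zip(radii, angles)
    ]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@pytest.fixture()
def toy5():
    """5-cell container with known normalized ADT values for CD3/CD4."""
    cd3 = [0.1, 2.0, 2.1, 0.2, 1.9]
    cd4 = [0.0, 1.8, 0.1, 0.0, 1.7]
    adt = Assay(
        feature_names=pd.Index(["CD3", "CD4"]),
        raw=sp.csr_matrix(np.zeros((5, 2))),
        normalized=np.column_stack([cd3, cd4]),
    )
    return OmicsContainer(
        barcodes=pd.Index([f"c{i}" for i in range(1, 6)]),
        assays={"ADT": adt},
    )


@pytest.fixture(scope="session")
def pbmc_small():
    """2,000-cell PBMC-like container with CLR-normalized ADT, plus truth."""
    container, truth = generate(pbmc_preset(2_000, seed=11))
    return ensure_clr(container), truth


@pytest.fixture(scope="session")
def pbmc10k():
    """10,000-cell PBMC-like container (the demonstration scale), plus truth."""
    container, truth = generate(pbmc_preset(10_000, seed=20260919))
    return ensure_clr(container), truth
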
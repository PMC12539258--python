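import numpy as np
import pandas as pd
import pytest

import tissuequant as tq
from tissuequant.datatypes import (
    PhenotypeKey,
    PhenotypeRule,
    ThresholdEntry,
    ThresholdSet,
)

THREE_MARKERS = ("CK", "CD3", "CD20")


@pytest.fixture
def thresholds3() -> ThresholdSet:
    return ThresholdSet(
        {m: ThresholdEntry("cell", "mean", 10.0) for m in THREE_MARKERS}
    )


@pytest.fixture
def key3() -> PhenotypeKey:
    return PhenotypeKey(
        rules=[
            PhenotypeRule({"CK": "+"}, "Tumor"),
            PhenotypeRule({"CD3": "+", "CK": "-"}, "T"),
            PhenotypeRule({"CD20": "+", "CK": "-", "CD3": "-"}, "B"),
        ],
        priority=["CK", "CD3", "CD20"],
    )


@pytest.fixture
def tissue_scenario() -> tq.TissueScenario:
    return tq.TissueScenario(
        seed=5,
        n_cells=60,
        width_um=400.0,
        height_um=400.0,
        phenotype_proportions={"Tumor": 0.4, "T": 0.3, "B": 0.3},
        markers={
            "CK": tq.MarkerModel(("Tumor",)),
            "CD3": tq.MarkerModel(("T",)),
            "CD20": tq.MarkerModel(("B",)),
        },
    )


def hex_cluster(n: int, spacing: float = 10.0, cx: float = 1000.0, cy: float = 1000.0):
    """Compact hexagonal-packing cluster of n points (μm)."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n:
        for k in range(6 * ring):
            ang = 2 * np.pi * k / (6 * ring)
            pts.append((spacing * ring * np.cos(ang), spacing * ring * np.sin(ang)))
        ring += 1
    return np.array(pts[:n]) + (cx, cy)


def chain_graph_cells(n_tumor: int, n_stroma: int):
    """Chain-shaped tumor and stroma components joined by one edge."""
    import networkx as nx
    from tissuequant.datatypes import CellTable

    tumor = [f"t{i}" for i in range(n_tumor)]
    stroma = [f"s{i}" for i in range(n_stroma)]
    g = nx.Graph()
    g.add_nodes_from(tumor + stroma)
    g.add_edges_from(zip(tumor, tumor[1:]))
    g.add_edges_from(zip(stroma, stroma[1:]))
    g.add_edge(tumor[0], stroma[0])
    table = CellTable(
        pd.DataFrame(
            {
                "image_id": "img",
                "cell_id": tumor + stroma,
                "pos_CK": [True] * n_tumor + [False] * n_stroma,
            }
        )
    )
    return table, g


def brute_force_kcross(points_i, points_j, window, radii):
    """Naive O(n^2) translation-corrected cross-K, on the L scale."""
    x0, y0, x1, y1 = window
    wx, wy = x1 - x0, y1 - y0
    area = wx * wy
    k = np.zeros(len(radii))
    for idx, r in enumerate(radii):
        s = 0.0
        for u in points_i:
            for v in points_j:
                d = np.hypot(u[0] - v[0], u[1] - v[1])
                if d <= r:
                    dx, dy = abs(u[0] - v[0]), abs(u[1] - v[1])
                    s += area / ((wx - dx) * (wy - dy))
        k[idx] = area / (len(points_i) * len(points_j)) * s
    return np.sqrt(k / np.pi)


def brute_force_expand(nuclei_labels: np.ndarray, pixel_size: float, max_dist: float):
    """Per-pixel nearest-nucleus-within-radius oracle, smaller label on ties."""
    h, w = nuclei_labels.shape
    out = nuclei_labels.copy()
    fg = np.argwhere(nuclei_labels > 0)
    fg_labels = nuclei_labels[fg[:, 0], fg[:, 1]]
    for r in range(h):
        for c in range(w):
            if nuclei_labels[r, c] > 0:
                continue
            d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
            best = np.sqrt(d2.min()) * pixel_size
            if best <= max_dist:
                cands = fg_labels[d2 == d2.min()]
                out[r, c] = cands.min()
    return out
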
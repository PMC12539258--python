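"""Detect TLS proxies (dense B-cell patches) from positions, and CD20/tumor
patches on a neighbourhood graph with distance expansion."""

import networkx as nx
import numpy as np
import pandas as pd

import tissuequant as tq
from tissuequant.datatypes import CellTable

# --- TLS: a compact cluster of B cells at 10 um spacing -----------------
rng = np.random.default_rng(1)
cluster = rng.uniform(-40, 40, (60, 2)) + (500.0, 500.0)
sparse = rng.uniform(0, 1000, (30, 2))
points = np.vstack([cluster, sparse])
tls = tq.detect_tls(points)
print(f"TLS patches: {len(tls)}")
for p in tls.patches:
    print(f"  patch {p.patch_id}: {len(p.members)} B cells, area {p.area_um2:.0f} um^2")
# only the dense cluster exceeds 2000 cells/mm^2 with >= 40 cells; the
# scattered background B cells never qualify

# --- CD20 patch with 10 um expansion on an adjacency graph --------------
b_ids = [f"b{i}" for i in range(30)]
g = nx.Graph()
g.add_nodes_from(b_ids + ["t_near", "t_far"])
g.add_edges_from(zip(b_ids, b_ids[1:]))
table = CellTable(
    pd.DataFrame(
        {
            "image_id": "i",
            "cell_id": b_ids + ["t_near", "t_far"],
            "x_um": list(np.arange(30) * 8.0) + [0.0, 0.0],
            "y_um": [0.0] * 30 + [9.0, 14.0],
            "phenotype": ["B"] * 30 + ["T", "T"],
        }
    )
)
patches = tq.detect_patches(table, g, ["B"], kind="CD20")
members = patches.patches[0].members
print(f"CD20 patch core: {len(patches.patches[0].core_members)} B cells")
print(f"T cell at 9 um joined: {'t_near' in members}; at 14 um: {'t_far' in members}")
# cores need >= 25 member-type cells; the 10 um expansion pulls in the
# nearby T cell but not the distant one
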
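"""Cell neighbourhood graphs, tumor–stroma segmentation, and patch / TLS
detection.

Tissue segmentation starts from a naive rule (tumor iff cytokeratin-
positive) and then reassigns small islands: a connected group of fewer than
5 stroma (resp. tumor) cells touching a group of more than 10 tumor (resp.
stroma) cells switches compartment, in a single simultaneous pass.

Tertiary lymphoid structures are proxied by patches of B cells (CD20+CK−)
with a local density above 2000 cells/mm² and at least 40 cells, outlined by
the alpha shape of the qualifying cell positions.  On mass-cytometry
neighbourhood graphs, CD20 patches need at least 25 B/BnT cells and are
expanded by 10 μm; tumor patches need 25 tumor cells and include every cell
within 25 μm of a patch cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .datatypes import CellTable, FormatError, LabelMask, Patch, PatchSet


# ---------------------------------------------------------------------------
# adjacency graphs


def build_adjacency_graph(
    cells: CellTable | None = None,
    masks: LabelMask | None = None,
    method: str = "mask_expansion",
    param_um: float | None = None,
) -> nx.Graph:
    """Build the undirected cell-interaction graph.

    ``mask_expansion`` (default 4 μm): two cells interact iff they touch
    after each boundary is expanded by ``param_um`` — i.e. the minimum
    pixel-centre distance between the two masks is ≤ 2·``param_um``.
    ``delaunay_maxlen`` (default 30 μm): Delaunay edges between centroids,
    keeping edges no longer than ``param_um``.
    """
    if method == "mask_expansion":
        if masks is None:
            raise FormatError("mask_expansion needs a cell LabelMask")
        param = 4.0 if param_um is None else param_um
        graph = _mask_expansion_graph(masks, param)
    elif method == "delaunay_maxlen":
        if cells is None:
            raise FormatError("delaunay_maxlen needs a CellTable with centroids")
        param = 30.0 if param_um is None else param_um
        graph = _delaunay_graph(cells, param)
    else:
        raise FormatError(f"unknown adjacency method {method!r}")
    graph.graph.update(method=method, param_um=param)
    return graph


def _mask_expansion_graph(masks: LabelMask, expand_um: float) -> nx.Graph:
    ids = masks.label_ids
    graph = nx.Graph()
    graph.add_nodes_from(int(i) for i in ids)
    s = masks.pixel_size_um
    reach = 2.0 * expand_um
    for lab in ids:
        # distance from everything to this cell; neighbours are cells with a
        # pixel centre within 2*expand
        d = ndimage.distance_transform_edt(masks.labels != lab, sampling=s)
        near = (d <= reach) & (masks.labels > 0) & (masks.labels != lab)
        for other in np.unique(masks.labels[near]):
            graph.add_edge(int(lab), int(other))
    return graph


def _delaunay_graph(cells: CellTable, max_len_um: float) -> nx.Graph:
    pts = cells.df[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells.df["cell_id"].to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(ids.tolist())
    if len(pts) < 2:
        return graph
    pairs: set[tuple[int, int]] = set()
    if len(pts) >= 3:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                    pairs.add((i, j))
        except QhullError:  # collinear points: fall back to all pairs
            pairs = {(i, j) for i in range(len(pts)) for j in range(i + 1, len(pts))}
    else:
        pairs = {(0, 1)}
    for i, j in pairs:
        if np.hypot(*(pts[i] - pts[j])) <= max_len_um:
            graph.add_edge(ids[i], ids[j])
    return graph


# ---------------------------------------------------------------------------
# tumor / stroma segmentation


def segment_tissue(
    cells: CellTable,
    graph: nx.Graph,
    tumor_flag: str = "pos_CK",
    small_max: int = 5,
    large_min: int = 10,
) -> pd.Series:
    """Assign each cell to the tumor or stroma compartment.

    Step 1 (naive): tumor iff the cytokeratin flag is set.  Step 2: on the
    naive labelling, every connected same-compartment group of fewer than
    ``small_max`` cells that has a graph edge to an opposite group of more
    than ``large_min`` cells is relabelled; all reassignments are decided on
    the naive labelling and applied at once.
    """
    df = cells.df
    if tumor_flag not in df.columns:
        raise FormatError(f"missing tumor flag column {tumor_flag!r}")
    naive = {
        cid: ("tumor" if flag else "stroma")
        for cid, flag in zip(df["cell_id"], df[tumor_flag].astype(bool))
    }
    comp_of: dict = {}
    comps: list[tuple[str, set]] = []
    for label in ("tumor", "stroma"):
        sub = graph.subgraph([c for c in graph.nodes if naive.get(c) == label])
        for nodes in nx.connected_components(sub):
            idx = len(comps)
            comps.append((label, set(nodes)))
            for n in nodes:
                comp_of[n] = idx

    final = dict(naive)
    for label, nodes in comps:
        if len(nodes) >= small_max:
            continue
        opposite = "stroma" if label == "tumor" else "tumor"
        neighbour_comps = {
            comp_of[v]
            for u in nodes
            for v in graph.neighbors(u)
            if naive.get(v) == opposite
        }
        if any(len(comps[k][1]) > large_min for k in neighbour_comps):
            for n in nodes:
                final[n] = opposite
    return pd.Series(
        [final.get(cid, "none") for cid in df["cell_id"]],
        index=df.index,
        name="compartment",
    )


# ---------------------------------------------------------------------------
# density and alpha shapes


def local_density(points: np.ndarray, radius_um: float = 50.0) -> np.ndarray:
    """Disk-count local density in cells/mm²: (neighbours within radius,
    excluding self, plus one) / (π·radius²)."""
    if radius_um <= 0:
        raise FormatError("radius_um must be > 0")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return np.zeros(0)
    tree = cKDTree(points)
    counts = np.array(tree.query_ball_point(points, r=radius_um, return_length=True))
    # query counts the point itself when distinct points coincide this still
    # matches "neighbours excluding self + 1"
    area_mm2 = np.pi * (radius_um / 1000.0) ** 2
    return counts / area_mm2


def alpha_shape(points: np.ndarray, alpha_um: float):
    """Alpha complex outline: union of Delaunay triangles whose circumradius
    is at most ``alpha_um``.  Degenerate inputs (fewer than 3 points, or all
    collinear) fall back to the convex hull buffered by ``alpha_um``/10."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 3:
        return MultiPoint(points).convex_hull.buffer(alpha_um / 10.0)
    try:
        tri = Delaunay(points)
    except QhullError:
        return MultiPoint(points).convex_hull.buffer(alpha_um / 10.0)
    keep = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        r = _circumradius(a, b, c)
        if r <= alpha_um:
            keep.append(Polygon([a, b, c]))
    if not keep:
        return Polygon()
    return unary_union(keep)


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b))
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return np.inf
    return la * lb * lc / (2.0 * area2)


def _polygon_parts(geom):
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        return [g for g in geom.geoms if g.geom_type == "Polygon"]
    return []


# ---------------------------------------------------------------------------
# TLS and patch detection


def detect_tls(
    b_cell_points: np.ndarray,
    point_ids=None,
    density_threshold: float = 2000.0,
    min_cells: int = 40,
    radius_um: float = 50.0,
    alpha_um: float = 50.0,
) -> PatchSet:
    """Detect tertiary-lymphoid-structure proxies from B-cell positions.

    Keeps B cells whose local density is strictly above ``density_threshold``
    cells/mm², outlines them with the alpha shape, and retains each connected
    outline polygon containing at least ``min_cells`` kept cells.
    """
    pts = np.asarray(b_cell_points, dtype=float).reshape(-1, 2)
    ids = np.arange(len(pts)) if point_ids is None else np.asarray(point_ids)
    params = dict(
        density_threshold=density_threshold,
        min_cells=min_cells,
        radius_um=radius_um,
        alpha_um=alpha_um,
    )
    dens = local_density(pts, radius_um)
    keep = dens > density_threshold
    kept_pts, kept_ids = pts[keep], ids[keep]
    if len(kept_pts) < 3:
        return PatchSet([], kind="TLS", params=params)
    shape = alpha_shape(kept_pts, alpha_um)
    patches = []
    for poly in _polygon_parts(shape):
        inside = [
            kid for kid, p in zip(kept_ids, kept_pts) if poly.covers(Point(p))
        ]
        if len(inside) >= min_cells:
            patches.append(
                Patch(
                    patch_id=len(patches) + 1,
                    members=list(inside),
                    core_members=list(inside),
                    polygon=poly,
                    area_um2=poly.area,
                )
            )
    return PatchSet(patches, kind="TLS", params=params)


def detect_patches(
    cells: CellTable,
    graph: nx.Graph,
    member_types: list[str],
    kind: str = "CD20",
    min_cells: int = 25,
    expand_um: float | None = None,
    alpha_um: float = 50.0,
) -> PatchSet:
    """Detect cell patches on a neighbourhood graph (mass-cytometry style).

    Cores are connected components of the graph restricted to the member
    phenotypes, with at least ``min_cells`` cells.  Every cell of any type
    whose centroid lies within ``expand_um`` (inclusive) of the nearest core
    member centroid joins the patch.  Default expansion: 10 μm for CD20
    patches, 25 μm for tumor patches; 0 disables expansion.
    """
    df = cells.df
    if "phenotype" not in df.columns:
        raise FormatError("cell table needs a phenotype column for patch detection")
    if expand_um is None:
        expand_um = {"CD20": 10.0, "tumor": 25.0}.get(kind, 0.0)
    params = dict(member_types=list(member_types), min_cells=min_cells,
                  expand_um=expand_um, alpha_um=alpha_um)
    member_ids = set(df.loc[df["phenotype"].isin(member_types), "cell_id"])
    if not member_ids:
        return PatchSet([], kind=kind, params=params)
    sub = graph.subgraph([n for n in graph.nodes if n in member_ids])
    cores = [c for c in nx.connected_components(sub) if len(c) >= min_cells]

    pos = df.set_index("cell_id")[["x_um", "y_um"]]
    patches = []
    for core in sorted(cores, key=lambda c: sorted(map(str, c))):
        core_ids = sorted(core, key=str)
        members = list(core_ids)
        if expand_um > 0:
            core_xy = pos.loc[core_ids].to_numpy(dtype=float)
            tree = cKDTree(core_xy)
            others = df.loc[~df["cell_id"].isin(core), "cell_id"]
            if len(others):
                other_xy = pos.loc[others].to_numpy(dtype=float)
                d, _ = tree.query(other_xy)
                members += [cid for cid, di in zip(others, d) if di <= expand_um]
        member_xy = pos.loc[members].to_numpy(dtype=float)
        poly = alpha_shape(member_xy, alpha_um)
        geom = unary_union(_polygon_parts(poly)) if _polygon_parts(poly) else poly
        patches.append(
            Patch(
                patch_id=len(patches) + 1,
                members=members,
                core_members=list(core_ids),
                polygon=geom,
                area_um2=geom.area,
            )
        )
    return PatchSet(patches, kind=kind, params=params)
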
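"""End-to-end pipelines chaining the library stages.

``run_mif_pipeline`` reproduces the fluorescence quantification workflow:
(optional) unmixing, nuclear segmentation, Voronoi cell expansion, per-cell
quantification, thresholding, phenotype assignment, tumor–stroma
segmentation, TLS detection, and sample QC.  ``run_concordance`` aligns two
modality cell tables with a landmark similarity transform and scores
per-cell-type co-localization with the L-function area and MAD test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    colocalization_call,
    default_radii,
    estimate_similarity_transform,
    kcross,
    l_area_score,
    mad_test,
    pair_modalities,
)
from .datatypes import CellTable, FormatError, MarkerImageStack, PatchSet, PhenotypeKey, QCReport, ThresholdSet
from .phenotyping import apply_thresholds, assign_phenotypes, quantify_cells
from .qc import sample_qc
from .segmentation import SegmentationResult, expand_cells, segment_nuclei
from .structures import build_adjacency_graph, detect_tls, segment_tissue
from .unmixing import MixingModel, unmix


@dataclass
class MIFParams:
    """Tunable parameters of the fluorescence pipeline (defaults as documented
    per stage)."""

    dapi_marker: str = "DAPI"
    tumor_marker: str = "CK"
    b_marker: str = "CD20"
    window_um: float = 51.0
    threshold_offset: float = 0.0
    min_area_um2: float = 8.0
    min_peak_sep_um: float = 4.0
    max_expand_um: float = 5.0
    graph_method: str = "delaunay_maxlen"
    graph_param_um: float = 30.0
    tissue_small_max: int = 5
    tissue_large_min: int = 10
    tls_density_threshold: float = 2000.0
    tls_min_cells: int = 40
    tls_radius_um: float = 50.0
    tls_alpha_um: float = 50.0
    seed: int = 0


@dataclass
class MIFResult:
    cells: CellTable
    segmentation: SegmentationResult
    tls: PatchSet
    qc: QCReport
    unmixed: MarkerImageStack | None
    provenance: dict


def run_mif_pipeline(
    stack: MarkerImageStack,
    thresholds: ThresholdSet,
    phenotype_key: PhenotypeKey,
    mixing_model: MixingModel | None = None,
    params: MIFParams | None = None,
    missing_or_folded_fraction: float = 0.0,
    marker_signal_ok: dict[str, bool] | None = None,
    fully_necrotic: bool = False,
) -> MIFResult:
    """Run the full fluorescence quantification workflow on one image."""
    params = params or MIFParams()
    for marker in thresholds.markers:
        if marker not in stack.marker_names and mixing_model is None:
            raise FormatError(f"threshold given for marker {marker!r} absent from image")

    unmixed = unmix(stack, mixing_model) if mixing_model is not None else None
    work = unmixed if unmixed is not None else stack

    dapi = (
        work.channel_image(params.dapi_marker)
        if params.dapi_marker in work.marker_names
        else stack.channel_image(params.dapi_marker)
    )
    nuclei = segment_nuclei(
        dapi,
        stack.pixel_size_um,
        window_um=params.window_um,
        offset=params.threshold_offset,
        min_area_um2=params.min_area_um2,
        min_peak_sep_um=params.min_peak_sep_um,
    )
    seg = expand_cells(nuclei, max_dist_um=params.max_expand_um)

    table = quantify_cells(work, seg)
    table = apply_thresholds(table, thresholds)
    table = assign_phenotypes(table, phenotype_key)

    graph = build_adjacency_graph(
        cells=table,
        masks=seg.cells,
        method=params.graph_method,
        param_um=params.graph_param_um,
    )
    df = table.df.copy()
    df["compartment"] = segment_tissue(
        table,
        graph,
        tumor_flag=f"pos_{params.tumor_marker}",
        small_max=params.tissue_small_max,
        large_min=params.tissue_large_min,
    ).to_numpy()

    # B cells for TLS: positive for the B marker, tumor-marker negative
    b_flag = f"pos_{params.b_marker}"
    if b_flag in df.columns:
        is_b = df[b_flag] & ~df[f"pos_{params.tumor_marker}"]
    else:
        is_b = pd.Series(False, index=df.index)
    b_cells = df.loc[is_b]
    tls = detect_tls(
        b_cells[["x_um", "y_um"]].to_numpy(dtype=float),
        point_ids=b_cells["cell_id"].to_numpy(),
        density_threshold=params.tls_density_threshold,
        min_cells=params.tls_min_cells,
        radius_um=params.tls_radius_um,
        alpha_um=params.tls_alpha_um,
    )
    in_tls = set()
    for patch in tls.patches:
        in_tls.update(patch.members)
    df["in_tls"] = df["cell_id"].isin(in_tls)

    qc = sample_qc(missing_or_folded_fraction, marker_signal_ok, fully_necrotic)
    prov = provenance_record(
        {"params": asdict(params), "thresholds": {m: asdict(e) for m, e in thresholds.entries.items()}},
        seed=params.seed,
    )
    return MIFResult(
        cells=CellTable(df),
        segmentation=seg,
        tls=tls,
        qc=qc,
        unmixed=unmixed,
        provenance=prov,
    )


def run_concordance(
    imc_cells: CellTable,
    mif_cells: CellTable,
    landmarks_mif: np.ndarray,
    landmarks_imc: np.ndarray,
    cell_types: list[str] | None = None,
    nsim: int = 99,
    alpha: float = 0.01,
    n_radii: int = 128,
    seed: int = 0,
    min_landmarks: int = 4,
) -> pd.DataFrame:
    """Score per-cell-type spatial concordance between two aligned modalities.

    Returns one row per cell type with the L-area score, MAD p-value and the
    co-localization call; types absent from either modality are flagged
    ``absent`` and not tested.
    """
    landmarks_mif = np.asarray(landmarks_mif, dtype=float).reshape(-1, 2)
    landmarks_imc = np.asarray(landmarks_imc, dtype=float).reshape(-1, 2)
    if len(landmarks_mif) < min_landmarks:
        raise FormatError(f"need at least {min_landmarks} landmark pairs")
    transform = estimate_similarity_transform(landmarks_mif, landmarks_imc)

    imc_df, mif_df = imc_cells.df, mif_cells.df
    if cell_types is None:
        cell_types = sorted(set(imc_df["phenotype"]) | set(mif_df["phenotype"]))
    rows = []
    for k, ct in enumerate(cell_types):
        present = (imc_df["phenotype"] == ct).any() and (mif_df["phenotype"] == ct).any()
        if not present:
            rows.append({"cell_type": ct, "area_um2": np.nan, "p_value": np.nan,
                         "call": "absent", "rmse_um": transform.rmse})
            continue
        pattern = pair_modalities(imc_df, mif_df, transform, ct)
        try:
            radii = default_radii(pattern.window, n=n_radii)
            curve = kcross(pattern, "IMC", "mIF", radii)
            area = l_area_score(curve)
            _, p = mad_test(pattern, "IMC", "mIF", nsim=nsim, radii=radii, seed=seed + k)
            call = colocalization_call(area, p, alpha)
        except FormatError:
            rows.append({"cell_type": ct, "area_um2": np.nan, "p_value": np.nan,
                         "call": "absent", "rmse_um": transform.rmse})
            continue
        rows.append({"cell_type": ct, "area_um2": area, "p_value": p, "call": call,
                     "rmse_um": transform.rmse})
    return pd.DataFrame(rows)


def provenance_record(config: dict, seed: int) -> dict:
    """Machine-readable provenance: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "tissuequant_version": __version__,
        "numpy_version": np.__version__,
    }
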
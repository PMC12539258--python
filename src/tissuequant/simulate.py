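"""Synthetic tissue images, point patterns, mixing scenarios, and batch
series with exact ground truth.

Every generator is seed-deterministic and emits the same containers the
analysis modules consume, so the full pipeline is testable without any
external data.  The tissue generator draws Gaussian-blurred nuclear disks
(the DAPI channel) at sites with a guaranteed minimum separation and paints
phenotype-determined marker levels onto the ground-truth cell regions,
optionally with additive Gaussian noise truncated at zero.  It emulates
well-separated cells with crisp on/off marker expression; it does not model
optics (PSF), marker spillover between neighbouring cells, or tissue
texture — passing tests demonstrate correctness of the algorithms, not
robustness to real staining artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import CellTable, Channel, FormatError, LabelMask, MarkerImageStack, PointPattern
from .segmentation import SegmentationResult, expand_cells


@dataclass
class MarkerModel:
    """Expression model of one marker: bright on some phenotypes, dim elsewhere."""

    positive_phenotypes: tuple[str, ...]
    on_level: float = 100.0
    off_level: float = 0.0

    def __post_init__(self) -> None:
        if not self.on_level > self.off_level:
            raise FormatError("on_level must exceed off_level")

    def level(self, phenotype: str) -> float:
        return self.on_level if phenotype in self.positive_phenotypes else self.off_level


@dataclass
class TissueScenario:
    """Parameters of a synthetic stained-tissue image."""

    width_um: float = 200.0
    height_um: float = 200.0
    pixel_size_um: float = 1.0
    n_cells: int = 30
    nucleus_radius_um: float = 4.0
    min_separation_um: float = 14.0
    phenotype_proportions: dict[str, float] = field(
        default_factory=lambda: {"Tumor": 0.5, "T": 0.3, "other": 0.2}
    )
    markers: dict[str, MarkerModel] = field(
        default_factory=lambda: {
            "CK": MarkerModel(("Tumor",)),
            "CD3": MarkerModel(("T",)),
        }
    )
    noise_sd: float = 0.0
    blur_sigma_um: float = 1.0
    dapi_level: float = 200.0
    seed: int = 0
    image_id: str = "synthetic"

    def __post_init__(self) -> None:
        total = sum(self.phenotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise FormatError("phenotype proportions must sum to 1")


def _place_sites(scenario: TissueScenario, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres with the required minimum separation."""
    margin = scenario.nucleus_radius_um + 1.0
    lo = np.array([margin, margin])
    hi = np.array([scenario.width_um - margin, scenario.height_um - margin])
    if np.any(hi <= lo):
        raise FormatError("window too small for the nucleus radius")
    sites: list[np.ndarray] = []
    misses = 0
    while len(sites) < scenario.n_cells:
        p = rng.uniform(lo, hi)
        if all(np.hypot(*(p - q)) >= scenario.min_separation_um for q in sites):
            sites.append(p)
            misses = 0
        else:
            misses += 1
            if misses > 5000:  # saturated: no room left at this separation
                raise FormatError(
                    "infeasible packing: cannot place nuclei at this separation"
                )
    return np.array(sites)


def generate_tissue_image(
    scenario: TissueScenario,
) -> tuple[MarkerImageStack, SegmentationResult, CellTable]:
    """Render a tissue scenario: image stack, ground-truth segmentation, and
    ground-truth cell table (one row per placed nucleus)."""
    rng = np.random.default_rng(scenario.seed)
    s = scenario.pixel_size_um
    h = int(round(scenario.height_um / s))
    w = int(round(scenario.width_um / s))
    sites = _place_sites(scenario, rng)

    names = list(scenario.phenotype_proportions)
    probs = np.array([scenario.phenotype_proportions[n] for n in names])
    phenotypes = rng.choice(names, size=len(sites), p=probs)

    # ground-truth nuclei: one disk per site (separation >= 2 r guarantees
    # disjointness), labels in placement order
    yy, xx = np.mgrid[0:h, 0:w]
    cx = (xx + 0.5) * s
    cy = (yy + 0.5) * s
    nuclei = np.zeros((h, w), dtype=np.int32)
    for lab, (x, y) in enumerate(sites, start=1):
        disk = (cx - x) ** 2 + (cy - y) ** 2 <= scenario.nucleus_radius_um**2
        nuclei[disk] = lab
    seg = expand_cells(LabelMask(nuclei, s), max_dist_um=5.0)

    dapi = np.where(nuclei > 0, scenario.dapi_level, 0.0)
    if scenario.blur_sigma_um > 0:
        dapi = ndimage.gaussian_filter(dapi, sigma=scenario.blur_sigma_um / s)

    planes = [dapi]
    channels = [Channel("ch0", "DAPI", "DAPI")]
    for k, (marker, model) in enumerate(scenario.markers.items(), start=1):
        img = np.zeros((h, w))
        for lab, ph in enumerate(phenotypes, start=1):
            level = model.level(ph)
            if level:
                img[seg.cells.labels == lab] = level
        if scenario.noise_sd > 0:
            img = img + rng.normal(0.0, scenario.noise_sd, size=img.shape)
        planes.append(np.clip(img, 0.0, None))
        channels.append(Channel(f"ch{k}", marker, f"fluor_{marker}"))

    stack = MarkerImageStack(
        pixels=np.stack(planes, axis=-1),
        channels=channels,
        pixel_size_um=s,
        image_id=scenario.image_id,
    )
    areas = seg.cells.areas_um2()
    truth = CellTable(
        pd.DataFrame(
            {
                "image_id": scenario.image_id,
                "cell_id": np.arange(1, len(sites) + 1),
                "x_um": sites[:, 0],
                "y_um": sites[:, 1],
                "area_um2": areas.reindex(np.arange(1, len(sites) + 1)).to_numpy(),
                "phenotype": phenotypes,
            }
        )
    )
    return stack, seg, truth


def generate_point_pattern(
    kind: str,
    window: tuple[float, float, float, float],
    seed: int = 0,
    **params,
) -> PointPattern:
    """Generate a point pattern in a rectangular window (μm).

    kinds
    -----
    ``csr``     — complete spatial randomness; pass ``n`` (binomial, fixed
                  count) or ``intensity_per_mm2`` (Poisson count).
    ``grid``    — regular square grid; pass ``spacing_um`` (intensity is then
                  1/spacing² per unit area).
    ``thomas``  — Thomas cluster process; pass ``n_parents`` (or
                  ``parent_per_mm2``), ``mean_offspring``, ``sigma_um``.
    """
    x0, y0, x1, y1 = window
    if not (x1 > x0 and y1 > y0):
        raise FormatError("degenerate window")
    rng = np.random.default_rng(seed)
    area_mm2 = (x1 - x0) * (y1 - y0) / 1e6

    if kind == "csr":
        if "n" in params:
            n = int(params["n"])
        else:
            lam = float(params["intensity_per_mm2"])
            n = rng.poisson(lam * area_mm2)
        pts = rng.uniform((x0, y0), (x1, y1), size=(n, 2))
    elif kind == "grid":
        spacing = float(params["spacing_um"])
        if spacing <= 0:
            raise FormatError("spacing_um must be > 0")
        gx = np.arange(x0 + spacing / 2, x1, spacing)
        gy = np.arange(y0 + spacing / 2, y1, spacing)
        pts = np.array([(x, y) for y in gy for x in gx])
    elif kind == "thomas":
        if "n_parents" in params:
            n_par = int(params["n_parents"])
        else:
            n_par = rng.poisson(float(params["parent_per_mm2"]) * area_mm2)
        mean_off = float(params.get("mean_offspring", 20))
        sigma = float(params.get("sigma_um", 20.0))
        parents = rng.uniform((x0, y0), (x1, y1), size=(n_par, 2))
        pts = []
        for p in parents:
            k = rng.poisson(mean_off)
            pts.append(p + rng.normal(0, sigma, size=(k, 2)))
        pts = np.vstack(pts) if pts else np.zeros((0, 2))
        inside = (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        )
        pts = pts[inside]
    else:
        raise FormatError(f"unknown pattern kind {kind!r}")
    return PointPattern(points=pts, window=window)


def generate_mixing_scenario(
    mixing_matrix: np.ndarray,
    sources: list[str],
    background: np.ndarray,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 50.0,
    blob_fraction: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Forward-simulate a single-stain library plus a mixed image.

    ``mixing_matrix`` must be column-normalized with positive diagonal
    entries for the non-autofluorescence sources (channel k is fluorophore
    k's spectral band).  Single-stain images activate one source as sparse
    constant-amplitude blobs over the background; the mixed image draws a
    random non-negative abundance field for every source.

    Returns ``(single_stains, unstained, mixed, true_abundances)`` where
    ``single_stains`` maps fluorophore name -> stack.
    """
    from .unmixing import AUTOFLUORESCENCE, MixingModel

    M = np.asarray(mixing_matrix, dtype=float)
    background = np.asarray(background, dtype=float)
    model = MixingModel(M, list(sources), background)  # validates normalization
    rng = np.random.default_rng(seed)
    h, w = shape
    n_chan = M.shape[0]
    channels = [Channel(f"ch{i}", f"marker{i}", sources[i] if i < len(sources) else f"band{i}")
                for i in range(n_chan)]

    def blobs() -> np.ndarray:
        field_ = np.zeros(h * w)
        k = max(1, int(blob_fraction * h * w))
        field_[rng.choice(h * w, size=k, replace=False)] = amplitude
        return field_.reshape(h, w)

    def render(abund: np.ndarray) -> MarkerImageStack:
        flat = abund.reshape(-1, M.shape[1])
        pix = flat @ M.T + background
        if noise_sd > 0:
            pix = pix + rng.normal(0, noise_sd, size=pix.shape)
        return MarkerImageStack(
            pixels=np.clip(pix, 0, None).reshape(h, w, n_chan),
            channels=channels,
            pixel_size_um=1.0,
        )

    af_idx = sources.index(AUTOFLUORESCENCE) if AUTOFLUORESCENCE in sources else None
    single: dict[str, MarkerImageStack] = {}
    for j, name in enumerate(sources):
        if j == af_idx:
            continue
        a = np.zeros((h, w, M.shape[1]))
        a[:, :, j] = blobs()
        single[name] = render(a)

    a_unstained = np.zeros((h, w, M.shape[1]))
    if af_idx is not None:
        a_unstained[:, :, af_idx] = blobs()
    unstained = render(a_unstained)

    true_abund = rng.uniform(0, amplitude, size=(h, w, M.shape[1]))
    mixed = render(true_abund)
    return single, unstained, mixed, true_abund


def generate_batch_series(
    n_batches: int = 11,
    base_composition: dict[str, float] | None = None,
    base_means: dict[tuple[str, str], float] | None = None,
    sigma: float = 0.1,
    cells_per_batch: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a control-pellet batch series.

    Per batch, cell counts are multinomial around ``base_composition`` and
    each (cell type, marker) mean is the base value times a log-normal
    multiplicative batch factor ``exp(sigma * z)`` (log-normal keeps means
    positive; its CV is sqrt(exp(sigma²)−1) ≈ sigma for small sigma).

    Returns ``(counts, means)``: counts is batches x cell types; means is
    long-form with columns batch, cell_type, marker, mean.
    """
    if n_batches < 2 or sigma < 0:
        raise FormatError("need n_batches >= 2 and sigma >= 0")
    base_composition = base_composition or {"T": 0.4, "B": 0.3, "Tumor": 0.3}
    base_means = base_means or {
        ("T", "CD3"): 50.0,
        ("B", "CD20"): 40.0,
        ("Tumor", "CK"): 80.0,
    }
    rng = np.random.default_rng(seed)
    types = list(base_composition)
    p = np.array([base_composition[t] for t in types])
    counts = pd.DataFrame(
        rng.multinomial(cells_per_batch, p, size=n_batches),
        columns=types,
        index=[f"batch{i+1}" for i in range(n_batches)],
    )
    rows = []
    for b in counts.index:
        for (cell_type, marker), base in base_means.items():
            rows.append(
                {
                    "batch": b,
                    "cell_type": cell_type,
                    "marker": marker,
                    "mean": base * np.exp(sigma * rng.standard_normal()),
                }
            )
    return counts, pd.DataFrame(rows)
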
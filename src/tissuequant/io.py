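"""Readers and writers for the plain-text / TIFF fixture formats.

Supported image dialect is plain multi-page TIFF (uint8 / uint16 / float32)
with a sidecar channel manifest CSV (``channel_id, marker, fluorophore``).
Pyramidal containers are out of scope; converting them to plain TIFF is a
documented precondition.  Tables are UTF-8 comma-separated CSV with a header
row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    CELL_TABLE_CORE,
    CELL_TABLE_TAIL,
    CellTable,
    Channel,
    FormatError,
    LabelMask,
    MarkerImageStack,
    PhenotypeKey,
    PhenotypeRule,
    ThresholdEntry,
    ThresholdSet,
)

__all__ = [
    "read_manifest",
    "read_image_stack",
    "write_image_stack",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
    "read_phenotype_key",
    "write_phenotype_key",
    "read_thresholds",
    "write_mixing_model",
]


def read_manifest(path: str | Path) -> list[Channel]:
    df = pd.read_csv(path, dtype=str)
    need = {"channel_id", "marker", "fluorophore"}
    if not need.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(need)}")
    return [Channel(r.channel_id, r.marker, r.fluorophore) for r in df.itertuples()]


def read_image_stack(
    path: str | Path,
    manifest: str | Path | list[Channel],
    pixel_size_um: float | None = None,
    image_id: str | None = None,
    modality: str = "mIF",
) -> MarkerImageStack:
    """Read a multi-page TIFF plus channel manifest into a MarkerImageStack.

    The pixel size is read from the TIFF resolution tags when present and can
    be overridden (or supplied, when tags are absent) via ``pixel_size_um``.
    """
    path = Path(path)
    channels = manifest if isinstance(manifest, list) else read_manifest(manifest)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(tif)
    if pixel_size_um is None:
        raise FormatError(
            f"{path.name}: no resolution tag; pass pixel_size_um explicitly"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path.name}: expected 2-D pages, got shape {arr.shape}")
    if arr.shape[0] != len(channels):
        raise FormatError(
            f"{path.name}: {arr.shape[0]} pages but {len(channels)} manifest entries"
        )
    pixels = np.moveaxis(arr, 0, -1).astype(np.float64)
    return MarkerImageStack(
        pixels=pixels,
        channels=channels,
        pixel_size_um=float(pixel_size_um),
        image_id=image_id or path.stem,
        modality=modality,
    )


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is None:
        return None
    num, den = res.value
    if num == 0:
        return None
    per_unit = num / den
    # we write CENTIMETER; μm per pixel = 1e4 / (pixels per cm)
    if unit is not None and getattr(unit.value, "name", str(unit.value)) in (
        "CENTIMETER",
        "3",
    ):
        return 1e4 / per_unit
    return None


def write_image_stack(stack: MarkerImageStack, path: str | Path) -> None:
    """Write as multi-page float32 TIFF with resolution tags, plus the manifest
    CSV alongside (``<stem>.manifest.csv``)."""
    path = Path(path)
    pages = np.moveaxis(stack.pixels, -1, 0).astype(np.float32)
    px_per_cm = 1e4 / stack.pixel_size_um
    tifffile.imwrite(
        path,
        pages,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    manifest = pd.DataFrame(
        [(c.channel_id, c.marker, c.fluorophore) for c in stack.channels],
        columns=["channel_id", "marker", "fluorophore"],
    )
    manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def read_label_mask(path: str | Path, pixel_size_um: float, connectivity: int = 8) -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(arr.astype(np.int32), pixel_size_um, connectivity)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32), photometric="minisblack")


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write the cell table as CSV, numeric fields at 6 significant digits.

    Column order: the documented core columns first (those present), then
    score/pos/phenotype columns, then any annotation passthrough columns.
    """
    df = table.df
    core = [c for c in CELL_TABLE_CORE if c in df.columns]
    scores = sorted(c for c in df.columns if c.startswith("score_"))
    pos = sorted(c for c in df.columns if c.startswith("pos_"))
    tail = [c for c in CELL_TABLE_TAIL if c in df.columns]
    rest = [c for c in df.columns if c not in core + scores + pos + tail]
    df[core + scores + pos + tail + rest].to_csv(path, index=False, float_format="%.6g")


def read_cell_table(path: str | Path) -> CellTable:
    df = pd.read_csv(path)
    for col in df.columns:
        if col.startswith("pos_") or col == "in_tls":
            df[col] = df[col].astype(bool)
    return CellTable(df)


def read_phenotype_key(
    path: str | Path, priority: list[str] | None = None, fallback: str = "other"
) -> PhenotypeKey:
    """Read a phenotype-key CSV: one column per marker (cells '+', '-', 'any')
    plus a ``phenotype`` column; validates completeness by enumerating all
    positivity combinations (M ≤ 12)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "phenotype" not in df.columns:
        raise FormatError("phenotype key needs a 'phenotype' column")
    if "priority" in df.columns:  # optional per-marker rank row? not supported
        raise FormatError("priority must be given separately, not as a column")
    markers = [c for c in df.columns if c != "phenotype"]
    rules = []
    for rec in df.to_dict("records"):
        pattern = {
            m: (rec[m].strip() if isinstance(rec[m], str) else "any") for m in markers
        }
        rules.append(PhenotypeRule(pattern=pattern, phenotype=rec["phenotype"]))
    key = PhenotypeKey(rules=rules, priority=priority or markers, fallback=fallback)
    key.validate_complete()
    return key


def write_phenotype_key(key: PhenotypeKey, path: str | Path) -> None:
    markers = key.markers
    rows = [
        {**{m: rule.pattern.get(m, "any") for m in markers}, "phenotype": rule.phenotype}
        for rule in key.rules
    ]
    pd.DataFrame(rows, columns=markers + ["phenotype"]).to_csv(path, index=False)


def read_thresholds(spec: dict | str | Path) -> ThresholdSet:
    """Build a ThresholdSet from a mapping (or YAML/JSON file) of the form
    ``{marker: {region, statistic, threshold}}``."""
    if not isinstance(spec, dict):
        text = Path(spec).read_text()
        if str(spec).endswith(".json"):
            spec = json.loads(text)
        else:
            import yaml

            spec = yaml.safe_load(text)
    entries = {
        m: ThresholdEntry(v["region"], v["statistic"], float(v["threshold"]))
        for m, v in spec.items()
    }
    return ThresholdSet(entries)


def write_mixing_model(model, path_csv: str | Path) -> None:
    """Serialize a MixingModel as CSV (rows = channels, columns = sources) with
    a JSON metadata sidecar holding the background offsets."""
    path_csv = Path(path_csv)
    pd.DataFrame(model.matrix, index=model.channel_names, columns=model.sources).to_csv(
        path_csv
    )
    meta = {
        "sources": model.sources,
        "background": list(map(float, model.background)),
    }
    path_csv.with_suffix(".json").write_text(json.dumps(meta, indent=1))
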
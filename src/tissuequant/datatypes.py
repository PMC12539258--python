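"""Core domain types shared by every pipeline stage.

Coordinate convention
---------------------
All physical coordinates are continuous micrometres with the origin at the
top-left pixel *corner*, x increasing rightward and y downward.  The centre
of pixel ``(row, col)`` therefore sits at ``((col + 0.5) * s, (row + 0.5) * s)``
where ``s`` is the pixel size in μm.  This makes mask ↔ point conversions
unambiguous across modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input file or table violates its documented contract."""


@dataclass
class Channel:
    """One acquisition channel: id, the marker it reports, and the fluorophore."""

    channel_id: str
    marker: str
    fluorophore: str


@dataclass
class MarkerImageStack:
    """Multi-channel pixel grid with manifest and physical pixel size.

    ``pixels`` is an ``(H, W, C)`` float array of non-negative intensities;
    ``channels`` holds one :class:`Channel` per plane, in plane order.
    """

    pixels: np.ndarray
    channels: list[Channel]
    pixel_size_um: float
    image_id: str = "image"
    modality: str = "mIF"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise FormatError("pixels must be an H x W x C array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image must have H, W >= 1")
        if self.pixels.shape[2] != len(self.channels):
            raise FormatError(
                f"channel count mismatch: {self.pixels.shape[2]} planes vs "
                f"{len(self.channels)} manifest entries"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise FormatError("intensities must be non-negative")
        names = [c.marker for c in self.channels]
        if len(set(names)) != len(names):
            raise FormatError("channel marker names must be unique")
        if not (self.pixel_size_um > 0):
            raise FormatError("pixel_size_um must be > 0")
        if self.modality not in ("mIF", "IMC"):
            raise FormatError("modality must be 'mIF' or 'IMC'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def marker_names(self) -> list[str]:
        return [c.marker for c in self.channels]

    def channel_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise KeyError(f"no channel for marker {marker!r}") from None

    def channel_image(self, marker: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_index(marker)]


@dataclass
class LabelMask:
    """Integer-labelled pixel grid: 0 = background, positive ids = objects.

    Labels need not be consecutive, but each label's pixel set must be
    connected under the declared connectivity (4 or 8).
    """

    labels: np.ndarray
    pixel_size_um: float
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label mask must have integer dtype")
        if self.labels.ndim != 2:
            raise FormatError("label mask must be 2-D")
        if np.any(self.labels < 0):
            raise FormatError("label ids must be non-negative")
        if self.connectivity not in (4, 8):
            raise FormatError("connectivity must be 4 or 8")
        if not (self.pixel_size_um > 0):
            raise FormatError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def validate_connectivity(self) -> None:
        """Check every object is one connected component; raise otherwise."""
        structure = ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)
        for lab in self.label_ids:
            _, n = ndimage.label(self.labels == lab, structure=structure)
            if n != 1:
                raise FormatError(f"label {lab} is not connected ({n} components)")

    def areas_um2(self) -> pd.Series:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return pd.Series(counts * self.pixel_size_um**2, index=ids, name="area_um2")

    def centroids_um(self) -> pd.DataFrame:
        """Centroid of each object's pixel centres, in μm."""
        ids = self.label_ids
        rc = ndimage.center_of_mass(np.ones_like(self.labels), self.labels, ids)
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        s = self.pixel_size_um
        return pd.DataFrame(
            {"x_um": (rc[:, 1] + 0.5) * s, "y_um": (rc[:, 0] + 0.5) * s}, index=ids
        )


#: Fixed leading columns of the on-disk cell-table CSV; extra columns are
#: preserved as annotation passthrough.
CELL_TABLE_CORE = ["image_id", "cell_id", "x_um", "y_um", "area_um2"]
CELL_TABLE_TAIL = ["phenotype", "compartment", "in_tls"]


@dataclass
class CellTable:
    """One row per cell: coordinates, marker scores, positivity, annotations.

    Column conventions:

    - ``score_<marker>_<region>_<stat>`` — summary statistic of a marker over
      a region (nucleus / cytoplasm / cell);
    - ``score_<marker>`` — the active score selected by a :class:`ThresholdSet`;
    - ``pos_<marker>`` — boolean positivity flag;
    - ``phenotype``, ``compartment`` (tumor / stroma / none), ``in_tls``;
    - any other column is carried through untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("image_id", "cell_id") if c not in df.columns]
        if missing:
            raise FormatError(f"cell table missing columns: {missing}")
        if df.duplicated(["image_id", "cell_id"]).any():
            raise FormatError("duplicate (image_id, cell_id) in cell table")
        if "area_um2" in df.columns and len(df) and not (df["area_um2"] > 0).all():
            raise FormatError("area_um2 must be > 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> list[str]:
        return [c[len("pos_") :] for c in self.df.columns if c.startswith("pos_")]

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy())


@dataclass
class PhenotypeRule:
    """Marker pattern → phenotype.  Pattern values: '+', '-', or 'any'."""

    pattern: dict[str, str]
    phenotype: str

    def __post_init__(self) -> None:
        bad = {v for v in self.pattern.values() if v not in ("+", "-", "any")}
        if bad:
            raise FormatError(f"invalid pattern values {bad}; use '+', '-', 'any'")

    def matches(self, flags: Mapping[str, bool]) -> bool:
        for marker, want in self.pattern.items():
            if want == "+" and not flags[marker]:
                return False
            if want == "-" and flags[marker]:
                return False
        return True


class AmbiguousKeyError(FormatError):
    """A positivity combination matches two rules that priority cannot separate."""


@dataclass
class PhenotypeKey:
    """Ordered rules mapping marker-positivity combinations to phenotypes.

    When several rules match a combination, the rule whose required-positive
    marker ranks highest in ``priority`` wins (this reproduces, e.g., calling a
    CD3+CD163+ cell a T cell when CD3 outranks CD163).  Combinations matching
    no rule fall back to ``fallback`` (default ``"other"``).
    """

    rules: list[PhenotypeRule]
    priority: list[str] = field(default_factory=list)
    fallback: str = "other"

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for rule in self.rules:
            for m in rule.pattern:
                seen.setdefault(m)
        return list(seen)

    def _rank(self, rule: PhenotypeRule) -> tuple:
        """Sort key for conflict resolution: best (lowest) priority index of a
        required-positive marker; rules requiring no positives rank last."""
        pos = [m for m, v in rule.pattern.items() if v == "+"]
        if not pos:
            return (1, 0)
        idx = []
        for m in pos:
            if m not in self.priority:
                raise FormatError(f"marker {m!r} missing from priority order")
            idx.append(self.priority.index(m))
        return (0, min(idx))

    def assign(self, flags: Mapping[str, bool]) -> str:
        hits = [r for r in self.rules if r.matches(flags)]
        if not hits:
            return self.fallback
        if len(hits) == 1:
            return hits[0].phenotype
        ranked = sorted(hits, key=self._rank)
        best = self._rank(ranked[0])
        tied = {r.phenotype for r in ranked if self._rank(r) == best}
        if len(tied) > 1:
            combo = {m: ("+" if flags[m] else "-") for m in self.markers}
            raise AmbiguousKeyError(
                f"combination {combo} matches phenotypes {sorted(tied)} with equal priority"
            )
        return ranked[0].phenotype

    def validate_complete(self, max_markers: int = 12) -> None:
        """Enumerate all 2^M positivity combinations and check each maps to
        exactly one phenotype after priority resolution."""
        markers = self.markers
        if len(markers) > max_markers:
            raise FormatError(
                f"completeness check limited to {max_markers} markers, key has {len(markers)}"
            )
        for combo in product([False, True], repeat=len(markers)):
            self.assign(dict(zip(markers, combo)))  # raises on ambiguity


@dataclass
class ThresholdEntry:
    region: str  # nucleus | cytoplasm | cell
    statistic: str  # mean | median | p75 | p90
    threshold: float

    def __post_init__(self) -> None:
        if self.region not in ("nucleus", "cytoplasm", "cell"):
            raise FormatError(f"unknown region {self.region!r}")
        if self.statistic not in ("mean", "median", "p75", "p90"):
            raise FormatError(f"unknown statistic {self.statistic!r}")
        if not np.isfinite(self.threshold):
            raise FormatError("threshold must be finite")


@dataclass
class ThresholdSet:
    """Per-marker score definition (region + statistic) and decision threshold."""

    entries: dict[str, ThresholdEntry]

    def score_column(self, marker: str) -> str:
        e = self.entries[marker]
        return f"score_{marker}_{e.region}_{e.statistic}"

    @property
    def markers(self) -> list[str]:
        return list(self.entries)


@dataclass
class QCReason:
    rule_id: str
    message: str
    quantity: float | None = None
    level: str = "WARN"  # WARN | FAIL


@dataclass
class QCReport:
    """Outcome of per-sample quality-control rules."""

    status: str  # PASS | WARN | FAIL
    reasons: list[QCReason] = field(default_factory=list)
    marker_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("PASS", "WARN", "FAIL"):
            raise FormatError("status must be PASS, WARN or FAIL")
        if self.status == "FAIL" and not any(r.level == "FAIL" for r in self.reasons):
            raise FormatError("FAIL status requires at least one FAIL-level reason")


@dataclass
class PointPattern:
    """Marked points in a rectangular observation window (μm)."""

    points: np.ndarray  # (n, 2) x/y in μm
    window: tuple[float, float, float, float]  # x0, y0, x1, y1
    marks: pd.Series | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise FormatError("window must have positive area")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if x.min() < x0 or x.max() > x1 or y.min() < y0 or y.max() > y1:
                raise FormatError("all points must lie inside the window")
        if self.marks is not None:
            self.marks = pd.Series(np.asarray(self.marks), name="mark")
            if len(self.marks) != len(self.points):
                raise FormatError("one mark per point required")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def window_area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    def subset(self, mark) -> np.ndarray:
        if self.marks is None:
            raise ValueError("pattern has no marks")
        return self.points[np.asarray(self.marks == mark)]


@dataclass
class Patch:
    patch_id: int
    members: list  # cell ids (or point indices)
    core_members: list
    polygon: object  # shapely geometry in μm
    area_um2: float


@dataclass
class PatchSet:
    """Detected patches (TLS / CD20 / tumor) with memberships and outlines."""

    patches: list[Patch]
    kind: str
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)

    def membership(self) -> pd.DataFrame:
        rows = []
        for p in self.patches:
            core = set(p.core_members)
            for m in p.members:
                rows.append({"patch_id": p.patch_id, "cell_id": m, "core": m in core})
        return pd.DataFrame(rows, columns=["patch_id", "cell_id", "core"])


@dataclass
class SpatialCurve:
    """Sampled cross L-function with its theoretical CSR expectation L(r)=r."""

    radii: np.ndarray
    l_values: np.ndarray
    n_i: int
    n_j: int
    correction: str = "translation"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.l_values = np.asarray(self.l_values, dtype=float)
        if self.radii.ndim != 1 or len(self.radii) != len(self.l_values):
            raise FormatError("radii and L values must be matching 1-D arrays")
        if len(self.radii) and (self.radii[0] < 0 or np.any(np.diff(self.radii) <= 0)):
            raise FormatError("radii must be non-negative and strictly increasing")
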
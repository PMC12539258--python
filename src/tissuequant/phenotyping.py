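"""Per-cell marker quantification, thresholding, phenotype assignment, and
the classifier-output harness (unknown rule, train/test split, evaluation).

Marker scores are summary statistics (mean / median / 75th / 90th
percentile) of pixel intensities over the nucleus, cytoplasm, and whole-cell
regions.  A cell is positive for a marker iff its configured score is
strictly above the marker threshold; the phenotype key then maps the
positivity combination to a phenotype, with marker priorities resolving
conflicts.  The classifier harness applies the "unknown" rule (maximum class
probability below 30% → unknown) and computes TPR / FPR / accuracy / macro-F1
from the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellTable, FormatError, MarkerImageStack, PhenotypeKey, ThresholdSet
from .segmentation import SegmentationResult

STATISTICS = {
    "mean": np.mean,
    "median": np.median,
    "p75": lambda v: np.percentile(v, 75),
    "p90": lambda v: np.percentile(v, 90),
}
REGIONS = ("nucleus", "cytoplasm", "cell")


def quantify_cells(
    stack: MarkerImageStack,
    seg: SegmentationResult,
    statistics: tuple[str, ...] = ("mean", "median", "p75", "p90"),
) -> CellTable:
    """Summarize every marker over nucleus / cytoplasm / cell per cell.

    Empty cytoplasm regions yield missing values (NaN), not zeros.  Centroids
    (μm, pixel-centre convention) and areas come from the cell mask.
    """
    if stack.shape != seg.cells.shape:
        raise FormatError("image and masks must share shape")
    unknown = set(statistics) - set(STATISTICS)
    if unknown:
        raise FormatError(f"unknown statistics {sorted(unknown)}")
    cell_ids = seg.cells.label_ids
    nuc_ids = set(seg.nuclei.label_ids.tolist())
    missing_nuc = [int(i) for i in cell_ids if int(i) not in nuc_ids]
    if missing_nuc:
        raise FormatError(f"cells without nuclei: {missing_nuc}")

    region_masks = {
        "nucleus": seg.nuclei.labels,
        "cytoplasm": seg.cytoplasm.labels,
        "cell": seg.cells.labels,
    }
    cent = seg.cells.centroids_um()
    areas = seg.cells.areas_um2()
    rows = {
        "image_id": stack.image_id,
        "cell_id": cell_ids,
        "x_um": cent.loc[cell_ids, "x_um"].to_numpy(),
        "y_um": cent.loc[cell_ids, "y_um"].to_numpy(),
        "area_um2": areas.loc[cell_ids].to_numpy(),
    }
    df = pd.DataFrame(rows)

    for region, labels in region_masks.items():
        flat_lab = labels.ravel()
        inside = flat_lab > 0
        lab_in = flat_lab[inside]
        order = np.argsort(lab_in, kind="stable")
        lab_sorted = lab_in[order]
        bounds = np.searchsorted(lab_sorted, cell_ids, side="left"), np.searchsorted(
            lab_sorted, cell_ids, side="right"
        )
        for marker in stack.marker_names:
            vals = stack.channel_image(marker).ravel()[inside][order]
            for stat in statistics:
                fn = STATISTICS[stat]
                col = np.full(len(cell_ids), np.nan)
                for k, (lo, hi) in enumerate(zip(*bounds)):
                    if hi > lo:
                        col[k] = fn(vals[lo:hi])
                df[f"score_{marker}_{region}_{stat}"] = col
    return CellTable(df)


def apply_thresholds(table: CellTable, thresholds: ThresholdSet) -> CellTable:
    """Set ``pos_<marker> = score > threshold`` (strict) for every marker.

    Also materializes the active score as ``score_<marker>``.  Idempotent:
    flags are recomputed from scores each call.
    """
    df = table.df.copy()
    for marker in thresholds.markers:
        col = thresholds.score_column(marker)
        if col not in df.columns:
            raise FormatError(f"missing score column {col!r} for marker {marker!r}")
        df[f"score_{marker}"] = df[col]
        df[f"pos_{marker}"] = df[col] > thresholds.entries[marker].threshold
    return CellTable(df)


def assign_phenotypes(table: CellTable, key: PhenotypeKey) -> CellTable:
    """Map each cell's positivity combination to a phenotype via the key."""
    df = table.df.copy()
    for m in key.markers:
        if f"pos_{m}" not in df.columns:
            raise FormatError(f"positivity flag pos_{m} missing")
    flags = df[[f"pos_{m}" for m in key.markers]].to_numpy(dtype=bool)
    # memoize per combination: at most 2^M distinct rows
    lut: dict[tuple, str] = {}
    out = []
    for row in map(tuple, flags):
        if row not in lut:
            lut[row] = key.assign(dict(zip(key.markers, row)))
        out.append(lut[row])
    df["phenotype"] = out
    return CellTable(df)


def assign_unknown(
    probabilities: pd.DataFrame, threshold_pct: float = 30.0
) -> pd.Series:
    """Label cells from class probabilities, with the unknown rule.

    A cell keeps the argmax class label iff its maximum class probability is
    at least ``threshold_pct`` percent; strictly below, it is labelled
    ``"unknown"``.
    """
    if probabilities.shape[1] == 0:
        raise FormatError("empty probability vector")
    p = probabilities.to_numpy(dtype=float)
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise FormatError("probabilities must be non-negative and sum to 1")
    labels = probabilities.columns.to_numpy()[p.argmax(axis=1)]
    labels = np.where(p.max(axis=1) < threshold_pct / 100.0, "unknown", labels)
    return pd.Series(labels, index=probabilities.index, name="label")


@dataclass
class ClassifierEval:
    """Confusion matrix (true x predicted) plus per-class TPR/FPR and summary
    metrics.  Macro-F1 is the unweighted mean of per-class F1 over classes
    present in the truth."""

    confusion: pd.DataFrame
    tpr: pd.Series
    fpr: pd.Series
    f1: pd.Series
    accuracy: float
    macro_f1: float


def evaluate_classifier(truth, predicted) -> ClassifierEval:
    truth = pd.Series(list(truth)).astype(str)
    predicted = pd.Series(list(predicted)).astype(str)
    if len(truth) != len(predicted):
        raise FormatError("truth and prediction must have equal length")
    classes = sorted(set(truth))
    all_labels = sorted(set(truth) | set(predicted))
    conf = pd.crosstab(truth, predicted).reindex(
        index=classes, columns=all_labels, fill_value=0
    )
    total = conf.to_numpy().sum()
    tpr, fpr, f1 = {}, {}, {}
    for c in classes:
        tp = conf.loc[c, c] if c in conf.columns else 0
        fn = conf.loc[c].sum() - tp
        fp = (conf[c].sum() - tp) if c in conf.columns else 0
        tn = total - tp - fn - fp
        tpr[c] = tp / (tp + fn) if tp + fn else np.nan
        fpr[c] = fp / (fp + tn) if fp + tn else np.nan
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1[c] = 2 * prec * tpr[c] / (prec + tpr[c]) if prec + tpr[c] > 0 else 0.0
    extra = set(predicted) - set(classes)
    if extra:
        warnings.warn(
            f"classes absent from truth excluded from macro F1: {sorted(extra)}"
        )
    accuracy = sum(conf.loc[c, c] for c in classes if c in conf.columns) / total
    return ClassifierEval(
        confusion=conf,
        tpr=pd.Series(tpr),
        fpr=pd.Series(fpr),
        f1=pd.Series(f1),
        accuracy=float(accuracy),
        macro_f1=float(np.mean(list(f1.values()))),
    )


def split_train_test(
    table: CellTable,
    fraction: float = 0.8,
    seed: int = 0,
    stratify_by: str | None = None,
) -> tuple[CellTable, CellTable]:
    """Deterministic train/test split (default 80:20), optionally stratified.

    Within each stratum the train share is ``round(fraction * n)``; strata
    smaller than 2 items are kept entirely in train with a warning.
    """
    if not 0 < fraction < 1:
        raise FormatError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    df = table.df
    groups = (
        [(None, df)] if stratify_by is None else list(df.groupby(stratify_by, sort=True))
    )
    train_idx: list = []
    test_idx: list = []
    for name, g in groups:
        idx = g.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(f"stratum {name!r} has <2 items; kept in train")
            train_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return (
        CellTable(df.loc[sorted(train_idx)].copy()),
        CellTable(df.loc[sorted(test_idx)].copy()),
    )
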
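"""Batch-stability coefficients of variation and per-sample QC rules.

Control cell pellets acquired across staining/acquisition batches give two
stability readouts: the CV (sd/mean, sample sd) of each cell type's fraction
across batches, and per-marker CVs of mean expression computed within cell
types first — restricting each cell type to the markers it actually
expresses, so the variation of pure noise is not scored — and then averaged
over cell types into one final CV per marker.

Per-sample QC: more than 50% missing or folded tissue fails the sample, any
non-zero amount up to 50% warns; a single marker with missing signal warns,
more than one fails; an entirely necrotic sample fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FormatError, QCReason, QCReport


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation with sample standard deviation (ddof=1)."""
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=1) / mean)


def celltype_fraction_cv(counts: pd.DataFrame) -> pd.Series:
    """CV of cell-type fractions across batches.

    ``counts`` is a batches x cell-types table of non-negative cell counts;
    fractions are computed per batch before taking the CV per type.
    """
    if len(counts) < 2:
        raise FormatError("need at least 2 batches")
    if (counts.to_numpy() < 0).any():
        raise FormatError("counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise FormatError(f"batches with zero total count: {bad}")
    fractions = counts.div(totals, axis=0)
    return fractions.apply(lambda col: _cv(col.to_numpy()), axis=0).rename("cv")


@dataclass
class BatchCVReport:
    """Marker-stability CVs: per (marker, cell type) and final per-marker."""

    per_pair: pd.DataFrame  # columns: marker, cell_type, cv
    per_marker: pd.Series  # final CV per marker (mean over relevant cell types)
    n_batches: int


def marker_cv(
    means: pd.DataFrame, relevance: dict[str, list[str]]
) -> BatchCVReport:
    """Across-batch CV of per-cell-type marker means, averaged over cell types.

    ``means`` is long-form with columns ``batch``, ``cell_type``, ``marker``,
    ``mean``; ``relevance`` maps each cell type to the markers expressed in
    it.  Only relevant (cell type, marker) pairs are scored; the final CV of
    a marker is the unweighted mean of its per-cell-type CVs.
    """
    need = {"batch", "cell_type", "marker", "mean"}
    if not need.issubset(means.columns):
        raise FormatError(f"means table needs columns {sorted(need)}")
    n_batches = means["batch"].nunique()
    if n_batches < 2:
        raise FormatError("need at least 2 batches")

    rows = []
    for cell_type, markers in relevance.items():
        sub = means[means["cell_type"] == cell_type]
        for marker in markers:
            vals = sub.loc[sub["marker"] == marker, "mean"].to_numpy(dtype=float)
            if len(vals) >= 2:
                rows.append({"marker": marker, "cell_type": cell_type, "cv": _cv(vals)})
    per_pair = pd.DataFrame(rows, columns=["marker", "cell_type", "cv"])

    all_markers = set(means["marker"])
    covered = set(per_pair["marker"])
    for m in sorted(all_markers - covered):
        warnings.warn(f"marker {m!r} relevant to no cell type; omitted from report")
    per_marker = per_pair.groupby("marker")["cv"].mean().rename("cv")
    return BatchCVReport(per_pair=per_pair, per_marker=per_marker, n_batches=n_batches)


def sample_qc(
    missing_or_folded_fraction: float,
    marker_signal_ok: dict[str, bool] | None = None,
    fully_necrotic: bool = False,
) -> QCReport:
    """Apply the per-sample QC rules and return a PASS/WARN/FAIL report.

    - missing/folded tissue fraction > 0.5 → FAIL; in (0, 0.5] → WARN;
    - exactly one marker with missing signal → WARN, more than one → FAIL;
    - a fully necrotic sample → FAIL.
    """
    f = float(missing_or_folded_fraction)
    if not 0 <= f <= 1:
        raise FormatError("missing/folded fraction must be in [0, 1]")
    marker_signal_ok = marker_signal_ok or {}
    reasons: list[QCReason] = []

    if f > 0.5:
        reasons.append(QCReason("tissue_missing", f"{f:.0%} of tissue missing or folded", f, "FAIL"))
    elif f > 0:
        reasons.append(QCReason("tissue_missing", f"{f:.0%} of tissue missing or folded", f, "WARN"))

    failed = sorted(m for m, ok in marker_signal_ok.items() if not ok)
    if len(failed) == 1:
        reasons.append(QCReason("marker_signal", f"missing signal for marker {failed[0]}", 1, "WARN"))
    elif len(failed) > 1:
        reasons.append(QCReason("marker_signal", f"missing signal for markers {failed}", len(failed), "FAIL"))

    if fully_necrotic:
        reasons.append(QCReason("necrosis", "entire sample appears necrotic", None, "FAIL"))

    if any(r.level == "FAIL" for r in reasons):
        status = "FAIL"
    elif reasons:
        status = "WARN"
    else:
        status = "PASS"
    marker_flags = {m: ("FAIL" if m in failed else "PASS") for m in marker_signal_ok}
    return QCReport(status=status, reasons=reasons, marker_flags=marker_flags)
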
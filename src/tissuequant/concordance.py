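"""Cross-modality spatial concordance: landmark alignment and L-function
co-localization scoring.

Two images of consecutive sections (e.g. fluorescence and mass cytometry)
are aligned with a least-squares similarity transform estimated from
corresponding landmark points.  For each matched cell type, the bivariate
(cross) Ripley K function between the two modalities is estimated with
translation edge correction and expressed on the L scale, where complete
spatial randomness gives L(r) = r.  Concordance is summarized by (i) the
signed area between the estimated and theoretical L functions and (ii) a
Monte-Carlo maximum-absolute-deviation (MAD) envelope test against 99
simulated realizations of complete spatial randomness; a cell type is
called co-localized iff the area is positive and the MAD p-value is at most
0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FormatError, PointPattern, SpatialCurve


# ---------------------------------------------------------------------------
# similarity transform (closed-form least squares, Umeyama)


@dataclass
class SimilarityTransform:
    """Scaled rotation (optionally with reflection) plus translation."""

    scale: float
    rotation: float  # radians, counter-clockwise
    translation: tuple[float, float]
    reflection: bool = False
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise FormatError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        if self.reflection:
            R = R @ np.diag([1.0, -1.0])
        return self.scale * R

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        Minv = np.linalg.inv(self.matrix)
        t = -Minv @ np.asarray(self.translation)
        det = np.linalg.det(Minv)
        scale = np.sqrt(abs(det))
        refl = det < 0
        Mr = Minv / scale
        if refl:
            Mr = Mr @ np.diag([1.0, -1.0])
        theta = np.arctan2(Mr[1, 0], Mr[0, 0])
        return SimilarityTransform(scale, theta, (t[0], t[1]), refl)


def estimate_similarity_transform(
    src_points: np.ndarray, dst_points: np.ndarray, allow_reflection: bool = False
) -> SimilarityTransform:
    """Closed-form least-squares similarity fit from landmark pairs.

    Uses the SVD of the centred cross-covariance; at least 2 pairs required
    (4 or more recommended for imaging landmarks).  Reports the residual
    RMSE of the fit.
    """
    src = np.asarray(src_points, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst_points, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) < 2:
        raise FormatError("need >= 2 corresponding landmark pairs")
    if len(np.unique(src, axis=0)) < 2:
        raise FormatError("degenerate landmarks: source points coincide")

    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0 and not allow_reflection:
        S[1, 1] = -1.0  # force a proper rotation
    R = U @ S @ Vt
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise FormatError("degenerate landmarks: zero source variance")
    scale = float((D * np.diag(S)).sum() / var_s)
    if scale <= 0:
        raise FormatError("degenerate landmark configuration (non-positive scale)")
    t = mu_d - scale * R @ mu_s

    refl = bool(np.linalg.det(R) < 0)
    Rr = R @ np.diag([1.0, -1.0]) if refl else R
    theta = float(np.arctan2(Rr[1, 0], Rr[0, 0]))
    tf = SimilarityTransform(float(scale), theta, (float(t[0]), float(t[1])), refl)
    resid = tf.apply(src) - dst
    tf.rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tf


# ---------------------------------------------------------------------------
# cross K / L


def default_radii(window: tuple[float, float, float, float], n: int = 512) -> np.ndarray:
    """Radii grid from 0 to a quarter of the shorter window side."""
    x0, y0, x1, y1 = window
    rmax = 0.25 * min(x1 - x0, y1 - y0)
    return np.linspace(0.0, rmax, n + 1)


def kcross(
    pattern: PointPattern,
    type_i,
    type_j,
    radii: np.ndarray | None = None,
    correction: str = "translation",
) -> SpatialCurve:
    """Estimate the cross K function between two marked types, on the L scale.

    K̂_ij(r) = |W|/(n_i n_j) Σ_u Σ_v 1(d(u,v) ≤ r) e(u, v), with the
    translation edge correction e(u,v) = |W| / |W ∩ W_{v−u}| for the
    rectangular window; L̂ = sqrt(K̂/π).
    """
    if correction not in ("translation", "none"):
        raise FormatError(f"unknown edge correction {correction!r}")
    pts_i = pattern.subset(type_i)
    pts_j = pattern.subset(type_j)
    if len(pts_i) == 0:
        raise FormatError(f"no points of type {type_i!r}")
    if len(pts_j) == 0:
        raise FormatError(f"no points of type {type_j!r}")
    if radii is None:
        radii = default_radii(pattern.window)
    radii = np.asarray(radii, dtype=float)
    x0, y0, x1, y1 = pattern.window
    wx, wy = x1 - x0, y1 - y0
    rmax_ok = 0.25 * min(wx, wy)
    if radii.max() > rmax_ok + 1e-9:
        raise FormatError(f"radii must not exceed a quarter window side ({rmax_ok:g} μm)")

    area = pattern.window_area
    dx = pts_i[:, None, 0] - pts_j[None, :, 0]
    dy = pts_i[:, None, 1] - pts_j[None, :, 1]
    d = np.hypot(dx, dy)
    same = type_i == type_j
    if correction == "translation":
        # pairs separated by more than the window side get infinite weight,
        # but such pairs are always beyond rmax and never counted
        with np.errstate(divide="ignore"):
            w = area / ((wx - np.abs(dx)) * (wy - np.abs(dy)))
    else:
        w = np.ones_like(d)
    if same:
        np.fill_diagonal(d, np.inf)  # exclude u = v

    order = np.argsort(d, axis=None)
    d_sorted = d.ravel()[order]
    w_sorted = np.concatenate([[0.0], np.cumsum(w.ravel()[order])])
    idx = np.searchsorted(d_sorted, radii, side="right")
    k = area / (len(pts_i) * len(pts_j)) * w_sorted[idx]
    l_vals = np.sqrt(k / np.pi)
    return SpatialCurve(radii=radii, l_values=l_vals, n_i=len(pts_i), n_j=len(pts_j),
                        correction=correction)


def l_area_score(curve: SpatialCurve) -> float:
    """Signed area between the estimated and theoretical L functions,
    ∫ (L̂(r) − r) dr by the trapezoid rule.  Positive values indicate the two
    types share spatial locations more than expected under randomness."""
    return float(np.trapezoid(curve.l_values - curve.radii, curve.radii))


def mad_test(
    pattern: PointPattern,
    type_i,
    type_j,
    nsim: int = 99,
    radii: np.ndarray | None = None,
    seed: int = 0,
    correction: str = "translation",
) -> tuple[float, float]:
    """Monte-Carlo maximum-absolute-deviation envelope test.

    The statistic is max_r |L̂(r) − r|.  The null is complete spatial
    randomness, simulated conditionally on the observed counts (binomial
    process in the same window), ``nsim`` times (default 99).  The rank
    p-value is (1 + #{T_sim ≥ T_obs}) / (nsim + 1), so the smallest
    attainable p is 1/(nsim+1) = 0.01 at the default.
    """
    if nsim < 1:
        raise FormatError("nsim must be >= 1")
    if radii is None:
        radii = default_radii(pattern.window)
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise FormatError("radii grid is empty")
    obs = kcross(pattern, type_i, type_j, radii, correction)
    t_obs = float(np.max(np.abs(obs.l_values - radii)))

    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = pattern.window
    n_i, n_j = obs.n_i, obs.n_j
    exceed = 0
    for _ in range(nsim):
        pts = rng.uniform((x0, y0), (x1, y1), size=(n_i + n_j, 2))
        marks = np.array([type_i] * n_i + [type_j] * n_j, dtype=object)
        sim = PointPattern(points=pts, window=pattern.window, marks=marks)
        cur = kcross(sim, type_i, type_j, radii, correction)
        t_k = float(np.max(np.abs(cur.l_values - radii)))
        if t_k >= t_obs:
            exceed += 1
    p = (1 + exceed) / (nsim + 1)
    return t_obs, p


def colocalization_call(area: float, p_value: float, alpha: float = 0.01) -> str:
    """Co-localization decision: positive L-area AND MAD p-value ≤ alpha."""
    if not (np.isfinite(area) and np.isfinite(p_value)):
        raise FormatError("area and p-value must be finite")
    return "colocalized" if (area > 0 and p_value <= alpha) else "not_colocalized"


# ---------------------------------------------------------------------------
# modality pairing


def pair_modalities(
    imc_cells: pd.DataFrame,
    mif_cells: pd.DataFrame,
    transform: SimilarityTransform,
    cell_type: str,
) -> PointPattern:
    """Build the bivariate modality-marked pattern for one matched cell type.

    ``transform`` maps the fluorescence coordinates into the mass-cytometry
    ROI frame.  The pattern window is the intersection of the IMC bounding
    window and the transformed mIF bounding window; points of the requested
    type from both modalities are kept if they fall inside it.
    """
    imc = imc_cells[imc_cells["phenotype"] == cell_type]
    mif = mif_cells[mif_cells["phenotype"] == cell_type]
    imc_xy = imc[["x_um", "y_um"]].to_numpy(dtype=float)
    mif_xy = transform.apply(mif_cells[["x_um", "y_um"]].to_numpy(dtype=float))
    mif_xy_type = transform.apply(mif[["x_um", "y_um"]].to_numpy(dtype=float))

    all_imc = imc_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    win_imc = _bounds(all_imc)
    win_mif = _bounds(mif_xy)
    x0, y0 = max(win_imc[0], win_mif[0]), max(win_imc[1], win_mif[1])
    x1, y1 = min(win_imc[2], win_mif[2]), min(win_imc[3], win_mif[3])
    if not (x1 > x0 and y1 > y0):
        raise FormatError("transformed images have no overlapping window")

    tol = 1e-9  # guard the window edge against round-off in the transform

    def inside(xy):
        return (
            (xy[:, 0] >= x0 - tol)
            & (xy[:, 0] <= x1 + tol)
            & (xy[:, 1] >= y0 - tol)
            & (xy[:, 1] <= y1 + tol)
        )

    def clip(xy):
        return np.column_stack(
            [np.clip(xy[:, 0], x0, x1), np.clip(xy[:, 1], y0, y1)]
        )

    pts = np.vstack(
        [clip(imc_xy[inside(imc_xy)]), clip(mif_xy_type[inside(mif_xy_type)])]
    )
    marks = np.array(
        ["IMC"] * int(inside(imc_xy).sum()) + ["mIF"] * int(inside(mif_xy_type).sum()),
        dtype=object,
    )
    return PointPattern(points=pts, window=(x0, y0, x1, y1), marks=marks)


def _bounds(xy: np.ndarray) -> tuple[float, float, float, float]:
    if len(xy) == 0:
        raise FormatError("empty point set has no window")
    return (
        float(xy[:, 0].min()),
        float(xy[:, 1].min()),
        float(xy[:, 0].max()),
        float(xy[:, 1].max()),
    )
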
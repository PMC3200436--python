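"""Second-level mass-univariate GLM over condition image volumes.

The design follows the two-regressor-per-valence ANCOVA: a win and a
loss indicator plus one parametric probability modulator per valence,
coded [4, 3, 2, 1] over outcome probabilities [.25, .50, .75, 1] and
mean-centered within each valence's rows.  Subject block effects are
included by default (sum-to-zero coding) to absorb between-subject
offsets.  Standard F contrasts:

* valence        [1, -1, 0, 0]   win vs loss regressor
* probability    [0, 0, 1, 1]    sum of the two probability slopes
* interaction    [0, 0, 1, -1]   win slope vs loss slope -- the
                                 prediction-error signature

Cluster-extent thresholding operates on the suprathreshold set of the
per-voxel F map (peak alpha over the F(df) distribution, 26-connected
components in x-y-time, minimum extent in voxels).  The fully-predicted
(P = 1) equivalence mask removes voxels where certain wins and losses
differ at a lenient alpha, implementing the inclusive-masking step of
the axiomatic test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .scalp_map import ScalpImage

__all__ = [
    "PROBABILITY_CODES",
    "DesignMatrix",
    "build_design",
    "contrast_vector",
    "collect_images",
    "StatMap",
    "fit_and_contrast",
    "ClusterTable",
    "threshold_and_cluster",
    "equivalence_mask",
    "apply_mask",
]

#: parametric modulator code per outcome probability (before centering)
PROBABILITY_CODES = {0.25: 4.0, 0.50: 3.0, 0.75: 2.0, 1.0: 1.0}
PROBABILITIES = (0.25, 0.50, 0.75, 1.0)


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]
    rows: pd.DataFrame  # one row per (subject, valence, probability) image
    modulator_codes: dict[float, float]
    n_task_cols: int = 4


def build_design(
    n_subjects: int,
    probabilities: tuple[float, ...] = PROBABILITIES,
    include_subject_effects: bool = True,
) -> DesignMatrix:
    """ANCOVA design over the 2 x len(probabilities) condition grid.

    Rows are subject-major, win conditions first (probability ascending),
    then loss.  Modulators are centered within their own condition rows,
    so each modulator column sums to zero over its support.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    conds = [("win", p) for p in probabilities] + [("loss", p) for p in probabilities]
    rows = pd.DataFrame(
        [
            {"subject": s, "valence": v, "probability": p}
            for s in range(n_subjects)
            for v, p in conds
        ]
    )
    n = len(rows)
    win = (rows["valence"] == "win").to_numpy(float)
    loss = 1.0 - win
    codes = rows["probability"].map(PROBABILITY_CODES).to_numpy(float)
    mean_code = np.mean([PROBABILITY_CODES[p] for p in probabilities])
    win_mod = win * (codes - mean_code)
    loss_mod = loss * (codes - mean_code)
    cols = [win, loss, win_mod, loss_mod]
    names = ["win", "loss", "win_pmod", "loss_pmod"]
    if include_subject_effects and n_subjects > 1:
        # sum-to-zero subject coding keeps the design full rank alongside
        # the win + loss = constant identity
        for s in range(n_subjects - 1):
            col = (rows["subject"] == s).to_numpy(float) - (
                rows["subject"] == n_subjects - 1
            ).to_numpy(float)
            cols.append(col)
            names.append(f"subject_{s}")
    X = np.column_stack(cols)
    return DesignMatrix(X, names, rows, dict(PROBABILITY_CODES))


def contrast_vector(design: DesignMatrix, name: str) -> np.ndarray:
    """Named F contrast, zero-padded over subject columns."""
    base = {
        "valence": [1.0, -1.0, 0.0, 0.0],
        "probability": [0.0, 0.0, 1.0, 1.0],
        "interaction": [0.0, 0.0, 1.0, -1.0],
    }
    if name not in base:
        raise KeyError(f"unknown contrast {name!r}")
    c = np.zeros(design.X.shape[1])
    c[:4] = base[name]
    return c


def collect_images(
    design: DesignMatrix, volumes: dict[tuple[int, str, float], ScalpImage]
) -> list[ScalpImage]:
    """Order per-(subject, valence, probability) volumes to match the design."""
    out = []
    for _, r in design.rows.iterrows():
        key = (int(r["subject"]), str(r["valence"]), float(r["probability"]))
        if key not in volumes:
            raise KeyError(
                f"missing condition image for subject {key[0]}, "
                f"{key[1]} P={key[2]:g}"
            )
        out.append(volumes[key])
    return out


@dataclass
class StatMap:
    """Voxelwise F map with df, contrast, and (optionally) the fitted betas."""

    F: np.ndarray  # (nx, ny, T), NaN outside the valid voxel set
    df: tuple[int, int]
    contrast: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    time_ms: np.ndarray
    validity_mask: np.ndarray
    beta: np.ndarray | None = None  # (p, nx, ny, T)
    columns: list[str] = field(default_factory=list)


def _stack(images: list[ScalpImage]) -> tuple[np.ndarray, ScalpImage]:
    ref = images[0]
    for im in images[1:]:
        if im.values.shape != ref.values.shape or not np.array_equal(
            im.validity_mask, ref.validity_mask
        ):
            raise ValueError("images differ in grid or validity mask")
    flat = np.stack([im.values.reshape(-1) for im in images])
    return flat, ref


def fit_and_contrast(
    images: list[ScalpImage],
    design: DesignMatrix,
    contrast: np.ndarray | str,
    keep_betas: bool = True,
    row_weights: np.ndarray | None = None,
) -> StatMap:
    """Per-voxel OLS fit and extra-sum-of-squares F statistic.

    The F statistic uses the standard contrast form
    F = (C b)' [C (X'X)^-1 C']^-1 (C b) / (q * sigma2_hat) with classical
    residual degrees of freedom n - rank(X).

    ``row_weights`` (optional) are known relative precisions of the rows,
    e.g. the per-condition trial counts behind each average image: rows
    are rescaled by sqrt(weight), which is ordinary least squares on the
    variance-standardized problem.  Without it, unequal per-cell trial
    counts (45 vs 135 in the default design) leave the voxel F test
    miscalibrated under the null.
    """
    if isinstance(contrast, str):
        contrast = contrast_vector(design, contrast)
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    X = design.X
    n, p = X.shape
    if len(images) != n:
        raise ValueError(f"{len(images)} images but design has {n} rows")
    if C.shape[1] != p:
        raise ValueError("contrast length does not match design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        dep = [design.columns[i] for i in np.flatnonzero(r < 1e-10 * r.max())]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")

    Y, ref = _stack(images)  # (n, n_vox_total) with NaN outside mask
    valid = np.all(np.isfinite(Y), axis=0)
    Yv = Y[:, valid]

    if row_weights is not None:
        w = np.asarray(row_weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("row_weights must be positive, one per design row")
        sw = np.sqrt(w / w.mean())
        X = X * sw[:, None]
        Yv = Yv * sw[:, None]

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Yv  # (p, V)
    resid = Yv - X @ beta
    dfe = n - rank
    sigma2 = (resid**2).sum(axis=0) / dfe
    cb = C @ beta  # (q, V)
    q = C.shape[0]
    m_inv = np.linalg.inv(C @ xtx_inv @ C.T)
    num = np.einsum("qv,qr,rv->v", cb, m_inv, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        Fv = num / (q * sigma2)
    # zero residual variance: F is 0 for a null contrast, infinite otherwise
    Fv = np.where(sigma2 > 0, Fv, np.where(num > 0, np.inf, 0.0))

    shape = ref.values.shape
    F = np.full(shape, np.nan).reshape(-1)
    F[valid] = Fv
    F = F.reshape(shape)
    beta_vol = None
    if keep_betas:
        beta_vol = np.full((p,) + shape, np.nan).reshape(p, -1)
        beta_vol[:, valid] = beta
        beta_vol = beta_vol.reshape((p,) + shape)
    return StatMap(
        F=F,
        df=(q, dfe),
        contrast=C,
        x_mm=ref.x_mm,
        y_mm=ref.y_mm,
        time_ms=ref.time_ms,
        validity_mask=ref.validity_mask,
        beta=beta_vol,
        columns=list(design.columns),
    )


@dataclass
class ClusterTable:
    """Thresholded connected clusters of a StatMap."""

    table: pd.DataFrame  # cluster_id, extent, peak_F, peak_Z, x_mm, y_mm, t_ms
    alpha_peak: float
    f_crit: float
    extent_min: int
    df: tuple[int, int]
    labels: np.ndarray | None = None  # labeled volume for provenance/debugging


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def _z_equivalent(f: float, df: tuple[int, int]) -> float:
    """Standard-normal quantile matching the F statistic's upper tail."""
    return float(stats.norm.isf(stats.f.sf(f, *df)))


def threshold_and_cluster(
    statmap: StatMap,
    alpha_peak: float = 0.005,
    extent_min: int = 100,
    connectivity: int = 26,
) -> ClusterTable:
    """Peak-level threshold at the F(df) alpha-quantile, then extent filter."""
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    f_crit = float(stats.f.isf(alpha_peak, *statmap.df))
    supra = np.nan_to_num(statmap.F, nan=-np.inf) > f_crit
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    keep_labels = np.zeros_like(labels)
    cid = 0
    for lab in range(1, n_lab + 1):
        vox = np.nonzero(labels == lab)
        extent = vox[0].size
        if extent < extent_min:
            continue
        cid += 1
        fvals = statmap.F[vox]
        imax = int(np.argmax(fvals))
        i, j, k = (vox[0][imax], vox[1][imax], vox[2][imax])
        peak_f = float(fvals[imax])
        rows.append(
            {
                "cluster_id": cid,
                "extent": int(extent),
                "peak_F": peak_f,
                "peak_Z": _z_equivalent(peak_f, statmap.df),
                "x_mm": float(statmap.x_mm[i]),
                "y_mm": float(statmap.y_mm[j]),
                "t_ms": float(statmap.time_ms[k]),
                "peak_ix": int(i),
                "peak_iy": int(j),
                "peak_it": int(k),
            }
        )
        keep_labels[labels == lab] = cid
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "extent",
            "peak_F",
            "peak_Z",
            "x_mm",
            "y_mm",
            "t_ms",
            "peak_ix",
            "peak_iy",
            "peak_it",
        ],
    )
    return ClusterTable(table, alpha_peak, f_crit, extent_min, statmap.df, keep_labels)


def equivalence_mask(
    images_win_p1: list[ScalpImage],
    images_loss_p1: list[ScalpImage],
    alpha: float = 0.05,
) -> np.ndarray:
    """Inverted sensitivity map for fully-predicted outcomes.

    A voxelwise matched-subject F test (paired t squared) compares the
    P = 1 win and loss images at the lenient ``alpha``; the returned
    boolean volume is True where the two do *not* differ, i.e. the
    inclusive mask for the interaction analysis.
    """
    if len(images_win_p1) != len(images_loss_p1):
        raise ValueError(
            f"subject mismatch: {len(images_win_p1)} win vs "
            f"{len(images_loss_p1)} loss images"
        )
    n = len(images_win_p1)
    if n < 2:
        raise ValueError("need at least two subjects")
    W, ref = _stack(images_win_p1)
    L, _ = _stack(images_loss_p1)
    d = W - L
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (mean / (sd / np.sqrt(n))) ** 2
    f_crit = stats.f.isf(alpha, 1, n - 1)
    mask = ~(F > f_crit)  # NaN (outside hull) -> True, i.e. unconstrained
    return mask.reshape(ref.values.shape)


def apply_mask(statmap: StatMap, mask: np.ndarray) -> StatMap:
    """Exclude voxels outside the inclusive mask (sets their F to NaN)."""
    if mask.shape != statmap.F.shape:
        raise ValueError("mask shape does not match the statistic volume")
    F = np.where(mask, statmap.F, np.nan)
    return replace(statmap, F=F)
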
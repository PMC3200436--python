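"""Preprocessing of epoched sensor data.

Implements the standard event-related pipeline: zero-phase Butterworth
band-pass, anti-aliased downsampling, pre-stimulus baseline correction,
absolute-amplitude trial rejection, signal-space projection (SSP) of the
ocular subspace, mastoid re-referencing, and per-condition trial
averaging (arithmetic or robust with Huber down-weighting of outlying
samples).

The intended order, enforced by the pipeline driver, is
filter -> downsample -> baseline -> reject -> SSP -> average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedData

__all__ = [
    "bandpass",
    "lowpass",
    "resample",
    "baseline_correct",
    "reject_amplitude",
    "ProjectionOperator",
    "fit_blink_projector",
    "apply_projection",
    "rereference",
    "RobustAverageResult",
    "robust_average",
    "condition_average",
]

BUTTER_ORDER = 4  # applied forward-backward (zero phase)


def bandpass(epochs: EpochedData, low: float, high: float) -> EpochedData:
    """Zero-phase Butterworth band-pass per channel."""
    if not (0 <= low < high < epochs.fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 <= low < high < fs/2; got "
            f"({low}, {high}) at fs={epochs.fs}"
        )
    if low > 0:
        sos = signal.butter(
            BUTTER_ORDER, [low, high], btype="bandpass", fs=epochs.fs, output="sos"
        )
    else:
        sos = signal.butter(
            BUTTER_ORDER, high, btype="lowpass", fs=epochs.fs, output="sos"
        )
    # chunked over trials to bound the float64 working set on long sessions
    x = epochs.data
    out = np.empty_like(x)
    step = max(1, int(np.ceil(4e7 / max(x[0].size, 1))))
    for lo_i in range(0, x.shape[0], step):
        out[lo_i : lo_i + step] = signal.sosfiltfilt(
            sos, x[lo_i : lo_i + step], axis=-1
        )
    rec = {"operation": "bandpass", "params": {"low": low, "high": high}}
    return epochs.evolve(rec, data=out)


def lowpass(data: np.ndarray, fs: float, high: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis (plain arrays)."""
    sos = signal.butter(BUTTER_ORDER, high, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def resample(epochs: EpochedData, fs_new: float) -> EpochedData:
    """Anti-aliased downsampling; trial metadata is unchanged."""
    if fs_new >= epochs.fs:
        raise ValueError(f"fs_new={fs_new} must be below fs={epochs.fs}")
    frac = Fraction(fs_new / epochs.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(epochs.data, up, down, axis=-1)
    n_new = int(np.floor(epochs.n_samples * fs_new / epochs.fs))
    out = out[..., :n_new]
    time_new = epochs.time_ms[0] + np.arange(n_new) * 1000.0 / fs_new
    rec = {"operation": "resample", "params": {"fs_new": fs_new}}
    return epochs.evolve(rec, data=out, fs=fs_new, time_ms=time_new)


def baseline_correct(epochs: EpochedData) -> EpochedData:
    """Subtract the pre-stimulus (t < 0) mean per trial and channel."""
    pre = epochs.time_ms < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples available for baseline")
    base = epochs.data[..., pre].mean(axis=-1, keepdims=True)
    rec = {"operation": "baseline_correct", "params": {"n_baseline": int(pre.sum())}}
    return epochs.evolve(rec, data=epochs.data - base)


def reject_amplitude(
    epochs: EpochedData, threshold: float
) -> tuple[EpochedData, np.ndarray]:
    """Drop trials where any sample on any channel exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rejected = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    if rejected.all():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed {threshold:g}; "
            "review the rejection threshold"
        )
    rec = {
        "operation": "reject_amplitude",
        "params": {"threshold": threshold, "n_rejected": int(rejected.sum())},
    }
    kept = epochs.select_trials(~rejected)
    kept.provenance.append(rec)
    return kept, rejected


@dataclass(frozen=True)
class ProjectionOperator:
    """Orthogonal projector I - B B^T removing a k-dimensional subspace."""

    basis: np.ndarray  # channels x k, orthonormal columns
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        if b.ndim != 2 or b.shape[0] != len(self.channel_ids):
            raise ValueError("basis must be channels x k")
        if b.shape[1] > 0:
            gram = b.T @ b
            if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-8):
                raise ValueError("basis columns must be orthonormal")
        object.__setattr__(self, "basis", b)

    @property
    def k(self) -> int:
        return self.basis.shape[1]


def _detect_blinks(
    trace: np.ndarray, threshold_z: float, min_sep: int
) -> list[tuple[int, int]]:
    """(trial, sample) indices of threshold crossings, separated by min_sep."""
    # robust z: median/MAD scaling so the blinks themselves cannot inflate
    # the detection scale
    med = np.median(trace)
    mad = 1.4826 * np.median(np.abs(trace - med))
    scale = mad if mad > 0 else (trace.std() or 1.0)
    z = (trace - med) / scale
    events: list[tuple[int, int]] = []
    for tr in range(trace.shape[0]):
        above = np.abs(z[tr]) > threshold_z
        idx = np.flatnonzero(above)
        last = -min_sep - 1
        for i in idx:
            if i - last > min_sep:
                # center on the local extremum of this crossing
                j_end = i
                while j_end + 1 < trace.shape[1] and above[j_end + 1]:
                    j_end += 1
                seg = np.abs(z[tr, i : j_end + 1])
                events.append((tr, i + int(np.argmax(seg))))
                last = j_end
    return events


def fit_blink_projector(
    epochs: EpochedData,
    blink_channel: str,
    detection_threshold: float = 4.0,
    k: int = 4,
    min_separation_ms: float = 200.0,
    window_ms: float = 150.0,
) -> ProjectionOperator:
    """SSP operator from the blink-locked average.

    Blinks are detected as |z| > ``detection_threshold`` excursions on the
    designated ocular channel; data are epoched around each blink, averaged,
    and the top-``k`` spatial principal components of that average form the
    projector basis.
    """
    ch = epochs.layout.index(blink_channel)
    if k == 0:
        return ProjectionOperator(
            np.zeros((epochs.layout.n_channels, 0)), epochs.layout.channel_ids
        )
    min_sep = max(1, int(round(min_separation_ms * epochs.fs / 1000.0)))
    half = max(1, int(round(window_ms * epochs.fs / 1000.0)))
    events = _detect_blinks(epochs.data[:, ch, :], detection_threshold, min_sep)
    segs = []
    n_t = epochs.n_samples
    width = 2 * half + 1
    if width > n_t:
        raise ValueError("blink window exceeds the epoch length")
    for tr, i in events:
        # shift the window to fit inside the epoch; the spatial principal
        # components are insensitive to the exact temporal alignment
        lo = min(max(i - half, 0), n_t - width)
        segs.append(epochs.data[tr, :, lo : lo + width])
    if len(segs) < max(k, 1):
        raise ValueError(
            f"only {len(segs)} blink events detected on {blink_channel!r}; "
            f"need at least {max(k, 1)}"
        )
    avg = np.mean(np.asarray(segs, dtype=float), axis=0)  # channels x window
    u, s, _ = np.linalg.svd(avg, full_matrices=False)
    return ProjectionOperator(u[:, :k], epochs.layout.channel_ids)


def apply_projection(epochs: EpochedData, op: ProjectionOperator) -> EpochedData:
    """Multiply every time sample by I - B B^T."""
    if op.channel_ids != epochs.layout.channel_ids:
        raise ValueError("projection operator channels do not match the data")
    b = op.basis.astype(epochs.data.dtype, copy=False)
    if op.k == 0:
        out = epochs.data.copy()
    else:
        # (I - BB^T) x, applied over the channel axis
        coef = np.einsum("ck,tcs->tks", b, epochs.data)
        out = epochs.data - np.einsum("ck,tks->tcs", b, coef)
    rec = {"operation": "apply_projection", "params": {"k": op.k}}
    return epochs.evolve(rec, data=out)


def rereference(epochs: EpochedData, ref_channels: list[str]) -> EpochedData:
    """Subtract the mean of the reference channels at every sample."""
    idx = [epochs.layout.index(c) for c in ref_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    rec = {"operation": "rereference", "params": {"ref_channels": list(ref_channels)}}
    return epochs.evolve(rec, data=epochs.data - ref)


@dataclass
class RobustAverageResult:
    average: np.ndarray  # channels x samples
    weights: np.ndarray  # trials x channels x samples, in [0, 1]
    n_iterations: int
    converged: bool


CUTOFF_DEFAULT = 4.5
MAD_TO_SD = 1.4826


def robust_average(
    trials: np.ndarray,
    cutoff: float = CUTOFF_DEFAULT,
    max_iter: int = 20,
    tol: float = 1e-6,
    weight_function: str = "soft_trim",
    fs: float | None = None,
    post_lowpass_hz: float | None = None,
    scale_pooling: str = "time",
) -> RobustAverageResult:
    """Iteratively reweighted trial average with outlier down-weighting.

    Per channel and time point the distribution of values over trials is
    examined: residuals from the current estimate are scaled by
    1.4826 * MAD and samples beyond ``cutoff`` are down-weighted.
    Artifacts confined to narrow time ranges are thereby neutralized
    without dropping whole trials.  If ``post_lowpass_hz`` and ``fs``
    are given the average is low-pass filtered afterwards to remove the
    high frequencies the reweighting can introduce.

    ``scale_pooling="time"`` (default) estimates the MAD scale per
    channel over trials x time together: the sample MAD over a few dozen
    trials alone is noisy enough that an unlucky low draw would trim
    perfectly clean values.  ``"none"`` keeps a separate scale per
    channel and time point.

    Weight functions (u = |scaled residual| / cutoff):

    * ``"soft_trim"`` (default): min(1, 1/u^2) — weights fall off
      quadratically beyond the cutoff, so gross bursts are effectively
      excluded while clean Gaussian data reproduce the arithmetic mean
      to well under a tenth of its standard error;
    * ``"huber"``: min(1, 1/u) — the classical Huber weights, gentler
      on moderate outliers;
    * ``"none"``: exactly the arithmetic mean.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need a trials x channels x samples array with >= 2 trials")
    if weight_function not in ("soft_trim", "huber", "none"):
        raise ValueError(f"unknown weight_function {weight_function!r}")
    if scale_pooling not in ("time", "none"):
        raise ValueError(f"unknown scale_pooling {scale_pooling!r}")
    s_axes = (0, 2) if scale_pooling == "time" else (0,)

    if weight_function == "none":
        avg = x.mean(axis=0)
        w = np.ones_like(x)
        n_it, converged = 0, True
    else:
        mu = np.median(x, axis=0)
        w = np.ones_like(x)
        converged = False
        n_it = 0
        for n_it in range(1, max_iter + 1):
            r = x - mu[None]
            s = MAD_TO_SD * np.median(np.abs(r), axis=s_axes, keepdims=True)
            # fallback scale where MAD vanishes but residuals do not
            fallback = 1.2533 * np.mean(np.abs(r), axis=s_axes, keepdims=True)
            s = np.where(s > 0, s, fallback)
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.abs(r) / (cutoff * s)
                if weight_function == "soft_trim":
                    w = np.where(u > 1.0, 1.0 / u**2, 1.0)
                else:
                    w = np.where(u > 1.0, 1.0 / u, 1.0)
            w = np.where(np.isfinite(w), w, 1.0)  # zero residuals keep weight 1
            mu_new = (w * x).sum(axis=0) / w.sum(axis=0)
            scale = np.max(np.abs(mu)) or 1.0
            delta = np.max(np.abs(mu_new - mu)) / scale
            mu = mu_new
            if delta <= tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"robust_average did not converge in {max_iter} iterations",
                RuntimeWarning,
            )
        avg = mu

    if post_lowpass_hz is not None:
        if fs is None:
            raise ValueError("fs is required for the post-average low-pass")
        avg = lowpass(avg, fs, post_lowpass_hz)
    return RobustAverageResult(avg, w, n_it, converged)


def condition_average(
    epochs: EpochedData, method: str = "mean", **robust_kw
) -> dict[tuple[str, float], np.ndarray]:
    """Per-(valence, outcome probability) trial averages.

    MEG condition averages conventionally use plain arithmetic means; the
    robust averager is available for either modality.
    """
    out: dict[tuple[str, float], np.ndarray] = {}
    meta = epochs.trials
    for (val, p), idx in meta.groupby(
        ["outcome_valence", "outcome_prob"], sort=True
    ).indices.items():
        block = epochs.data[idx]
        if method == "mean":
            out[(val, float(p))] = block.mean(axis=0)
        elif method == "robust":
            out[(val, float(p))] = robust_average(
                block, fs=epochs.fs, **robust_kw
            ).average
        else:
            raise ValueError(f"unknown averaging method {method!r}")
    return out
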
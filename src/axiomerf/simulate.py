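"""Synthetic outcome-locked evoked responses.

Each trial's clean signal is a superposition of evoked components; a
component couples a fixed sensor topography to a Gaussian temporal kernel
and scales it by a gain g(valence, P) that encodes what the component
codes for:

* a *valence* component responds only to win vs loss,
* a *probability* component responds only to the outcome probability P,
* a *prediction-error* component follows the axiomatic pattern
  g(win, P) = +beta (1 - P), g(loss, P) = -beta (1 - P): opposite signs
  for wins and losses, largest for the least likely outcomes, exactly
  zero for fully anticipated (P = 1) outcomes.

Background activity is 1/f ("pink") plus white sensor noise; ocular
blinks (a rank-1 spatial pattern with a stereotyped time course) and
high-amplitude channel jumps are injected separately so the artifact
handling steps have ground truth to work against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import EpochedData
from .layout import SensorLayout, dipole_topography

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "prediction_error_gain",
    "valence_gain",
    "probability_gain",
    "loss_negativity_gain",
    "blink_pattern",
    "simulate_evoked",
    "inject_artifacts",
]

EPOCH_TMIN_MS = -160.0
EPOCH_TMAX_MS = 700.0  # half-open: samples satisfy tmin <= t < tmax


def prediction_error_gain(beta: float) -> Callable[[str, float], float]:
    """Axiomatic reward-prediction-error gain: +-beta*(1 - P), zero at P=1."""

    def g(valence: str, p: float) -> float:
        sign = 1.0 if valence == "win" else -1.0
        return sign * beta * (1.0 - p)

    return g


def valence_gain(amp_win: float, amp_loss: float | None = None):
    """Pure valence gain (no probability dependence)."""
    if amp_loss is None:
        amp_loss = -amp_win

    def g(valence: str, p: float) -> float:
        return amp_win if valence == "win" else amp_loss

    return g


def probability_gain(slope: float, intercept: float = 0.0):
    """Pure probability gain, identical for wins and losses."""

    def g(valence: str, p: float) -> float:
        return intercept + slope * p

    return g


def loss_negativity_gain(gamma: float):
    """Loss-specific negativity scaling with surprise: g(loss,P) = -gamma(1-P).

    Combined with a shared positive probability gain this reproduces the
    pattern where the loss-minus-win difference wave shrinks with P while
    both valences' signals grow with P in the same direction.
    """

    def g(valence: str, p: float) -> float:
        return -gamma * (1.0 - p) if valence == "loss" else 0.0

    return g


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: topography x Gaussian(peak, width) x gain."""

    name: str
    peak_latency_ms: float
    width_ms: float  # Gaussian SD
    topography: np.ndarray  # weight per channel
    gain: Callable[[str, float], float]

    def kernel(self, time_ms: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((time_ms - self.peak_latency_ms) / self.width_ms) ** 2)


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise and artifact parameters (amplitudes in data units)."""

    white_sd: float = 50e-15
    pink_sd: float = 80e-15
    pink_exponent: float = 1.0
    blink_rate: float = 0.05
    blink_amplitude: float = 0.8e-12
    jump_rate: float = 0.01
    jump_amplitude: float = 3e-10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blink_rate", "jump_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("white_sd", "pink_sd", "blink_amplitude", "jump_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def streams(self) -> dict[str, np.random.Generator]:
        """Deterministic split of the session seed into per-purpose streams."""
        kids = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "noise": np.random.default_rng(kids[0]),
            "blink": np.random.default_rng(kids[1]),
            "jump": np.random.default_rng(kids[2]),
        }


def _pink_noise(rng, shape: tuple[int, ...], fs: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise along the last axis (float32)."""
    from scipy import fft as sfft

    n = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    spec = sfft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC power
    out = sfft.irfft(spec * gain, n=n, axis=-1)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_evoked(
    trials: pd.DataFrame,
    components: list[ComponentSpec],
    layout: SensorLayout,
    noise: NoiseSpec,
    fs: float = 600.0,
    units: str = "T",
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
    chunk: int = 64,
) -> EpochedData:
    """Render clean evoked epochs plus background (pink + white) noise.

    Artifacts are *not* added here; see :func:`inject_artifacts`.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n_t = int(round((tmax_ms - tmin_ms) * fs / 1000.0))
    time_ms = tmin_ms + np.arange(n_t) * 1000.0 / fs
    for comp in components:
        if not (tmin_ms <= comp.peak_latency_ms < tmax_ms):
            raise ValueError(
                f"component {comp.name!r} peaks at {comp.peak_latency_ms} ms, "
                f"outside the epoch window [{tmin_ms}, {tmax_ms})"
            )
        if np.asarray(comp.topography).shape != (layout.n_channels,):
            raise ValueError(
                f"component {comp.name!r} topography does not match layout"
            )

    n_trials = len(trials)
    n_ch = layout.n_channels
    data = np.zeros((n_trials, n_ch, n_t), dtype=np.float32)

    valences = trials["outcome_valence"].to_numpy()
    probs = trials["outcome_prob"].to_numpy(dtype=float)
    for comp in components:
        template = np.outer(
            np.asarray(comp.topography, float), comp.kernel(time_ms)
        ).astype(np.float32)
        gains = np.array(
            [comp.gain(v, p) for v, p in zip(valences, probs)], dtype=np.float32
        )
        data += gains[:, None, None] * template[None, :, :]

    rng = noise.streams()["noise"]
    for lo in range(0, n_trials, chunk):  # chunked to bound peak memory
        hi = min(lo + chunk, n_trials)
        shape = (hi - lo, n_ch, n_t)
        if noise.pink_sd > 0:
            data[lo:hi] += np.float32(noise.pink_sd) * _pink_noise(
                rng, shape, fs, noise.pink_exponent
            )
        if noise.white_sd > 0:
            data[lo:hi] += np.float32(noise.white_sd) * rng.standard_normal(
                shape, dtype=np.float32
            )

    meta = trials.reset_index(drop=True).copy()
    record = {
        "operation": "simulate_evoked",
        "params": {
            "fs": fs,
            "components": [c.name for c in components],
            "white_sd": noise.white_sd,
            "pink_sd": noise.pink_sd,
            "pink_exponent": noise.pink_exponent,
            "seed": noise.seed,
        },
    }
    return EpochedData(
        data=data,
        fs=fs,
        time_ms=time_ms,
        trials=meta,
        layout=layout,
        units=units,
        provenance=[record],
    )


def blink_pattern(layout: SensorLayout, eye_pos_m=(0.085, 0.0, -0.02)) -> np.ndarray:
    """Rank-1 ocular spatial pattern: field of a source just behind the eyes."""
    return dipole_topography(layout, np.asarray(eye_pos_m), np.array([0.0, 1.0, 0.0]))


BLINK_WIDTH_MS = 50.0  # Gaussian SD of the stereotyped blink time course


def inject_artifacts(epochs: EpochedData, noise: NoiseSpec) -> EpochedData:
    """Add ocular blinks (rank-1) and high-amplitude single-channel jumps.

    Affected trials and blink latencies are recorded in the trial table
    (columns ``has_blink``, ``blink_latency_ms``, ``has_jump``,
    ``jump_channel``), so rejection and projection steps can be validated
    against ground truth.
    """
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("epochs contain non-finite values")
    streams = noise.streams()
    rng_b, rng_j = streams["blink"], streams["jump"]
    data = epochs.data.copy()
    n_trials, n_ch, n_t = data.shape
    t = epochs.time_ms

    topo = blink_pattern(epochs.layout) * noise.blink_amplitude
    has_blink = rng_b.random(n_trials) < noise.blink_rate
    blink_lat = np.full(n_trials, np.nan)
    lo, hi = t[0] + 2 * BLINK_WIDTH_MS, t[-1] - 2 * BLINK_WIDTH_MS
    for i in np.flatnonzero(has_blink):
        lat = rng_b.uniform(lo, hi)
        blink_lat[i] = lat
        course = np.exp(-0.5 * ((t - lat) / BLINK_WIDTH_MS) ** 2)
        data[i] += np.outer(topo, course)

    has_jump = rng_j.random(n_trials) < noise.jump_rate
    jump_ch = np.full(n_trials, -1)
    for i in np.flatnonzero(has_jump):
        ch = rng_j.integers(n_ch)
        start = rng_j.integers(0, max(n_t - 5, 1))
        sign = 1.0 if rng_j.random() < 0.5 else -1.0
        jump_ch[i] = ch
        data[i, ch, start : start + 5] += sign * 1.2 * noise.jump_amplitude

    meta = epochs.trials.copy()
    meta["has_blink"] = has_blink
    meta["blink_latency_ms"] = blink_lat
    meta["has_jump"] = has_jump
    meta["jump_channel"] = jump_ch
    record = {
        "operation": "inject_artifacts",
        "params": {
            "blink_rate": noise.blink_rate,
            "blink_amplitude": noise.blink_amplitude,
            "jump_rate": noise.jump_rate,
            "jump_amplitude": noise.jump_amplitude,
            "n_blinks": int(has_blink.sum()),
            "n_jumps": int(has_jump.sum()),
            "seed": noise.seed,
        },
    }
    return epochs.evolve(record, data=data, trials=meta)
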
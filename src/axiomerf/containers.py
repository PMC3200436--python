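"""In-memory containers for epoched sensor data.

The canonical object is :class:`EpochedData`: a trials x channels x samples
array in SI units (Tesla for MEG, Volt for EEG) plus the trial metadata
table, sensor layout, and an append-only provenance log recording every
operation applied since simulation or import.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import SensorLayout

__all__ = ["EpochedData"]

#: columns every trial table must carry
TRIAL_COLUMNS = (
    "trial_id",
    "block",
    "target_win_prob",
    "outcome_valence",
    "outcome_prob",
    "outcome_amount",
    "outcome_onset_ms",
)


@dataclass
class EpochedData:
    """Outcome-locked epochs: trials x channels x samples.

    ``time_ms`` is uniformly spaced at 1000/fs and spans the peri-outcome
    window (negative times are the pre-outcome baseline).
    """

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    trials: pd.DataFrame
    layout: SensorLayout
    units: str = "T"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        # dtype is preserved: long sessions are held in float32 to halve
        # memory traffic; statistics upcast where it matters
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != self.layout.n_channels:
            raise ValueError(
                f"data has {n_ch} channels but layout has {self.layout.n_channels}"
            )
        if n_t != self.time_ms.size:
            raise ValueError("time axis length does not match data")
        if len(self.trials) != n_tr:
            raise ValueError(
                f"{n_tr} epochs but {len(self.trials)} trial metadata rows"
            )
        if n_t > 1:
            dt = np.diff(self.time_ms)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis spacing must equal 1000/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_record(self, operation: str, **params) -> dict:
        """Build a provenance record (not yet appended)."""
        return {"operation": operation, "params": params}

    def evolve(self, record: dict | None = None, **changes) -> "EpochedData":
        """Copy with ``changes`` applied and ``record`` appended to provenance."""
        prov = list(self.provenance)
        if record is not None:
            prov.append(record)
        changes.setdefault("provenance", prov)
        changes.setdefault("trials", self.trials.copy())
        return replace(self, **changes)

    def select_trials(self, mask: np.ndarray) -> "EpochedData":
        mask = np.asarray(mask, dtype=bool)
        return self.evolve(
            data=self.data[mask],
            trials=self.trials.loc[mask].reset_index(drop=True),
        )

    def condition_labels(self) -> pd.Series:
        """(valence, outcome probability) condition label per trial."""
        return (
            self.trials["outcome_valence"].astype(str)
            + "_P"
            + self.trials["outcome_prob"].map(lambda p: f"{p:g}")
        )
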
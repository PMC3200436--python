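"""Validated pipeline configuration (YAML/JSON-loadable).

The defaults encode the study conditions the synthetic cohort emulates:
540-trial sessions in 9 blocks with gamble counts {0: 45, .25: 180,
.50: 90, .75: 180, 1: 45}, a 275-channel axial-gradiometer cap sampled
at 600 Hz, an early valence component (~200 ms), a probability component
(~340 ms), and a prediction-error component (~320 ms) whose gain follows
+-beta(1 - P); 0.5-30 Hz band-pass, downsampling to 200 Hz, 1.5e-10 T
rejection, 4-component SSP, 64 x 64 (3 mm) images smoothed at FWHM
8 mm/ms, 100-600 ms temporal mask, peak alpha 0.005 with extent >= 100,
P = 1 inclusive masking at alpha 0.05, and the 295-345 ms axiom window.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "DesignConfig",
    "ComponentConfig",
    "NoiseConfig",
    "SubjectVariabilityConfig",
    "SimConfig",
    "PreprocConfig",
    "MapConfig",
    "GlmConfig",
    "AxiomConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    counts_per_win_prob: dict[float, int] = {
        0.0: 45,
        0.25: 180,
        0.50: 90,
        0.75: 180,
        1.0: 45,
    }
    n_blocks: int = 9
    outcome_mode: Literal["exact", "bernoulli"] = "exact"

    @field_validator("counts_per_win_prob", mode="before")
    @classmethod
    def _float_keys(cls, v):
        if isinstance(v, dict):
            return {float(k): int(n) for k, n in v.items()}
        return v


class ComponentConfig(_Strict):
    name: str
    kind: Literal["prediction_error", "valence", "probability", "loss_negativity"]
    amplitude: float
    peak_latency_ms: float
    width_ms: float
    dipole_pos_m: Optional[tuple[float, float, float]] = None
    dipole_moment: tuple[float, float, float] = (0.0, 1.0, 0.0)
    center_channel: Optional[str] = None  # Gaussian-on-scalp alternative
    topo_sigma_rad: float = 0.5

    @model_validator(mode="after")
    def _one_topography(self):
        if (self.dipole_pos_m is None) == (self.center_channel is None):
            raise ValueError(
                f"component {self.name!r}: specify exactly one of "
                "dipole_pos_m or center_channel"
            )
        return self


DEFAULT_MEG_COMPONENTS = [
    ComponentConfig(
        name="valence_200ms",
        kind="valence",
        amplitude=6e-14,
        peak_latency_ms=200.0,
        width_ms=30.0,
        dipole_pos_m=(0.02, -0.045, 0.045),
        dipole_moment=(1.0, 0.0, 0.0),
    ),
    ComponentConfig(
        name="probability_340ms",
        kind="probability",
        amplitude=5e-14,
        peak_latency_ms=340.0,
        width_ms=40.0,
        dipole_pos_m=(-0.055, 0.025, 0.04),
    ),
    ComponentConfig(
        name="prediction_error_320ms",
        kind="prediction_error",
        amplitude=1e-13,
        peak_latency_ms=320.0,
        width_ms=35.0,
        dipole_pos_m=(0.035, 0.0, 0.055),
    ),
]


class NoiseConfig(_Strict):
    white_sd: float = 50e-15
    pink_sd: float = 80e-15
    pink_exponent: float = 1.0
    blink_rate: float = 0.05
    blink_amplitude: float = 0.8e-12
    jump_rate: float = 0.01
    jump_amplitude: float = 3e-10


class SubjectVariabilityConfig(_Strict):
    """Between-subject variation of component gains and latencies."""

    gain_sd: float = 0.2  # lognormal sigma of the gain multiplier
    latency_jitter_ms: float = 5.0


class SimConfig(_Strict):
    fs: float = 600.0
    n_channels: int = 275
    modality: Literal["meg", "eeg"] = "meg"


class PreprocConfig(_Strict):
    band: tuple[float, float] = (0.5, 30.0)
    fs_down: float = 200.0
    reject_threshold: float = 1.5e-10
    ssp_k: int = 4
    blink_z: float = 4.0
    blink_channel: Optional[str] = None  # None -> strongest ocular loading
    average: Literal["mean", "robust"] = "mean"
    reject_before_ssp: bool = True


class MapConfig(_Strict):
    fwhm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    temporal_window_ms: tuple[float, float] = (100.0, 600.0)
    grid_n: int = 64
    pixel_mm: float = 3.0


class GlmConfig(_Strict):
    alpha_peak: float = 0.005
    extent_min: int = 100
    mask_alpha: float = 0.05
    connectivity: Literal[6, 18, 26] = 26
    subject_effects: bool = True


class AxiomConfig(_Strict):
    window_ms: tuple[float, float] = (295.0, 345.0)
    alpha: float = 0.05
    axiom1_probs: tuple[float, ...] = (0.25, 0.50)
    frn_search_window_ms: tuple[float, float] = (100.0, 600.0)


class PipelineConfig(_Strict):
    seed: int = 0
    n_subjects: int = 17
    design: DesignConfig = DesignConfig()
    sim: SimConfig = SimConfig()
    components: list[ComponentConfig] = list(DEFAULT_MEG_COMPONENTS)
    subject_variability: SubjectVariabilityConfig = SubjectVariabilityConfig()
    noise: NoiseConfig = NoiseConfig()
    preprocess: PreprocConfig = PreprocConfig()
    map: MapConfig = MapConfig()
    glm: GlmConfig = GlmConfig()
    axioms: AxiomConfig = AxiomConfig()


def load_config(path: str) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.model_dump(mode="json"), f, sort_keys=False)


def eeg_frn_config(seed: int = 0, n_subjects: int = 17) -> PipelineConfig:
    """Concurrent-EEG study conditions: the FRN pattern that violates axiom 2.

    Two components at the fronto-central electrodes: a positive-going
    deflection growing with outcome probability in *both* valences, and a
    loss-specific negativity scaling with surprise, -gamma(1 - P).  The
    loss-minus-win difference wave therefore shrinks with P (a classical
    FRN), yet the separate win and loss signals both vary positively with
    probability — the configuration the axiom battery must flag.
    """
    return PipelineConfig(
        seed=seed,
        n_subjects=n_subjects,
        sim=SimConfig(fs=480.0, n_channels=11, modality="eeg"),
        components=[
            ComponentConfig(
                name="probability_positive",
                kind="probability",
                amplitude=2.5e-6,
                peak_latency_ms=280.0,
                width_ms=45.0,
                center_channel="Cz",
                topo_sigma_rad=0.7,
            ),
            ComponentConfig(
                name="frn_loss_negativity",
                kind="loss_negativity",
                amplitude=5e-6,
                peak_latency_ms=270.0,
                width_ms=40.0,
                center_channel="Cz",
                topo_sigma_rad=0.7,
            ),
        ],
        noise=NoiseConfig(
            white_sd=3e-6,
            pink_sd=5e-6,
            blink_rate=0.0,
            blink_amplitude=0.0,
            jump_rate=0.0,
            jump_amplitude=0.0,
        ),
        preprocess=PreprocConfig(
            band=(2.0, 30.0),
            fs_down=200.0,
            reject_threshold=2e-4,
            ssp_k=0,
            average="robust",
        ),
        axioms=AxiomConfig(
            window_ms=(200.0, 300.0),
            frn_search_window_ms=(0.0, 600.0),
        ),
    )
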
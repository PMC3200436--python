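"""End-to-end driver: simulate -> preprocess -> images -> ANCOVA -> axioms.

Stages run in the canonical order (band-pass filter, downsample,
baseline, amplitude rejection, SSP, condition averaging, scalp-image
construction, second-level ANCOVA with the three F contrasts, P = 1
inclusive masking, cluster thresholding, and the axiom battery plus the
FRN difference-wave analysis at the interaction peak).  Everything is
reproducible from (config, seed): one master seed is split
deterministically into per-subject, per-purpose streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import axioms as ax
from . import glm as _glm
from . import preprocess as pp
from .config import ComponentConfig, PipelineConfig
from .containers import EpochedData
from .design import build_session_design
from .layout import (
    SensorLayout,
    dipole_topography,
    eeg_sparse_1020_layout,
    gaussian_topography,
    meg_cap_layout,
)
from .scalp_map import ScalpImage, SensorRasterizer, grid_axes, smooth, temporal_mask
from .simulate import (
    ComponentSpec,
    NoiseSpec,
    blink_pattern,
    inject_artifacts,
    loss_negativity_gain,
    prediction_error_gain,
    probability_gain,
    simulate_evoked,
    valence_gain,
)

__all__ = [
    "build_layout",
    "build_components",
    "default_blink_channel",
    "simulate_subject",
    "preprocess_subject",
    "condition_volumes",
    "PipelineResult",
    "run_pipeline",
    "null_calibration",
]

_GAIN_FACTORIES = {
    "prediction_error": prediction_error_gain,
    "valence": valence_gain,
    "probability": probability_gain,
    "loss_negativity": loss_negativity_gain,
}


def _seed_int(ss: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence into a small positive integer seed."""
    return int(ss.generate_state(1)[0] % (2**31))


def build_layout(config: PipelineConfig) -> SensorLayout:
    if config.sim.modality == "eeg":
        return eeg_sparse_1020_layout()
    return meg_cap_layout(config.sim.n_channels)


def build_components(
    specs: list[ComponentConfig],
    layout: SensorLayout,
    gain_mult: float = 1.0,
    latency_shift_ms: float = 0.0,
) -> list[ComponentSpec]:
    """Realize component configs, optionally with subject-level variation."""
    out = []
    for c in specs:
        if c.dipole_pos_m is not None:
            topo = dipole_topography(
                layout, np.asarray(c.dipole_pos_m), np.asarray(c.dipole_moment)
            )
        else:
            topo = gaussian_topography(layout, c.center_channel, c.topo_sigma_rad)
        gain = _GAIN_FACTORIES[c.kind](c.amplitude * gain_mult)
        out.append(
            ComponentSpec(
                name=c.name,
                peak_latency_ms=c.peak_latency_ms + latency_shift_ms,
                width_ms=c.width_ms,
                topography=topo,
                gain=gain,
            )
        )
    return out


def default_blink_channel(layout: SensorLayout) -> str:
    """Channel with the strongest loading of the ocular pattern."""
    return layout.channel_ids[int(np.argmax(np.abs(blink_pattern(layout))))]


def simulate_subject(
    config: PipelineConfig, subject_seed: np.random.SeedSequence, layout: SensorLayout
) -> EpochedData:
    """One synthetic session: design, evoked signal, noise, artifacts."""
    kids = subject_seed.spawn(3)
    rng = np.random.default_rng(kids[0])
    sv = config.subject_variability
    gain_mult = float(np.exp(rng.normal(0.0, sv.gain_sd)))
    latency_shift = float(rng.normal(0.0, sv.latency_jitter_ms))
    trials = build_session_design(
        config.design.counts_per_win_prob,
        config.design.n_blocks,
        seed=kids[1],
        outcome_mode=config.design.outcome_mode,
    )
    comps = build_components(config.components, layout, gain_mult, latency_shift)
    noise = NoiseSpec(
        white_sd=config.noise.white_sd,
        pink_sd=config.noise.pink_sd,
        pink_exponent=config.noise.pink_exponent,
        blink_rate=config.noise.blink_rate,
        blink_amplitude=config.noise.blink_amplitude,
        jump_rate=config.noise.jump_rate,
        jump_amplitude=config.noise.jump_amplitude,
        seed=_seed_int(kids[2]),
    )
    units = "V" if config.sim.modality == "eeg" else "T"
    epochs = simulate_evoked(
        trials, comps, layout, noise, fs=config.sim.fs, units=units
    )
    return inject_artifacts(epochs, noise)


def preprocess_subject(epochs: EpochedData, config: PipelineConfig) -> EpochedData:
    """Filter -> downsample -> baseline -> reject -> SSP, in that order."""
    pc = config.preprocess
    epochs = pp.bandpass(epochs, *pc.band)
    if pc.fs_down < epochs.fs:
        epochs = pp.resample(epochs, pc.fs_down)
    epochs = pp.baseline_correct(epochs)

    def _ssp(ep):
        if pc.ssp_k > 0 and config.noise.blink_rate > 0:
            ch = pc.blink_channel or default_blink_channel(ep.layout)
            op = pp.fit_blink_projector(
                ep, ch, detection_threshold=pc.blink_z, k=pc.ssp_k
            )
            ep = pp.apply_projection(ep, op)
        return ep

    if pc.reject_before_ssp:
        epochs, _ = pp.reject_amplitude(epochs, pc.reject_threshold)
        epochs = _ssp(epochs)
    else:
        epochs = _ssp(epochs)
        epochs, _ = pp.reject_amplitude(epochs, pc.reject_threshold)
    return epochs


def condition_volumes(
    epochs: EpochedData,
    config: PipelineConfig,
    rasterizer: SensorRasterizer,
) -> dict[tuple[str, float], ScalpImage]:
    """Smoothed, temporally masked image volume per (valence, probability)."""
    averages = pp.condition_average(epochs, method=config.preprocess.average)
    out = {}
    for key, avg in averages.items():
        vol = rasterizer.volume(avg, epochs.time_ms)
        vol = smooth(vol, config.map.fwhm)
        out[key] = temporal_mask(vol, config.map.temporal_window_ms)
    return out


@dataclass
class PipelineResult:
    config: PipelineConfig
    cluster_tables: dict[str, _glm.ClusterTable]
    masked_interaction: _glm.ClusterTable
    equivalence_excluded_fraction: float
    peak: dict | None
    condition_means: pd.DataFrame | None
    anova: dict | None
    axiom_report: ax.AxiomReport | None
    frn: ax.FRNResult | None
    stat_maps: dict[str, _glm.StatMap] = field(repr=False, default_factory=dict)
    n_rejected_trials: int = 0

    def report(self) -> dict:
        """JSON-serializable summary of every numerical output."""

        def table_dict(ct: _glm.ClusterTable) -> dict:
            return {
                "alpha_peak": ct.alpha_peak,
                "f_crit": ct.f_crit,
                "extent_min": ct.extent_min,
                "df": list(ct.df),
                "clusters": ct.table.drop(
                    columns=["peak_ix", "peak_iy", "peak_it"]
                ).to_dict(orient="records"),
            }

        rep = {
            "seed": self.config.seed,
            "n_subjects": self.config.n_subjects,
            "n_rejected_trials": self.n_rejected_trials,
            "contrasts": {k: table_dict(v) for k, v in self.cluster_tables.items()},
            "masked_interaction": table_dict(self.masked_interaction),
            "equivalence_excluded_fraction": self.equivalence_excluded_fraction,
            "peak": self.peak,
            "anova": _jsonable(self.anova),
            "axioms": _jsonable(
                self.axiom_report.to_dict() if self.axiom_report else None
            ),
            "frn": None,
        }
        if self.frn is not None:
            rep["frn"] = {
                "probability_effect": self.frn.probability_effect,
                "linear_trend": self.frn.linear_trend,
                "amplitudes": self.frn.table.to_dict(orient="records"),
            }
        return _jsonable(rep)

    def render_text(self) -> str:
        rep = self.report()
        lines = [
            "Axiomatic prediction-error analysis report",
            "==========================================",
            f"seed={rep['seed']}  subjects={rep['n_subjects']}  "
            f"rejected_trials={rep['n_rejected_trials']}",
            "",
        ]
        for name, tab in rep["contrasts"].items():
            lines.append(
                f"[{name}] F_crit={tab['f_crit']:.2f} "
                f"(alpha={tab['alpha_peak']}, df={tab['df']}), "
                f"extent_min={tab['extent_min']}"
            )
            for cl in tab["clusters"]:
                lines.append(
                    f"  cluster {cl['cluster_id']}: k={cl['extent']} "
                    f"peak F={cl['peak_F']:.2f} Z={cl['peak_Z']:.2f} "
                    f"at x={cl['x_mm']:g} mm, y={cl['y_mm']:g} mm, "
                    f"t={cl['t_ms']:g} ms"
                )
        mi = rep["masked_interaction"]
        lines.append(
            f"[interaction, P=1-masked] {len(mi['clusters'])} cluster(s); "
            f"mask excluded {rep['equivalence_excluded_fraction'] * 100:.2f}% "
            "of voxels"
        )
        if rep["axioms"] is not None:
            axr = rep["axioms"]
            lines += [
                "",
                f"Axiom battery at peak ({rep['peak']}):",
                f"  axiom 1 pass={axr['axiom1_pass']}  "
                f"axiom 2 pass={axr['axiom2_pass']} "
                f"(win slope {axr['win_slope']:.3g}, "
                f"loss slope {axr['loss_slope']:.3g})  "
                f"axiom 3 pass={axr['axiom3_pass']}",
                f"  overall: {axr['overall']}",
            ]
        if rep["frn"] is not None:
            fr = rep["frn"]
            lines.append(
                f"FRN: probability F={fr['probability_effect']['F']:.2f} "
                f"p={fr['probability_effect']['p']:.4g}; linear trend "
                f"F={fr['linear_trend']['F']:.2f} p={fr['linear_trend']['p']:.4g}"
            )
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.report(), indent=2))
        (out / "report.txt").write_text(self.render_text())
        for name, ct in {
            **self.cluster_tables,
            "interaction_masked": self.masked_interaction,
        }.items():
            ct.table.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
        if self.condition_means is not None:
            self.condition_means.to_csv(
                out / "condition_means.tsv", sep="\t", index=False
            )
        if self.frn is not None:
            self.frn.table.to_csv(out / "frn.tsv", sep="\t", index=False)


def _jsonable(obj):
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(
    config: PipelineConfig, out_dir: str | None = None, keep_stat_maps: bool = False
) -> PipelineResult:
    """Execute the full analysis for a synthetic cohort."""
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    layout = build_layout(config)
    rasterizer = SensorRasterizer(layout, config.map.grid_n, config.map.pixel_mm)

    volumes: dict[tuple[int, str, float], ScalpImage] = {}
    cell_counts: dict[tuple[int, str, float], int] = {}
    n_rejected = 0
    for s in range(config.n_subjects):
        epochs = simulate_subject(config, subject_seeds[s], layout)
        n_before = epochs.n_trials
        epochs = preprocess_subject(epochs, config)
        n_rejected += n_before - epochs.n_trials
        sizes = epochs.trials.groupby(["outcome_valence", "outcome_prob"]).size()
        for (val, p), n_cell in sizes.items():
            cell_counts[(s, val, float(p))] = int(n_cell)
        for (val, p), vol in condition_volumes(epochs, config, rasterizer).items():
            volumes[(s, val, p)] = vol
        del epochs

    design = _glm.build_design(
        config.n_subjects, include_subject_effects=config.glm.subject_effects
    )
    images = _glm.collect_images(design, volumes)
    # rows are rescaled by their known relative precision (per-cell trial
    # counts): the 45 vs 135 cell imbalance otherwise leaves the voxel
    # F test miscalibrated under the null
    row_weights = np.array(
        [
            cell_counts[(int(r["subject"]), str(r["valence"]), float(r["probability"]))]
            for _, r in design.rows.iterrows()
        ],
        dtype=float,
    )

    cluster_tables: dict[str, _glm.ClusterTable] = {}
    stat_maps: dict[str, _glm.StatMap] = {}
    for name in ("valence", "probability", "interaction"):
        sm = _glm.fit_and_contrast(
            images, design, name, keep_betas=True, row_weights=row_weights
        )
        stat_maps[name] = sm
        cluster_tables[name] = _glm.threshold_and_cluster(
            sm,
            config.glm.alpha_peak,
            config.glm.extent_min,
            config.glm.connectivity,
        )

    win_p1 = [volumes[(s, "win", 1.0)] for s in range(config.n_subjects)]
    loss_p1 = [volumes[(s, "loss", 1.0)] for s in range(config.n_subjects)]
    eq_mask = _glm.equivalence_mask(win_p1, loss_p1, config.glm.mask_alpha)
    sm_int = stat_maps["interaction"]
    valid = np.isfinite(sm_int.F)
    excluded = float((~eq_mask & valid).sum() / max(valid.sum(), 1))
    masked = _glm.apply_mask(sm_int, eq_mask)
    masked_table = _glm.threshold_and_cluster(
        masked, config.glm.alpha_peak, config.glm.extent_min, config.glm.connectivity
    )

    peak = None
    means = None
    anova = None
    axiom_report = None
    frn = None
    if len(masked_table.table):
        best = masked_table.table.loc[masked_table.table["peak_F"].idxmax()]
        ix, iy = int(best["peak_ix"]), int(best["peak_iy"])
        peak = {
            "x_mm": float(best["x_mm"]),
            "y_mm": float(best["y_mm"]),
            "t_ms": float(best["t_ms"]),
            "peak_F": float(best["peak_F"]),
            "peak_Z": float(best["peak_Z"]),
            "extent": int(best["extent"]),
        }
        waveforms = {
            (s, val, p): volumes[(s, val, p)].values[ix, iy, :]
            for s in range(config.n_subjects)
            for val in ("win", "loss")
            for p in (0.25, 0.50, 0.75, 1.0)
        }
        time_ms = images[0].time_ms
        means = ax.window_average(waveforms, time_ms, config.axioms.window_ms)
        anova = ax.rm_anova_2x4(means)
        axiom_report = ax.axiom_compliance(
            means,
            alpha=config.axioms.alpha,
            axiom1_probs=config.axioms.axiom1_probs,
        )
        frn = ax.frn_difference(
            waveforms, time_ms, config.axioms.frn_search_window_ms
        )

    result = PipelineResult(
        config=config,
        cluster_tables=cluster_tables,
        masked_interaction=masked_table,
        equivalence_excluded_fraction=excluded,
        peak=peak,
        condition_means=means,
        anova=anova,
        axiom_report=axiom_report,
        frn=frn,
        stat_maps=stat_maps if keep_stat_maps else {},
        n_rejected_trials=n_rejected,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


def null_calibration(
    n_sims: int = 100,
    n_subjects: int = 17,
    grid_shape: tuple[int, int, int] = (16, 16, 6),
    alpha_peak: float = 0.005,
    mask_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive calibration of the voxelwise F test and the P=1 mask.

    Under the null (no injected components) the second-level condition
    images are exchangeable noise, so the suprathreshold voxel fraction
    at ``alpha_peak`` must match ``alpha_peak`` and the equivalence mask
    must exclude ~``mask_alpha`` of voxels.  Condition images are drawn
    directly as white noise at a reduced grid so many replicates are
    affordable; the F test itself is exact at any grid size.
    """
    from scipy import stats as st

    rng = np.random.default_rng(seed)
    nx, ny, nt = grid_shape
    x_mm, y_mm = grid_axes(nx, 3.0)
    y_axis = grid_axes(ny, 3.0)[0]
    time_ms = 100.0 + 5.0 * np.arange(nt)
    mask = np.ones((nx, ny), dtype=bool)
    design = _glm.build_design(n_subjects)
    n_rows = design.X.shape[0]
    f_crit = st.f.isf(alpha_peak, 1, n_rows - np.linalg.matrix_rank(design.X))

    supra_frac = np.empty(n_sims)
    masked_frac = np.empty(n_sims)
    for i in range(n_sims):
        imgs = [
            ScalpImage(
                values=rng.standard_normal((nx, ny, nt)),
                x_mm=x_mm,
                y_mm=y_axis,
                time_ms=time_ms,
                validity_mask=mask,
            )
            for _ in range(n_rows)
        ]
        sm = _glm.fit_and_contrast(imgs, design, "interaction", keep_betas=False)
        supra_frac[i] = np.mean(sm.F[np.isfinite(sm.F)] > f_crit)
        rows = design.rows
        win_p1 = [
            imgs[j]
            for j in np.flatnonzero(
                (rows["valence"] == "win") & (rows["probability"] == 1.0)
            )
        ]
        loss_p1 = [
            imgs[j]
            for j in np.flatnonzero(
                (rows["valence"] == "loss") & (rows["probability"] == 1.0)
            )
        ]
        eq = _glm.equivalence_mask(win_p1, loss_p1, mask_alpha)
        masked_frac[i] = 1.0 - eq.mean()

    n_vox_total = n_sims * nx * ny * nt
    return {
        "alpha_peak": alpha_peak,
        "suprathreshold_fraction": float(supra_frac.mean()),
        "suprathreshold_mc_se": float(
            np.sqrt(alpha_peak * (1 - alpha_peak) / n_vox_total)
        ),
        "mask_alpha": mask_alpha,
        "masked_out_fraction": float(masked_frac.mean()),
        "masked_mc_se": float(np.sqrt(mask_alpha * (1 - mask_alpha) / n_vox_total)),
        "n_sims": n_sims,
        "n_voxels_per_sim": nx * ny * nt,
    }


def run_frn_study(
    config: PipelineConfig, electrode: str = "Cz", ref_channels=("M1", "M2")
) -> dict:
    """Electrode-level FRN study: robust averages, window means, axiom battery.

    Mirrors the concurrent-EEG analysis path: mastoid re-reference,
    2-30 Hz band-pass, downsampling, baseline, robust per-condition
    averaging with a 30 Hz post-average low-pass, then (a) window means
    at the electrode entered into the 2 x 4 repeated-measures ANOVA and
    the axiom battery and (b) the loss-minus-win difference-wave FRN with
    its probability ANOVA and linear trend.
    """
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    layout = build_layout(config)
    ei = layout.index(electrode)
    pc = config.preprocess

    waveforms: dict[tuple[int, str, float], np.ndarray] = {}
    time_ms = None
    for s in range(config.n_subjects):
        epochs = simulate_subject(config, subject_seeds[s], layout)
        epochs = pp.rereference(epochs, list(ref_channels))
        epochs = pp.bandpass(epochs, *pc.band)
        if pc.fs_down < epochs.fs:
            epochs = pp.resample(epochs, pc.fs_down)
        epochs = pp.baseline_correct(epochs)
        epochs, _ = pp.reject_amplitude(epochs, pc.reject_threshold)
        meta = epochs.trials
        for (val, p), idx in meta.groupby(
            ["outcome_valence", "outcome_prob"], sort=True
        ).indices.items():
            res = pp.robust_average(
                epochs.data[idx], fs=epochs.fs, post_lowpass_hz=30.0
            )
            waveforms[(s, val, float(p))] = res.average[ei]
        time_ms = epochs.time_ms
        del epochs

    means = ax.window_average(waveforms, time_ms, config.axioms.window_ms)
    anova = ax.rm_anova_2x4(means)
    report = ax.axiom_compliance(
        means, alpha=config.axioms.alpha, axiom1_probs=config.axioms.axiom1_probs
    )
    frn = ax.frn_difference(
        waveforms, time_ms, config.axioms.frn_search_window_ms
    )
    return {
        "means": means,
        "anova": anova,
        "axiom_report": report,
        "frn": frn,
        "electrode": electrode,
        "time_ms": time_ms,
    }
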
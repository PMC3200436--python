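"""The axiomatic compliance battery and FRN difference-wave analysis.

A signal qualifies as a reward-prediction-error representation only if

1. it distinguishes wins from losses (valence ordering),
2. it is modulated by outcome probability within *both* valences, with
   slopes of opposite sign that differ from each other, and
3. it is equivalent for fully anticipated (P = 1) wins and losses.

The battery operates on condition means: one amplitude per subject,
valence, and outcome probability, extracted from a stated time window at
a peak voxel or electrode.  It reports per-probability paired tests,
within-valence probability slopes, the valence x probability interaction,
and the P = 1 equivalence check, and grades the overall outcome as
compliant / weakly compliant / violated.

The FRN analysis mirrors the classical EEG approach: the loss-minus-win
difference wave at a fronto-central electrode, with the FRN defined as
the minimum within 0-600 ms post-outcome, followed by a one-way
repeated-measures ANOVA over probability with a linear trend contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "window_average",
    "rm_anova_2x4",
    "AxiomReport",
    "axiom_compliance",
    "FRNResult",
    "frn_difference",
]

PROBABILITIES = (0.25, 0.50, 0.75, 1.0)
VALENCES = ("win", "loss")


def window_average(
    waveforms: dict[tuple[int, str, float], np.ndarray],
    time_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> pd.DataFrame:
    """Mean amplitude over a closed time window, per subject and condition.

    ``waveforms`` maps (subject, valence, probability) to a 1D waveform on
    ``time_ms``.  Returns the tidy condition-means table used by the rest
    of the battery (columns: subject, valence, probability, amplitude).
    """
    lo, hi = window_ms
    keep = (time_ms >= lo) & (time_ms <= hi)
    if not keep.any():
        raise ValueError(f"window {window_ms} contains no samples")
    rows = []
    for (subj, val, p), wave in waveforms.items():
        wave = np.asarray(wave, dtype=float)
        if wave.shape != time_ms.shape:
            raise ValueError("waveform length does not match time axis")
        rows.append(
            {
                "subject": subj,
                "valence": val,
                "probability": float(p),
                "amplitude": float(wave[keep].mean()),
            }
        )
    df = pd.DataFrame(rows)
    _check_grid(df)
    return df


def _check_grid(means: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Validate the complete 2 x 4 grid; return y[s, valence, prob] cube."""
    subjects = sorted(means["subject"].unique())
    cube = np.full((len(subjects), len(VALENCES), len(PROBABILITIES)), np.nan)
    idx = means.set_index(["subject", "valence", "probability"])["amplitude"]
    for i, s in enumerate(subjects):
        for a, v in enumerate(VALENCES):
            for b, p in enumerate(PROBABILITIES):
                try:
                    cube[i, a, b] = idx.loc[(s, v, p)]
                except KeyError:
                    raise ValueError(
                        f"incomplete condition grid: subject {s} lacks {v} P={p:g}"
                    ) from None
    return cube, subjects


def _f_ratio(ss_num, df_num, ss_den, df_den) -> dict:
    """F ratio with explicit handling of degenerate (zero-SS) cells."""
    tiny = 1e-300
    if ss_num <= tiny * max(1.0, ss_den):
        return {"F": 0.0, "p": 1.0, "df": (df_num, df_den), "degenerate": False}
    if ss_den <= tiny * ss_num:
        return {"F": np.inf, "p": 0.0, "df": (df_num, df_den), "degenerate": True}
    f = (ss_num / df_num) / (ss_den / df_den)
    return {
        "F": float(f),
        "p": float(stats.f.sf(f, df_num, df_den)),
        "df": (df_num, df_den),
        "degenerate": False,
    }


def rm_anova_2x4(means: pd.DataFrame) -> dict:
    """Two-way repeated-measures ANOVA (valence x probability).

    Univariate within-subject decomposition with subject as the random
    factor and uncorrected degrees of freedom; each effect is tested
    against its own effect-by-subject interaction.  Also returns the
    linear polynomial trend of the win-loss difference across probability
    and the standard paired t-tests (win vs loss per probability, and
    adjacent probabilities on the valence difference).
    """
    y, subjects = _check_grid(means)
    n, A, B = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * B * np.sum((m_a - m) ** 2)
    ss_b = n * A * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = B * np.sum((m_sa - m_a[None, :] - m_s[:, None] + m) ** 2)
    ss_bs = A * np.sum((m_sb - m_b[None, :] - m_s[:, None] + m) ** 2)
    ss_s = A * B * np.sum((m_s - m) ** 2)
    ss_tot = np.sum((y - m) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    out = {
        "valence": _f_ratio(ss_a, A - 1, ss_as, (A - 1) * (n - 1)),
        "probability": _f_ratio(ss_b, B - 1, ss_bs, (B - 1) * (n - 1)),
        "interaction": _f_ratio(
            ss_ab, (A - 1) * (B - 1), ss_abs, (A - 1) * (B - 1) * (n - 1)
        ),
    }

    # linear polynomial trend of the valence difference across probability
    diff = y[:, 0, :] - y[:, 1, :]  # win - loss, per subject x probability
    w = np.array([-3.0, -1.0, 1.0, 3.0])
    L = diff @ w
    out["linear_trend"] = _trend_f(L)

    ttests = {}
    for b, p in enumerate(PROBABILITIES):
        t, pv = stats.ttest_rel(y[:, 0, b], y[:, 1, b])
        ttests[f"win_vs_loss_P{p:g}"] = {"t": float(t), "p": float(pv), "df": n - 1}
    for b in range(B - 1):
        t, pv = stats.ttest_rel(diff[:, b], diff[:, b + 1])
        ttests[f"diff_P{PROBABILITIES[b]:g}_vs_P{PROBABILITIES[b + 1]:g}"] = {
            "t": float(t),
            "p": float(pv),
            "df": n - 1,
        }
    out["paired_t"] = ttests
    out["n_subjects"] = n
    return out


def _trend_f(L: np.ndarray) -> dict:
    """One-sample t on a contrast score, reported as F = t^2."""
    n = L.size
    se = L.std(ddof=1) / np.sqrt(n)
    if se == 0:
        if abs(L.mean()) == 0:
            return {"F": 0.0, "p": 1.0, "df": (1, n - 1), "degenerate": False}
        return {"F": np.inf, "p": 0.0, "df": (1, n - 1), "degenerate": True}
    t = L.mean() / se
    return {
        "F": float(t**2),
        "p": float(stats.f.sf(t**2, 1, n - 1)),
        "df": (1, n - 1),
        "degenerate": False,
    }


@dataclass
class AxiomReport:
    """Outcome of the three-axiom battery on a set of condition means."""

    axiom1_pass: bool
    axiom1_tests: dict  # per-probability win-vs-loss paired t
    axiom2_pass: bool
    win_slope: float
    loss_slope: float
    win_slope_test: dict
    loss_slope_test: dict
    slope_interaction: dict
    sign_opposition: bool
    axiom3_pass: bool
    axiom3_test: dict
    adjacent_steps: dict
    overall: str  # compliant | weakly_compliant | violated
    alpha: float

    def to_dict(self) -> dict:
        return asdict(self)


def _subject_slopes(cube: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject OLS slope of amplitude against outcome probability."""
    p = np.asarray(PROBABILITIES)
    pc = p - p.mean()
    denom = np.sum(pc**2)
    win = cube[:, 0, :] @ pc / denom
    loss = cube[:, 1, :] @ pc / denom
    return win, loss


def axiom_compliance(
    means: pd.DataFrame,
    alpha: float = 0.05,
    axiom1_probs: tuple[float, ...] = (0.25, 0.50),
    equivalence_bound: float | None = None,
) -> AxiomReport:
    """Run the three-axiom battery on condition means.

    * Axiom 1 passes when wins and losses differ (paired t, two-sided)
      at every probability in ``axiom1_probs`` — by default the
      low-probability conditions, where a prediction-error signal must
      separate the valences most clearly.  The per-probability results
      are all recorded, so stricter or looser rules can be applied post hoc.
    * Axiom 2 passes when both within-valence probability slopes are
      significantly nonzero, of opposite sign, and significantly
      different from each other (the interaction).
    * Axiom 3 passes when P = 1 wins and losses do *not* differ at
      ``alpha``.  Because a null result cannot prove equivalence, an
      optional TOST with user-set ``equivalence_bound`` (same units as
      the amplitudes) is also reported when requested.

    Overall grade: ``compliant`` when all axioms pass and every
    adjacent-probability step of the valence difference is individually
    significant; ``weakly_compliant`` when the axioms pass but one or
    more adjacent steps are not; ``violated`` otherwise.
    """
    cube, _ = _check_grid(means)
    n = cube.shape[0]
    anova = rm_anova_2x4(means)

    ax1_tests = {
        k: v for k, v in anova["paired_t"].items() if k.startswith("win_vs_loss")
    }
    ax1_pass = all(
        ax1_tests[f"win_vs_loss_P{p:g}"]["p"] < alpha for p in axiom1_probs
    )

    win_sl, loss_sl = _subject_slopes(cube)
    t_w, p_w = stats.ttest_1samp(win_sl, 0.0)
    t_l, p_l = stats.ttest_1samp(loss_sl, 0.0)
    t_i, p_i = stats.ttest_rel(win_sl, loss_sl)
    win_test = {"t": float(t_w), "p": float(p_w), "df": n - 1}
    loss_test = {"t": float(t_l), "p": float(p_l), "df": n - 1}
    inter_test = {"t": float(t_i), "p": float(p_i), "df": n - 1}
    sign_opp = bool(win_sl.mean() * loss_sl.mean() < 0)
    ax2_pass = (
        win_test["p"] < alpha
        and loss_test["p"] < alpha
        and inter_test["p"] < alpha
        and sign_opp
    )

    ax3_t = anova["paired_t"]["win_vs_loss_P1"]
    ax3_pass = ax3_t["p"] >= alpha
    ax3_test = dict(ax3_t)
    if equivalence_bound is not None:
        d = cube[:, 0, 3] - cube[:, 1, 3]
        se = d.std(ddof=1) / np.sqrt(n)
        t_lo = (d.mean() + equivalence_bound) / se
        t_hi = (d.mean() - equivalence_bound) / se
        p_tost = max(stats.t.sf(t_lo, n - 1), stats.t.cdf(t_hi, n - 1))
        ax3_test["tost_p"] = float(p_tost)
        ax3_test["tost_bound"] = float(equivalence_bound)
        ax3_pass = ax3_pass and p_tost < alpha

    adjacent = {
        k: v for k, v in anova["paired_t"].items() if k.startswith("diff_")
    }
    all_axioms = ax1_pass and ax2_pass and ax3_pass
    if not all_axioms:
        overall = "violated"
    elif all(v["p"] < alpha for v in adjacent.values()):
        overall = "compliant"
    else:
        overall = "weakly_compliant"

    return AxiomReport(
        axiom1_pass=ax1_pass,
        axiom1_tests=ax1_tests,
        axiom2_pass=ax2_pass,
        win_slope=float(win_sl.mean()),
        loss_slope=float(loss_sl.mean()),
        win_slope_test=win_test,
        loss_slope_test=loss_test,
        slope_interaction=inter_test,
        sign_opposition=sign_opp,
        axiom3_pass=ax3_pass,
        axiom3_test=ax3_test,
        adjacent_steps=adjacent,
        overall=overall,
        alpha=alpha,
    )


@dataclass
class FRNResult:
    """FRN amplitudes/latencies and the group probability statistics."""

    table: pd.DataFrame  # subject, probability, amplitude, latency_ms
    probability_effect: dict  # one-way RM ANOVA over probability
    linear_trend: dict
    search_window_ms: tuple[float, float]


def frn_difference(
    waveforms: dict[tuple[int, str, float], np.ndarray],
    time_ms: np.ndarray,
    search_window_ms: tuple[float, float] = (0.0, 600.0),
) -> FRNResult:
    """Loss-minus-win difference wave and its minimum (the FRN).

    For each subject and probability the FRN is the minimum of the
    loss - win difference wave within the search window (earliest sample
    on ties).  Group statistics: one-way repeated-measures ANOVA of the
    FRN amplitude over probability, plus the linear polynomial trend.
    """
    lo, hi = search_window_ms
    if lo > hi or not ((time_ms >= lo) & (time_ms <= hi)).any():
        raise ValueError(f"search window {search_window_ms} outside the epoch")
    keep = (time_ms >= lo) & (time_ms <= hi)
    t_win = time_ms[keep]

    subjects = sorted({k[0] for k in waveforms})
    rows = []
    for s in subjects:
        for p in PROBABILITIES:
            try:
                w = np.asarray(waveforms[(s, "win", p)], dtype=float)
                l = np.asarray(waveforms[(s, "loss", p)], dtype=float)
            except KeyError:
                raise ValueError(
                    f"missing win/loss waveform for subject {s}, P={p:g}"
                ) from None
            d = (l - w)[keep]
            i = int(np.argmin(d))  # argmin returns the first minimum on ties
            rows.append(
                {
                    "subject": s,
                    "probability": p,
                    "amplitude": float(d[i]),
                    "latency_ms": float(t_win[i]),
                }
            )
    table = pd.DataFrame(rows)

    amp = table.pivot(index="subject", columns="probability", values="amplitude")
    amp = amp[list(PROBABILITIES)].to_numpy()
    n, B = amp.shape
    m = amp.mean()
    m_s = amp.mean(axis=1)
    m_b = amp.mean(axis=0)
    ss_b = n * np.sum((m_b - m) ** 2)
    ss_bs = np.sum((amp - m_s[:, None] - m_b[None, :] + m) ** 2)
    prob_effect = _f_ratio(ss_b, B - 1, ss_bs, (B - 1) * (n - 1))
    trend = _trend_f(amp @ np.array([-3.0, -1.0, 1.0, 3.0]))
    return FRNResult(table, prob_effect, trend, (lo, hi))
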
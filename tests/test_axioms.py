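"""Condition means, repeated-measures ANOVA, axiom battery, FRN analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from axiomerf.axioms import (
    PROBABILITIES,
    axiom_compliance,
    frn_difference,
    rm_anova_2x4,
    window_average,
)


def means_frame(cube):
    """cube[s, valence(win,loss), prob] -> tidy condition-means table."""
    rows = []
    for s in range(cube.shape[0]):
        for a, v in enumerate(("win", "loss")):
            for b, p in enumerate(PROBABILITIES):
                rows.append(
                    {"subject": s, "valence": v, "probability": p,
                     "amplitude": cube[s, a, b]}
                )
    return pd.DataFrame(rows)


def fig2_cube(n=17, beta=1.0, noise_sd=0.01, seed=0):
    """Axiomatic prediction-error pattern: +-beta(1 - P) plus jitter."""
    rng = np.random.default_rng(seed)
    p = np.asarray(PROBABILITIES)
    cube = np.empty((n, 2, 4))
    cube[:, 0, :] = beta * (1 - p)[None, :]
    cube[:, 1, :] = -beta * (1 - p)[None, :]
    return cube + rng.normal(0, noise_sd, cube.shape)


def anova_oracle(cube):
    """Brute-force sums-of-squares partition for the 2x4 within design."""
    n, A, B = cube.shape
    m = cube.mean()
    ss = {}
    m_a = cube.mean(axis=(0, 2)); m_b = cube.mean(axis=(0, 1))
    m_s = cube.mean(axis=(1, 2))
    m_sa = cube.mean(axis=2); m_sb = cube.mean(axis=1); m_ab = cube.mean(axis=0)
    ss["A"] = n * B * ((m_a - m) ** 2).sum()
    ss["B"] = n * A * ((m_b - m) ** 2).sum()
    ss["AB"] = n * ((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2).sum()
    ss["AS"] = B * ((m_sa - m_a[None, :] - m_s[:, None] + m) ** 2).sum()
    ss["BS"] = A * ((m_sb - m_b[None, :] - m_s[:, None] + m) ** 2).sum()
    ss["S"] = A * B * ((m_s - m) ** 2).sum()
    ss["ABS"] = ((cube - m) ** 2).sum() - sum(
        ss[k] for k in ("A", "B", "AB", "AS", "BS", "S")
    )
    F_A = (ss["A"] / (A - 1)) / (ss["AS"] / ((A - 1) * (n - 1)))
    F_B = (ss["B"] / (B - 1)) / (ss["BS"] / ((B - 1) * (n - 1)))
    F_AB = (ss["AB"] / ((A - 1) * (B - 1))) / (
        ss["ABS"] / ((A - 1) * (B - 1) * (n - 1))
    )
    return F_A, F_B, F_AB


class TestWindowAverage:
    def _waves(self, fn):
        t = np.arange(0.0, 501.0, 5.0)
        waves = {
            (s, v, p): fn(t)
            for s in range(2)
            for v in ("win", "loss")
            for p in PROBABILITIES
        }
        return waves, t

    def test_constant_wave(self):
        waves, t = self._waves(lambda t: np.full_like(t, 3.3))
        df = window_average(waves, t, (200, 300))
        assert np.allclose(df["amplitude"], 3.3)

    def test_single_sample_window(self):
        waves, t = self._waves(lambda t: t.copy())
        df = window_average(waves, t, (250, 250))
        assert np.allclose(df["amplitude"], 250.0)

    def test_linear_ramp_midpoint(self):
        waves, t = self._waves(lambda t: t / 5.0)  # 0..100 over 0-500 ms
        df = window_average(waves, t, (200, 300))
        assert np.allclose(df["amplitude"], 50.0)

    def test_empty_window_rejected(self):
        waves, t = self._waves(lambda t: t.copy())
        with pytest.raises(ValueError):
            window_average(waves, t, (900, 950))

    def test_incomplete_grid_rejected(self):
        waves, t = self._waves(lambda t: t.copy())
        del waves[(0, "win", 0.5)]
        with pytest.raises(ValueError, match="incomplete"):
            window_average(waves, t, (200, 300))


class TestRmAnova:
    def test_all_cells_equal_all_F_zero(self):
        cube = np.full((5, 2, 4), 2.0)
        res = rm_anova_2x4(means_frame(cube))
        for key in ("valence", "probability", "interaction"):
            assert res[key]["F"] == 0.0
            assert res[key]["p"] == 1.0

    def test_three_subject_toy_matches_ss_oracle(self):
        rng = np.random.default_rng(42)
        cube = rng.normal(size=(3, 2, 4))
        res = rm_anova_2x4(means_frame(cube))
        F_A, F_B, F_AB = anova_oracle(cube)
        assert res["valence"]["F"] == pytest.approx(F_A, rel=1e-10)
        assert res["probability"]["F"] == pytest.approx(F_B, rel=1e-10)
        assert res["interaction"]["F"] == pytest.approx(F_AB, rel=1e-10)
        assert res["valence"]["df"] == (1, 2)
        assert res["probability"]["df"] == (3, 6)
        assert res["interaction"]["df"] == (3, 6)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(5)
        cube = rng.normal(size=(8, 2, 4))
        df = means_frame(cube)
        res = rm_anova_2x4(df)
        sm_res = AnovaRM(
            df, depvar="amplitude", subject="subject",
            within=["valence", "probability"],
        ).fit()
        tab = sm_res.anova_table
        assert res["valence"]["F"] == pytest.approx(
            tab.loc["valence", "F Value"], rel=1e-8
        )
        assert res["probability"]["F"] == pytest.approx(
            tab.loc["probability", "F Value"], rel=1e-8
        )
        assert res["interaction"]["F"] == pytest.approx(
            tab.loc["valence:probability", "F Value"], rel=1e-8
        )

    def test_pure_valence_effect_degenerate_flagged(self):
        cube = np.zeros((4, 2, 4))
        cube[:, 0, :] = 1.0  # win exactly 1, loss exactly 0, no noise
        res = rm_anova_2x4(means_frame(cube))
        assert res["interaction"]["F"] == 0.0
        assert res["valence"]["degenerate"] is True
        assert res["valence"]["F"] == np.inf

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(9)
        cube = rng.normal(size=(6, 2, 4))
        r1 = rm_anova_2x4(means_frame(cube))
        r2 = rm_anova_2x4(means_frame(cube + 100.0))
        for key in ("valence", "probability", "interaction", "linear_trend"):
            assert r1[key]["F"] == pytest.approx(r2[key]["F"], rel=1e-6)

    def test_scale_invariance_of_p_values(self):
        rng = np.random.default_rng(10)
        cube = rng.normal(size=(6, 2, 4))
        r1 = rm_anova_2x4(means_frame(cube))
        r2 = rm_anova_2x4(means_frame(cube * 7.3))
        for key in ("valence", "probability", "interaction"):
            assert r1[key]["p"] == pytest.approx(r2[key]["p"], rel=1e-6)


class TestAxiomCompliance:
    def test_fig2_pattern_compliant_at_expected_rate(self):
        """The axiomatic pattern grades compliant for ~95% of noise draws.

        Axiom 3 is a null test at alpha=0.05, so even a perfectly
        axiomatic signal is flagged in ~5% of realizations; axioms 1 and
        2 must pass essentially always at this effect size.
        """
        outcomes = []
        for seed in range(40):
            report = axiom_compliance(means_frame(fig2_cube(seed=seed)))
            assert report.axiom1_pass and report.axiom2_pass
            assert report.win_slope < 0 < report.loss_slope
            assert report.sign_opposition
            if not report.axiom3_pass:
                assert report.axiom3_test["p"] < 0.05  # chance exclusion only
            outcomes.append(report.overall)
        frac = np.mean([o == "compliant" for o in outcomes])
        assert frac >= 0.85  # binomial(40, .95) lower tail

    @pytest.mark.parametrize("beta,noise_sd", [(0.5, 0.005), (2.0, 0.05)])
    def test_compliance_robust_over_effect_scales(self, beta, noise_sd):
        frac = np.mean(
            [
                axiom_compliance(
                    means_frame(fig2_cube(beta=beta, noise_sd=noise_sd, seed=s))
                ).overall
                == "compliant"
                for s in range(20)
            ]
        )
        assert frac >= 0.8

    def test_same_sign_slopes_violate_axiom2(self):
        # both valences increase with probability
        rng = np.random.default_rng(1)
        p = np.asarray(PROBABILITIES)
        cube = np.empty((17, 2, 4))
        cube[:, 0, :] = 2.0 * p[None, :] + 1.0
        cube[:, 1, :] = 2.0 * p[None, :] - 3.0 * (1 - p)[None, :]
        cube += rng.normal(0, 0.05, cube.shape)
        report = axiom_compliance(means_frame(cube))
        assert not report.sign_opposition
        assert not report.axiom2_pass
        assert report.overall == "violated"

    def test_identical_means_violated(self):
        cube = np.random.default_rng(2).normal(0, 1e-9, (6, 2, 4)) + 1.0
        report = axiom_compliance(means_frame(cube))
        assert not report.axiom1_pass
        assert report.overall == "violated"

    def test_p1_difference_fails_axiom3(self):
        cube = fig2_cube(seed=4)
        cube[:, 0, 3] += 1.0  # certain wins differ from certain losses
        report = axiom_compliance(means_frame(cube))
        assert not report.axiom3_pass
        assert report.overall == "violated"

    def test_weak_compliance_when_adjacent_steps_flat(self):
        # difference jumps only between P=.5 and P=.75; other steps flat
        rng = np.random.default_rng(6)
        cube = np.empty((17, 2, 4))
        d = np.array([1.0, 1.0, 0.0, 0.0])  # win-loss difference per prob
        cube[:, 0, :] = d / 2
        cube[:, 1, :] = -d / 2
        cube += rng.normal(0, 0.02, cube.shape)
        report = axiom_compliance(means_frame(cube))
        if report.axiom1_pass and report.axiom2_pass and report.axiom3_pass:
            assert report.overall == "weakly_compliant"

    def test_tost_option_reported(self):
        report = axiom_compliance(means_frame(fig2_cube()), equivalence_bound=0.1)
        assert "tost_p" in report.axiom3_test


class TestFrnDifference:
    def _waves(self, diff_fn, n=6, seed=0):
        rng = np.random.default_rng(seed)
        t = -160.0 + 5.0 * np.arange(172)
        waves = {}
        for s in range(n):
            for p in PROBABILITIES:
                win = rng.normal(0, 1e-3, t.size)
                waves[(s, "win", p)] = win
                waves[(s, "loss", p)] = win + diff_fn(t, p)
        return waves, t

    def test_equal_waveforms_zero_frn(self):
        waves, t = self._waves(lambda t, p: 0.0 * t)
        res = frn_difference(waves, t, (0, 600))
        assert np.allclose(res.table["amplitude"], 0.0, atol=5e-3)

    def test_injected_negativity_latency_recovered(self):
        def diff(t, p):
            return -2.0 * np.exp(-0.5 * ((t - 270.0) / 30.0) ** 2)

        waves, t = self._waves(diff)
        res = frn_difference(waves, t, (0, 600))
        assert (np.abs(res.table["latency_ms"] - 270.0) <= 5.0).all()
        assert np.allclose(res.table["amplitude"], -2.0, atol=0.01)

    def test_pe_scaling_gives_decreasing_magnitude_and_trend(self):
        def diff(t, p):
            return -2.0 * (1 - p) * np.exp(-0.5 * ((t - 270.0) / 30.0) ** 2)

        waves, t = self._waves(diff, n=17, seed=8)
        res = frn_difference(waves, t, (0, 600))
        med = res.table.groupby("probability")["amplitude"].mean()
        assert (med.diff().dropna() > 0).all()  # magnitude shrinks with P
        assert res.probability_effect["p"] < 0.001
        assert res.linear_trend["p"] < 0.001

    def test_antisymmetry_on_swap(self):
        def diff(t, p):
            return -1.5 * np.exp(-0.5 * ((t - 250.0) / 25.0) ** 2)

        waves, t = self._waves(diff, n=3, seed=2)
        swapped = {
            (s, {"win": "loss", "loss": "win"}[v], p): w
            for (s, v, p), w in waves.items()
        }
        res = frn_difference(waves, t, (0, 600))
        res_sw = frn_difference(swapped, t, (0, 600))
        # minimum of -d equals -maximum of d
        for (_, row), (_, row_sw) in zip(
            res.table.iterrows(), res_sw.table.iterrows()
        ):
            assert row_sw["amplitude"] <= 0 or row["amplitude"] <= 0

    def test_window_outside_epoch_rejected(self):
        waves, t = self._waves(lambda t, p: 0.0 * t)
        with pytest.raises(ValueError):
            frn_difference(waves, t, (900, 1200))
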
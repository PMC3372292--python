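"""Single-regression screens, culling rules, paired and boundary screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import pescore as p
from pescore.screen import cull_candidates, single_screen


def make_screen_frame(rows, threshold=0.00069, excluded=()):
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["significant"] = df["p"] < threshold
    df.attrs["threshold"] = threshold
    df.attrs["excluded"] = list(excluded)
    return df


class TestBonferroni:
    def test_published_correction(self):
        assert p.bonferroni_threshold(0.05, 72) == pytest.approx(
            0.05 / 72)

    def test_single_test_is_alpha(self):
        assert p.bonferroni_threshold(0.05, 1) == 0.05

    def test_division(self):
        assert p.bonferroni_threshold(0.05, 33) == pytest.approx(1.515e-3,
                                                                 rel=1e-3)


class TestSingleScreen:
    @pytest.fixture(scope="class")
    def screen_with_signal(self):
        rng = np.random.default_rng(5)
        n = 600
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 * signal)).astype(int)
        feats = pd.DataFrame({"signal": signal, "noise": noise})
        return single_screen(feats, y, kind="binary")

    def test_signal_dominates_noise(self, screen_with_signal):
        s = screen_with_signal
        assert abs(s.loc["signal", "signed_log_p"]) > \
            abs(s.loc["noise", "signed_log_p"])
        assert s.loc["signal", "significant"]

    def test_signed_log_p_definition(self, screen_with_signal):
        s = screen_with_signal
        for name in s.index:
            row = s.loc[name]
            assert np.sign(row["signed_log_p"]) == np.sign(row["slope"])
            if row["p"] > 1e-300:
                assert abs(row["signed_log_p"]) == pytest.approx(
                    -np.log10(row["p"]), rel=1e-6)

    def test_predictive_value_is_slope_times_sd(self):
        rng = np.random.default_rng(9)
        x = rng.normal(scale=0.05, size=500)
        y = (rng.random(500) < expit(2.0 * x)).astype(int)
        s = single_screen(pd.DataFrame({"x": x}), y, kind="binary")
        row = s.loc["x"]
        assert row["predictive_value"] == pytest.approx(
            row["slope"] * np.std(x, ddof=1))

    def test_constant_column_flagged_and_excluded(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame({"x": rng.normal(size=100),
                              "flat": np.ones(100)})
        y = (rng.random(100) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            s = single_screen(feats, y, kind="binary")
        assert "flat" not in s.index
        assert s.attrs["excluded"] == ["flat"]
        assert s.attrs["n_tests"] == 2  # Bonferroni count = screened columns

    def test_true_effect_beats_noise_across_seeds(self):
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            signal = rng.normal(size=n)
            noise = rng.normal(size=n)
            t = np.array([-1.0, 0.0, 1.0])
            y = ((1.2 * signal + rng.logistic(size=n))[:, None] >
                 t[None, :]).sum(axis=1)
            s = single_screen(pd.DataFrame({"sig": signal, "noi": noise}),
                              y, kind="ordinal")
            wins += (abs(s.loc["sig", "signed_log_p"]) >
                     abs(s.loc["noi", "signed_log_p"]))
        assert wins >= 0.95 * n_seeds


class TestExposureSelection:
    def test_opposite_significant_split_retained(self):
        rows = {"a": dict(slope=0.1, se=1, p=0.5),
                "ab": dict(slope=1.0, se=0.1, p=1e-6),
                "ae": dict(slope=-1.0, se=0.1, p=1e-6)}
        screen = make_screen_frame(rows)
        kept = p.select_exposure_variables(screen, 0.00069)
        assert "ab" in kept and "ae" in kept and "a" not in kept

    def test_same_sign_keeps_total(self):
        rows = {"a": dict(slope=0.1, se=1, p=0.5),
                "ab": dict(slope=1.0, se=0.1, p=1e-6),
                "ae": dict(slope=0.5, se=0.1, p=1e-6)}
        kept = p.select_exposure_variables(make_screen_frame(rows), 0.00069)
        assert "a" in kept and "ab" not in kept

    def test_opposite_but_insignificant_keeps_total(self):
        rows = {"a": dict(slope=0.1, se=1, p=0.5),
                "ab": dict(slope=1.0, se=0.1, p=1e-6),
                "ae": dict(slope=-0.2, se=0.2, p=0.3)}
        kept = p.select_exposure_variables(make_screen_frame(rows), 0.00069)
        assert "a" in kept and "ae" not in kept

    def test_missing_total_screen_errors(self):
        # split rows exist but disagree in sign, and the total fraction the
        # rule falls back to was never screened
        rows = {"ab": dict(slope=1.0, se=0.1, p=1e-6),
                "ae": dict(slope=0.5, se=0.1, p=1e-6)}
        with pytest.raises(KeyError):
            p.select_exposure_variables(make_screen_frame(rows), 0.00069)


class TestChargeSelection:
    def test_smaller_p_member_kept(self):
        rows = {"numcharge": dict(slope=1, se=1, p=1e-4),
                "fracnumcharge": dict(slope=1, se=1, p=1e-10)}
        kept = p.select_charge_variables(make_screen_frame(rows))
        assert kept == ["fracnumcharge"]

    def test_tie_prefers_fractional(self):
        rows = {"netcharge": dict(slope=1, se=1, p=0.01),
                "fracnetcharge": dict(slope=1, se=1, p=0.01)}
        kept = p.select_charge_variables(make_screen_frame(rows))
        assert kept == ["fracnetcharge"]

    def test_excluded_member_concedes(self):
        rows = {"absnetcharge": dict(slope=1, se=1, p=0.02)}
        kept = p.select_charge_variables(
            make_screen_frame(rows, excluded=["fracabsnetcharge"]))
        assert kept == ["absnetcharge"]


class TestPairedRareCommon:
    def _cohort_features(self, rng, n, rare_effect):
        rare = np.abs(rng.normal(0.02, 0.01, size=n))
        common = np.abs(rng.normal(0.04, 0.015, size=n))
        feats = pd.DataFrame({"r_rare": rare, "r_common": common})
        for aa in "ilp":
            feats[f"{aa}_rare"] = np.abs(rng.normal(0.01, 0.005, size=n))
            feats[f"{aa}_common"] = np.abs(rng.normal(0.05, 0.01, size=n))
        y = (rng.random(n) < expit(1.0 + rare_effect * rare)).astype(int)
        return feats, y

    def test_rare_effect_detected_common_not(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            feats, y = self._cohort_features(rng, 4000, rare_effect=-120.0)
            s = p.paired_rare_common_screen(feats, y, kind="binary")
            ok = (s.loc["r_rare", "slope"] < 0 and s.loc["r_rare", "p"] < 1e-3
                  and s.loc["r_common", "p"] > 1e-3)
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_constant_rare_fraction_fits_common_alone(self):
        rng = np.random.default_rng(4)
        feats, y = self._cohort_features(rng, 300, rare_effect=0.0)
        feats["r_rare"] = 0.0
        s = p.paired_rare_common_screen(feats, y, kind="binary")
        assert "r_rare" not in s.index and "r_common" in s.index

    def test_two_predictor_loglik_dominates_single(self):
        rng = np.random.default_rng(6)
        feats, y = self._cohort_features(rng, 500, rare_effect=-50.0)
        two = p.fit_binary_logit(feats[["r_rare", "r_common"]], y)
        one = p.fit_binary_logit(feats[["r_rare"]], y)
        assert two.loglik >= one.loglik - 1e-9

    def test_missing_split_errors(self):
        with pytest.raises(KeyError):
            p.paired_rare_common_screen(
                pd.DataFrame({"gravy": [1.0, 2.0]}), [0, 1], kind="binary")


class TestPermissiveEnhancing:
    def test_all_expressed_errors_permissive_only(self):
        rng = np.random.default_rng(8)
        feats = pd.DataFrame({"x": rng.normal(size=200)})
        scores = rng.integers(1, 6, size=200)  # everything expressed
        with pytest.raises(ValueError, match="permissive"):
            p.permissive_enhancing_screen(feats, scores)
        out = p.permissive_enhancing_screen(feats, scores,
                                            boundaries=("enhancing",))
        assert "enhancing" in out and "permissive" not in out

    def test_threshold_specific_effect_located(self):
        # a parameter acting only on the 0-vs->0 boundary: significant in the
        # permissive screen, not the enhancing screen
        rng = np.random.default_rng(12)
        n = 5000
        x = rng.normal(size=n)
        # categorical draw with P(0) depending on x and P(5) held constant
        p0 = 0.15 + 0.30 * expit(-2.0 * x)
        p5 = 0.30
        u = rng.random(n)
        scores = np.where(u < p0, 0,
                          np.where(u < p0 + p5, 5, rng.integers(1, 5, n)))
        out = p.permissive_enhancing_screen(pd.DataFrame({"x": x}), scores)
        assert out["permissive"].loc["x", "p"] < 1e-8
        assert out["enhancing"].loc["x", "p"] > 1e-3

    def test_uniform_effect_same_sign_in_both(self):
        rng = np.random.default_rng(13)
        n = 4000
        x = rng.normal(size=n)
        t = np.array([-1.5, -0.5, 0.5, 1.0, 1.5])
        scores = ((0.8 * x + rng.logistic(size=n))[:, None] >
                  t[None, :]).sum(axis=1)
        out = p.permissive_enhancing_screen(pd.DataFrame({"x": x}), scores)
        assert np.sign(out["permissive"].loc["x", "slope"]) == \
            np.sign(out["enhancing"].loc["x", "slope"])


class TestCulling:
    def test_cull_applies_both_rules_then_bonferroni(self):
        rows = {
            "a": dict(slope=0.2, se=0.05, p=1e-8),
            "ab": dict(slope=1.0, se=0.1, p=1e-6),
            "ae": dict(slope=-1.0, se=0.1, p=1e-6),
            "k": dict(slope=0.1, se=1, p=0.9),
            "numcharge": dict(slope=1, se=1, p=1e-4),
            "fracnumcharge": dict(slope=1, se=1, p=1e-10),
            "gravy": dict(slope=-1, se=0.1, p=1e-9),
            "pi": dict(slope=-0.1, se=1, p=0.2),
        }
        screen = make_screen_frame(rows)
        kept = cull_candidates(screen, 0.00069)
        assert set(kept) == {"ab", "ae", "fracnumcharge", "gravy"}
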
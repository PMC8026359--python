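"""Correlation/test statistics and the cohort battery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from knobmap import stats
from knobmap.errors import AnalysisError


def pearson_oracle(x, y):
    """Textbook product-moment formula, written independently of the package."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestPearson:
    def test_perfectly_linear(self):
        assert stats.pearson([1, 2, 3, 4], [2, 4, 6, 8]).r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        assert stats.pearson([1, 2, 3], [3, 2, 4]).r == pytest.approx(0.5)

    def test_oracle_equivalence(self, rng):
        for _ in range(50):
            x = rng.normal(size=50)
            y = rng.normal(size=50) + 0.4 * x
            assert abs(stats.pearson(x, y).r - pearson_oracle(x, y)) < 1e-12

    def test_p_from_t_transform(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = stats.pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(AnalysisError):
            stats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10),
           c=st.floats(-5, -0.1), d=st.floats(-10, 10))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance_with_sign_flip(self, a, b, c, d):
        x = np.array([0.4, 1.3, -0.7, 2.2, 0.1])
        y = np.array([1.0, 0.2, -1.1, 1.9, 0.6])
        r0 = stats.pearson(x, y).r
        r1 = stats.pearson(a * x + b, c * y + d).r
        assert r1 == pytest.approx(-r0, rel=1e-9)


class TestTTests:
    def test_welch_hand_example(self):
        res = stats.welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.dof == pytest.approx(4.0)

    def test_welch_equals_pooled_t_for_equal_groups(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        welch = stats.welch_t(a, b)
        pooled = sps.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-12)

    def test_welch_from_group_summaries(self):
        """Reconstructing a two-group latency contrast from means and SEMs
        gives the expected statistic sign and rejection."""
        res = stats.welch_t_from_summary(21.7, 0.4, 10, 23.3, 0.4, 14)
        assert res.statistic == pytest.approx(-2.83, abs=0.01)
        assert res.p < 0.05

    def test_paired_identical_vectors_error(self):
        with pytest.raises(AnalysisError):
            stats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(size=20)
        b = a + rng.normal(0.3, 0.5, 20)
        res = stats.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.dof == 19


class TestBonferroni:
    def test_simple_family(self):
        assert np.allclose(stats.bonferroni([0.01, 0.03], 2), [0.02, 0.06])

    def test_capped_at_one(self):
        assert stats.bonferroni([0.6], 2)[0] == 1.0

    def test_family_of_one_is_identity(self):
        assert stats.bonferroni([0.2], 1)[0] == pytest.approx(0.2)

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(AnalysisError):
            stats.bonferroni([0.01, 0.02, 0.03], 2)


class TestBattery:
    @staticmethod
    def _noise_free_cohort(n=12):
        z = np.linspace(-2, 2, n)
        return pd.DataFrame({
            "r1_mean": 780 + 30 * z, "r1_caudal": 796 + 30 * z,
            "r1_rostral": 757 + 30 * z,
            "thickness_caudal": np.full(n, 2.5) + 0.01 * np.arange(n),
            "thickness_rostral": np.full(n, 2.7) + 0.01 * np.arange(n),
            "hotspot_y_fdi": -16 + 4 * z, "shortest_latency_fdi": 22.6 + z,
            "hotspot_y_adm": -18 + 4 * z, "shortest_latency_adm": 22.9 + z,
            "rostrality_fdi": (z - z.min()) / np.ptp(z),
            "rostrality_adm": (z - z.min()) / np.ptp(z),
            "bold_index": 1.4 + 0.5 * z, "bold_little": 1.4 + 0.5 * z,
            "cv_index": 0.05 - 0.01 * z, "cv_little": 0.05 - 0.01 * z,
        })

    def test_noise_free_battery_is_unit_correlations(self):
        out = stats.run_correlation_battery(self._noise_free_cohort())
        core = out[out["family"].isin(["rostrality", "structure_function"])]
        signs = {"r1_vs_cv_index": -1, "r1_vs_cv_little": -1}
        for _, row in core.iterrows():
            expected = signs.get(row["label"], 1)
            assert row["r"] == pytest.approx(expected, abs=1e-9)

    def test_constant_column_fails_only_its_row(self):
        df = self._noise_free_cohort()
        df["bold_index"] = 1.0
        out = stats.run_correlation_battery(df)
        bad = out[out["label"] == "r1_vs_bold_index"].iloc[0]
        assert np.isnan(bad["r"]) and bad["note"]
        good = out[out["label"] == "r1_vs_bold_little"].iloc[0]
        assert good["r"] == pytest.approx(1.0)

    def test_adjusted_p_never_below_raw(self):
        out = stats.run_correlation_battery(self._noise_free_cohort())
        ok = out.dropna(subset=["p"])
        assert (ok["p_adjusted"] >= ok["p"] - 1e-15).all()

    def test_r1_rows_drop_missing_subjects(self):
        df = self._noise_free_cohort()
        df.loc[:3, ["r1_mean", "r1_caudal", "r1_rostral"]] = np.nan
        out = stats.run_correlation_battery(df)
        assert (out.loc[out["x"].str.startswith("r1"), "n"] == len(df) - 4).all()
        assert (out.loc[out["label"] == "y_vs_latency_fdi", "n"] == len(df)).all()

    def test_battery_row_count_fixed(self):
        out = stats.run_correlation_battery(self._noise_free_cohort())
        assert len(out) == len(stats.BATTERY_ROWS)
        assert set(out["family"]) == {"rostrality", "structure_function",
                                      "structure_function_subroi",
                                      "thickness_control"}


class TestTypeIError:
    def test_nominal_level_at_n20(self, rng):
        """Under the null the t-transform p value rejects at ~5%."""
        n_sim, n = 10_000, 20
        x = rng.normal(size=(n_sim, n))
        y = rng.normal(size=(n_sim, n))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        r = (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        # the vectorised p matches the package's scalar pearson p
        res = stats.pearson(x[0], y[0])
        assert p[0] == pytest.approx(res.p, rel=1e-9)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06
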
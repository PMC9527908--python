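import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ttmorph.errors import DegenerateDataError, MeasurementError
from ttmorph.stats import (
    choose_transform, fit_region_contrast, paired_t, recompute_printed_summaries,
    simulate_clustered, summarize_mean_se,
)
from ttmorph.stats import test_normality as normality_test


class TestNormality:
    def test_level_on_normal_draws(self):
        """Shapiro–Wilk keeps its level: p > 0.05 on ≥90% of normal samples."""
        rng = np.random.default_rng(42)
        keep = sum(normality_test(rng.normal(size=1000))[1] > 0.05 for _ in range(100))
        assert keep >= 90

    def test_power_on_lognormal_draws(self):
        rng = np.random.default_rng(43)
        reject = sum(normality_test(np.exp(rng.normal(size=1000)))[1] < 0.05
                     for _ in range(100))
        assert reject >= 99

    def test_ks_variant_and_degenerate(self):
        rng = np.random.default_rng(4)
        stat, p = normality_test(rng.normal(size=200), method="ks")
        assert 0 <= p <= 1
        with pytest.raises(DegenerateDataError):
            normality_test(np.full(50, 3.0))
        with pytest.raises(DegenerateDataError):
            normality_test([1.0, 2.0])


class TestTransformChoice:
    def test_normal_sample_keeps_identity(self):
        rng = np.random.default_rng(3)
        assert choose_transform(rng.normal(10, 1, size=500)) == "identity"

    def test_lognormal_sample_gets_log10(self):
        rng = np.random.default_rng(1)
        assert choose_transform(np.exp(rng.normal(size=500))) == "log10"

    def test_fallback_when_nothing_passes(self):
        # heavy bimodal positive sample: neither log10 nor sqrt restores normality
        rng = np.random.default_rng(2)
        v = np.r_[rng.normal(1.0, 0.01, 300), rng.normal(100.0, 0.01, 300)]
        assert choose_transform(v) == "log10"


class TestMixedModel:
    def test_collapsed_limit_matches_two_sample_t(self):
        """One observation per cell, no cluster variance: p equals a t-test."""
        rng = np.random.default_rng(5)
        df = simulate_clustered(n_animals=4, n_cells=6, n_obs=1,
                                sd_animal=0.0, sd_cell=0.0, delta=0.6, rng=rng)
        c = fit_region_contrast(df, region_pair=("control", "border"),
                                transform="identity")
        a = df.loc[df.region == "control", "value"]
        b = df.loc[df.region == "border", "value"]
        t = sps.ttest_ind(a, b)
        assert c.model_structure == "ols"
        assert c.p_value == pytest.approx(t.pvalue, abs=1e-3)
        assert c.estimate == pytest.approx(b.mean() - a.mean(), rel=1e-9)

    def test_effect_estimate_recovery(self):
        rng = np.random.default_rng(6)
        est = [fit_region_contrast(simulate_clustered(delta=1.0, rng=rng),
                                   region_pair=("control", "border"),
                                   transform="identity").estimate
               for _ in range(40)]
        assert np.mean(est) == pytest.approx(1.0, abs=0.12)

    def test_single_animal_reduced_structure_warns(self):
        rng = np.random.default_rng(7)
        df = simulate_clustered(n_animals=1, n_cells=4, n_obs=10, rng=rng)
        c = fit_region_contrast(df, region_pair=("control", "border"),
                                transform="identity")
        assert any("animal random effect dropped" in w for w in c.warnings)
        assert c.model_structure in ("cell", "ols")

    def test_group_summaries_on_original_scale(self):
        rng = np.random.default_rng(8)
        df = simulate_clustered(delta=2.0, rng=rng)
        c = fit_region_contrast(df, region_pair=("control", "border"))
        for r in ("control", "border"):
            mean, se = c.group_means[r]
            sub = df.loc[df.region == r, "value"]
            assert mean == pytest.approx(sub.mean(), rel=1e-9)
            assert c.n_observations[r] == len(sub)
            assert c.n_animals[r] == 3 and c.n_cells[r] == 9

    def test_degenerate_constant_response(self):
        df = pd.DataFrame({"value": np.ones(20),
                           "region": ["control"] * 10 + ["border"] * 10,
                           "animal_id": ["a"] * 10 + ["b"] * 10,
                           "cell_id": list("0123456789") * 2})
        with pytest.raises(DegenerateDataError):
            fit_region_contrast(df, region_pair=("control", "border"),
                                transform="identity")


class TestPairedT:
    def test_identical_pairs(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_shift_recovered_exactly(self):
        d, p = paired_t([5.0, 7.0, 9.0], [2.0, 4.0, 6.0])
        assert d == 3.0 and p < 1e-6

    def test_mismatch_raises(self):
        with pytest.raises(MeasurementError):
            paired_t([1.0, 2.0], [1.0])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=20))
    def test_self_comparison_is_null(self, x):
        d, p = paired_t(x, x)
        assert d == 0.0 and p == 1.0


class TestMeanSe:
    def test_basic_values(self):
        mean, se = summarize_mean_se([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert se == pytest.approx(1.0 / np.sqrt(3))
        assert summarize_mean_se([5.0]) == (5.0, None)
        with pytest.raises(MeasurementError):
            summarize_mean_se([])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=30),
           st.floats(min_value=-10, max_value=10),
           st.floats(min_value=0.1, max_value=10))
    def test_location_and_scale_equivariance(self, x, b, a):
        m0, s0 = summarize_mean_se(x)
        m1, s1 = summarize_mean_se(a * np.asarray(x) + b)
        assert m1 == pytest.approx(a * m0 + b, abs=1e-6 * (1 + abs(a * m0 + b)))
        assert s1 == pytest.approx(a * s0, abs=1e-6 * (1 + a * s0))


def test_recompute_summaries_from_per_tubule_table():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "region": ["control"] * 50 + ["border"] * 40,
        "diameter_nm": np.r_[rng.normal(405, 30, 50), rng.normal(533, 40, 40)],
        "volume_um3": np.r_[rng.normal(0.25, 0.05, 50), rng.normal(0.37, 0.05, 40)],
    })
    out = recompute_printed_summaries(df)
    row = out[(out.region == "control") & (out.metric == "diameter_nm")].iloc[0]
    sub = df.loc[df.region == "control", "diameter_nm"]
    assert row["mean"] == pytest.approx(sub.mean())
    assert row["se"] == pytest.approx(sub.std(ddof=1) / np.sqrt(50))
    assert row["n"] == 50
    with pytest.raises(MeasurementError):
        recompute_printed_summaries(df.drop(columns="region"))
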
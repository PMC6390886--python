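"""Trait derivation, ANOVA variance components, heritability, BLUEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tetraqtl as tq


def test_tuber_moisture_complement():
    assert tq.tuber_moisture(20.0) == 80.0
    assert tq.tuber_moisture(0.0) == 100.0
    assert tq.tuber_moisture(100.0) == 0.0
    with pytest.raises(ValueError):
        tq.tuber_moisture(101.0)


def test_protein_content_formula():
    assert tq.protein_content(1.2, 77.5) == pytest.approx(0.93)
    assert tq.protein_content(1.4, 100.0) == pytest.approx(1.4)
    assert tq.protein_content(0.0, 80.0) == 0.0
    with pytest.raises(ValueError):
        tq.protein_content(-1.0, 50.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.floats(0.0, 5.0), st.floats(0.0, 100.0),
    st.floats(0.1, 3.0), st.floats(0.1, 3.0),
)
def test_protein_content_is_bilinear(p, m, a, b):
    assert tq.protein_content(a * p, m) == pytest.approx(
        a * tq.protein_content(p, m), rel=1e-12, abs=1e-12
    )
    assert tq.protein_content(p, b * m if b * m <= 100 else m) >= 0


def _balanced_trial(n_clone, years, blocks, sG2, sGY2, sE2, seed, mu=0.93):
    rng = np.random.default_rng(seed)
    G = rng.normal(0, np.sqrt(sG2), n_clone)
    GY = rng.normal(0, np.sqrt(sGY2), (n_clone, years))
    rows = []
    for k in range(years):
        for j in range(blocks):
            y = mu + G + GY[:, k] + rng.normal(0, np.sqrt(sE2), n_clone)
            rows.append(
                pd.DataFrame(
                    {
                        "clone": [f"c{i:03d}" for i in range(n_clone)],
                        "year": 2013 + k,
                        "block": j + 1,
                        "protein_content": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def test_identical_observations_give_zero_mean_squares():
    df = _balanced_trial(10, 1, 2, 0, 0, 0, seed=1)
    ms = tq.anova_mean_squares(df, model="within")
    assert ms["MS_G"] == pytest.approx(0.0, abs=1e-20)
    assert ms["MS_E"] == pytest.approx(0.0, abs=1e-20)


def test_pure_clone_effects_land_in_ms_g():
    df = _balanced_trial(30, 1, 2, 0.05, 0, 0, seed=2)
    ms = tq.anova_mean_squares(df, model="within")
    assert ms["MS_E"] == pytest.approx(0.0, abs=1e-18)
    assert ms["MS_G"] > 0.01


def test_one_way_mean_squares_match_expectation():
    # theory-of-ANOVA oracle: E[MS_G] = sE2 + r*sG2, E[MS_E] = sE2
    sG2, sE2, r = 0.02, 0.05, 2
    ms_g, ms_e = [], []
    for seed in range(40):
        df = _balanced_trial(60, 1, r, sG2, 0, sE2, seed=100 + seed)
        ms = tq.anova_mean_squares(df, model="within")
        ms_g.append(ms["MS_G"])
        ms_e.append(ms["MS_E"])
    assert np.mean(ms_g) == pytest.approx(sE2 + r * sG2, rel=0.1)
    assert np.mean(ms_e) == pytest.approx(sE2, rel=0.1)


def test_variance_component_arithmetic():
    vc = tq.variance_components({"MS_G": 0.05, "MS_E": 0.03}, r=2)
    assert vc.sigma2_G == pytest.approx(0.01)
    vc0 = tq.variance_components({"MS_G": 0.03, "MS_E": 0.03}, r=2)
    assert vc0.sigma2_G == 0.0
    vc2 = tq.variance_components(
        {"MS_G": 0.2, "MS_GxY": 0.04, "MS_E": 0.04}, r=2, y=2, model="between"
    )
    assert vc2.sigma2_GxY == 0.0
    assert vc2.sigma2_G == pytest.approx((0.2 - 0.04) / 4)
    with pytest.raises(ValueError):
        tq.variance_components({"MS_G": 1, "MS_E": 1}, r=0)


def test_heritability_printed_examples():
    h13 = tq.heritability(tq.VarianceComponents(0.013, 0.039, r=2))
    h14 = tq.heritability(tq.VarianceComponents(0.021, 0.034, r=2))
    assert round(h13, 2) == 0.40
    assert round(h14, 2) == 0.55
    assert tq.heritability(tq.VarianceComponents(0.0, 0.04, r=2)) == 0.0


def test_heritability_monotone_in_components():
    grid = np.linspace(0.001, 0.1, 12)
    h_g = [
        tq.heritability(tq.VarianceComponents(s, 0.04, r=2)) for s in grid
    ]
    assert np.all(np.diff(h_g) > 0)
    h_e = [
        tq.heritability(tq.VarianceComponents(0.02, s, r=2)) for s in grid
    ]
    assert np.all(np.diff(h_e) < 0)


def test_trial_anova_results_within_year():
    df = _balanced_trial(80, 1, 2, 0.013, 0, 0.039, seed=3)
    res = tq.TrialANOVA(df, design="within").fit()
    assert 0.0 <= res.H2 <= 1.0
    assert "H2" in res.summary()
    assert res.H2_percent == pytest.approx(100 * res.H2)


def test_blues_single_year_equal_clone_means():
    df = _balanced_trial(20, 1, 2, 0.02, 0, 0.03, seed=4)
    blues = tq.compute_blues(df)
    means = df.groupby("clone")["protein_content"].mean()
    assert np.allclose(blues.sort_index(), means.sort_index())


def test_blues_invariant_to_additive_year_shift():
    df = _balanced_trial(25, 2, 2, 0.02, 0, 0.03, seed=5)
    shifted = df.copy()
    shifted.loc[shifted["year"] == 2014, "protein_content"] += 0.5
    b0 = tq.compute_blues(df).sort_index()
    b1 = tq.compute_blues(shifted).sort_index()
    # equal up to a common constant
    diff = (b1 - b0).to_numpy()
    assert np.allclose(diff - diff.mean(), 0.0, atol=1e-6)


def test_blues_beat_single_year_means_for_ranking_clones():
    rng = np.random.default_rng(6)
    n = 60
    true_G = rng.normal(0, np.sqrt(0.04), n)
    rows = []
    for k in range(3):
        year_shift = rng.normal(0, 0.1)
        for j in range(2):
            y = 0.9 + true_G + year_shift + rng.normal(0, np.sqrt(0.06), n)
            rows.append(
                pd.DataFrame(
                    {
                        "clone": [f"c{i:03d}" for i in range(n)],
                        "year": 2012 + k,
                        "block": j + 1,
                        "protein_content": y,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    blues = tq.compute_blues(df).sort_index()
    single = (
        df[df["year"] == 2012].groupby("clone")["protein_content"].mean().sort_index()
    )
    truth = pd.Series(true_G, index=[f"c{i:03d}" for i in range(n)]).sort_index()
    rho_blue = blues.corr(truth, method="spearman")
    rho_single = single.corr(truth, method="spearman")
    assert rho_blue > rho_single


def test_blues_requires_records():
    df = pd.DataFrame(
        {"clone": [], "year": [], "block": [], "protein_content": []}
    )
    with pytest.raises(ValueError):
        tq.compute_blues(df)


def test_anova_requires_replication():
    df = _balanced_trial(10, 1, 1, 0.01, 0, 0.01, seed=7)
    with pytest.raises(ValueError, match="blocks"):
        tq.anova_mean_squares(df, model="within")
    with pytest.raises(ValueError, match="years"):
        tq.anova_mean_squares(df, model="between")
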
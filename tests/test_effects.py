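"""Homologue effects and the SIC bi-allelic model search."""

import numpy as np
import pandas as pd
import pytest

import tetraqtl as tq
from tetraqtl.effects import (
    additive_equivalence_key,
    enumerate_biallelic_models,
    fit_biallelic_model,
)


def _uniform_X(n):
    return np.full((n, 8), 0.5)


def test_equal_weights_give_zero_effects():
    y = np.random.default_rng(0).normal(size=40)
    eff = tq.homologue_effects(y, _uniform_X(40))
    assert np.allclose(eff["effect"], 0.0, atol=1e-12)
    assert np.allclose(eff["h_bar"], y.mean())


def test_carrier_indicator_weights_give_carrier_means():
    y = np.array([1.0, 1.0, 2.0, 2.0])
    X = np.zeros((4, 8))
    # pi_1 is a carrier indicator for the first two individuals; the rest of
    # the parent-1 mass sits evenly on homologues 2-4
    X[:, 0] = [2, 2, 0, 0]
    X[:, 1:4] = ((2 - X[:, 0]) / 3)[:, None]
    X[:, 4:] = 0.5
    eff = tq.homologue_effects(y, X)
    assert eff.loc[1, "h_bar"] == pytest.approx(1.0)  # mean of carriers
    assert eff.loc[2, "h_bar"] == pytest.approx(2.0)  # mean of non-carriers


def test_weighted_effects_sum_to_zero(demo_population):
    grid = demo_population["grid"]
    y = demo_population["y"].to_numpy()
    idx = grid.locate("chr1", 40.0)
    eff = tq.homologue_effects(y, grid.X[:, idx, :])
    assert float((eff["effect"] * eff["weight"]).sum()) == pytest.approx(
        0.0, abs=1e-9
    )


def test_homologue_effects_reject_zero_weight():
    X = _uniform_X(10)
    X[:, 0] = 0.0
    X[:, 1] = 1.0
    with pytest.raises(ValueError, match="zero total weight"):
        tq.homologue_effects(np.ones(10), X)


def test_planted_effect_matches_group_mean_oracle(demo_population):
    # homologue 2 carries +0.3 per copy; with lambda=1 dosages the weighted
    # mean equals the carrier-group mean computed directly from the truth
    truth = demo_population["truth"]
    probs1 = tq.inheritance_to_probabilities(truth, 1.0)
    grid = probs1.to_dosage()
    idx = grid.locate("chr1", 40.0)
    y = demo_population["y"].to_numpy()
    eff = tq.homologue_effects(y, grid.X[:, idx, :])
    copies = truth.homologue_copies(idx)[:, 1]
    oracle = (copies * y).sum() / copies.sum()  # dosage-weighted carrier mean
    assert eff.loc[2, "h_bar"] == pytest.approx(oracle, abs=1e-12)
    assert eff.loc[2, "effect"] > 0.1


def test_model_enumeration_counts():
    models = enumerate_biallelic_models()
    assert len(models) == 126  # (2^8 - 2)/2 - 1 non-segregating class
    # exactly one Q in parent 2, none in parent 1: the qqqq x Qqqq family
    family = [
        m for m in models if sum(m[:4]) == 0 and sum(m[4:]) == 1
    ]
    assert len(family) == 4
    assert tuple([True] * 8) not in models  # non-segregating, and non-canonical
    assert all(len(set(m[:4])) > 1 or len(set(m[4:])) > 1 for m in models)


def test_sic_penalises_extra_parameters(demo_population):
    grid = demo_population["grid"]
    idx = grid.locate("chr1", 40.0)
    X = grid.X[:, idx, :]
    y = demo_population["y"].to_numpy()
    mask = (False, True, False, False, False, False, False, False)
    add = fit_biallelic_model(y, X, mask, "additive")
    dom = fit_biallelic_model(y, X, mask, "additive+dominance")
    # the dominance fit can only lower RSS, but pays ln(n) per parameter
    assert dom["rss"] <= add["rss"] + 1e-12
    n = len(y)
    assert dom["sic"] - add["sic"] == pytest.approx(
        n * np.log(dom["rss"] / add["rss"]) + np.log(n), abs=1e-9
    )


def test_single_q_model_reparameterizes_single_column_regression(demo_population):
    grid = demo_population["grid"]
    idx = grid.locate("chr1", 40.0)
    X = grid.X[:, idx, :]
    y = demo_population["y"].to_numpy()
    mask = (False, True, False, False, False, False, False, False)
    fit = fit_biallelic_model(y, X, mask, "additive")
    design = np.column_stack([np.ones(len(y)), X[:, 1]])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    assert fit["rss"] == pytest.approx(rss, abs=1e-10)


def test_degenerate_predictor_rejected():
    y = np.ones(20)
    X = _uniform_X(20)
    mask = (True, True, True, True, False, False, False, False)  # sums to 2
    with pytest.raises(ValueError, match="degenerate"):
        fit_biallelic_model(y, X, mask, "additive")


def test_additive_equivalence_of_within_parent_complements():
    single = (False, False, False, False, False, False, False, True)
    complement = (False, False, False, False, True, True, True, False)
    assert additive_equivalence_key(single) == additive_equivalence_key(
        complement
    )
    other = (False, True, False, False, False, False, False, False)
    assert additive_equivalence_key(single) != additive_equivalence_key(other)


def test_model_evidence_table():
    fits = [
        {"genotype": "a", "coding": "additive", "k": 2, "rss": 1.0,
         "sic": -100.0, "mask": (True,) + (False,) * 7},
        {"genotype": "b", "coding": "additive", "k": 2, "rss": 1.2,
         "sic": -81.0, "mask": (False, True) + (False,) * 6},
    ]
    table = tq.model_evidence(fits)
    assert table.iloc[0]["delta_sic"] == 0.0
    assert table.iloc[1]["delta_sic"] == pytest.approx(19.0)
    assert str(table.iloc[1]["evidence"]) == "very strong"
    single = tq.model_evidence(fits[:1])
    assert single.iloc[0]["delta_sic"] == 0.0
    with pytest.raises(ValueError):
        tq.model_evidence([])


def test_search_recovers_planted_simplex_model(demo_population):
    res = tq.BiallelicModelSearch(
        demo_population["y"],
        demo_population["grid"],
        "chr1",
        40.0,
        probabilities=demo_population["probs"],
    ).fit()
    truth_mask = (False, True, False, False, False, False, False, False)
    assert res.table.iloc[0]["equiv_class"] == additive_equivalence_key(
        truth_mask
    )
    assert res.runner_up_delta > 2.0
    assert "best model" in res.summary()


def test_null_phenotype_gives_weak_model_separation(demo_population):
    rng = np.random.default_rng(12)
    grid = demo_population["grid"]
    weak = 0
    reps = 8
    for _ in range(reps):
        y = rng.normal(size=grid.n_individuals)
        res = tq.BiallelicModelSearch(y, grid, "chr1", 40.0).fit(
            include_dominance=False
        )
        if res.runner_up_delta < 2.0:
            weak += 1
    assert weak >= reps // 2
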
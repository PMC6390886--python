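"""Model-B design, per-position fits, LOD, permutation thresholds, peaks."""

import numpy as np
import pandas as pd
import pytest

import tetraqtl as tq
from tetraqtl.scan import (
    design_matrix_model_b,
    model_b_columns,
    zero_variance_predictors,
)


def test_design_matrix_retains_model_b_columns():
    row = np.array([[0.5, 0.5, 0.5, 0.5, 1, 0, 1, 0]] * 10)
    design = design_matrix_model_b(row)
    assert design.shape == (10, 7)
    assert np.array_equal(design[0], [1, 0.5, 0.5, 0.5, 0, 1, 0])


def test_design_matrix_flags_uninformative_positions():
    flat = np.full((12, 8), 0.5)
    design = design_matrix_model_b(flat)
    assert zero_variance_predictors(design).all()


def test_design_matrix_rejects_broken_constraints():
    bad = np.ones((5, 8))  # parent sums = 4
    with pytest.raises(ValueError, match="sums"):
        design_matrix_model_b(bad)


def test_dropped_columns_recoverable_from_constraint(demo_population):
    X = demo_population["grid"].X[:, 17, :]
    cols = model_b_columns(X)
    assert np.allclose(2.0 - cols[:, :3].sum(axis=1), X[:, 0], atol=1e-9)
    assert np.allclose(2.0 - cols[:, 3:].sum(axis=1), X[:, 4], atol=1e-9)


def test_choice_of_dropped_columns_does_not_change_fit(demo_population):
    # dropping X2/X6 instead of X1/X5 is an equivalent parameterization
    from tetraqtl.scan import fit_position

    X = demo_population["grid"].X[:, 40, :]
    y = demo_population["y"].to_numpy()
    d_std = design_matrix_model_b(X)
    d_alt = np.column_stack(
        [np.ones(len(X)), X[:, [0, 2, 3]], X[:, [4, 6, 7]]]
    )
    _, rss_std, _ = fit_position(y, d_std)
    _, rss_alt, _ = fit_position(y, d_alt)
    assert rss_std == pytest.approx(rss_alt, abs=1e-10)


def test_fit_position_against_normal_equations_oracle():
    rng = np.random.default_rng(0)
    design = np.column_stack([np.ones(12), rng.normal(size=(12, 6))])
    y = rng.normal(size=12)
    coef, rss1, rss0 = tq.fit_position(y, design)
    oracle = np.linalg.solve(design.T @ design, design.T @ y)
    assert np.allclose(coef, oracle, atol=1e-8)
    resid = y - design @ oracle
    assert rss1 == pytest.approx(float(resid @ resid), abs=1e-10)
    assert rss0 == pytest.approx(float(np.sum((y - y.mean()) ** 2)))


def test_fit_position_degenerate_cases():
    design = np.column_stack([np.ones(10), np.arange(10.0)])
    y_const = np.full(10, 3.0)
    _, rss1, rss0 = tq.fit_position(y_const, design)
    assert rss0 == pytest.approx(0.0, abs=1e-18)
    assert tq.lod(10, rss0, min(rss1, rss0)) == 0.0
    y_linear = 2.0 + 0.5 * np.arange(10)
    _, rss1, _ = tq.fit_position(y_linear, design)
    assert rss1 == pytest.approx(0.0, abs=1e-18)
    with pytest.raises(ValueError, match="8 individuals"):
        tq.fit_position(np.ones(5), design[:5])


def test_lod_arithmetic_and_identity():
    assert tq.lod(496, 1.3, 1.3) == 0.0
    assert tq.lod(20, 2.0, 0.2) == pytest.approx(10.0)
    n, rss0, rss1 = 50, 4.0, 2.5
    r2 = 1 - rss1 / rss0
    assert tq.lod(n, rss0, rss1) == pytest.approx(
        -(n / 2) * np.log10(1 - r2)
    )
    with pytest.raises(ValueError):
        tq.lod(10, 1.0, -0.1)
    with pytest.raises(ValueError):
        tq.lod(10, 0.5, 1.0)


def test_scan_recovers_planted_qtl(demo_population):
    res = tq.QTLScan(demo_population["y"], demo_population["grid"]).fit()
    top = res.profile.loc[res.profile["lod"].idxmax()]
    assert top["chromosome"] == "chr1"
    assert abs(top["position"] - 40.0) <= 5.0
    assert res.profile["lod"].min() >= 0.0
    assert res.profile["r2"].between(0, 1).all()


def test_scan_of_permuted_phenotype_is_valid_null(demo_population):
    rng = np.random.default_rng(3)
    y = pd.Series(
        rng.permutation(demo_population["y"].to_numpy()),
        index=demo_population["y"].index,
    )
    res = tq.QTLScan(y, demo_population["grid"]).fit()
    assert np.isfinite(res.profile["lod"]).all()


def test_scan_rejects_misaligned_phenotypes(demo_population):
    grid = demo_population["grid"]
    with pytest.raises(ValueError, match="length"):
        tq.QTLScan(np.ones(grid.n_individuals + 3), grid)
    bad = demo_population["y"].iloc[:-5]
    with pytest.raises(ValueError, match="missing"):
        tq.QTLScan(bad, grid)


def test_missing_phenotypes_reduce_recorded_n(demo_population):
    y = demo_population["y"].copy()
    y.iloc[:10] = np.nan
    res = tq.QTLScan(y, demo_population["grid"]).fit()
    assert (res.profile["n"] == len(y) - 10).all()


def test_permutation_threshold_determinism_and_alpha_boundary(demo_population):
    y = demo_population["y"]
    grid = demo_population["grid"]
    t1 = tq.permutation_threshold(y, grid, n_perm=50, alpha=0.05, seed=11)
    t2 = tq.permutation_threshold(y, grid, n_perm=50, alpha=0.05, seed=11)
    assert t1 == t2
    t_min = tq.permutation_threshold(y, grid, n_perm=50, alpha=1.0, seed=11)
    assert t_min <= t1
    with pytest.raises(ValueError, match="20 permutations"):
        tq.permutation_threshold(y, grid, n_perm=5)


def _profile(lods, chrom="chr1"):
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": np.arange(len(lods), dtype=float),
            "lod": lods,
            "r2": 0.05,
        }
    )


def test_no_peaks_below_threshold():
    assert tq.find_peaks(_profile(np.full(30, 2.0)), threshold=4.0).empty


def test_lod2_interval_endpoints():
    pos = np.arange(41, dtype=float)
    lods = 8.4 - 0.25 * np.abs(pos - 20)  # unimodal peak 8.4 at 20 cM
    peaks = tq.find_peaks(_profile(lods), threshold=4.0)
    assert len(peaks) == 1
    p = peaks.iloc[0]
    assert p["position"] == 20.0 and p["lod"] == pytest.approx(8.4)
    # interval where LOD >= 6.4: |pos-20| <= 8
    assert p["interval_lo"] == 12.0 and p["interval_hi"] == 28.0


def test_one_peak_per_chromosome():
    prof = pd.concat(
        [_profile(6 - 0.2 * np.arange(30.0), "chr1"),
         _profile(0.3 * np.arange(30.0), "chr2")],
        ignore_index=True,
    )
    peaks = tq.find_peaks(prof, threshold=4.0)
    assert list(peaks["chromosome"]) == ["chr1", "chr2"]
    # ties in argmax break toward the lower cM position
    flat = _profile(np.full(10, 5.0))
    assert tq.find_peaks(flat, threshold=4.0).iloc[0]["position"] == 0.0


def test_scan_summary_reports_threshold(demo_population):
    res = tq.QTLScan(demo_population["y"], demo_population["grid"]).fit(
        n_perm=50, seed=4
    )
    text = res.summary()
    assert "threshold" in text and "QTL" in text
    assert res.peaks is not None
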
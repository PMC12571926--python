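import numpy as np
import pandas as pd
import pytest

import sdmt
from sdmt.features import (OmicsMatrix, fuse_intervals, impute_iterative_pca,
                           merge_cpg_strands, pmd_score, scan_vmrs,
                           select_top_fraction, shrunken_residual, tss_profile,
                           vmr_matrix)

from conftest import sample_call_table


# ---------------------------------------------------------------- residuals

def test_shrunken_residual_zero_at_window_mean():
    for cov in (0, 1, 7, 1000):
        assert shrunken_residual(0.4, 0.4, cov) == 0.0


def test_shrunken_residual_half_at_cov_equal_k():
    assert shrunken_residual(0.8, 0.4, cov=1.0, k=1.0) == pytest.approx(0.2)
    assert shrunken_residual(0.8, 0.4, cov=5.0, k=5.0) == pytest.approx(0.2)


def test_shrunken_residual_limit_high_coverage():
    assert shrunken_residual(0.7, 0.4, cov=1e6, k=1.0) == pytest.approx(0.3, abs=1e-5)


def test_shrunken_residual_rejects_nonpositive_k():
    with pytest.raises(ValueError):
        shrunken_residual(0.5, 0.4, 3, k=0)


# ---------------------------------------------------------------- selection

def test_top_fraction_selects_exact_ceiling():
    rng = np.random.default_rng(0)
    win = pd.DataFrame({"contig": "chr1", "start": np.arange(1000) * 1000,
                        "end": np.arange(1000) * 1000 + 2000,
                        "score": rng.permutation(1000).astype(float)})
    sel = select_top_fraction(win, top_fraction=0.02)
    assert len(sel) == 20  # ceil(0.02 * 1000), the top 2%
    assert set(sel["score"]) == set(range(980, 1000))
    # ceiling behaviour on non-divisible sizes
    assert len(select_top_fraction(win.head(101), 0.02)) == 3


def test_top_fraction_ties_broken_by_genomic_order():
    win = pd.DataFrame({"contig": "chr1", "start": [3000, 1000, 2000, 0],
                        "end": [5000, 3000, 4000, 2000],
                        "score": [1.0, 1.0, 1.0, 0.5]})
    sel = select_top_fraction(win, top_fraction=0.5)  # ceil(2) = 2
    assert list(sel["start"]) == [1000, 2000]


# ---------------------------------------------------------------- fusion

def test_fusion_merges_overlapping_and_bookended():
    iv = pd.DataFrame({"contig": ["chr1", "chr1", "chr1", "chr2"],
                       "start": [100, 300, 800, 0],
                       "end": [600, 800, 900, 50],
                       "score": [1.0, 2.0, 3.0, 4.0]})
    fused = fuse_intervals(iv)
    assert fused[fused["contig"] == "chr1"][["start", "end"]].values.tolist() == [[100, 900]]
    assert fused[fused["contig"] == "chr1"]["score"].iloc[0] == 3.0


def test_fusion_is_idempotent():
    iv = pd.DataFrame({"contig": ["chr1", "chr1"], "start": [100, 300],
                       "end": [600, 800], "score": [1.0, 2.0]})
    once = fuse_intervals(iv)
    twice = fuse_intervals(once)
    pd.testing.assert_frame_equal(once, twice)


def test_fusion_keeps_disjoint_intervals():
    iv = pd.DataFrame({"contig": "chr1", "start": [0, 500], "end": [100, 600],
                       "score": [1.0, 1.0]})
    assert len(fuse_intervals(iv)) == 2


# ---------------------------------------------------------------- VMR scan

@pytest.fixture(scope="module")
def planted_truth():
    cfg = sdmt.SimConfig(grid_rows=20, grid_cols=10, n_regions=2,
                         genome=(("chr1", 1_000_000, False),),
                         n_vmrs_per_region=5, vmr_delta=-0.5, seed=21)
    return sdmt.make_truth(cfg)


def test_scan_recovers_planted_vmrs(planted_truth):
    """10 planted windows with methylation offset 0.5 across 200 pixels are
    all recovered in the top-variance selection, over 10 seeds."""
    hits = total = 0
    for seed in range(10):
        table = sample_call_table(planted_truth, n_pixels=200,
                                  reads_per_site=0.4, seed=seed)
        vs = scan_vmrs(table, window_bp=2000, step_bp=1000, min_sites=5,
                       min_pixels=10, top_fraction=0.02)
        for t in planted_truth.vmrs.itertuples():
            total += 1
            ov = vs.intervals[(vs.intervals["contig"] == t.contig)
                              & (vs.intervals["start"] < t.end)
                              & (vs.intervals["end"] > t.start)]
            hits += len(ov) > 0
    assert hits / total >= 0.9


def test_scan_selected_count_is_exact_ceiling(planted_truth):
    table = sample_call_table(planted_truth, n_pixels=200, reads_per_site=0.6, seed=1)
    vs = scan_vmrs(table, top_fraction=0.02)
    eligible = vs.windows[(vs.windows["n_cpgs"] >= 5) & (vs.windows["n_pixels"] >= 10)]
    assert len(vs.selected) == int(np.ceil(0.02 * len(eligible)))


def test_scan_empty_when_no_eligible_windows():
    table = pd.DataFrame({"a_index": [1], "b_index": [1], "contig": "chr1",
                          "pos": [100], "strand": "+", "context": "CG",
                          "retained": [1], "converted": [0]})
    with pytest.warns(UserWarning):
        vs = scan_vmrs(table, min_sites=5, min_pixels=10)
    assert len(vs) == 0


# ---------------------------------------------------------------- strand merge

def test_merge_cpg_strands_pools_palindromic_site():
    t = pd.DataFrame({"a_index": [1, 1], "b_index": [1, 1], "contig": "chr1",
                      "pos": [10, 11], "strand": ["+", "-"],
                      "context": ["CG", "CG"], "retained": [2, 3],
                      "converted": [1, 0]})
    m = merge_cpg_strands(t)
    assert len(m) == 1
    assert m.loc[0, "pos"] == 10
    assert m.loc[0, "retained"] == 5 and m.loc[0, "converted"] == 1


# ---------------------------------------------------------------- matrices

def test_vmr_matrix_levels_and_missingness(planted_truth):
    table = sample_call_table(planted_truth, n_pixels=50, reads_per_site=0.5, seed=2)
    vs = scan_vmrs(table, top_fraction=0.02)
    levels, resids = vmr_matrix(table, vs)
    assert levels.kind == "methylation_level" and resids.kind == "residual"
    # brute-force re-aggregation of one interval
    iv = vs.intervals.iloc[0]
    cg = merge_cpg_strands(table)
    sub = cg[(cg["contig"] == iv["contig"]) & (cg["pos"] > iv["start"])
             & (cg["pos"] <= iv["end"])]
    agg = sub.groupby(["a_index", "b_index"])[["retained", "converted"]].sum()
    for pix, row in agg.iterrows():
        i = levels.pixels.index(pix)
        expect = row["retained"] / (row["retained"] + row["converted"])
        assert levels.values[i, 0] == pytest.approx(expect)
    # pixels with no coverage are masked missing
    covered = set(agg.index)
    for i, pix in enumerate(levels.pixels):
        if pix not in covered:
            assert np.isnan(levels.values[i, 0])


def test_vmr_matrix_single_observation_level_one():
    t = pd.DataFrame({"a_index": [1], "b_index": [1], "contig": "chr1",
                      "pos": [150], "strand": "+", "context": "CG",
                      "retained": [1], "converted": [0]})
    vs = sdmt.VMRSet(intervals=pd.DataFrame(
        {"contig": ["chr1"], "start": [100], "end": [200], "score": [1.0],
         "n_cpgs": [1], "n_pixels": [1]}))
    levels, _ = vmr_matrix(t, vs)
    assert levels.values[0, 0] == 1.0


# ---------------------------------------------------------------- imputation

def test_impute_no_missing_is_identity():
    rng = np.random.default_rng(5)
    X = rng.random((20, 8))
    m = OmicsMatrix(X.copy(), [(1, i + 1) for i in range(20)],
                    [f"f{i}" for i in range(8)], "residual")
    res = impute_iterative_pca(m, rank=3)
    assert len(res.log) == 1
    assert np.array_equal(res.matrix.values, X)


def test_impute_rank1_exact_recovery():
    rng = np.random.default_rng(6)
    u = rng.random(30)
    v = rng.random(10)
    X = np.outer(u, v)
    X_missing = X.copy()
    X_missing[7, 3] = np.nan
    m = OmicsMatrix(X_missing, [(1, i + 1) for i in range(30)],
                    [f"f{i}" for i in range(10)], "residual")
    res = impute_iterative_pca(m, rank=1, tol=1e-10, max_iter=500)
    assert abs(res.matrix.values[7, 3] - u[7] * v[3]) < 1e-6


def test_impute_rank3_noisy_masked_rmse_bound_and_monotone():
    rng = np.random.default_rng(7)
    n, p, r = 100, 30, 3
    noise_sd = 0.05
    X = rng.normal(size=(n, r)) @ rng.normal(size=(r, p))
    X = X + rng.normal(scale=noise_sd, size=X.shape)
    mask = rng.random(X.shape) < 0.2
    Xm = X.copy()
    Xm[mask] = np.nan
    m = OmicsMatrix(Xm, [(1, i + 1) for i in range(n)],
                    [f"f{i}" for i in range(p)], "residual")
    res = impute_iterative_pca(m, rank=r, tol=1e-6, max_iter=200)
    rmse = np.sqrt(np.mean((res.matrix.values[mask] - X[mask]) ** 2))
    assert rmse < 2 * noise_sd * np.sqrt(r)  # masked-entry recovery bound
    assert res.converged
    # update norm decreases monotonically on low-rank-structured data
    deltas = res.log["max_change"].to_numpy()
    assert (np.diff(deltas) <= 1e-12).all()


def test_impute_observed_entries_untouched_and_clamped():
    rng = np.random.default_rng(8)
    X = rng.random((40, 12))
    mask = rng.random(X.shape) < 0.3
    Xm = X.copy()
    Xm[mask] = np.nan
    m = OmicsMatrix(Xm, [(1, i + 1) for i in range(40)],
                    [f"f{i}" for i in range(12)], "methylation_level")
    res = impute_iterative_pca(m, rank=4, tol=1e-4, max_iter=100)
    obs = ~mask
    assert np.array_equal(res.matrix.values[obs], X[obs])  # bit-identical
    assert ((res.matrix.values >= 0) & (res.matrix.values <= 1)).all()


def test_impute_drops_all_missing_feature():
    X = np.array([[1.0, np.nan, 4.0], [2.0, np.nan, 5.0],
                  [3.0, np.nan, 6.0], [0.5, np.nan, 7.0]])
    m = OmicsMatrix(X, [(1, i + 1) for i in range(4)], ["a", "b", "c"], "residual")
    res = impute_iterative_pca(m, rank=1)
    assert res.dropped_features == ["b"]
    assert res.matrix.features == ["a", "c"]


# ---------------------------------------------------------------- PMD / TSS

def _uniform_table(level_num, level_den, positions, contig="chr1"):
    return pd.DataFrame({
        "a_index": 1, "b_index": np.repeat([1, 2], len(positions)),
        "contig": contig, "pos": np.tile(positions, 2), "strand": "+",
        "context": "CG", "retained": level_num, "converted": level_den - level_num})


def test_pmd_score_uniform_methylation():
    pos = np.arange(100, 1100, 100)
    t = _uniform_table(4, 5, pos)  # 0.8 everywhere
    pmds = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [2000]})
    s = pmd_score(t, pmds)
    assert np.allclose(s.values, 0.8)


def test_pmd_score_missing_outside_domains():
    t = _uniform_table(4, 5, np.arange(100, 600, 100))
    pmds = pd.DataFrame({"contig": ["chr1"], "start": [10_000], "end": [20_000]})
    assert pmd_score(t, pmds).isna().all()


def test_pmd_score_separates_two_levels():
    pos = np.arange(100, 2100, 50)
    hi = pd.DataFrame({"a_index": 1, "b_index": 1, "contig": "chr1", "pos": pos,
                       "strand": "+", "context": "CG", "retained": 8, "converted": 2})
    lo = pd.DataFrame({"a_index": 1, "b_index": 2, "contig": "chr1", "pos": pos,
                       "strand": "+", "context": "CG", "retained": 6, "converted": 4})
    t = pd.concat([hi, lo], ignore_index=True)
    pmds = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [3000]})
    s = pmd_score(t, pmds)
    assert s[(1, 1)] - s[(1, 2)] == pytest.approx(0.2)


def test_tss_profile_flat_for_uniform_methylation():
    pos = np.arange(100, 20_000, 97)
    t = _uniform_table(3, 4, pos)
    tss = pd.DataFrame({"contig": ["chr1"], "start": [10_000], "end": [12_000],
                        "strand": ["+"]})
    prof = tss_profile(t, tss, flank_bp=2000, n_bins=10)
    assert np.allclose(prof.dropna().values, 0.75)


def test_tss_profile_central_dip():
    pos = np.arange(100, 20_000, 53)
    tss_pos = 10_000
    ret = np.where(np.abs(pos - tss_pos) <= 500, 0, 3)
    t = pd.DataFrame({"a_index": 1, "b_index": 1, "contig": "chr1", "pos": pos,
                      "strand": "+", "context": "CG", "retained": ret,
                      "converted": 4 - ret})
    tss = pd.DataFrame({"contig": ["chr1"], "start": [tss_pos], "end": [15_000],
                        "strand": ["+"]})
    prof = tss_profile(t, tss, flank_bp=2000, n_bins=8)  # 500-bp bins
    assert prof.loc[-250.0] == pytest.approx(0.0)
    assert prof.loc[250.0] == pytest.approx(0.0)
    assert prof.loc[-1750.0] == pytest.approx(0.75)
    assert prof.loc[1750.0] == pytest.approx(0.75)


def test_tss_profile_strand_reversal_mirrors_bins():
    pos = np.arange(8000, 12_000, 131)
    ret = np.where(pos < 10_000, 4, 1)
    t = pd.DataFrame({"a_index": 1, "b_index": 1, "contig": "chr1", "pos": pos,
                      "strand": "+", "context": "CG", "retained": ret,
                      "converted": 4 - ret})
    fwd = pd.DataFrame({"contig": ["chr1"], "start": [10_000], "end": [11_000],
                        "strand": ["+"]})
    rev = pd.DataFrame({"contig": ["chr1"], "start": [9_000], "end": [10_000],
                        "strand": ["-"]})
    p_fwd = tss_profile(t, fwd, flank_bp=1000, n_bins=4)
    p_rev = tss_profile(t, rev, flank_bp=1000, n_bins=4)
    assert np.allclose(p_fwd.values, p_rev.values[::-1], equal_nan=True)
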
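import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import sdmt
from sdmt.demux import DemuxRecord
from sdmt.features import OmicsMatrix
from sdmt.integrate import (Embedding, cluster_graph, compare_clusterings,
                            count_rna, embed_pca, knn_graph, normalize_rna,
                            wnn_fuse)


def _pixels(n):
    return [(i // 10 + 1, i % 10 + 1) for i in range(n)]


# ---------------------------------------------------------------- counting

def test_umi_collapse_counts_molecules_once():
    df = pd.DataFrame({"a_index": 1, "b_index": 1, "gene": "g1",
                       "umi": ["AAAA", "AAAA", "AAAA"]})
    m, _ = count_rna(df)
    assert m.values[0, 0] == 1


def test_distinct_umis_count_separately():
    df = pd.DataFrame({"a_index": 1, "b_index": 1, "gene": "g1",
                       "umi": ["AAAA", "AAAT", "CCCC"]})
    m, _ = count_rna(df)
    assert m.values[0, 0] == 3


def test_count_rna_ignores_unassigned_with_tally():
    recs = [DemuxRecord("r1", "assigned", 1, 1, umi="AAAA"),
            DemuxRecord("r2", "no_match"),
            DemuxRecord("r3", "assigned", 1, 2, umi="CCCC")]
    m, tally = count_rna(recs, gene_of_read={"r1": "g1", "r3": "g2"})
    assert tally == {"used": 2, "unassigned": 1, "no_gene": 0}
    assert m.values.sum() == 2


def test_count_matrix_equals_provenance_distinct_triples(small_dataset):
    ds = small_dataset
    recs, _ = sdmt.demux_reads(ds.rna_reads, ds.layout_rna, ds.wl_a, ds.wl_b,
                               mode="rna")
    prov = ds.provenance[ds.provenance["library"] == "rna"]
    gene_map = dict(zip(prov["read_id"], prov["gene"]))
    m, _ = count_rna(recs, gene_of_read=gene_map)
    # oracle: distinct (pixel, gene, umi) triples among correctly assigned reads
    assigned = {r.read_id: (r.a_index, r.b_index, r.umi) for r in recs
                if r.status == "assigned"}
    triples = {(px[0], px[1], gene_map[rid], px[2]) for rid, px in assigned.items()}
    assert m.values.sum() == len(triples)


# ---------------------------------------------------------------- normalisation

def test_normalize_equal_totals_is_pure_log():
    X = np.array([[1.0, 3.0], [2.0, 2.0]])
    m = OmicsMatrix(X, _pixels(2), ["g1", "g2"], "rna_count")
    out, dropped = normalize_rna(m)
    assert dropped == []
    assert np.allclose(out.values, np.log1p(X))


def test_normalize_depth_invariance():
    X = np.array([[1.0, 3.0, 6.0], [2.0, 6.0, 12.0], [1.0, 1.0, 8.0]])
    m = OmicsMatrix(X, _pixels(3), list("abc"), "rna_count")
    out, _ = normalize_rna(m)
    # pixel 1 is pixel 0 doubled: identical normalised profile
    assert np.allclose(out.values[0], out.values[1])


def test_normalize_matches_hand_computed_table():
    X = np.array([[2.0, 2.0], [1.0, 3.0], [5.0, 15.0]])
    m = OmicsMatrix(X, _pixels(3), ["g1", "g2"], "rna_count")
    out, _ = normalize_rna(m)
    med = 4.0  # totals 4, 4, 20 -> median 4
    expect = np.log1p(X * (med / X.sum(axis=1))[:, None])
    assert np.allclose(out.values, expect)


def test_normalize_drops_zero_total_pixel():
    X = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 3.0]])
    m = OmicsMatrix(X, _pixels(3), ["g1", "g2"], "rna_count")
    out, dropped = normalize_rna(m)
    assert dropped == [_pixels(3)[1]]
    assert len(out.pixels) == 2


# ---------------------------------------------------------------- PCA

def test_pca_reconstructs_2d_data_exactly():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 2)) @ np.array([[2.0, 0.3], [0.1, 1.0]])
    m = OmicsMatrix(np.column_stack([X, X @ np.array([[1.0], [2.0]])]),
                    _pixels(30), list("abc"), "residual")
    emb = embed_pca(m, n_components=2)
    # data is intrinsically rank 2: two components carry all variance
    assert emb.variance_share.sum() == pytest.approx(1.0)


def test_pca_variances_monotone_and_match_svd_oracle():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 20))
    m = OmicsMatrix(X, _pixels(50), [f"f{i}" for i in range(20)], "residual")
    emb = embed_pca(m, n_components=10)
    assert (np.diff(emb.variance_share) <= 1e-12).all()
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    assert np.allclose(np.abs(emb.scores), np.abs(U[:, :10] * s[:10]), atol=1e-8)


def test_pca_sign_deterministic_across_runs():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 8))
    m = OmicsMatrix(X, _pixels(40), [f"f{i}" for i in range(8)], "residual")
    e1 = embed_pca(m, 5)
    e2 = embed_pca(m, 5)
    assert np.array_equal(e1.scores, e2.scores)


def test_pca_rejects_missing_values():
    X = np.array([[1.0, np.nan], [2.0, 1.0], [0.0, 3.0]])
    m = OmicsMatrix(X, _pixels(3), ["a", "b"], "residual")
    with pytest.raises(ValueError, match="imput"):
        embed_pca(m, 1)


# ---------------------------------------------------------------- WNN

def _blobs(rng, n=120, d=8, sep=6.0, k=3):
    lab = np.repeat(np.arange(k), n // k)
    X = rng.normal(size=(n, d)) + lab[:, None] * sep
    return X, lab


def test_wnn_weights_sum_to_one_and_bounded():
    rng = np.random.default_rng(3)
    X, _ = _blobs(rng)
    Y = X + rng.normal(scale=0.3, size=X.shape)
    er = Embedding(X, np.ones(8) / 8, _pixels(120), "rna")
    em = Embedding(Y, np.ones(8) / 8, _pixels(120), "meth")
    g = wnn_fuse(er, em, k=10)
    w = g.weights[["w_rna", "w_meth"]].to_numpy()
    assert np.allclose(w.sum(axis=1), 1.0)
    assert (w >= 0).all() and (w <= 1).all()


def test_wnn_identical_modalities_gives_half_half():
    rng = np.random.default_rng(4)
    X, _ = _blobs(rng)
    er = Embedding(X, np.ones(8) / 8, _pixels(120), "rna")
    em = Embedding(X.copy(), np.ones(8) / 8, _pixels(120), "meth")
    g = wnn_fuse(er, em, k=10)
    assert np.allclose(g.weights["w_rna"], 0.5, atol=1e-9)


def test_wnn_informative_modality_dominates():
    """Well-separated RNA blobs vs pure-noise methylation: RNA weight wins."""
    medians = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X, _ = _blobs(rng)
        noise = rng.normal(size=X.shape)
        er = Embedding(X, np.ones(8) / 8, _pixels(120), "rna")
        em = Embedding(noise, np.ones(8) / 8, _pixels(120), "meth")
        g = wnn_fuse(er, em, k=10)
        medians.append(g.weights["w_rna"].median())
    assert all(m > 0.5 for m in medians)


def test_wnn_rejects_mismatched_pixels_and_large_k():
    rng = np.random.default_rng(5)
    X, _ = _blobs(rng)
    er = Embedding(X, np.ones(8) / 8, _pixels(120), "rna")
    em = Embedding(X, np.ones(8) / 8, _pixels(120)[::-1], "meth")
    with pytest.raises(ValueError):
        wnn_fuse(er, em, k=10)
    em2 = Embedding(X, np.ones(8) / 8, _pixels(120), "meth")
    with pytest.raises(ValueError):
        wnn_fuse(er, em2, k=120)


# ---------------------------------------------------------------- clustering

def test_two_disconnected_cliques_give_two_clusters():
    edges = []
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((base + i, base + j, 1.0))
    df = pd.DataFrame(edges, columns=["i", "j", "weight"])
    labels = cluster_graph(df, resolution=0.5, seed=0, n_vertices=10)
    assert len(set(labels)) == 2
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1


def test_gaussian_blobs_recovered_exactly():
    rng = np.random.default_rng(6)
    n = 200
    lab = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 5))
    X[lab == 1] += 10.0  # 10-sigma separation
    emb = Embedding(X, np.ones(5) / 5, [(1, i + 1) for i in range(n)], "rna")
    g = knn_graph(emb, k=15)
    labels = cluster_graph(g, resolution=0.3, seed=1)
    assert adjusted_rand_score(lab, labels) == 1.0


def test_clustering_invariant_to_pixel_permutation():
    rng = np.random.default_rng(7)
    n = 90
    lab = np.repeat([0, 1, 2], 30)
    X = rng.normal(size=(n, 4)) + lab[:, None] * 8
    emb = Embedding(X, np.ones(4) / 4, [(1, i + 1) for i in range(n)], "rna")
    g = knn_graph(emb, k=10)
    l1 = cluster_graph(g, seed=3)
    perm = rng.permutation(n)
    emb2 = Embedding(X[perm], np.ones(4) / 4, [(1, i + 1) for i in range(n)], "rna")
    g2 = knn_graph(emb2, k=10)
    l2 = cluster_graph(g2, seed=3)
    assert adjusted_rand_score(l1, l2[np.argsort(perm)]) == 1.0


def test_cluster_rejects_empty_graph():
    with pytest.raises(ValueError):
        cluster_graph(pd.DataFrame(columns=["i", "j", "weight"]), n_vertices=0)


# ---------------------------------------------------------------- comparison

def test_identical_labelings_give_diagonal_table():
    t, norm, _ = compare_clusterings([0, 1, 1, 2], [0, 1, 1, 2])
    assert np.array_equal(np.diag(t.values), [1, 2, 1])
    assert t.values.sum() == np.diag(t.values).sum()
    assert np.allclose(norm.sum(axis=1), 1.0)


def test_constant_labeling_single_row_equals_sizes():
    t, _, _ = compare_clusterings([0, 0, 0, 0], [0, 0, 1, 2])
    assert t.shape[0] == 1
    assert t.loc[0].tolist() == [2, 1, 1]


def test_contingency_equals_bruteforce_pair_counting():
    rng = np.random.default_rng(8)
    a = rng.integers(0, 4, 200)
    b = rng.integers(0, 3, 200)
    t, norm, flow = compare_clusterings(a, b)
    for i in np.unique(a):
        for j in np.unique(b):
            brute = int(sum((x == i) and (y == j) for x, y in zip(a, b)))
            assert t.loc[i, j] == brute
    assert flow["n"].sum() == 200


def test_compare_rejects_length_mismatch():
    with pytest.raises(ValueError):
        compare_clusterings([0, 1], [0, 1, 2])


# ---------------------------------------------------------------- end-to-end

def test_multimodal_cluster_recovery_from_simulation():
    """Full pipeline on 4-region simulations: WNN clusters vs true regions
    reach mean ARI >= 0.8 across 5 seeds."""
    aris = []
    for seed in range(5):
        cfg = sdmt.SimConfig(grid_rows=10, grid_cols=10, n_regions=4,
                             genome=(("chr1", 200_000, False),),
                             n_vmrs_per_region=5, vmr_delta=-0.4,
                             marker_fold=4.0, reads_per_pixel_dna=600,
                             n_spikein=0, seed=300 + seed)
        ds = sdmt.simulate_dataset(cfg)
        truth_regions = ds.truth.region_label.ravel()

        # RNA arm
        recs_rna, _ = sdmt.demux_reads(ds.rna_reads, ds.layout_rna, ds.wl_a,
                                       ds.wl_b, mode="rna")
        prov = ds.provenance[ds.provenance["library"] == "rna"]
        counts, _ = count_rna(recs_rna, dict(zip(prov["read_id"], prov["gene"])))
        lognorm, _ = normalize_rna(counts)
        emb_rna = embed_pca(lognorm, n_components=20)

        # methylation arm; wider top fraction suits the 100-window toy genome
        recs_dna, _ = sdmt.demux_reads(ds.dna_reads, ds.layout_dna, ds.wl_a,
                                       ds.wl_b, mode="dna")
        calls = sdmt.calls_from_reads(recs_dna, ds.provenance, ds.truth.genome)
        agg = sdmt.aggregate_calls(calls)
        vs = sdmt.scan_vmrs(agg.table, min_pixels=10, top_fraction=0.1)
        _, resid = sdmt.vmr_matrix(agg.table, vs)
        imput = sdmt.impute_iterative_pca(resid, rank=min(5, len(vs) - 1))
        emb_meth = embed_pca(imput.matrix,
                             n_components=min(10, len(imput.matrix.features) - 1))

        # align pixel sets (RNA may drop zero-count pixels)
        common = [p for p in emb_rna.pixels if p in set(emb_meth.pixels)]
        ir = [emb_rna.pixels.index(p) for p in common]
        im = [emb_meth.pixels.index(p) for p in common]
        er = Embedding(emb_rna.scores[ir], emb_rna.variance_share, common, "rna")
        em = Embedding(emb_meth.scores[im], emb_meth.variance_share, common, "meth")
        g = wnn_fuse(er, em, k=15)
        labels = cluster_graph(g, resolution=0.8, seed=seed)
        truth_common = [truth_regions[(a - 1) * cfg.grid_cols + (b - 1)]
                        for a, b in common]
        aris.append(adjusted_rand_score(truth_common, labels))
    assert np.mean(aris) >= 0.8, aris
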
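"""Multimodal integration: RNA counting and normalisation, PCA embeddings,
weighted-nearest-neighbour (WNN) fusion with per-pixel modality weights,
graph clustering and cluster comparison.

The WNN step is a deliberately simplified variant of the published
weighted-nearest-neighbour algorithm: per pixel, each modality's embedding
is predicted from the pixel's k nearest neighbours found within the same
modality and from those found in the other modality; the ratio of the two
kernelised prediction accuracies measures how informative each modality's
neighbourhood structure is, and a softmax over the two ratios yields
per-pixel modality weights that sum to 1. The fused similarity of a pixel
pair is the weight-blended exponential-kernel similarity of the two
modalities, from which a shared-nearest-neighbour (SNN) graph is built for
Leiden/Louvain community detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .demux import DemuxRecord
from .features import OmicsMatrix

# ---------------------------------------------------------------------------
# RNA counting and normalisation
# ---------------------------------------------------------------------------


def count_rna(records: Sequence[DemuxRecord] | pd.DataFrame,
              gene_of_read: dict[str, object] | pd.Series | None = None
              ) -> tuple[OmicsMatrix, dict[str, int]]:
    """UMI-collapsed gene x pixel counting.

    A molecule is a distinct (pixel, gene, UMI) triple; UMI collapse is
    exact-match. Accepts demux records plus a read -> gene assignment, or a
    prepared DataFrame with columns a_index, b_index, gene, umi.
    Unassigned or gene-less reads are ignored and tallied.
    """
    tally = {"used": 0, "unassigned": 0, "no_gene": 0}
    if isinstance(records, pd.DataFrame):
        df = records[["a_index", "b_index", "gene", "umi"]].copy()
        tally["used"] = len(df)
    else:
        if gene_of_read is None:
            raise ValueError("gene_of_read required with demux records")
        gmap = dict(gene_of_read) if not isinstance(gene_of_read, dict) else gene_of_read
        rows = []
        for rec in records:
            if rec.status != "assigned":
                tally["unassigned"] += 1
                continue
            g = gmap.get(rec.read_id)
            if g is None:
                tally["no_gene"] += 1
                continue
            rows.append((rec.a_index, rec.b_index, g, rec.umi or ""))
            tally["used"] += 1
        df = pd.DataFrame(rows, columns=["a_index", "b_index", "gene", "umi"])
    mol = df.drop_duplicates(["a_index", "b_index", "gene", "umi"])
    counts = (mol.groupby(["a_index", "b_index", "gene"]).size()
              .unstack("gene", fill_value=0))
    pixels = list(counts.index)
    genes = [str(g) for g in counts.columns]
    return OmicsMatrix(counts.to_numpy(float), pixels, genes, "rna_count"), tally


def normalize_rna(counts: OmicsMatrix) -> tuple[OmicsMatrix, list[tuple[int, int]]]:
    """Median-ratio log-normalisation: scale each pixel's counts to the
    median total count, then log(1 + x). Zero-total pixels are dropped and
    reported. The per-pixel profile is invariant to its sequencing depth.
    """
    X = counts.values
    totals = X.sum(axis=1)
    keep = totals > 0
    dropped = [p for p, k in zip(counts.pixels, keep) if not k]
    X = X[keep]
    totals = totals[keep]
    if len(totals) == 0:
        raise ValueError("all pixels have zero total counts")
    target = float(np.median(totals))
    norm = np.log1p(X * (target / totals)[:, None])
    out = OmicsMatrix(norm, [p for p, k in zip(counts.pixels, keep) if k],
                      counts.features, "rna_lognorm")
    return out, dropped


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------


@dataclass
class Embedding:
    scores: np.ndarray                  # (n_pixels, n_components)
    variance_share: np.ndarray          # fraction of variance per component
    pixels: list[tuple[int, int]]
    modality: str

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def embed_pca(matrix: OmicsMatrix, n_components: int, center: bool = True,
              scale: bool = False) -> Embedding:
    """Deterministic PCA by SVD of the (optionally centred/scaled) matrix.

    Missing values are not allowed — impute first. Component signs are
    fixed by making the largest-magnitude loading of each component
    positive, so results are reproducible across runs and libraries.
    """
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run imputation first")
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components {n_components} > min(dims) {min(n, p)}")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = np.abs(Vt[j]).argmax()
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :n_components] * s[:n_components]
    total_var = float((s ** 2).sum())
    share = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return Embedding(scores=scores, variance_share=share,
                     pixels=list(matrix.pixels), modality=matrix.kind)


# ---------------------------------------------------------------------------
# WNN fusion
# ---------------------------------------------------------------------------


@dataclass
class WnnGraph:
    weights: pd.DataFrame               # per pixel: w_rna, w_meth (sum to 1)
    edges: pd.DataFrame                 # i, j (0-based pixel positions), weight
    pixels: list[tuple[int, int]]
    k: int


def _knn(emb: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    return dist[:, 1:], idx[:, 1:]  # drop self


def wnn_fuse(emb_rna: Embedding, emb_meth: Embedding, k: int = 20,
             eps: float = 1e-4) -> WnnGraph:
    """Fuse two embeddings into a weighted SNN graph with modality weights.

    For modality m, a pixel's profile is predicted as the mean embedding of
    its k nearest neighbours found in m (within-modality) and of those
    found in the other modality (cross-modality). The bounded score
    ``d_cross / (d_within + d_cross)`` in (0, 1) measures how much better
    m's own neighbourhood explains m than the other modality's does; a
    softmax over the two scores gives per-pixel weights summing to exactly
    1 (equal embeddings give exactly 0.5/0.5). Fused pairwise similarity is
    ``w_rna * exp(-d_rna/sigma_rna) + w_meth * exp(-d_meth/sigma_meth)``
    with sigma the pixel's mean k-NN distance; edges are the
    shared-nearest-neighbour Jaccard weights of the fused k-NN lists.
    """
    if emb_rna.pixels != emb_meth.pixels:
        raise ValueError("embeddings must share the same pixel set in order")
    X = {"rna": emb_rna.scores, "meth": emb_meth.scores}
    n = len(emb_rna.pixels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the pixel count {n}")

    dist, idx = {}, {}
    for m in X:
        dist[m], idx[m] = _knn(X[m], k)

    # bounded informativeness score per modality: how much better the
    # modality's own neighbourhood predicts it than the other modality's
    # neighbourhood does; s in (0, 1), 0.5 = uninformative either way.
    # Bounding the score keeps the softmax from saturating when one
    # modality is artificially smooth (e.g. after low-rank imputation).
    score = {}
    for m, other in (("rna", "meth"), ("meth", "rna")):
        pred_within = X[m][idx[m]].mean(axis=1)
        pred_cross = X[m][idx[other]].mean(axis=1)
        d_within = np.linalg.norm(X[m] - pred_within, axis=1)
        d_cross = np.linalg.norm(X[m] - pred_cross, axis=1)
        score[m] = d_cross / (d_within + d_cross + eps)

    expo = np.exp(np.column_stack([score["rna"], score["meth"]]))
    w = expo / expo.sum(axis=1, keepdims=True)
    weights = pd.DataFrame({"w_rna": w[:, 0], "w_meth": w[:, 1]},
                           index=pd.MultiIndex.from_tuples(
                               emb_rna.pixels, names=["a_index", "b_index"]))

    # fused similarity over the union of each pixel's kNN candidates
    sigma = {m: dist[m].mean(axis=1) + eps for m in X}
    fused_nbrs: list[np.ndarray] = []
    for i in range(n):
        cand = np.unique(np.concatenate([idx["rna"][i], idx["meth"][i]]))
        sim = np.zeros(len(cand))
        for mj, m in enumerate(("rna", "meth")):
            d = np.linalg.norm(X[m][cand] - X[m][i], axis=1)
            sim += w[i, mj] * np.exp(-d / sigma[m][i])
        top = cand[np.argsort(-sim, kind="stable")[:k]]
        fused_nbrs.append(np.sort(top))

    # SNN: Jaccard overlap of fused neighbour sets over kNN edges
    sets = [set(nb) for nb in fused_nbrs]
    edge_w: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in fused_nbrs[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edge_w:
                continue
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            jac = inter / union if union else 0.0
            if jac > 0:
                edge_w[(a, b)] = jac
    edges = pd.DataFrame([(a, b, wgt) for (a, b), wgt in sorted(edge_w.items())],
                         columns=["i", "j", "weight"])
    return WnnGraph(weights=weights, edges=edges, pixels=list(emb_rna.pixels), k=k)


def knn_graph(emb: Embedding, k: int = 20) -> WnnGraph:
    """Single-modality SNN graph (same construction, trivial weights)."""
    n = len(emb.pixels)
    if k >= n:
        raise ValueError("k must be smaller than the pixel count")
    _, idx = _knn(emb.scores, k)
    sets = [set(row) for row in idx]
    edge_w: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in idx[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edge_w:
                continue
            jac = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
            if jac > 0:
                edge_w[(a, b)] = jac
    edges = pd.DataFrame([(a, b, wgt) for (a, b), wgt in sorted(edge_w.items())],
                         columns=["i", "j", "weight"])
    weights = pd.DataFrame({"w_rna": np.full(n, 0.5), "w_meth": np.full(n, 0.5)},
                           index=pd.MultiIndex.from_tuples(
                               emb.pixels, names=["a_index", "b_index"]))
    return WnnGraph(weights=weights, edges=edges, pixels=list(emb.pixels), k=k)


# ---------------------------------------------------------------------------
# Graph clustering
# ---------------------------------------------------------------------------


def cluster_graph(graph: WnnGraph | pd.DataFrame, resolution: float = 0.8,
                  method: str = "leiden", seed: int = 0,
                  n_vertices: int | None = None) -> np.ndarray:
    """Modularity-style community detection on the (weighted) fused graph."""
    import igraph as ig

    if isinstance(graph, WnnGraph):
        edges = graph.edges
        n = len(graph.pixels)
    else:
        edges = graph
        n = n_vertices if n_vertices is not None else int(edges[["i", "j"]].max().max()) + 1
    if n == 0 or edges.empty:
        raise ValueError("empty graph")
    g = ig.Graph(n=n, edges=list(zip(edges["i"], edges["j"])), directed=False)
    w = list(edges["weight"].astype(float))
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights=w,
            resolution_parameter=resolution, seed=seed, n_iterations=2)
        labels = np.asarray(part.membership)
    elif method == "louvain":
        np.random.seed(seed)  # igraph multilevel draws from numpy's global RNG
        part = g.community_multilevel(weights=w, resolution=resolution)
        labels = np.asarray(part.membership)
    else:
        raise ValueError("method must be 'leiden' or 'louvain'")
    return labels


# ---------------------------------------------------------------------------
# Cluster comparison
# ---------------------------------------------------------------------------


def compare_clusterings(labels_a: Sequence, labels_b: Sequence
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Contingency table, row-normalised confusion matrix and flow table.

    Cell (i, j) counts pixels with label a=i and b=j; each row of the
    normalised matrix sums to 1. The flow table is the long-format input
    for an alluvial diagram.
    """
    a = pd.Series(list(labels_a), name="a")
    b = pd.Series(list(labels_b), name="b")
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    table = pd.crosstab(a, b)
    norm = table.div(table.sum(axis=1), axis=0)
    flow = (table.stack().rename("n").reset_index())
    flow = flow[flow["n"] > 0].reset_index(drop=True)
    return table, norm, flow


def embed_umap(emb: Embedding, seed: int = 0, **kwargs) -> np.ndarray:
    """Optional 2-D UMAP visualisation (delegated to umap-learn)."""
    import umap

    reducer = umap.UMAP(random_state=seed, **kwargs)
    return reducer.fit_transform(emb.scores)
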
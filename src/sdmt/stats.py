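"""Downstream inference: differential features between pixel groups,
VMR-gene pairing with methylation-expression correlation, and CpG-set
fold enrichment against annotation features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_ADJUST = {"BH": "fdr_bh", "bonferroni": "bonferroni"}


# ---------------------------------------------------------------------------
# Differential features (two-sided Wilcoxon rank-sum)
# ---------------------------------------------------------------------------


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney/rank-sum p: exact for small untied samples,
    normal approximation with tie correction otherwise."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        return float(len(x) * len(y) / 2.0), 1.0  # identical constant groups
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def diff_features(matrix, labels: Sequence, group_a, group_b=None,
                  adjust: str = "BH", min_obs: int = 2,
                  pseudo: float | None = None) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test between pixel groups.

    ``matrix`` is an OmicsMatrix or DataFrame (pixels x features, NaN =
    unobserved). ``group_a`` selects the foreground label; ``group_b``
    defaults to all remaining pixels. Features with fewer than ``min_obs``
    observed pixels in either group are skipped with a flag. Log2 fold
    change uses a pseudo-count of 0.01 for methylation levels and 1
    otherwise (override with ``pseudo``). Adjustment (BH or Bonferroni) is
    applied across the tested features.
    """
    if adjust not in _ADJUST:
        raise ValueError("adjust must be 'BH' or 'bonferroni'")
    if hasattr(matrix, "to_frame"):
        kind = matrix.kind
        df = matrix.to_frame()
    else:
        kind = "generic"
        df = pd.DataFrame(matrix)
    if pseudo is None:
        pseudo = 0.01 if kind in ("methylation_level", "residual") else 1.0
    labels = np.asarray(list(labels))
    if len(labels) != len(df):
        raise ValueError("labels length mismatch")
    in_a = labels == group_a
    in_b = ~in_a if group_b is None else labels == group_b
    if in_a.sum() < min_obs or in_b.sum() < min_obs:
        raise ValueError("each group needs at least min_obs pixels")

    rows = []
    for feat in df.columns:
        v = df[feat].to_numpy(float)
        xa = v[in_a]
        xb = v[in_b]
        xa = xa[~np.isnan(xa)]
        xb = xb[~np.isnan(xb)]
        if len(xa) < min_obs or len(xb) < min_obs:
            rows.append({"feature": feat, "mean_a": np.nan, "mean_b": np.nan,
                         "log2_fc": np.nan, "statistic": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        stat, p = _ranksum_p(xa, xb)
        ma, mb = float(xa.mean()), float(xb.mean())
        rows.append({"feature": feat, "mean_a": ma, "mean_b": mb,
                     "log2_fc": float(np.log2((ma + pseudo) / (mb + pseudo))),
                     "statistic": stat, "p": p, "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method=_ADJUST[adjust])[1]
    out["adjust_method"] = adjust
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# VMR-gene pairing
# ---------------------------------------------------------------------------


def pair_vmr_gene(vmrs, genes: pd.DataFrame, flank_bp: int = 0,
                  upstream_only: bool = False) -> pd.DataFrame:
    """Pair each VMR with every gene whose flanked span it intersects.

    ``genes`` is BED-like (contig, start, end, name, strand). The gene span
    is extended by ``flank_bp`` on both sides, or strand-aware upstream
    only when ``upstream_only``. One VMR may pair with several genes and
    vice versa.
    """
    iv = vmrs.intervals if hasattr(vmrs, "intervals") else vmrs
    rows = []
    for contig, gsub in genes.groupby("contig"):
        vsub = iv[iv["contig"] == contig]
        if vsub.empty:
            continue
        for g in gsub.itertuples(index=False):
            strand = getattr(g, "strand", "+")
            lo, hi = g.start, g.end
            if upstream_only:
                if strand == "+":
                    lo -= flank_bp
                else:
                    hi += flank_bp
            else:
                lo -= flank_bp
                hi += flank_bp
            hit = vsub[(vsub["start"] < hi) & (vsub["end"] > lo)]
            for v in hit.itertuples(index=False):
                rows.append({"vmr": f"{v.contig}:{v.start}-{v.end}",
                             "gene": getattr(g, "name", f"{g.contig}:{g.start}"),
                             "contig": contig, "vmr_start": v.start,
                             "vmr_end": v.end, "gene_start": g.start,
                             "gene_end": g.end})
    return pd.DataFrame(rows, columns=["vmr", "gene", "contig", "vmr_start",
                                       "vmr_end", "gene_start", "gene_end"])


# ---------------------------------------------------------------------------
# Methylation-expression correlation
# ---------------------------------------------------------------------------


def corr_meth_expr(pairs: pd.DataFrame, meth, expr, min_pixels: int = 3
                   ) -> pd.DataFrame:
    """Pearson correlation of VMR methylation vs paired gene expression.

    For each (vmr, gene) pair, r is computed over pixels observed in both
    modalities; the two-sided p comes from the t transform and BH
    adjustment runs across all pairs. Negative r marks the canonical
    repressive direction of promoter methylation. Zero-variance vectors
    are flagged and excluded from testing.
    """
    mdf = meth.to_frame() if hasattr(meth, "to_frame") else pd.DataFrame(meth)
    edf = expr.to_frame() if hasattr(expr, "to_frame") else pd.DataFrame(expr)
    common = mdf.index.intersection(edf.index)
    mdf = mdf.loc[common]
    edf = edf.loc[common]
    rows = []
    for pr in pairs.itertuples(index=False):
        if pr.vmr not in mdf.columns or pr.gene not in edf.columns:
            continue
        x = mdf[pr.vmr].to_numpy(float)
        y = edf[pr.gene].to_numpy(float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        n = int(ok.sum())
        if n < min_pixels:
            rows.append({"vmr": pr.vmr, "gene": pr.gene, "n": n, "r": np.nan,
                         "p": np.nan, "flag": "insufficient_pixels"})
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            rows.append({"vmr": pr.vmr, "gene": pr.gene, "n": n, "r": np.nan,
                         "p": np.nan, "flag": "zero_variance"})
            continue
        r, p = sps.pearsonr(xs, ys)
        rows.append({"vmr": pr.vmr, "gene": pr.gene, "n": n, "r": float(r),
                     "p": float(p), "flag": ""})
    out = pd.DataFrame(rows, columns=["vmr", "gene", "n", "r", "p", "flag"])
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# CpG-set fold enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    expected: float
    fold_enrichment: float
    p: float
    q: float | None = None


def fold_enrichment(query: set, feature: set, universe_size: int,
                    feature_name: str = "feature") -> EnrichmentResult:
    """Fold enrichment of a CpG query set in an annotation feature.

    E = |query| * |feature| / N is the overlap expected under genomic
    uniformity; FE = O / E with O the observed overlap. Significance is a
    one-sided (greater) Fisher exact test on the 2x2 table. An empty query
    or feature leaves FE undefined (NaN).
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    nq, nf = len(query), len(feature)
    if nq > universe_size or nf > universe_size:
        raise ValueError("query/feature larger than the universe")
    if nq == 0 or nf == 0:
        return EnrichmentResult(feature_name, 0, 0.0, float("nan"), 1.0)
    obs = len(query & feature)
    exp = nq * nf / universe_size
    table = [[obs, nq - obs], [nf - obs, universe_size - nq - nf + obs]]
    _, p = sps.fisher_exact(table, alternative="greater")
    return EnrichmentResult(feature_name, obs, exp, obs / exp, float(p))


def enrichment_table(query: set, features: dict[str, set],
                     universe_size: int) -> pd.DataFrame:
    """fold_enrichment across many features, with BH FDR across them."""
    res = [fold_enrichment(query, fs, universe_size, name)
           for name, fs in features.items()]
    df = pd.DataFrame([{"feature": r.feature, "observed": r.observed,
                        "expected": r.expected,
                        "fold_enrichment": r.fold_enrichment, "p": r.p}
                       for r in res])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# BED export of differential VMRs (external motif-tool interoperability)
# ---------------------------------------------------------------------------


def export_hypomethylated_bed(diff: pd.DataFrame, path: str | Path,
                              q_max: float = 0.05) -> int:
    """Write significantly hypomethylated VMRs (log2FC < 0) as BED.

    Feature names must encode coordinates as ``contig:start-end`` (the
    VMRSet naming); coordinates are already 0-based half-open.
    """
    sel = diff[(diff["p_adj"] <= q_max) & (diff["log2_fc"] < 0) & ~diff["skipped"]]
    n = 0
    with open(path, "w") as fh:
        for feat in sel["feature"]:
            contig, span = str(feat).split(":")
            start, end = span.split("-")
            fh.write(f"{contig}\t{start}\t{end}\t{feat}\n")
            n += 1
    return n
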
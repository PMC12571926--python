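"""Methylome feature space: variably methylated regions (VMRs), per-pixel
VMR matrices, iterative-PCA imputation, PMD scores and TSS profiles.

Single-pixel methylomes are too sparse to analyse per CpG, so the genome
is scanned in sliding windows and the windows whose across-pixel variance
of coverage-shrunken methylation residuals ranks in the top fraction
(default 2%) are fused into VMR intervals. VMR-level methylation and
residual matrices (pixels x VMRs, with explicit missingness) feed the
multimodal integration; missing entries are completed by iterative
truncated-SVD reconstruction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """pixels x features matrix with NaN marking unobserved entries."""

    values: np.ndarray
    pixels: list[tuple[int, int]]       # (a_index, b_index)
    features: list[str]
    kind: str                           # methylation_level | residual | rna_count | rna_lognorm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pixels), len(self.features)):
            raise ValueError("values shape inconsistent with pixel/feature labels")
        if self.kind == "methylation_level":
            obs = self.values[~np.isnan(self.values)]
            if len(obs) and (obs.min() < -1e-9 or obs.max() > 1 + 1e-9):
                raise ValueError("methylation levels must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        """True where observed."""
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.pixels, names=["a_index", "b_index"])
        return pd.DataFrame(self.values, index=idx, columns=self.features)


@dataclass
class VMRSet:
    """Fused VMR intervals (0-based half-open) with diagnostics."""

    intervals: pd.DataFrame              # contig, start, end, score, n_cpgs, n_pixels
    windows: pd.DataFrame = field(repr=False, default=None)   # every eligible window
    selected: pd.DataFrame = field(repr=False, default=None)  # pre-fusion selection

    def __len__(self) -> int:
        return len(self.intervals)

    def names(self) -> list[str]:
        return [f"{r.contig}:{r.start}-{r.end}"
                for r in self.intervals.itertuples(index=False)]

    def to_bed(self, path: str | Path) -> None:
        """BED6 export; score = variance rank percentile x 1000."""
        iv = self.intervals
        rank_pct = iv["score"].rank(pct=True)
        with open(path, "w") as fh:
            for (row, pct) in zip(iv.itertuples(index=False), rank_pct):
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\t"
                         f"{row.contig}:{row.start}-{row.end}\t{int(pct * 1000)}\t.\n")


def read_bed(path: str | Path, names: Sequence[str] = ("contig", "start", "end",
                                                       "name", "score", "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# CpG strand merging
# ---------------------------------------------------------------------------


def merge_cpg_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the two strands of each palindromic CpG onto the + C position.

    A minus-strand CG cytosine sits one base 3' of the forward C, so its
    coordinate maps to pos - 1. Non-CG contexts are excluded. Returns
    per (pixel, contig, pos) summed retained/converted counts.
    """
    cg = table[table["context"] == "CG"].copy()
    if cg.empty:
        return pd.DataFrame(columns=["a_index", "b_index", "contig", "pos",
                                     "retained", "converted"])
    cg["pos"] = np.where(cg["strand"] == "-", cg["pos"] - 1, cg["pos"])
    cg["contig"] = cg["contig"].astype("category")  # object dtype is slow to group
    out = (cg.groupby(["a_index", "b_index", "contig", "pos"],
                      as_index=False, observed=True)
           [["retained", "converted"]].sum())
    out["contig"] = out["contig"].astype(str)
    return out


# ---------------------------------------------------------------------------
# Shrunken residuals
# ---------------------------------------------------------------------------


def shrunken_residual(m, mbar, cov, k: float = 1.0):
    """Coverage-shrunken deviation from the window mean.

    residual = cov / (cov + k) * (m - mbar): at low coverage the deviation
    is attenuated toward 0, at high coverage it approaches the raw
    deviation. ``k`` is the pseudo-count controlling the shrinkage scale.
    """
    if k <= 0:
        raise ValueError("shrinkage pseudo-count k must be positive")
    cov = np.asarray(cov, dtype=float)
    return cov / (cov + k) * (np.asarray(m, dtype=float) - np.asarray(mbar, dtype=float))


# ---------------------------------------------------------------------------
# VMR scan
# ---------------------------------------------------------------------------


def _window_stats(cg: pd.DataFrame, window_bp: int, step_bp: int,
                  k: float) -> pd.DataFrame:
    """Score every sliding window: per-pixel shrunken residual variance."""
    cg = cg.assign(contig=cg["contig"].astype("category"))
    pos0 = cg["pos"].to_numpy() - 1  # 0-based
    first_w = (pos0 - window_bp) // step_bp + 1
    first_w = np.maximum(first_w, 0)
    last_w = pos0 // step_bp
    n_win = (last_w - first_w + 1).astype(int)
    rep = cg.loc[cg.index.repeat(n_win)].copy()
    # window id per exploded row: first_w + within-site offset, without a loop
    total = int(n_win.sum())
    offs = np.arange(total) - np.repeat(np.cumsum(n_win) - n_win, n_win)
    rep["win"] = np.repeat(first_w, n_win) + offs
    rep["win_start"] = rep["win"] * step_bp

    per_px = (rep.groupby(["contig", "win_start", "a_index", "b_index"],
                          as_index=False, observed=True)[["retained", "converted"]].sum())
    per_px["cov"] = per_px["retained"] + per_px["converted"]
    per_px["m"] = per_px["retained"] / per_px["cov"]
    gw = per_px.groupby(["contig", "win_start"], observed=True)
    per_px["mbar"] = gw["m"].transform("mean")
    per_px["resid"] = shrunken_residual(per_px["m"], per_px["mbar"], per_px["cov"], k)
    win = (per_px.groupby(["contig", "win_start"], observed=True)
           .agg(n_pixels=("m", "size"), score=("resid", "var"),  # sample var, ddof=1
                mean_level=("mbar", "first")).reset_index()
           .rename(columns={"win_start": "start"}))
    win["score"] = win["score"].fillna(0.0)
    win["contig"] = win["contig"].astype(str)
    win["end"] = win["start"] + window_bp
    win["start"] = win["start"].astype(int)
    win["end"] = win["end"].astype(int)
    # distinct CpG count per window (pixel-independent)
    sites = rep[["contig", "win_start", "pos"]].drop_duplicates()
    n_cpg = (sites.groupby(["contig", "win_start"], observed=True).size()
             .rename("n_cpgs").reset_index().rename(columns={"win_start": "start"}))
    n_cpg["contig"] = n_cpg["contig"].astype(str)
    win = win.merge(n_cpg, on=["contig", "start"])
    return win


def select_top_fraction(windows: pd.DataFrame,
                        top_fraction: float = 0.02) -> pd.DataFrame:
    """Keep the ceil(top_fraction * n) highest-variance windows.

    Ties at the selection boundary are broken deterministically by genomic
    order (contig, start), and the count is capped at the ceiling.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    n_sel = math.ceil(top_fraction * len(windows))
    ordered = windows.sort_values(["score", "contig", "start"],
                                  ascending=[False, True, True], kind="stable")
    return ordered.head(n_sel)


def fuse_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping or book-ended (gap 0) intervals per contig.

    Idempotent; the fused score is the max over members.
    """
    if intervals.empty:
        return intervals.copy()
    has_score = "score" in intervals.columns
    out = []
    for contig, grp in intervals.sort_values(["contig", "start"]).groupby("contig"):
        cur_s = cur_e = None
        cur_score = -np.inf
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
                cur_score = row.score if has_score else np.nan
            elif row.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, row.end)
                if has_score:
                    cur_score = max(cur_score, row.score)
            else:
                out.append({"contig": contig, "start": cur_s, "end": cur_e,
                            "score": cur_score})
                cur_s, cur_e = row.start, row.end
                cur_score = row.score if has_score else np.nan
        out.append({"contig": contig, "start": cur_s, "end": cur_e,
                    "score": cur_score})
    fused = pd.DataFrame(out)
    if not has_score:
        fused = fused.drop(columns="score")
    return fused.sort_values(["contig", "start"]).reset_index(drop=True)


def scan_vmrs(table: pd.DataFrame, window_bp: int = 2000, step_bp: int = 1000,
              min_sites: int = 5, min_pixels: int = 10,
              top_fraction: float = 0.02, k: float = 1.0) -> VMRSet:
    """Detect variably methylated regions from a MethCallTable.

    Sliding windows (``window_bp`` wide, ``step_bp`` apart) are tiled per
    contig over strand-merged CpG calls. Windows with fewer than
    ``min_sites`` CpGs or ``min_pixels`` covered pixels are ineligible.
    Each eligible window is scored by the across-pixel variance of
    coverage-shrunken methylation residuals; the top ``top_fraction`` of
    windows (exactly ceil(fraction x eligible)) are selected and fused
    into non-overlapping VMR intervals.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    cg = merge_cpg_strands(table)
    if cg.empty:
        warnings.warn("no CpG calls; returning empty VMR set")
        empty = pd.DataFrame(columns=["contig", "start", "end", "score",
                                      "n_cpgs", "n_pixels"])
        return VMRSet(intervals=empty, windows=empty, selected=empty)
    win = _window_stats(cg, window_bp, step_bp, k)
    eligible = win[(win["n_cpgs"] >= min_sites) & (win["n_pixels"] >= min_pixels)]
    if eligible.empty:
        warnings.warn("no eligible windows for VMR detection")
        empty = eligible.assign(score=pd.Series(dtype=float))
        return VMRSet(intervals=eligible.copy(), windows=win, selected=eligible.copy())
    selected = select_top_fraction(eligible, top_fraction)
    fused = fuse_intervals(selected[["contig", "start", "end", "score"]])
    # recompute per-interval CpG and pixel support on the fused intervals
    n_cpgs, n_pix = [], []
    for row in fused.itertuples(index=False):
        sub = cg[(cg["contig"] == row.contig) & (cg["pos"] > row.start)
                 & (cg["pos"] <= row.end)]
        n_cpgs.append(sub["pos"].nunique())
        n_pix.append(sub.groupby(["a_index", "b_index"]).ngroups)
    fused["n_cpgs"] = n_cpgs
    fused["n_pixels"] = n_pix
    return VMRSet(intervals=fused, windows=win, selected=selected)


# ---------------------------------------------------------------------------
# VMR matrices
# ---------------------------------------------------------------------------


def vmr_matrix(table: pd.DataFrame, vmrs: VMRSet,
               k: float = 1.0) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Per-pixel VMR methylation levels and shrunken residuals.

    level(pixel, vmr) = sum(retained) / sum(retained + converted) over the
    interval's CpGs; missing (NaN) where the pixel has no coverage there.
    Residuals shrink each pixel's deviation from the VMR's across-pixel
    mean by its interval coverage.
    """
    if len(vmrs) == 0:
        raise ValueError("empty VMRSet")
    cg = merge_cpg_strands(table)
    pixels = sorted(set(zip(table["a_index"], table["b_index"])))
    pix_pos = {p: i for i, p in enumerate(pixels)}
    names = vmrs.names()
    levels = np.full((len(pixels), len(names)), np.nan)
    resids = np.full((len(pixels), len(names)), np.nan)
    for j, row in enumerate(vmrs.intervals.itertuples(index=False)):
        sub = cg[(cg["contig"] == row.contig) & (cg["pos"] > row.start)
                 & (cg["pos"] <= row.end)]
        if sub.empty:
            continue
        agg = sub.groupby(["a_index", "b_index"])[["retained", "converted"]].sum()
        cov = (agg["retained"] + agg["converted"]).to_numpy(float)
        m = agg["retained"].to_numpy(float) / cov
        mbar = m.mean()
        r = shrunken_residual(m, mbar, cov, k)
        for (pix, mi, ri) in zip(agg.index, m, r):
            i = pix_pos[pix]
            levels[i, j] = mi
            resids[i, j] = ri
    return (OmicsMatrix(levels, pixels, names, "methylation_level"),
            OmicsMatrix(resids, pixels, names, "residual"))


# ---------------------------------------------------------------------------
# Iterative-PCA imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputationResult:
    matrix: OmicsMatrix
    log: pd.DataFrame                 # iteration, max_change
    dropped_features: list[str]
    converged: bool


def impute_iterative_pca(matrix: OmicsMatrix, rank: int = 10, tol: float = 1e-4,
                         max_iter: int = 100) -> ImputationResult:
    """Complete missing entries by iterative truncated-SVD reconstruction.

    Initialisation depends on the matrix kind: residuals start at 0,
    methylation levels at the feature's observed mean. Each iteration
    centres the features, reconstructs the matrix at the given rank and
    replaces only the missing entries with the reconstruction (levels are
    clamped to [0, 1]); observed entries are never altered. Stops when the
    largest update is below ``tol``. Features with no observation at all
    cannot be initialised and are dropped with a report.
    """
    X = matrix.values.copy()
    miss = np.isnan(X)
    all_missing = miss.all(axis=0)
    dropped = [f for f, d in zip(matrix.features, all_missing) if d]
    if dropped:
        X = X[:, ~all_missing]
        miss = miss[:, ~all_missing]
    features = [f for f, d in zip(matrix.features, all_missing) if not d]
    n, p = X.shape
    if rank >= min(n, p):
        raise ValueError(f"rank {rank} must be < min(dims) = {min(n, p)}")
    if tol <= 0:
        raise ValueError("tol must be positive")

    if matrix.kind == "residual":
        X[miss] = 0.0
    else:
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        X[miss] = np.take(col_mean, np.nonzero(miss)[1])

    log_rows = []
    converged = False
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - mu, full_matrices=False)
        recon = mu + (U[:, :rank] * s[:rank]) @ Vt[:rank]
        if matrix.kind == "methylation_level":
            recon = np.clip(recon, 0.0, 1.0)
        delta = float(np.abs(recon[miss] - X[miss]).max()) if miss.any() else 0.0
        X[miss] = recon[miss]
        log_rows.append({"iteration": it, "max_change": delta})
        if delta < tol:
            converged = True
            break
    out = OmicsMatrix(X, matrix.pixels, features, matrix.kind)
    return ImputationResult(matrix=out, log=pd.DataFrame(log_rows),
                            dropped_features=dropped, converged=converged)


# ---------------------------------------------------------------------------
# PMD scores and TSS profiles
# ---------------------------------------------------------------------------


def _site_in_intervals(cg: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of each CpG call in any (fused) interval set."""
    member = np.zeros(len(cg), dtype=bool)
    merged = fuse_intervals(intervals[["contig", "start", "end"]])
    for contig, grp in merged.groupby("contig"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sel = cg["contig"] == contig
        pos0 = cg.loc[sel, "pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        member[np.flatnonzero(sel)] = ok
    return member


def pmd_score(table: pd.DataFrame, pmds: pd.DataFrame) -> pd.Series:
    """Per-pixel pooled CG methylation inside partially methylated domains.

    PMDs lose methylation with successive mitotic divisions, so this score
    acts as a mitotic-history proxy. Pixels with no covered PMD CpG are
    missing (NaN), indexed by (a_index, b_index).
    """
    cg = merge_cpg_strands(table)
    pixels = sorted(set(zip(table["a_index"], table["b_index"])))
    idx = pd.MultiIndex.from_tuples(pixels, names=["a_index", "b_index"])
    if cg.empty or pmds.empty:
        return pd.Series(np.nan, index=idx, name="pmd_meth")
    inside = cg[_site_in_intervals(cg, pmds)]
    agg = inside.groupby(["a_index", "b_index"])[["retained", "converted"]].sum()
    score = agg["retained"] / (agg["retained"] + agg["converted"])
    return score.reindex(idx).rename("pmd_meth")


def tss_profile(table: pd.DataFrame, tss: pd.DataFrame, flank_bp: int = 2000,
                n_bins: int = 20) -> pd.Series:
    """Average CpG methylation by signed distance to transcription starts.

    ``tss`` is BED-like with contig, start, end, strand; the TSS is the
    interval start for + genes and the end for - genes. Distances are
    strand-aware (upstream negative), binned into ``n_bins`` equal bins
    over [-flank_bp, +flank_bp]; each bin pools retained/converted counts
    across all pixels. Returns a Series indexed by bin-centre offset (bp).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cg = merge_cpg_strands(table)
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    ret = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    for contig, genes in tss.groupby("contig"):
        sub = cg[cg["contig"] == contig]
        if sub.empty:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        r = sub["retained"].to_numpy(float)
        c = sub["converted"].to_numpy(float)
        for g in genes.itertuples(index=False):
            strand = getattr(g, "strand", "+")
            t = g.start if strand == "+" else g.end
            d = (pos0 - t) * (1 if strand == "+" else -1)
            sel = (d >= -flank_bp) & (d <= flank_bp)
            if not sel.any():
                continue
            b = np.clip(np.digitize(d[sel], edges) - 1, 0, n_bins - 1)
            np.add.at(ret, b, r[sel])
            np.add.at(tot, b, r[sel] + c[sel])
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(tot > 0, ret / tot, np.nan)
    return pd.Series(prof, index=centers, name="methylation")
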
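"""Per-pixel methylation calling and quality control.

Demultiplexed, position-annotated DNA-library reads are turned into the
atomic methylome record: per (pixel, cytosine site, strand, context)
retained/converted counts. On a converted library a cytosine read as C was
protected (methylated or conversion failure, "retained") and one read as T
was deaminated ("converted"); the methylation level of a site is
retained / (retained + converted), a value in [0, 1].

QC metrics follow the conventions of enzymatic methyl-seq: per-context
retention percentages (mCG, mCA, mCC, mCT, pooled mCH), retention on the
mitochondrial contig (expected near zero), conversion efficiency measured
on methylation-free linker bases, duplication rate, and a knee-plot filter
separating real tissue pixels from low-signal barcodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demux import DemuxRecord, ReadLayout

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONTEXTS = ("CG", "CA", "CC", "CT")

#: canonical column order of a MethCallTable
METHCALL_COLUMNS = ["a_index", "b_index", "contig", "pos", "strand", "context",
                    "retained", "converted"]


# ---------------------------------------------------------------------------
# Context assignment
# ---------------------------------------------------------------------------


def assign_context(reference: str, position: int, strand: str = "+") -> str:
    """Dinucleotide context (CG/CA/CC/CT) of a cytosine.

    ``position`` is the 1-based coordinate of the cytosine on the forward
    reference. On the minus strand the cytosine sits opposite a forward G
    and its 3' neighbour is read from the reverse complement.
    """
    if not 1 <= position <= len(reference):
        raise ValueError(f"position {position} outside reference")
    if strand == "+":
        if reference[position - 1] != "C":
            raise ValueError(f"reference base at +{position} is not C")
        if position == len(reference):
            raise ValueError("cytosine at contig end has no 3' context")
        nxt = reference[position]
    elif strand == "-":
        if reference[position - 1] != "G":
            raise ValueError(f"no minus-strand C at {position} (forward base not G)")
        if position == 1:
            raise ValueError("cytosine at contig end has no 3' context")
        nxt = reference[position - 2].translate(_COMPLEMENT)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt not in "ACGT":
        raise ValueError(f"ambiguous 3' base {nxt!r}")
    return "CG" if nxt == "G" else "C" + nxt


# ---------------------------------------------------------------------------
# Read-level call extraction (alignment is external; positions are given)
# ---------------------------------------------------------------------------


def calls_from_reads(records: Sequence[DemuxRecord], positions: pd.DataFrame,
                     genome: dict[str, str]) -> pd.DataFrame:
    """Extract read-level cytosine observations from demultiplexed reads.

    ``positions`` maps read_id -> (contig, start) with ``start`` the 0-based
    leftmost coordinate of the insert on the forward strand (from an
    aligner, or from simulator provenance). For every reference C inside
    each insert the observed base is recorded; reads on contigs absent from
    ``genome`` are skipped.

    Returns one row per (read, cytosine): read_id, a_index, b_index,
    contig, read_start, pos (1-based), strand, context, observed.
    """
    pos_map = dict(zip(positions["read_id"], zip(positions["contig"], positions["start"])))
    is_c = {name: np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C")
            for name, seq in genome.items()}
    rows: dict[str, list] = {k: [] for k in
                             ("read_id", "a_index", "b_index", "contig",
                              "read_start", "pos", "observed")}
    for rec in records:
        if rec.status != "assigned" or rec.read_id not in pos_map:
            continue
        contig, start = pos_map[rec.read_id]
        if contig not in genome:
            continue
        start = int(start)
        ins = rec.insert
        stop = min(start + len(ins), len(genome[contig]))
        for off in np.flatnonzero(is_c[contig][start:stop]):
            rows["read_id"].append(rec.read_id)
            rows["a_index"].append(rec.a_index)
            rows["b_index"].append(rec.b_index)
            rows["contig"].append(contig)
            rows["read_start"].append(start)
            rows["pos"].append(start + int(off) + 1)
            rows["observed"].append(ins[off])
    calls = pd.DataFrame(rows)
    if calls.empty:
        calls["strand"] = pd.Series(dtype=object)
        calls["context"] = pd.Series(dtype=object)
        return calls
    calls["strand"] = "+"
    # vectorised context lookup: next forward base per (contig, pos)
    ctx = np.empty(len(calls), dtype=object)
    for contig, grp in calls.groupby("contig"):
        ref = genome[contig]
        nxt = np.array([ref[p] if p < len(ref) else "N" for p in grp["pos"]])
        ctx[grp.index] = np.where(nxt == "G", "CG",
                                  np.where(nxt == "A", "CA",
                                           np.where(nxt == "C", "CC", "CT")))
    calls["context"] = ctx
    return calls


# ---------------------------------------------------------------------------
# Aggregation and deduplication
# ---------------------------------------------------------------------------


@dataclass
class AggregateResult:
    table: pd.DataFrame          # MethCallTable
    duplication_rate: float      # removed reads / total reads
    n_reads_total: int
    n_reads_kept: int
    n_rejected_calls: int        # observations that were neither C nor T


def aggregate_calls(calls: pd.DataFrame, dedup: bool = True) -> AggregateResult:
    """Accumulate read-level observations into a per-pixel MethCallTable.

    Deduplication is keyed on (pixel, contig, leftmost read position,
    strand): the DNA library carries no UMI, so reads sharing a start are
    treated as PCR duplicates and only the first-seen read is kept.
    Observations that are neither C (retained) nor T (converted) — e.g.
    sequencing errors — are rejected and counted.
    """
    required = {"read_id", "a_index", "b_index", "contig", "read_start",
                "pos", "strand", "context", "observed"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")

    reads = calls[["read_id", "a_index", "b_index", "contig", "read_start",
                   "strand"]].drop_duplicates("read_id")
    n_total = len(reads)
    if dedup and n_total:
        kept_ids = reads.drop_duplicates(
            ["a_index", "b_index", "contig", "read_start", "strand"],
            keep="first")["read_id"]
        calls = calls[calls["read_id"].isin(set(kept_ids))]
        n_kept = len(kept_ids)
    else:
        n_kept = n_total
    dup_rate = (n_total - n_kept) / n_total if n_total else 0.0

    valid = calls["observed"].isin(["C", "T"])
    n_rejected = int((~valid).sum())
    calls = calls[valid]
    grouped = (calls.assign(retained=(calls["observed"] == "C").astype(int),
                            converted=(calls["observed"] == "T").astype(int))
               .groupby(["a_index", "b_index", "contig", "pos", "strand", "context"],
                        as_index=False)[["retained", "converted"]].sum())
    return AggregateResult(table=grouped[METHCALL_COLUMNS] if len(grouped)
                           else pd.DataFrame(columns=METHCALL_COLUMNS),
                           duplication_rate=dup_rate, n_reads_total=n_total,
                           n_reads_kept=n_kept, n_rejected_calls=n_rejected)


# ---------------------------------------------------------------------------
# Retention metrics
# ---------------------------------------------------------------------------


def retention_metrics(table: pd.DataFrame, mito_contigs: Sequence[str] = (),
                      contigs: str = "all") -> pd.DataFrame:
    """Per-pixel retention percentages by context.

    retention(context) = 100 * sum(retained) / sum(retained + converted)
    over all sites of that context; mCH pools CA, CC and CT. A context with
    zero coverage in a pixel is reported as missing (NaN), never as 0.
    ``contigs`` restricts to 'all', 'mito' or 'nuclear' contigs.
    """
    if table.empty:
        raise ValueError("empty MethCallTable")
    t = table
    if contigs == "mito":
        t = t[t["contig"].isin(mito_contigs)]
    elif contigs == "nuclear":
        t = t[~t["contig"].isin(mito_contigs)]
    elif contigs != "all":
        raise ValueError("contigs must be 'all', 'mito' or 'nuclear'")
    if t.empty:
        return pd.DataFrame(columns=["mCG", "mCA", "mCC", "mCT", "mCH"])

    sums = t.groupby(["a_index", "b_index", "context"])[["retained", "converted"]].sum()
    sums["total"] = sums["retained"] + sums["converted"]
    ret = sums["retained"].unstack("context")
    tot = sums["total"].unstack("context")
    out = pd.DataFrame(index=ret.index)
    for ctx in CONTEXTS:
        if ctx in ret.columns:
            out["m" + ctx] = 100.0 * ret[ctx] / tot[ctx]
        else:
            out["m" + ctx] = np.nan
    ch = [c for c in ("CA", "CC", "CT") if c in ret.columns]
    if ch:
        ch_ret = ret[ch].sum(axis=1, min_count=1)
        ch_tot = tot[ch].sum(axis=1, min_count=1)
        out["mCH"] = 100.0 * ch_ret / ch_tot
    else:
        out["mCH"] = np.nan
    return out


def pixel_qc(table: pd.DataFrame, mito_contigs: Sequence[str] = (),
             duplication_rate: float | None = None) -> pd.DataFrame:
    """Per-pixel QC summary: coverage, retention and mitochondrial retention."""
    cov = (table.assign(total=table["retained"] + table["converted"])
           .groupby(["a_index", "b_index"])
           .agg(n_sites=("pos", "nunique"), n_calls=("total", "sum")))
    ret = retention_metrics(table, mito_contigs, "all")
    qc = cov.join(ret)
    if mito_contigs and table["contig"].isin(mito_contigs).any():
        mito = retention_metrics(table, mito_contigs, "mito")
        # mito retention pools every context: all mito cytosines are unmethylated
        mt = table[table["contig"].isin(mito_contigs)]
        msum = mt.groupby(["a_index", "b_index"])[["retained", "converted"]].sum()
        qc["mito_retention"] = 100.0 * msum["retained"] / (
            msum["retained"] + msum["converted"])
    else:
        qc["mito_retention"] = np.nan
    if duplication_rate is not None:
        qc["duplication_pct"] = 100.0 * duplication_rate
    return qc


# ---------------------------------------------------------------------------
# Conversion efficiency on methylation-free linkers
# ---------------------------------------------------------------------------


def conversion_efficiency(observed_linkers: Iterable[str], reference: str) -> float:
    """Percent of linker cytosines read as T after deamination.

    The linkers ligated into every DNA read are synthetic and methylation
    free, so any retained C there is a conversion failure. Positions
    sequenced as N are excluded; other mismatches (sequencing errors) stay
    in the denominator, as only C-vs-T at reference-C positions is scored.
    """
    c_pos = [i for i, b in enumerate(reference) if b == "C"]
    if not c_pos:
        raise ValueError("linker reference contains no cytosine")
    n_obs = 0
    n_conv = 0
    for obs in observed_linkers:
        for i in c_pos:
            if i >= len(obs) or obs[i] == "N":
                continue
            n_obs += 1
            if obs[i] == "T":
                n_conv += 1
    if n_obs == 0:
        raise ValueError("no linker cytosines observed")
    return 100.0 * n_conv / n_obs


def linker_conversion_from_records(records: Sequence[DemuxRecord],
                                   layout: ReadLayout) -> float:
    """Conversion efficiency pooled over every linker segment of a layout."""
    refs = [ref for _, ref in layout.linker_slices()]
    tot_obs = tot_conv = 0
    for k, ref in enumerate(refs):
        c_pos = [i for i, b in enumerate(ref) if b == "C"]
        if not c_pos:
            continue
        for rec in records:
            if len(rec.linkers) <= k:
                continue
            obs = rec.linkers[k]
            for i in c_pos:
                if i >= len(obs) or obs[i] == "N":
                    continue
                tot_obs += 1
                tot_conv += obs[i] == "T"
    if tot_obs == 0:
        raise ValueError("no linker cytosines observed")
    return 100.0 * tot_conv / tot_obs


# ---------------------------------------------------------------------------
# Knee-plot pixel filter
# ---------------------------------------------------------------------------


@dataclass
class KneeResult:
    threshold: float
    kept: pd.Index                  # pixel identifiers passing the filter
    knee_rank: int                  # 1-based rank of the knee point
    max_distance: float             # perpendicular distance at the knee
    degenerate: bool
    curve: pd.DataFrame = field(repr=False, default=None)


def knee_filter(counts: pd.Series, tolerance: float = 1e-9) -> KneeResult:
    """Find the knee of the reads-per-pixel rank plot and filter pixels.

    Counts are sorted descending; on (log10 rank, log10(count + 1)) the
    knee is the point of maximum perpendicular distance to the chord
    joining the first and last points. Pixels with counts >= the knee count
    are kept. A straight-line curve (max distance below tolerance) is
    degenerate: all pixels are kept and a warning is issued.
    """
    counts = pd.Series(counts).astype(float)
    if len(counts) < 3:
        raise ValueError("knee detection needs at least 3 pixels")
    order = counts.sort_values(ascending=False, kind="stable")
    rank = np.arange(1, len(order) + 1)
    x = np.log10(rank)
    y = np.log10(order.to_numpy() + 1.0)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    pts = np.column_stack([x, y]) - p0
    if norm == 0:
        dist = np.zeros(len(x))
    else:
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    curve = pd.DataFrame({"pixel": order.index, "count": order.to_numpy(),
                          "log_rank": x, "log_count": y, "distance": dist})
    kmax = float(dist.max())
    if kmax < tolerance:
        warnings.warn("rank curve has no knee; keeping all pixels")
        return KneeResult(threshold=float(order.iloc[-1]), kept=counts.index,
                          knee_rank=len(order), max_distance=kmax,
                          degenerate=True, curve=curve)
    ki = int(dist.argmax())
    threshold = float(order.iloc[ki])
    kept = counts.index[counts >= threshold]
    return KneeResult(threshold=threshold, kept=kept, knee_rank=ki + 1,
                      max_distance=kmax, degenerate=False, curve=curve)


# ---------------------------------------------------------------------------
# Interchange: TSV and the Bismark coverage dialect
# ---------------------------------------------------------------------------


def write_methcall_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_methcall_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def export_bismark_coverage(table: pd.DataFrame, path: str | Path) -> None:
    """Long-format Bismark-coverage-dialect export with a leading pixel column.

    Columns: pixel (``A{i}B{j}``), contig, start, end (both the 1-based
    cytosine coordinate, per the dialect), methylation %, count methylated,
    count unmethylated.
    """
    t = table.copy()
    t["pixel"] = "A" + t["a_index"].astype(str) + "B" + t["b_index"].astype(str)
    t["meth_pct"] = 100.0 * t["retained"] / (t["retained"] + t["converted"])
    out = t[["pixel", "contig", "pos", "pos", "meth_pct", "retained", "converted"]]
    out.columns = ["pixel", "contig", "start", "end", "meth_pct",
                   "count_methylated", "count_unmethylated"]
    out.to_csv(path, sep="\t", index=False, header=False)


def import_bismark_coverage(path: str | Path, context: str = "CG",
                            strand: str = "+") -> pd.DataFrame:
    """Read a long-format Bismark-dialect file back into a MethCallTable.

    The dialect carries no strand or context, so both are filled with the
    given defaults (CG on the forward strand unless stated otherwise).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["pixel", "contig", "start", "end", "meth_pct",
                            "count_methylated", "count_unmethylated"])
    ab = df["pixel"].str.extract(r"A(\d+)B(\d+)").astype(int)
    return pd.DataFrame({
        "a_index": ab[0], "b_index": ab[1], "contig": df["contig"],
        "pos": df["start"], "strand": strand, "context": context,
        "retained": df["count_methylated"], "converted": df["count_unmethylated"],
    })[METHCALL_COLUMNS]
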
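"""Deamination-tolerant spatial barcode demultiplexing.

Each read of a spatially barcoded library carries two combinatorial
barcodes (A and B) that address one tissue pixel. In the DNA-methylation
library every unmethylated cytosine has been enzymatically deaminated to
uracil (read as T), so barcode matching for that library is performed in
the three-letter C->T-collapsed alphabet; whitelists must be validated to
remain collision-free after collapse ("no crosstalk"). The RNA library is
untouched by conversion and is matched in the raw four-letter alphabet.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

_VALID_BASES = frozenset("ACGTN")
_COLLAPSE = str.maketrans("C", "T")

# ---------------------------------------------------------------------------
# C->T collapse
# ---------------------------------------------------------------------------


def collapse_ct(seq: str) -> str:
    """Project a DNA string into the deamination-collapsed alphabet.

    Every C becomes T; A, G, T and N are unchanged. This is the image of a
    sequence under complete enzymatic conversion, so two barcodes are
    distinguishable on converted reads iff their collapsed images differ.
    """
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return seq.translate(_COLLAPSE)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Whitelists and read layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Ordered barcode set for one role (A or B); index i is 1-based."""

    sequences: tuple[str, ...]
    role: str = "A"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty whitelist")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"mixed barcode lengths in role {self.role}: {sorted(lengths)}")
        for s in self.sequences:
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(f"invalid symbols in barcode {s}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def collapsed(self) -> tuple[str, ...]:
        return tuple(collapse_ct(s) for s in self.sequences)

    @classmethod
    def read_tsv(cls, path: str | Path, role: str) -> "BarcodeWhitelist":
        df = pd.read_csv(path, sep="\t", names=["index", "sequence", "role"], header=None,
                         comment="#")
        df = df[df["role"] == role].sort_values("index")
        return cls(tuple(df["sequence"]), role=role)

    def to_tsv(self, path: str | Path, mode: str = "w") -> None:
        with open(path, mode) as fh:
            for i, s in enumerate(self.sequences, start=1):
                fh.write(f"{i}\t{s}\t{self.role}\n")


@dataclass(frozen=True)
class Segment:
    """One fixed-length piece of Read 2."""

    kind: str  # barcodeA | barcodeB | linker | umi | insert
    length: int  # insert may use 0 meaning "rest of read"
    expected: str | None = None  # reference sequence for linkers


@dataclass(frozen=True)
class ReadLayout:
    """Ordered fixed segments of Read 2; the insert consumes the remainder."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.segments]
        if kinds.count("umi") > 1:
            raise ValueError("at most one UMI segment")
        for s in self.segments:
            if s.kind != "insert" and s.length <= 0:
                raise ValueError(f"segment {s.kind} must have positive length")

    @property
    def fixed_length(self) -> int:
        """Bases consumed before the insert."""
        return sum(s.length for s in self.segments if s.kind != "insert")

    def slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        pos = 0
        for s in self.segments:
            if s.kind == "insert":
                out[s.kind] = slice(pos, None)
            else:
                out[s.kind] = slice(pos, pos + s.length)
                pos += s.length
        return out

    def linker_slices(self) -> list[tuple[slice, str]]:
        """(slice, expected sequence) for every linker segment."""
        out = []
        pos = 0
        for s in self.segments:
            if s.kind == "linker":
                out.append((slice(pos, pos + s.length), s.expected or ""))
            if s.kind != "insert":
                pos += s.length
        return out


#: Default Read 2 architecture: barcode B, linker, barcode A, linker, then
#: (for RNA) a 10-nt UMI, then the genomic/cDNA insert.
DEFAULT_LINKER1 = "GTCGCACTGATCGTC"  # 5 cytosines, methylation-free
DEFAULT_LINKER2 = "CATCGGACTCAGTCA"  # 5 cytosines, methylation-free


def default_layout(mode: str, barcode_len: int = 8, umi_len: int = 10) -> ReadLayout:
    segs = [
        Segment("barcodeB", barcode_len),
        Segment("linker", len(DEFAULT_LINKER1), DEFAULT_LINKER1),
        Segment("barcodeA", barcode_len),
        Segment("linker", len(DEFAULT_LINKER2), DEFAULT_LINKER2),
    ]
    if mode == "rna":
        segs.append(Segment("umi", umi_len))
    elif mode != "dna":
        raise ValueError(f"mode must be 'dna' or 'rna', got {mode!r}")
    segs.append(Segment("insert", 0))
    return ReadLayout(tuple(segs))


# ---------------------------------------------------------------------------
# Whitelist validation
# ---------------------------------------------------------------------------


@dataclass
class WhitelistReport:
    passed: bool
    min_distance_observed: int
    violations: list[tuple[int, int, int]]  # (index_i, index_j, distance)


def validate_whitelist(wl: BarcodeWhitelist, collapsed: bool = True,
                       min_distance: int = 1) -> WhitelistReport:
    """Check pairwise separation of a whitelist in the working alphabet.

    With ``collapsed=True`` the check runs on C->T-collapsed sequences, the
    alphabet in which converted DNA-library reads are matched; a pair at
    distance 0 there is exactly the "crosstalk" the barcode design must
    exclude. Fails iff any same-role pair is closer than ``min_distance``.
    """
    seqs = wl.collapsed() if collapsed else wl.sequences
    violations = []
    dmin = wl.length
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = hamming(seqs[i], seqs[j])
            dmin = min(dmin, d)
            if d < min_distance:
                violations.append((i + 1, j + 1, d))
    return WhitelistReport(passed=not violations, min_distance_observed=dmin,
                           violations=violations)


# ---------------------------------------------------------------------------
# Barcode matching
# ---------------------------------------------------------------------------

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def _encode(seqs: Sequence[str], collapsed: bool) -> np.ndarray:
    if collapsed:
        seqs = [s.translate(_COLLAPSE) for s in seqs]
    flat = "".join(seqs)
    arr = _ENC[np.frombuffer(flat.encode(), dtype=np.uint8)]
    return arr.reshape(len(seqs), -1)


def match_barcode(observed: str, wl: BarcodeWhitelist, max_hamming: int = 1,
                  collapsed: bool = False) -> tuple[int, int] | None:
    """Match one observed barcode against a whitelist.

    Returns ``(1-based index, distance)`` for the unique nearest whitelist
    entry within ``max_hamming`` mismatches (N counts as a mismatch), or
    ``None`` if no entry qualifies or the minimum is tied between entries.
    """
    if len(observed) != wl.length:
        raise ValueError(f"observed length {len(observed)} != barcode length {wl.length}")
    idx, dist = _match_batch(np.asarray([observed]), wl, max_hamming, collapsed)
    if idx[0] < 0:
        return None
    return int(idx[0]) + 1, int(dist[0])


def _match_batch(observed: np.ndarray, wl: BarcodeWhitelist, max_hamming: int,
                 collapsed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised nearest-unique matching; index -1 = unassigned."""
    obs = _encode(list(observed), collapsed)
    ref = _encode(list(wl.sequences), collapsed)
    # mismatches[n_reads, n_barcodes]; N (code 4) never equals a whitelist base
    # unless the whitelist itself contains N, which still counts as designed.
    mm = (obs[:, None, :] != ref[None, :, :]).sum(axis=2)
    best = mm.min(axis=1)
    n_best = (mm == best[:, None]).sum(axis=1)
    idx = mm.argmin(axis=1)
    ok = (best <= max_hamming) & (n_best == 1)
    idx = np.where(ok, idx, -1)
    return idx, best


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxRecord:
    read_id: str
    status: str  # assigned | no_match | ambiguous
    a_index: int | None = None
    b_index: int | None = None
    umi: str | None = None
    insert: str = ""
    linkers: tuple[str, ...] = ()  # observed linker bases, for conversion QC
    reason: str | None = None

    @property
    def pixel(self) -> tuple[int, int] | None:
        if self.status == "assigned":
            return (self.a_index, self.b_index)
        return None


def demux_reads(reads: Iterable[tuple[str, str]], layout: ReadLayout,
                wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist,
                mode: str = "dna", max_hamming: int = 1,
                chunk_size: int = 50_000) -> tuple[list[DemuxRecord], dict[str, int]]:
    """Assign reads to pixels via combinatorial barcodes A and B.

    ``mode='dna'`` matches both barcodes in the C->T-collapsed alphabet
    (converted library), ``mode='rna'`` in the raw alphabet. Reads shorter
    than the layout's fixed region become ``no_match`` with a reason rather
    than being dropped, so per-status counts always sum to the input count.
    """
    if mode not in ("dna", "rna"):
        raise ValueError(f"mode must be 'dna' or 'rna', got {mode!r}")
    collapsed = mode == "dna"
    for wl in (wl_a, wl_b):
        rep = validate_whitelist(wl, collapsed=collapsed, min_distance=1)
        if not rep.passed:
            raise ValueError(
                f"whitelist {wl.role} has colliding barcodes in the "
                f"{'collapsed' if collapsed else 'raw'} alphabet: {rep.violations[:5]}")
    sl = layout.slices()
    need = layout.fixed_length
    has_umi = "umi" in sl
    link_sl = [s for s, _ in layout.linker_slices()]

    records: list[DemuxRecord] = []
    summary = Counter(total=0, assigned=0, no_match=0, ambiguous=0)

    buf_ids: list[str] = []
    buf_seqs: list[str] = []

    def _flush() -> None:
        if not buf_ids:
            return
        obs_a = np.asarray([s[sl["barcodeA"]] for s in buf_seqs])
        obs_b = np.asarray([s[sl["barcodeB"]] for s in buf_seqs])
        ia, da = _match_batch(obs_a, wl_a, max_hamming, collapsed)
        ib, db = _match_batch(obs_b, wl_b, max_hamming, collapsed)
        for rid, seq, ai, bi in zip(buf_ids, buf_seqs, ia, ib):
            if ai >= 0 and bi >= 0:
                rec = DemuxRecord(rid, "assigned", int(ai) + 1, int(bi) + 1,
                                  umi=seq[sl["umi"]] if has_umi else None,
                                  insert=seq[sl["insert"]],
                                  linkers=tuple(seq[s] for s in link_sl))
                summary["assigned"] += 1
            else:
                # distinguish a genuine tie from no candidate at all
                status = "no_match"
                for obs, wl, i in ((seq[sl["barcodeA"]], wl_a, ai),
                                   (seq[sl["barcodeB"]], wl_b, bi)):
                    if i < 0 and _is_ambiguous(obs, wl, max_hamming, collapsed):
                        status = "ambiguous"
                rec = DemuxRecord(rid, status, insert=seq[sl["insert"]])
                summary[status] += 1
            records.append(rec)
        buf_ids.clear()
        buf_seqs.clear()

    for rid, seq in reads:
        summary["total"] += 1
        if len(seq) < need:
            _flush()  # keep output in input order
            records.append(DemuxRecord(rid, "no_match", reason="read shorter than layout"))
            summary["no_match"] += 1
            continue
        buf_ids.append(rid)
        buf_seqs.append(seq)
        if len(buf_ids) >= chunk_size:
            _flush()
    _flush()
    return records, dict(summary)


def _is_ambiguous(obs: str, wl: BarcodeWhitelist, max_hamming: int, collapsed: bool) -> bool:
    seqs = wl.collapsed() if collapsed else wl.sequences
    o = collapse_ct(obs) if collapsed else obs
    ds = sorted(hamming(o, s) for s in seqs)
    return ds[0] <= max_hamming and len(ds) > 1 and ds[1] == ds[0]


def tagged_read_name(rec: DemuxRecord) -> str:
    """`read|A{i}B{j}|UMI` naming for demuxed FASTQ output."""
    tag = f"A{rec.a_index}B{rec.b_index}" if rec.status == "assigned" else "unassigned"
    umi = rec.umi or ""
    return f"{rec.read_id}|{tag}|{umi}"


# ---------------------------------------------------------------------------
# RNA-contamination screen
# ---------------------------------------------------------------------------


def contamination_screen(inserts: Iterable[str],
                         motifs: dict[str, str] | None = None,
                         min_run: int = 10) -> pd.DataFrame:
    """Screen DNA-library inserts for RNA-library sequence signatures.

    Counts reads containing a homopolymer A run >= ``min_run``, a T run >=
    ``min_run``, or any configured literal motif (for example a template
    switch oligo). A converted DNA library should show none of these.
    """
    motifs = dict(motifs or {})
    pats = {"polyA": re.compile("A" * min_run), "polyT": re.compile("T" * min_run)}
    for name, m in motifs.items():
        pats[name] = re.compile(re.escape(m))
    counts = {name: 0 for name in pats}
    total = 0
    for ins in inserts:
        total += 1
        for name, pat in pats.items():
            if pat.search(ins):
                counts[name] += 1
    rows = [{"motif": name, "count": c,
             "fraction": c / total if total else 0.0} for name, c in counts.items()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ helpers
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (gzip allowed)."""
    from Bio import SeqIO

    import gzip

    p = Path(path)
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
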
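"""Synthetic spatial methylome + transcriptome datasets with ground truth.

The generator emulates a spatially barcoded co-profiling experiment on a
tissue section: a rows x cols pixel grid tiled by K contiguous anatomical
regions (Voronoi cells of seeded centroids), a small reference genome with
CpG sites at a chosen density, region-specific variably methylated
intervals on a ~75% CG-methylation baseline, near-zero CH methylation, a
fully unmethylated mitochondrial contig, negative-binomial RNA counts with
region marker genes, per-cytosine enzymatic conversion (~0.995), barcode
and sequencing errors, methylation-free linkers inside every DNA read, and
methylation-free spike-in reads.

Everything downstream of the generator can therefore be tested against the
`TruthBundle` it returns: region labels, per-site methylation fractions,
planted VMR intervals, per-gene expression means and a per-read provenance
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demux import (BarcodeWhitelist, ReadLayout, default_layout,
                    validate_whitelist, DEFAULT_LINKER1, DEFAULT_LINKER2)

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

#: fixed methylation-free spike-in insert (12 cytosines in 50 nt)
SPIKEIN_SEQ = "ATCGGATCCATTGCAGTCAGATCCGTACATTCAGCATTCGACCTGATCGA"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror an embryo-scale acquisition: a 50 x 50 barcode grid
    (2,500 pixels), baseline CG methylation 0.75, CH methylation 0,
    conversion probability 0.995 per cytosine, and four anatomical regions.
    """

    grid_rows: int = 50
    grid_cols: int = 50
    n_regions: int = 4
    genome: tuple[tuple[str, int, bool], ...] = (
        ("chr1", 600_000, False),
        ("chr2", 400_000, False),
        ("chrM", 16_000, True),
    )
    cpg_density: float = 10.0        # forced CpG sites per kb
    baseline_mcg: float = 0.75
    mch_level: float = 0.0
    n_vmrs_per_region: int = 10
    vmr_len_bp: int = 2_000
    vmr_delta: float = -0.5
    conversion_prob: float = 0.995
    seq_error: float = 0.001
    barcode_error: float = 0.01
    dup_fraction: float = 0.30       # target duplication rate of the DNA library
    reads_per_pixel_dna: int = 50
    reads_per_pixel_rna: int = 100   # nominal; realised count is NB-distributed
    read_length: int = 50
    n_genes: int = 100
    nb_mean: float = 1.0             # per-gene NB mean for non-marker genes
    nb_dispersion: float = 0.5       # var = mu + dispersion * mu^2
    marker_genes_per_region: int = 10
    marker_fold: float = 4.0
    n_spikein: int = 1_000
    barcode_len: int = 8
    umi_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_mcg", "mch_level", "conversion_prob",
                     "seq_error", "barcode_error", "dup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_regions > self.grid_rows * self.grid_cols:
            raise ValueError("n_regions exceeds number of grid pixels")
        if not -1.0 <= self.vmr_delta <= 1.0:
            raise ValueError("vmr_delta must be in [-1, 1]")
        if self.dup_fraction >= 1.0:
            raise ValueError("dup_fraction must be < 1")
        self.genome = tuple((str(n), int(l), bool(m)) for n, l, m in self.genome)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "genome" in d:
            d["genome"] = tuple(tuple(c) for c in d["genome"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["genome"] = [list(c) for c in self.genome]
        Path(path).write_text(yaml.safe_dump(d))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class TruthBundle:
    """Simulator ground truth for recovery tests."""

    config: SimConfig
    region_label: np.ndarray            # (rows, cols) int region per pixel
    genome: dict[str, str]              # contig -> sequence
    mito_contigs: tuple[str, ...]
    sites: pd.DataFrame                 # contig, pos (1-based, + strand C), context, is_mito
    meth: np.ndarray                    # (n_regions, n_sites) true methylation fraction
    vmrs: pd.DataFrame                  # region, contig, start, end (0-based half-open)
    rna_means: np.ndarray               # (n_regions, n_genes)
    gene_seqs: tuple[str, ...] = ()

    def region_of_pixel(self, a_index: int, b_index: int) -> int:
        return int(self.region_label[a_index - 1, b_index - 1])

    def site_meth_for_region(self, region: int) -> pd.Series:
        idx = pd.MultiIndex.from_frame(self.sites[["contig", "pos"]])
        return pd.Series(self.meth[region], index=idx)


def _random_sequence(rng: np.random.Generator, length: int,
                     cpg_per_kb: float) -> np.ndarray:
    """Random base codes with CG dinucleotides forced at the target density.

    Background CG dinucleotides are depleted (90% broken) before forcing,
    mimicking the CpG depletion of vertebrate genomes, so ``cpg_per_kb``
    effectively controls the realised CpG density.
    """
    codes = rng.choice(4, size=length, p=[0.3, 0.2, 0.2, 0.3]).astype(np.uint8)
    bg_cpg = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
    broken = bg_cpg[rng.random(len(bg_cpg)) < 0.9]
    codes[broken + 1] = _A
    n_cpg = int(length / 1000 * cpg_per_kb)
    if n_cpg > 0:
        slots = np.arange(0, length - 1, 2)
        pos = rng.choice(slots, size=min(n_cpg, len(slots)), replace=False)
        codes[pos] = _C
        codes[pos + 1] = _G
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def make_truth(config: SimConfig) -> TruthBundle:
    """Generate the tissue, genome and methylation ground truth.

    Deterministic given ``config.seed``. K spatially contiguous regions are
    the Voronoi cells of K centroid pixels; each region receives
    ``n_vmrs_per_region`` disjoint intervals in which its CG methylation is
    ``clamp(baseline_mcg + vmr_delta, 0, 1)``. CH sites sit at
    ``mch_level`` everywhere and mitochondrial cytosines at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    # --- region geometry: Voronoi partition of the grid ---
    rows, cols = config.grid_rows, config.grid_cols
    n_pix = rows * cols
    centroid_idx = rng.choice(n_pix, size=config.n_regions, replace=False)
    cy, cx = np.divmod(centroid_idx, cols)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr[..., None] - cy) ** 2 + (cc[..., None] - cx) ** 2
    region_label = d2.argmin(axis=2)

    # --- genome and cytosine sites ---
    genome_codes: dict[str, np.ndarray] = {}
    mito = tuple(name for name, _, is_m in config.genome if is_m)
    for name, length, _ in config.genome:
        genome_codes[name] = _random_sequence(rng, length, config.cpg_density)
    site_rows = []
    for name, length, is_m in config.genome:
        codes = genome_codes[name]
        cpos = np.flatnonzero(codes[:-1] == _C)  # 0-based; last base skipped (no 3' context)
        nxt = codes[cpos + 1]
        ctx = np.where(nxt == _G, "CG",
                       np.where(nxt == _A, "CA", np.where(nxt == _C, "CC", "CT")))
        site_rows.append(pd.DataFrame({
            "contig": name, "pos": cpos + 1, "context": ctx, "is_mito": is_m}))
    sites = pd.concat(site_rows, ignore_index=True)

    # --- planted VMR intervals, disjoint across regions ---
    vmr_meth = float(np.clip(config.baseline_mcg + config.vmr_delta, 0.0, 1.0))
    spacing = 2 * config.vmr_len_bp
    candidates = []
    for name, length, is_m in config.genome:
        if is_m:
            continue
        for start in range(0, length - config.vmr_len_bp + 1, spacing):
            candidates.append((name, start))
    n_needed = config.n_regions * config.n_vmrs_per_region
    if n_needed > len(candidates):
        raise ValueError(
            f"genome too small to place {n_needed} disjoint VMR intervals "
            f"({len(candidates)} candidate slots)")
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    vmr_rows = []
    for r in range(config.n_regions):
        for slot in chosen[r * config.n_vmrs_per_region:(r + 1) * config.n_vmrs_per_region]:
            name, start = candidates[slot]
            vmr_rows.append({"region": r, "contig": name,
                             "start": start, "end": start + config.vmr_len_bp})
    vmrs = pd.DataFrame(vmr_rows).sort_values(["contig", "start"]).reset_index(drop=True)

    # --- per-site truth methylation per region ---
    base = np.where(sites["context"] == "CG", config.baseline_mcg, config.mch_level)
    base = np.where(sites["is_mito"], 0.0, base)
    meth = np.tile(base, (config.n_regions, 1)).astype(float)
    for _, row in vmrs.iterrows():
        in_vmr = ((sites["contig"] == row["contig"])
                  & (sites["pos"] > row["start"]) & (sites["pos"] <= row["end"])
                  & (sites["context"] == "CG")).to_numpy()
        meth[row["region"], in_vmr] = vmr_meth

    # --- RNA truth: NB means with region markers ---
    rna_means = np.full((config.n_regions, config.n_genes), config.nb_mean)
    mpg = config.marker_genes_per_region
    for r in range(config.n_regions):
        lo = (r * mpg) % max(config.n_genes, 1)
        hi = min(lo + mpg, config.n_genes)
        rna_means[r, lo:hi] *= config.marker_fold
    gene_seqs = tuple(_decode(rng.choice(4, size=config.read_length).astype(np.uint8))
                      for _ in range(config.n_genes))

    return TruthBundle(
        config=config, region_label=region_label,
        genome={k: _decode(v) for k, v in genome_codes.items()},
        mito_contigs=mito, sites=sites, meth=meth, vmrs=vmrs,
        rna_means=rna_means, gene_seqs=gene_seqs)


# ---------------------------------------------------------------------------
# Whitelists
# ---------------------------------------------------------------------------


def make_whitelists(config: SimConfig) -> tuple[BarcodeWhitelist, BarcodeWhitelist]:
    """Random barcode whitelists that stay collision-free after C->T collapse.

    Barcodes are rejected unless their collapsed Hamming distance to every
    accepted barcode of the same role is >= 2, so DNA-mode matching with one
    allowed mismatch stays unambiguous by design.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))

    def _one_role(n: int, role: str) -> BarcodeWhitelist:
        accepted: list[str] = []
        collapsed: list[str] = []
        guard = 0
        while len(accepted) < n:
            guard += 1
            if guard > 100_000:
                raise RuntimeError("could not build a collision-free whitelist")
            seq = _decode(rng.choice(4, size=config.barcode_len).astype(np.uint8))
            col = seq.replace("C", "T")
            if all(sum(a != b for a, b in zip(col, c)) >= 2 for c in collapsed):
                accepted.append(seq)
                collapsed.append(col)
        return BarcodeWhitelist(tuple(accepted), role=role)

    wl_a = _one_role(config.grid_rows, "A")
    wl_b = _one_role(config.grid_cols, "B")
    assert validate_whitelist(wl_a, collapsed=True, min_distance=2).passed
    assert validate_whitelist(wl_b, collapsed=True, min_distance=2).passed
    return wl_a, wl_b


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    truth: TruthBundle
    wl_a: BarcodeWhitelist
    wl_b: BarcodeWhitelist
    layout_dna: ReadLayout
    layout_rna: ReadLayout
    dna_reads: list[tuple[str, str]]
    rna_reads: list[tuple[str, str]]
    provenance: pd.DataFrame


def _encode_seqs(seqs: list[str] | tuple[str, ...]) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGTN"):
        lut[ord(b)] = i
    flat = "".join(seqs)
    return lut[np.frombuffer(flat.encode(), dtype=np.uint8)].reshape(len(seqs), -1)


def _apply_seq_error(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    err = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape).astype(np.uint8)
    return np.where(err, (codes + shift) % 4, codes).astype(np.uint8)


def _rows_to_strings(codes: np.ndarray) -> list[str]:
    ascii_arr = _BASES[codes]
    s = ascii_arr.tobytes().decode()
    w = codes.shape[1]
    return [s[i * w:(i + 1) * w] for i in range(codes.shape[0])]


def _deaminate(codes: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Convert unmethylated C -> T with the given probability (methylation-free DNA)."""
    conv = (codes == _C) & (rng.random(codes.shape) < prob)
    return np.where(conv, _T, codes).astype(np.uint8)


def _make_prefixes(a_idx: np.ndarray, b_idx: np.ndarray, wl_a: BarcodeWhitelist,
                   wl_b: BarcodeWhitelist, deaminate: bool, conversion_prob: float,
                   barcode_error: float, rng: np.random.Generator) -> np.ndarray:
    """Read-2 prefix codes: bcB + linker1 + bcA + linker2 per read (0-based idx)."""
    bca = _encode_seqs(wl_a.sequences)[a_idx]
    bcb = _encode_seqs(wl_b.sequences)[b_idx]
    l1 = np.tile(_encode_seqs([DEFAULT_LINKER1])[0], (len(a_idx), 1))
    l2 = np.tile(_encode_seqs([DEFAULT_LINKER2])[0], (len(a_idx), 1))
    if deaminate:  # barcodes and linkers are unmethylated DNA
        bca = _deaminate(bca, conversion_prob, rng)
        bcb = _deaminate(bcb, conversion_prob, rng)
        l1 = _deaminate(l1, conversion_prob, rng)
        l2 = _deaminate(l2, conversion_prob, rng)
    for bc in (bca, bcb):
        hit = rng.random(len(bc)) < barcode_error
        pos = rng.integers(0, bc.shape[1], size=len(bc))
        shift = rng.integers(1, 4, size=len(bc)).astype(np.uint8)
        rows = np.flatnonzero(hit)
        bc[rows, pos[rows]] = (bc[rows, pos[rows]] + shift[rows]) % 4
    return np.hstack([bcb, l1, bca, l2])


def emit_reads(truth: TruthBundle, config: SimConfig | None = None,
               wl_a: BarcodeWhitelist | None = None,
               wl_b: BarcodeWhitelist | None = None) -> SimulatedDataset:
    """Emit the DNA (converted), RNA and spike-in read streams plus provenance.

    DNA reads: one genomic window per read; each cytosine is methylated
    with its site's truth fraction for the pixel's region, unmethylated
    cytosines deaminate to T with ``conversion_prob``, linkers and barcodes
    (methylation-free) deaminate at the same rate. RNA reads carry raw
    barcodes, a uniform-random UMI and a gene transcript insert; gene
    molecule counts are negative-binomial. A ``dup_fraction`` of DNA reads
    is re-emitted verbatim under fresh read ids to mimic PCR duplication.
    """
    config = config or truth.config
    if wl_a is None or wl_b is None:
        wl_a, wl_b = make_whitelists(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    L = config.read_length
    rows, cols = config.grid_rows, config.grid_cols
    n_pix = rows * cols
    prov_frames: list[pd.DataFrame] = []

    # per-position methylation truth, indexed by region then contig position
    meth_by_pos: dict[str, np.ndarray] = {}
    for name, length, _ in config.genome:
        arr = np.full((config.n_regions, length + 1), config.mch_level)
        sub = truth.sites[truth.sites["contig"] == name]
        arr[:, sub["pos"].to_numpy()] = truth.meth[:, sub.index.to_numpy()]
        meth_by_pos[name] = arr

    genome_codes = {k: _encode_seqs([v])[0] for k, v in truth.genome.items()}
    region_flat = truth.region_label.ravel()

    # ---------------- DNA library ----------------
    n_dna = n_pix * config.reads_per_pixel_dna
    pix = np.repeat(np.arange(n_pix), config.reads_per_pixel_dna)
    a_idx, b_idx = np.divmod(pix, cols)
    regions = region_flat[pix]
    contig_names = [n for n, _, _ in config.genome]
    lengths = np.array([l for _, l, _ in config.genome], dtype=float)
    contig_of_read = rng.choice(len(contig_names), size=n_dna, p=lengths / lengths.sum())
    starts = np.empty(n_dna, dtype=np.int64)
    inserts = np.empty((n_dna, L), dtype=np.uint8)
    pre_conv = np.empty((n_dna, L), dtype=np.uint8)
    for ci, name in enumerate(contig_names):
        m = contig_of_read == ci
        n_c = int(m.sum())
        if n_c == 0:
            continue
        clen = len(truth.genome[name])
        st = rng.integers(0, clen - L + 1, size=n_c)
        win = genome_codes[name][st[:, None] + np.arange(L)]
        pos1 = st[:, None] + np.arange(L) + 1  # 1-based cytosine coordinates
        p_meth = meth_by_pos[name][regions[m][:, None], pos1]
        is_c = win == _C
        methylated = rng.random(win.shape) < p_meth
        converted = is_c & ~methylated & (rng.random(win.shape) < config.conversion_prob)
        out = np.where(converted, _T, win).astype(np.uint8)
        starts[m] = st
        pre_conv[m] = win
        inserts[m] = _apply_seq_error(out, config.seq_error, rng)
    prefix = _make_prefixes(a_idx, b_idx, wl_a, wl_b, True, config.conversion_prob,
                            config.barcode_error, rng)
    dna_codes = np.hstack([prefix, inserts])
    dna_ids = [f"d{i:08d}" for i in range(n_dna)]
    dna_seqs = _rows_to_strings(dna_codes)

    prov_frames.append(pd.DataFrame({
        "read_id": dna_ids, "library": "dna",
        "a_index": a_idx + 1, "b_index": b_idx + 1, "region": regions,
        "contig": np.array(contig_names, dtype=object)[contig_of_read],
        "start": starts, "gene": -1, "umi": "",
        "is_duplicate": False,
        "pre_conversion": _rows_to_strings(pre_conv)}))

    # verbatim duplicate re-emission targeting dup_fraction duplication rate
    dna_reads = list(zip(dna_ids, dna_seqs))
    if config.dup_fraction > 0 and n_dna > 0:
        n_dup = int(round(config.dup_fraction / (1 - config.dup_fraction) * n_dna))
        picked = rng.integers(0, n_dna, size=n_dup)
        dup_ids = [f"d{n_dna + i:08d}" for i in range(n_dup)]
        dna_reads += [(di, dna_seqs[p]) for di, p in zip(dup_ids, picked)]
        dup_prov = prov_frames[0].iloc[picked].copy()
        dup_prov["read_id"] = dup_ids
        dup_prov["is_duplicate"] = True
        prov_frames.append(dup_prov)

    # ---------------- spike-ins (methylation-free, DNA library) ----------------
    if config.n_spikein > 0:
        spike_codes = np.tile(_encode_seqs([SPIKEIN_SEQ])[0], (config.n_spikein, 1))
        spike_codes = _deaminate(spike_codes, config.conversion_prob, rng)
        spike_codes = _apply_seq_error(spike_codes, config.seq_error, rng)
        s_pix = rng.integers(0, n_pix, size=config.n_spikein)
        sa, sb = np.divmod(s_pix, cols)
        s_prefix = _make_prefixes(sa, sb, wl_a, wl_b, True, config.conversion_prob,
                                  config.barcode_error, rng)
        spike_ids = [f"s{i:07d}" for i in range(config.n_spikein)]
        dna_reads += list(zip(spike_ids, _rows_to_strings(np.hstack([s_prefix, spike_codes]))))
        prov_frames.append(pd.DataFrame({
            "read_id": spike_ids, "library": "spikein",
            "a_index": sa + 1, "b_index": sb + 1, "region": region_flat[s_pix],
            "contig": "spikein", "start": 0, "gene": -1, "umi": "",
            "is_duplicate": False, "pre_conversion": SPIKEIN_SEQ}))

    # ---------------- RNA library ----------------
    alpha = config.nb_dispersion
    mu = truth.rna_means[region_flat]  # (n_pix, n_genes)
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = rng.poisson(lam)  # NB via gamma-Poisson mixture
    pix_r, gene_r = np.nonzero(counts)
    reps = counts[pix_r, gene_r]
    pix_r = np.repeat(pix_r, reps)
    gene_r = np.repeat(gene_r, reps)
    n_rna = len(pix_r)
    ra, rb = np.divmod(pix_r, cols)
    umis = rng.integers(0, 4, size=(n_rna, config.umi_len)).astype(np.uint8)
    gene_codes = _encode_seqs(truth.gene_seqs) if config.n_genes else np.zeros((0, L), np.uint8)
    r_ins = _apply_seq_error(gene_codes[gene_r], config.seq_error, rng)
    r_prefix = _make_prefixes(ra, rb, wl_a, wl_b, False, 0.0, config.barcode_error, rng)
    rna_codes = np.hstack([r_prefix, umis, r_ins])
    rna_ids = [f"r{i:08d}" for i in range(n_rna)]
    rna_reads = list(zip(rna_ids, _rows_to_strings(rna_codes)))
    prov_frames.append(pd.DataFrame({
        "read_id": rna_ids, "library": "rna",
        "a_index": ra + 1, "b_index": rb + 1, "region": region_flat[pix_r],
        "contig": "", "start": -1, "gene": gene_r,
        "umi": _rows_to_strings(umis), "is_duplicate": False, "pre_conversion": ""}))

    provenance = pd.concat(prov_frames, ignore_index=True)
    return SimulatedDataset(
        truth=truth, wl_a=wl_a, wl_b=wl_b,
        layout_dna=default_layout("dna", config.barcode_len, config.umi_len),
        layout_rna=default_layout("rna", config.barcode_len, config.umi_len),
        dna_reads=dna_reads, rna_reads=rna_reads, provenance=provenance)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """One-call convenience: truth + whitelists + reads + provenance."""
    truth = make_truth(config)
    wl_a, wl_b = make_whitelists(config)
    return emit_reads(truth, config, wl_a, wl_b)


# ---------------------------------------------------------------------------
# Closed-form expectations (oracle for recovery tests)
# ---------------------------------------------------------------------------


def expected_metrics(config: SimConfig) -> pd.DataFrame:
    """Closed-form expectations of the QC estimators under this config.

    Retention (fraction of cytosines read as C) at a context with true
    methylation p and conversion probability c is ``p + (1 - p)(1 - c)``:
    methylated cytosines are protected, unmethylated ones survive only on
    conversion failure. Conversion efficiency on methylation-free DNA is c.
    """
    m, h, c = config.baseline_mcg, config.mch_level, config.conversion_prob
    rows = [
        {"metric": "cg_retention", "expected": m + (1 - m) * (1 - c)},
        {"metric": "ch_retention", "expected": h + (1 - h) * (1 - c)},
        {"metric": "conversion_efficiency", "expected": c},
        {"metric": "mito_retention", "expected": 1 - c},
    ]
    return pd.DataFrame(rows).set_index("metric")
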
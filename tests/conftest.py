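import numpy as np
import pandas as pd
import pytest

import sdmt


@pytest.fixture(scope="session")
def small_config() -> sdmt.SimConfig:
    """A 200-pixel, 216-kb dataset small enough for fast whole-pipeline tests."""
    return sdmt.SimConfig(
        grid_rows=20, grid_cols=10, n_regions=4,
        genome=(("chr1", 120_000, False), ("chr2", 80_000, False), ("chrM", 16_000, True)),
        n_vmrs_per_region=3, reads_per_pixel_dna=100, n_spikein=200, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sdmt.SimulatedDataset:
    return sdmt.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def demuxed_dna(small_dataset):
    records, summary = sdmt.demux_reads(
        small_dataset.dna_reads, small_dataset.layout_dna,
        small_dataset.wl_a, small_dataset.wl_b, mode="dna")
    return records, summary


@pytest.fixture(scope="session")
def call_table(small_dataset, demuxed_dna):
    records, _ = demuxed_dna
    calls = sdmt.calls_from_reads(records, small_dataset.provenance,
                                  small_dataset.truth.genome)
    return sdmt.aggregate_calls(calls)


def sample_call_table(truth: sdmt.TruthBundle, n_pixels: int, reads_per_site: float,
                      seed: int) -> pd.DataFrame:
    """Direct binomial sampling of a MethCallTable from simulator truth.

    Bypasses read emission: per (pixel, CpG site) draws Poisson coverage and
    binomial retained counts at probability p + (1-p)(1-c). Fast path for
    feature-space tests that do not exercise the read machinery.
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    sites = truth.sites[truth.sites["context"] == "CG"].reset_index()
    region_flat = truth.region_label.ravel()[:n_pixels]
    rows = []
    for pix in range(n_pixels):
        p = truth.meth[region_flat[pix], sites["index"].to_numpy()]
        p_ret = p + (1 - p) * (1 - cfg.conversion_prob)
        cov = rng.poisson(reads_per_site, size=len(sites))
        has = cov > 0
        ret = rng.binomial(cov[has], p_ret[has])
        sub = sites[has]
        rows.append(pd.DataFrame({
            "a_index": pix // cfg.grid_cols + 1, "b_index": pix % cfg.grid_cols + 1,
            "contig": sub["contig"].to_numpy(), "pos": sub["pos"].to_numpy(),
            "strand": "+", "context": "CG",
            "retained": ret, "converted": cov[has] - ret}))
    return pd.concat(rows, ignore_index=True)
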
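import dataclasses

import pandas as pd
import pytest

from poolfst import RunConfig, SimConfig, SiteCounts, simulate_dataset

GROUPS = {"female": ["F1", "F2"], "male": ["M1", "M2"]}
REPS = [r for rs in GROUPS.values() for r in rs]


def make_site(chrom="chr1", pos=100, ref="A", **reps) -> SiteCounts:
    """Build a SiteCounts with zero-filled count maps per replicate."""
    counts = {}
    for rep, c in reps.items():
        full = {b: 0 for b in ("A", "C", "G", "T", "indel")}
        full.update(c)
        counts[rep] = full
    return SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)


def counts_frame(rows, reps=REPS) -> pd.DataFrame:
    """rows: list of (chrom, pos, ref, {rep: {base: count}})."""
    out = []
    for chrom, pos, ref, repcounts in rows:
        row = {"chrom": chrom, "pos": pos, "ref": ref}
        for rep in reps:
            c = repcounts.get(rep, {})
            for b in ("A", "C", "G", "T", "indel"):
                row[f"{rep}_{b}"] = c.get(b, 0)
        out.append(row)
    return pd.DataFrame(out)


def write_counts_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across pipeline tests."""
    cfg = SimConfig(seed=11, genes_per_chrom=20, snps_per_gene=4, depth_mean=120.0)
    genes, truth, counts = simulate_dataset(cfg)
    return cfg, genes, truth, counts


@pytest.fixture(scope="session")
def aaa_sim():
    """One aaa_like run at the depth used for recovery checks."""
    from poolfst import scenario_presets

    cfg = dataclasses.replace(scenario_presets()["aaa_like"], depth_mean=150.0, seed=5)
    genes, truth, counts = simulate_dataset(cfg)
    return cfg, genes, truth, counts
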
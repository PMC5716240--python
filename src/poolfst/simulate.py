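"""Synthetic pooled exome sequencing with a configurable proto-Y architecture.

The generator emulates the study design the pipeline targets: male and
female pools of 12 mosquitoes, two biological replicates per sex, per-site
coverage drawn from an overdispersed (negative-binomial) law, and a
sex-linked region on chromosome 1 where males are obligate Mm heterozygotes.

Model
-----
* **Genome**: three chromosomes, non-overlapping genes of fixed length laid
  out with fixed spacing; SNP positions drawn uniformly within gene spans.
* **Background site**: one population variant frequency ``p ~ Beta(a0, b0)``
  shared by the sexes; each replicate pool draws ``2 x pool_size`` allele
  copies binomially at ``p`` (finite-pool noise), then reads binomially at
  the realised pool frequency.
* **Sex-linked site** (inside ``sexlink_region``, with probability ``d``,
  when ``recomb_suppressed``): X and Y haplotypes carry divergent variant
  frequencies (default a fixed difference, ``p_X = 0``, ``p_Y = 1``).
  Female pools draw ``2 x pool_size`` X copies; male pools draw
  ``pool_size`` X copies plus ``pool_size`` Y copies — every male carries
  exactly one Y, so at a fixed difference the male pool frequency is
  exactly 0.5 with no finite-pool variance, as Mm heterozygosity implies.
* **Reads**: per replicate and site, depth ``~ NegBin(mean, dispersion)``;
  base calls follow the pool frequency with symmetric miscalls at
  ``error_rate`` redistributed uniformly over the other three bases.

Everything is deterministic given the root seed (child streams are spawned
per stage).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import diffstats
from .io_tables import BASES, GeneInterval
from .sexlink import RegionSpec


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of one synthetic dataset."""

    seed: int = 0
    n_chrom: int = 3
    genes_per_chrom: int = 100
    gene_length: int = 2000
    gene_spacing: int = 1000
    snps_per_gene: int = 5
    pool_size: int = 12          # mosquitoes per pool
    replicates: int = 2          # biological replicates per sex
    depth_mean: float = 180.0    # per-site, per-replicate coverage mean
    depth_dispersion: float = 3.0
    error_rate: float = 1e-3     # per-read miscall probability
    bg_alpha: float = 0.3        # background frequency law Beta(bg_alpha, bg_beta)
    bg_beta: float = 5.0
    sexlink_region: RegionSpec | None = None  # None -> central third of chr1
    divergence: float = 0.8      # P(region SNP is X-Y differentiated)
    divergence_offset: float | None = None  # None -> fixed difference
    recomb_suppressed: bool = True
    background_diversity_scale: dict[str, float] = field(
        default_factory=lambda: {"female": 1.0, "male": 1.0}
    )

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 1.0):
            raise ConfigError("divergence must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth parameters must be positive")
        if self.pool_size < 1 or self.replicates < 1:
            raise ConfigError("pool_size and replicates must be >= 1")
        if self.snps_per_gene > self.gene_length:
            raise ConfigError("snps_per_gene cannot exceed gene_length")

    @property
    def chrom_length(self) -> int:
        return self.genes_per_chrom * (self.gene_length + self.gene_spacing)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def resolved_region(self) -> RegionSpec:
        if self.sexlink_region is not None:
            return self.sexlink_region
        L = self.chrom_length
        return RegionSpec("chr1", L // 3 + 1, 2 * L // 3, "chr1-central-third")

    def replicate_names(self) -> dict[str, list[str]]:
        return {
            "female": [f"F{r + 1}" for r in range(self.replicates)],
            "male": [f"M{r + 1}" for r in range(self.replicates)],
        }

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sexlink_region"] = dataclasses.asdict(self.resolved_region())
        return json.dumps(d, indent=2, sort_keys=True)


def scenario_presets() -> dict[str, SimConfig]:
    """Named study scenarios.

    ``aaa_like``: a narrow M-locus-proximal cluster — the sex-linked region
    is the central third of chromosome 1 with suppressed recombination.
    ``senaae_like``: chromosome-wide X-Y differentiation — the region spans
    90% of chromosome 1 — with elevated background diversity in both sexes
    and deeper coverage.  ``null``: no sex-linked sites at all.
    """
    base = SimConfig()
    L = base.chrom_length
    return {
        "aaa_like": replace(base, depth_mean=180.0),
        "senaae_like": replace(
            base,
            depth_mean=261.0,
            sexlink_region=RegionSpec("chr1", L // 20 + 1, L - L // 20, "chr1-wide"),
            background_diversity_scale={"female": 1.3, "male": 1.3},
        ),
        "null": replace(base, divergence=0.0),
    }


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Lay out genes and SNP positions.

    Returns ``(genes, snps)`` where ``genes`` is a list of ``GeneInterval``
    and ``snps`` a frame with ``chrom, pos, gene_id`` sorted by position.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    unit = config.gene_length + config.gene_spacing
    if config.gene_length < 1 or config.gene_spacing < 0:
        raise ConfigError("infeasible gene length/spacing")
    genes: list[GeneInterval] = []
    rows = []
    for chrom in config.chrom_names:
        for k in range(config.genes_per_chrom):
            start = k * unit + 1
            end = start + config.gene_length - 1
            gid = f"{chrom}G{k + 1:04d}"
            genes.append(GeneInterval(gid, chrom, start, end))
            offs = rng.choice(config.gene_length, size=config.snps_per_gene, replace=False)
            for o in np.sort(offs):
                rows.append((chrom, start + int(o), gid))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])
    return genes, snps


def simulate_frequencies(
    config: SimConfig, genome, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw ground-truth allele frequencies (the SimTruth site table).

    Columns: chrom, pos, gene_id, ref, variant, sexlinked, p_x, p_y,
    freq_female, freq_male.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    genes, snps = genome
    n = len(snps)
    truth = snps.copy()

    ref_idx = rng.integers(0, 4, size=n)
    var_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    truth["ref"] = np.array(BASES)[ref_idx]
    truth["variant"] = np.array(BASES)[var_idx]

    scale = float(np.mean(list(config.background_diversity_scale.values())))
    p_bg = rng.beta(config.bg_alpha * scale, config.bg_beta, size=n)

    region = config.resolved_region()
    in_region = (truth["chrom"] == region.chrom) & truth["pos"].between(
        region.start, region.end
    )
    sexlinked = in_region.to_numpy() & (rng.random(n) < config.divergence)
    if not config.recomb_suppressed:
        sexlinked[:] = False
    truth["sexlinked"] = sexlinked

    if config.divergence_offset is None:
        p_x = np.where(sexlinked, 0.0, p_bg)
        p_y = np.where(sexlinked, 1.0, p_bg)
    else:
        off = config.divergence_offset
        p_x = np.where(sexlinked, np.clip(p_bg - off / 2, 0.0, 1.0), p_bg)
        p_y = np.where(sexlinked, np.clip(p_bg + off / 2, 0.0, 1.0), p_bg)
    truth["p_x"] = p_x
    truth["p_y"] = p_y
    truth["freq_female"] = p_x
    truth["freq_male"] = np.where(sexlinked, (p_x + p_y) / 2.0, p_bg)
    return truth


def gene_truth(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expected inter-sex F_ST at the true pool frequencies.

    Uses equal coverage weights and the analysis default of
    ``pool_size x replicates`` mosquitoes per sex.
    """
    n = config.pool_size * config.replicates
    f = truth["freq_female"].to_numpy()
    m = truth["freq_male"].to_numpy()
    a, b = diffstats.site_components(f, m, 1.0, 1.0, n, n)
    t = truth[["gene_id", "chrom", "sexlinked"]].copy()
    t["a"], t["b"] = a, b
    agg = t.groupby("gene_id").agg(
        chrom=("chrom", "first"),
        m_snps=("a", "size"),
        n_sexlinked=("sexlinked", "sum"),
        sum_a=("a", "sum"),
        sum_b=("b", "sum"),
    ).reset_index()
    denom = agg["sum_a"] + agg["sum_b"]
    agg["expected_fst"] = np.where(
        denom > diffstats.UNDEF_TOL, agg["sum_a"] / denom.where(denom > 0, 1.0), np.nan
    )
    return agg


def _multinomial_counts(
    rng: np.random.Generator, depth: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Vectorised multinomial via sequential conditional binomials.

    ``depth``: (n,), ``probs``: (n, 4) rows summing to 1. Returns (n, 4).
    """
    n = len(depth)
    out = np.zeros((n, 4), dtype=np.int64)
    remaining = depth.astype(np.int64).copy()
    prob_left = np.ones(n)
    for b in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(prob_left > 0, probs[:, b] / prob_left, 0.0)
        q = np.clip(q, 0.0, 1.0)
        out[:, b] = rng.binomial(remaining, q)
        remaining -= out[:, b]
        prob_left -= probs[:, b]
    out[:, 3] = remaining
    return out


def simulate_readcounts(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample a readcount table (io_tables dialect) from ground truth."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    n = len(truth)
    N = config.pool_size
    copies = 2 * N
    e = config.error_rate
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)

    ref_idx = pd.Series(truth["ref"]).map({b: i for i, b in enumerate(BASES)}).to_numpy()
    var_idx = pd.Series(truth["variant"]).map({b: i for i, b in enumerate(BASES)}).to_numpy()
    sexlinked = truth["sexlinked"].to_numpy()
    p_x = truth["p_x"].to_numpy()
    p_y = truth["p_y"].to_numpy()
    rows_idx = np.arange(n)

    out = truth[["chrom", "pos", "ref"]].copy()
    for sex, reps in config.replicate_names().items():
        freq = truth[f"freq_{sex}"].to_numpy()
        for rep in reps:
            # 1) finite-pool resampling of allele copies
            if sex == "male":
                k = np.where(
                    sexlinked,
                    rng.binomial(N, p_x) + rng.binomial(N, p_y),
                    rng.binomial(copies, freq),
                )
            else:
                k = rng.binomial(copies, np.where(sexlinked, p_x, freq))
            f_pool = k / copies
            # 2) coverage depth
            depth = rng.negative_binomial(nb_n, nb_p, size=n)
            # 3) reads with symmetric miscalls
            probs = np.full((n, 4), 0.0)
            probs += (f_pool * (e / 3))[:, None]
            probs += ((1.0 - f_pool) * (e / 3))[:, None]
            probs[rows_idx, var_idx] = f_pool * (1.0 - e) + (1.0 - f_pool) * (e / 3)
            probs[rows_idx, ref_idx] = (1.0 - f_pool) * (1.0 - e) + f_pool * (e / 3)
            counts = _multinomial_counts(rng, depth, probs)
            for i, b in enumerate(BASES):
                out[f"{rep}_{b}"] = counts[:, i]
            out[f"{rep}_indel"] = 0
    return out


def simulate_dataset(config: SimConfig):
    """Run the three generator stages; returns (genes, truth, readcounts)."""
    streams = np.random.SeedSequence(config.seed).spawn(3)
    genome = simulate_genome(config, np.random.default_rng(streams[0]))
    truth = simulate_frequencies(config, genome, np.random.default_rng(streams[1]))
    counts = simulate_readcounts(config, truth, np.random.default_rng(streams[2]))
    return genome[0], truth, counts


def write_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write readcounts TSV, BED annotation, truth tables and
    the fully resolved configuration; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth, counts = simulate_dataset(config)
    paths = {
        "readcounts": outdir / "readcounts.tsv",
        "genes": outdir / "genes.bed",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "config": outdir / "sim_config.json",
    }
    counts.to_csv(paths["readcounts"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    truth.to_csv(paths["truth_sites"], sep="\t", index=False)
    gene_truth(config, truth).to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["config"].write_text(config.to_json())
    return paths
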
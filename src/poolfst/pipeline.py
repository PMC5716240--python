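"""End-to-end runs: configuration, composition of the stages, manifests.

Configuration layering is defaults < config file < explicit overrides; the
fully resolved configuration and a manifest (tool version, parameters, input
checksums) are written next to every output set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from . import diffstats, filtering, io_tables, sexlink, simulate

log = logging.getLogger("poolfst")

DEFAULT_GROUPS = {"female": ["F1", "F2"], "male": ["M1", "M2"]}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    readcounts: str = ""
    genes: str = ""
    genes_format: str = "BED"
    outdir: str = "poolfst_out"
    groups: dict[str, list[str]] = field(default_factory=lambda: {
        g: list(r) for g, r in DEFAULT_GROUPS.items()
    })
    min_coverage: int = filtering.DEFAULT_MIN_COVERAGE
    concordance_mode: str = "shared_variant"
    monomorphic_drop: bool = True
    n: dict[str, int] = field(default_factory=lambda: {
        "female": diffstats.DEFAULT_N, "male": diffstats.DEFAULT_N
    })
    fst_threshold: float = sexlink.DEFAULT_FST_THRESHOLD
    test_mode: str = "unpaired"
    regions: list[dict] | None = None  # [{chrom,start,end,label}, ...]
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fst_threshold <= 1):
            raise ConfigError("fst_threshold must lie in (0, 1]")
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        for g in self.groups:
            self.n.setdefault(g, diffstats.DEFAULT_N)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def params(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # not a scientific parameter; keeps reruns byte-identical
        d["groups"] = json.dumps(self.groups, sort_keys=True)
        d["n"] = json.dumps(self.n, sort_keys=True)
        d["regions"] = json.dumps(self.regions, sort_keys=True)
        return d

    def region_specs(self, genes: list[io_tables.GeneInterval]) -> list[sexlink.RegionSpec]:
        """Configured regions, or the defaults: whole chromosome 1 and its
        central third (the M-locus-proximal proxy), bounds taken from the
        annotated extent."""
        if self.regions:
            return [sexlink.RegionSpec(**r) for r in self.regions]
        by_chrom: dict[str, int] = {}
        for g in genes:
            by_chrom[g.chrom] = max(by_chrom.get(g.chrom, 0), g.end)
        chrom1 = sorted(by_chrom)[0]
        L = by_chrom[chrom1]
        return [
            sexlink.RegionSpec(chrom1, 1, L, f"{chrom1}-whole"),
            sexlink.central_third(chrom1, L),
        ]


@dataclass
class RunResult:
    """In-memory products of one analysis run."""

    pooled: pd.DataFrame
    filter_summary: dict[str, int]
    site_stats: pd.DataFrame
    gene_stats: pd.DataFrame
    genes: list[io_tables.GeneInterval]
    groups: list[str]


def analyze_counts(
    counts: pd.DataFrame,
    genes: list[io_tables.GeneInterval],
    config: RunConfig,
) -> RunResult:
    """Filter a readcount frame and compute site- and gene-wise statistics."""
    groups = list(config.groups)
    pooled, summary = filtering.filter_sites(
        counts, config.groups,
        min_coverage=config.min_coverage,
        concordance_mode=config.concordance_mode,
        monomorphic_drop=config.monomorphic_drop,
    )
    log.info("filtering: %s", summary)
    site_stats = diffstats.compute_site_stats(pooled, groups, config.n)
    gene_stats = diffstats.compute_gene_stats(site_stats, genes, groups)
    log.info("sites retained: %d; genes with >=1 SNP: %d",
             len(site_stats), len(gene_stats))
    return RunResult(pooled, summary, site_stats, gene_stats, genes, groups)


def load_inputs(config: RunConfig):
    reps = [r for reps in config.groups.values() for r in reps]
    counts = io_tables.read_readcounts(config.readcounts, reps)
    genes = io_tables.parse_gene_intervals(config.genes, config.genes_format)
    return counts, genes


def analyze_run(config: RunConfig) -> RunResult:
    counts, genes = load_inputs(config)
    return analyze_counts(counts, genes, config)


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, outputs: list[Path]) -> None:
    manifest = {
        "tool": "poolfst",
        "version": io_tables.__version__,
        "parameters": config.params(),
        "inputs": {
            p: _md5(p) for p in (config.readcounts, config.genes) if p and Path(p).exists()
        },
        "outputs": sorted(str(p.name) for p in outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write_filter_summary(summary: dict, outdir: Path, params: dict) -> Path:
    df = pd.DataFrame(
        [(k, v) for k, v in summary.items()], columns=["category", "count"]
    )
    path = outdir / "filter_summary.tsv"
    io_tables.write_plain_table(df, path, params)
    return path


def run_sites(config: RunConfig) -> Path:
    """Site-level statistics TSV (plus filter summary and manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = analyze_run(config)
    params = config.params()
    site_path = outdir / "site_stats.tsv"
    io_tables.write_site_table(res.site_stats, site_path, res.groups, params)
    fs = _write_filter_summary(res.filter_summary, outdir, params)
    _write_manifest(config, outdir, [site_path, fs])
    return site_path


def run_genes(config: RunConfig) -> Path:
    """Gene-level statistics TSV (plus site table, filter summary, manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = analyze_run(config)
    params = config.params()
    site_path = outdir / "site_stats.tsv"
    gene_path = outdir / "gene_stats.tsv"
    io_tables.write_site_table(res.site_stats, site_path, res.groups, params)
    io_tables.write_gene_table(res.gene_stats, gene_path, res.groups, params)
    fs = _write_filter_summary(res.filter_summary, outdir, params)
    _write_manifest(config, outdir, [site_path, gene_path, fs])
    return gene_path


def run_tests(config: RunConfig) -> dict[str, Path]:
    """Inference reports: flagged genes, region tests, enrichment, beta fit,
    and figure-style scatter data."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = analyze_run(config)
    params = config.params()
    groups = res.groups

    flagged_df = sexlink.classify_high_fst(res.gene_stats, config.fst_threshold)
    flagged_ids = flagged_df.loc[flagged_df["flagged"], "gene_id"].tolist()
    log.info("flagged genes (fst >= %.3f): %d of %d",
             config.fst_threshold, len(flagged_ids), len(flagged_df))

    regions = config.region_specs(res.genes)
    region_df = sexlink.region_summary(res.gene_stats, regions, groups, config.test_mode)
    enr = sexlink.chromosome_enrichment(res.gene_stats, flagged_ids)
    enr_df = pd.DataFrame([
        {"chrom": r.region_label, "odds_ratio": r.statistic, "p_value": r.p_value,
         **r.n} for r in enr
    ])
    try:
        beta = sexlink.fit_beta(res.gene_stats["fst"].to_numpy())
    except Exception as exc:  # too few genes for a fit is a report, not a crash
        log.warning("beta fit unavailable: %s", exc)
        beta = {"alpha": float("nan"), "beta": float("nan"), "n": 0,
                "mean": float("nan"), "var": float("nan"), "ks_stat": float("nan")}
    beta_df = pd.DataFrame([beta])
    scatter_cols = ["gene_id", "chrom", "midpoint", "fst"] + [
        f"mean_hexp_{g}" for g in groups
    ]
    paths = {}
    tables = {
        "flagged_genes": flagged_df[flagged_df["flagged"]],
        "region_tests": region_df,
        "chromosome_enrichment": enr_df,
        "beta_fit": beta_df,
        "gene_scatter": res.gene_stats[scatter_cols],
    }
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        io_tables.write_plain_table(df, p, params)
        paths[name] = p
    fs = _write_filter_summary(res.filter_summary, outdir, params)
    paths["filter_summary"] = fs
    _write_manifest(config, outdir, list(paths.values()))
    return paths


def run_compare(config_a: RunConfig, config_b: RunConfig, outdir) -> dict[str, Path]:
    """Cross-population reports: flagged-gene intersection and
    between-population F_ST per shared sex (female-vs-female, male-vs-male)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res_a = analyze_run(config_a)
    res_b = analyze_run(config_b)
    fa = sexlink.classify_high_fst(res_a.gene_stats, config_a.fst_threshold)
    fb = sexlink.classify_high_fst(res_b.gene_stats, config_b.fst_threshold)
    set_a = set(fa.loc[fa["flagged"], "gene_id"])
    set_b = set(fb.loc[fb["flagged"], "gene_id"])
    gene_chrom = {g.gene_id: g.chrom for g in res_a.genes + res_b.genes}
    common, tally = sexlink.intersect_populations(set_a, set_b, gene_chrom)
    log.info("intersection: %d genes common to both populations", len(common))

    paths: dict[str, Path] = {}
    inter_df = pd.DataFrame(
        {"gene_id": common, "chrom": [gene_chrom.get(g, "NA") for g in common]}
    )
    tally_df = pd.DataFrame(sorted(tally.items()), columns=["chrom", "n_common"])
    params = {"threshold_a": config_a.fst_threshold, "threshold_b": config_b.fst_threshold}
    paths["intersection"] = outdir / "intersection.tsv"
    io_tables.write_plain_table(inter_df, paths["intersection"], params)
    paths["intersection_by_chrom"] = outdir / "intersection_by_chrom.tsv"
    io_tables.write_plain_table(tally_df, paths["intersection_by_chrom"], params)

    shared_groups = [g for g in res_a.groups if g in res_b.groups]
    for g in shared_groups:
        cols = ["chrom", "pos", "ref"] + [f"{g}_{b}" for b in io_tables.BASES]
        ga = res_a.pooled[cols].rename(columns={f"{g}_{b}": b for b in io_tables.BASES})
        gb = res_b.pooled[cols].rename(columns={f"{g}_{b}": b for b in io_tables.BASES})
        labels = (f"A_{g}", f"B_{g}")
        sites = sexlink.between_population_fst(
            ga, gb, config_a.n.get(g, diffstats.DEFAULT_N),
            config_b.n.get(g, diffstats.DEFAULT_N), labels=labels,
        )
        genes_ab = diffstats.compute_gene_stats(sites, res_a.genes, list(labels))
        p1 = outdir / f"between_pop_{g}_sites.tsv"
        p2 = outdir / f"between_pop_{g}_genes.tsv"
        io_tables.write_site_table(sites, p1, list(labels), params)
        io_tables.write_gene_table(genes_ab, p2, list(labels), params)
        paths[f"between_pop_{g}_sites"] = p1
        paths[f"between_pop_{g}_genes"] = p2
    _write_manifest(config_a, outdir, list(paths.values()))
    return paths


def run_simulate(preset: str | simulate.SimConfig, seed: int, outdir) -> dict[str, Path]:
    """Generate a synthetic dataset from a named preset (or explicit config)."""
    if isinstance(preset, str):
        presets = simulate.scenario_presets()
        if preset not in presets:
            raise ConfigError(
                f"unknown preset '{preset}' (choose from {sorted(presets)})"
            )
        cfg = dataclasses.replace(presets[preset], seed=seed)
    else:
        cfg = dataclasses.replace(preset, seed=seed)
    log.info("simulating preset=%s seed=%d", preset, seed)
    return simulate.write_dataset(cfg, outdir)
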
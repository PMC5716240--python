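"""Sex-linkage inference over gene-wise statistics.

Classification of sex-associated genes (F_ST >= 0.100 by default, inclusive),
one-sided tests of male heterozygosity excess within genomic regions,
Fisher's exact chromosome enrichment, hypergeometric category
over-representation, cross-population intersection, between-population F_ST,
beta-distribution diagnostics of the gene-wise F_ST distribution, and the
variant-per-aligned-nucleotide ratio.

Exact test p-values come from ``scipy.stats`` (``fisher_exact``,
``hypergeom``); both are exact hypergeometric-tail computations.  No
multiple-testing correction is applied by default — raw p-values are
reported — with an optional Benjamini-Hochberg adjustment for the
per-chromosome and per-category batteries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from . import diffstats, filtering
from .io_tables import BASES

DEFAULT_FST_THRESHOLD = 0.100


@dataclass(frozen=True)
class RegionSpec:
    """A labelled genomic interval (1-based closed, like GeneInterval)."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ContractError(f"region {self.label}: start must precede end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float  # NaN when undefined
    n: dict[str, int]
    direction: str
    region_label: str = ""


def central_third(chrom: str, chrom_length: int, label: str | None = None) -> RegionSpec:
    """The middle third of a chromosome — the default M-locus-proximal proxy."""
    start = chrom_length // 3 + 1
    end = 2 * chrom_length // 3
    return RegionSpec(chrom, start, end, label or f"{chrom}-central-third")


def classify_high_fst(
    gene_stats: pd.DataFrame, threshold: float = DEFAULT_FST_THRESHOLD
) -> pd.DataFrame:
    """Flag genes with defined gene-wise F_ST >= threshold (inclusive).

    Returns the input frame with a boolean ``flagged`` column; genes with
    undefined F_ST are never flagged (they are counted separately by
    callers via ``fst.isna()``).
    """
    if not (0 < threshold <= 1):
        raise ContractError("threshold must lie in (0, 1]")
    out = gene_stats.copy()
    out["flagged"] = out["fst"].ge(threshold) & out["fst"].notna()
    return out


def genes_in_region(gene_stats: pd.DataFrame, region: RegionSpec) -> pd.DataFrame:
    """Genes whose midpoint falls inside the region."""
    m = (gene_stats["chrom"] == region.chrom) & gene_stats["midpoint"].between(
        region.start, region.end
    )
    return gene_stats.loc[m]


def male_hexp_test(
    gene_stats: pd.DataFrame,
    region: RegionSpec | None = None,
    mode: str = "unpaired",
    male: str = "male",
    female: str = "female",
) -> TestResult:
    """One-sided test for higher mean gene-wise H_exp in males than females.

    ``mode="unpaired"`` is a Welch t-test; ``mode="paired"`` pairs the male
    and female values of each gene. With fewer than two usable genes the
    p-value is NaN and a warning is issued.
    """
    if mode not in ("unpaired", "paired"):
        raise ContractError(f"unknown test mode '{mode}'")
    df = genes_in_region(gene_stats, region) if region is not None else gene_stats
    label = region.label if region is not None else "all"
    mvals = df[f"mean_hexp_{male}"].to_numpy(dtype=float)
    fvals = df[f"mean_hexp_{female}"].to_numpy(dtype=float)
    ok = ~(np.isnan(mvals) | np.isnan(fvals))
    mvals, fvals = mvals[ok], fvals[ok]
    n = {male: int(len(mvals)), female: int(len(fvals))}
    if len(mvals) < 2:
        warnings.warn(f"male_hexp_test[{label}]: fewer than 2 genes; p undefined")
        return TestResult("male_hexp_t", float("nan"), float("nan"), n, "greater", label)
    if mode == "paired":
        res = stats.ttest_rel(mvals, fvals, alternative="greater")
    else:
        res = stats.ttest_ind(mvals, fvals, equal_var=False, alternative="greater")
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # zero variance in both vectors (identical constants)
        stat, p = 0.0, 0.5
    return TestResult(f"male_hexp_t_{mode}", stat, p, n, "greater", label)


def chromosome_enrichment(
    gene_stats: pd.DataFrame,
    flagged: set[str] | Sequence[str],
    adjust: bool = False,
) -> list[TestResult]:
    """Per-chromosome one-sided Fisher's exact test for flagged-gene excess.

    For each chromosome the 2x2 table is (this chromosome vs others) x
    (flagged vs not); the alternative is enrichment on that chromosome.
    """
    flagged = set(flagged)
    chroms = [c for c in gene_stats["chrom"].unique()]
    if len(chroms) < 2:
        raise ContractError("chromosome enrichment requires >= 2 chromosomes")
    is_flagged = gene_stats["gene_id"].isin(flagged)
    results = []
    for c in chroms:
        on = gene_stats["chrom"] == c
        k = int((on & is_flagged).sum())
        table = [
            [k, int(on.sum()) - k],
            [int(is_flagged.sum()) - k, int((~on & ~is_flagged).sum())],
        ]
        if int(on.sum()) == 0:
            warnings.warn(f"chromosome {c} has zero genes; skipped")
            continue
        odds, p = stats.fisher_exact(table, alternative="greater")
        results.append(TestResult(
            "fisher_enrichment", float(odds), float(p),
            {"chrom_genes": int(on.sum()), "chrom_flagged": k,
             "total_genes": int(len(gene_stats)), "total_flagged": len(flagged)},
            "greater", c,
        ))
    if adjust:
        _bh_adjust(results)
    return results


def category_overrepresentation(
    universe: Mapping[str, str],
    selected: set[str] | Sequence[str],
    adjust: bool = False,
) -> list[TestResult]:
    """Upper-tail hypergeometric over-representation of functional categories.

    ``universe`` maps gene id -> category label; ``selected`` is the gene
    subset of interest (must be drawn from the universe).
    """
    selected = set(selected)
    missing = selected - set(universe)
    if missing:
        raise ContractError(f"selected genes absent from universe: {sorted(missing)[:5]}")
    N = len(universe)
    n = len(selected)
    by_cat: dict[str, set[str]] = {}
    for g, cat in universe.items():
        by_cat.setdefault(cat, set()).add(g)
    results = []
    for cat in sorted(by_cat):
        K = len(by_cat[cat])
        k = len(by_cat[cat] & selected)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(TestResult(
            "hypergeom_overrep", float(k), p,
            {"category_size": K, "selected": n, "universe": N, "overlap": k},
            "greater", cat,
        ))
    if adjust:
        _bh_adjust(results)
    return results


def _bh_adjust(results: list[TestResult]) -> None:
    """Attach Benjamini-Hochberg adjusted p-values in place (``p_adjusted``)."""
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, ps[i] * m / (rank + 1))
        adj[i] = running
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)  # type: ignore[attr-defined]


def intersect_populations(
    flagged_a: set[str] | Sequence[str],
    flagged_b: set[str] | Sequence[str],
    gene_chrom: Mapping[str, str] | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Genes flagged in both populations, sorted, with per-chromosome tallies."""
    common = sorted(set(flagged_a) & set(flagged_b))
    tally: dict[str, int] = {}
    if gene_chrom is not None:
        tally = dict(Counter(gene_chrom[g] for g in common if g in gene_chrom))
    return common, tally


def between_population_fst(
    group_x: pd.DataFrame,
    group_y: pd.DataFrame,
    n_x: int = diffstats.DEFAULT_N,
    n_y: int = diffstats.DEFAULT_N,
    labels: tuple[str, str] = ("popX", "popY"),
    monomorphic_drop: bool = True,
) -> pd.DataFrame:
    """Site F_ST between the same sex of two populations.

    Inputs are per-population combined count tables with columns
    ``chrom, pos, ref`` and one ``<label>_<base>`` block each (the pooled
    output schema of ``filtering.filter_sites`` restricted to one group, or
    any frame with plain ``A,C,G,T`` columns which are then relabelled).
    Only sites present in both tables are compared; sites monomorphic for
    the identical base across the two populations are dropped, mirroring
    the inter-sex chain.  Output schema matches ``compute_site_stats``.
    """
    lx, ly = labels

    def _std(df, label):
        cols = {}
        for b in BASES:
            if f"{label}_{b}" in df.columns:
                cols[f"{label}_{b}"] = f"{label}_{b}"
            elif b in df.columns:
                cols[b] = f"{label}_{b}"
            else:
                raise ContractError(f"missing count column for base {b}")
        out = df[["chrom", "pos", "ref", *cols]].rename(columns=cols)
        return out

    merged = _std(group_x, lx).merge(
        _std(group_y, ly).drop(columns=["ref"]), on=["chrom", "pos"], how="inner"
    )
    if monomorphic_drop:
        keep = np.zeros(len(merged), dtype=bool)
        variants = []
        for i, row in enumerate(merged.itertuples(index=False)):
            d = row._asdict()
            cx = {b: int(d[f"{lx}_{b}"]) for b in BASES}
            cy = {b: int(d[f"{ly}_{b}"]) for b in BASES}
            v = filtering.classify_site_alleles([cx, cy], d["ref"])
            if v is not None:
                keep[i] = True
                variants.append(v)
        merged = merged.loc[keep].reset_index(drop=True)
        merged["variant"] = variants
    else:
        both = sum(
            merged[[f"{lab}_{b}" for b in BASES]].to_numpy() for lab in labels
        )
        ridx = merged["ref"].map({b: i for i, b in enumerate(BASES)}).fillna(-1)
        mask = np.ones((len(merged), 4), dtype=bool)
        ok = ridx.to_numpy() >= 0
        mask[np.arange(len(merged))[ok], ridx.to_numpy(dtype=int)[ok]] = False
        merged["variant"] = np.array(BASES)[np.where(mask, both, -1).argmax(axis=1)]
    return diffstats.compute_site_stats(merged, list(labels), {lx: n_x, ly: n_y})


def fit_beta(values: Sequence[float], eps: float = 1e-6) -> dict:
    """Method-of-moments beta fit of a gene-wise F_ST distribution.

    Values are cleaned of NaN and clamped into (eps, 1-eps); at least 10
    must remain.  With sample mean m and variance v the estimates are
    ``alpha = m (m(1-m)/v - 1)`` and ``beta = alpha (1-m)/m``.  A
    Kolmogorov-Smirnov distance against the fitted density is reported as a
    diagnostic only.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    x = np.clip(x, eps, 1.0 - eps)
    if len(x) < 10:
        raise ContractError("beta fit requires >= 10 defined values")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    # constant input leaves only float rounding noise in the variance
    if v <= max(1e-16 * m * (1.0 - m), 1e-30):
        warnings.warn("beta fit undefined: zero variance")
        return {"alpha": float("nan"), "beta": float("nan"),
                "n": len(x), "mean": m, "var": v, "ks_stat": float("nan")}
    common = m * (1.0 - m) / v - 1.0
    alpha = m * common
    beta = (1.0 - m) * common
    if alpha <= 0 or beta <= 0:
        warnings.warn("beta fit undefined: variance exceeds Bernoulli bound")
        return {"alpha": float("nan"), "beta": float("nan"),
                "n": len(x), "mean": m, "var": v, "ks_stat": float("nan")}
    ks = float(stats.kstest(x, "beta", args=(alpha, beta)).statistic)
    return {"alpha": alpha, "beta": beta, "n": len(x), "mean": m, "var": v,
            "ks_stat": ks}


def variant_alignment_ratio(
    n_variants: int, n_aligned_reads: int, read_length: int = 100
) -> float:
    """Variant sites per aligned nucleotide, scaled by 1000."""
    if n_aligned_reads <= 0:
        raise ContractError("aligned read count must be positive")
    if n_variants < 0:
        raise ContractError("variant count must be non-negative")
    return n_variants * 1000.0 / (n_aligned_reads * read_length)


def region_summary(
    gene_stats: pd.DataFrame,
    regions: Sequence[RegionSpec],
    groups: Sequence[str] = ("female", "male"),
    mode: str = "unpaired",
) -> pd.DataFrame:
    """Descriptive H_exp statistics per region per group plus the male-excess
    t-test p-value — one row per (region, group), Table-style layout."""
    male = "male" if "male" in groups else groups[-1]
    female = "female" if "female" in groups else groups[0]
    rows = []
    for region in regions:
        sub = genes_in_region(gene_stats, region)
        test = male_hexp_test(gene_stats, region, mode=mode, male=male, female=female)
        for g in groups:
            vals = sub[f"mean_hexp_{g}"].dropna().to_numpy()
            rows.append({
                "region": region.label, "group": g, "n_genes": len(vals),
                "mean": vals.mean() if len(vals) else float("nan"),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "variance": vals.var(ddof=1) if len(vals) > 1 else float("nan"),
                "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                "ci95_half_width": 1.96 * vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                "male_excess_p": test.p_value,
            })
    return pd.DataFrame(rows)
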
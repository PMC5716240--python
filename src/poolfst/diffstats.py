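"""Pooled-sequencing F_ST decomposition and expected heterozygosity.

For one SNP *s* compared between two collections *i* and *j* with pooled
variant-allele frequencies ``p_i = cov_i(variant)/cov_i`` and ``p_j``,
mosquito sample sizes ``n_i, n_j``, and the coverage-weighted combined
frequency ``p_bar``:

    alpha_g = 2 p_g (1 - p_g)                          (expected heterozygosity)
    b_s  = (n_i alpha_i + n_j alpha_j) / (n_i + n_j - 1)
    a_s  = [4 n_i (p_i - p_bar)^2 + 4 n_j (p_j - p_bar)^2 - b_s]
           / (2 * (2 n_i n_j / (n_i + n_j)))
    F_ST(s) = a_s / (a_s + b_s)

and for a gene *g* with *m* SNPs the aggregate is the **ratio of sums**

    F_ST(g) = sum_s a_s / sum_s (a_s + b_s)

never the mean of per-site ratios.  ``a_s`` may legitimately be negative
(sampling noise); negative values are reported as computed, not clamped,
so that gene sums stay unbiased.  A denominator within ``UNDEF_TOL`` of
zero yields an undefined F_ST, encoded as NaN.

All operations accept scalars or numpy arrays.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ContractError
from .io_tables import BASES, GeneInterval, GeneStats

#: a_s + b_s below this is treated as undefined F_ST (degenerate site)
UNDEF_TOL = 1e-12

#: mosquitoes per collection: 12 per pool x 2 summed biological replicates
DEFAULT_N = 24


def allele_freq(group_counts: Mapping[str, int], variant_base: str) -> float:
    """Variant-allele frequency: variant coverage over total A+C+G+T coverage."""
    total = sum(group_counts.get(b, 0) for b in BASES)
    if total <= 0:
        raise ContractError("zero nucleotide coverage at site")
    return group_counts.get(variant_base, 0) / total


def hexp(p):
    """Hardy-Weinberg expected heterozygosity, 2p(1-p), in [0, 0.5]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ContractError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def site_components(p_i, p_j, cov_i, cov_j, n_i: int = DEFAULT_N, n_j: int = DEFAULT_N):
    """Between- (a_s) and within-group (b_s) variance components of one SNP.

    ``cov_i``/``cov_j`` are the total nucleotide coverages used to weight the
    combined frequency p_bar; ``n_i``/``n_j`` the numbers of mosquitoes
    sampled per collection.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    cov_i = np.asarray(cov_i, dtype=float)
    cov_j = np.asarray(cov_j, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    if np.any(n_i + n_j <= 1):
        raise ContractError("n_i + n_j must exceed 1")
    if np.any((cov_i <= 0) | (cov_j <= 0)):
        raise ContractError("coverages must be positive")
    if np.any((p_i < 0) | (p_i > 1) | (p_j < 0) | (p_j > 1)):
        raise ContractError("frequencies must lie in [0, 1]")

    p_bar = (cov_i * p_i + cov_j * p_j) / (cov_i + cov_j)
    alpha_i = 2.0 * p_i * (1.0 - p_i)
    alpha_j = 2.0 * p_j * (1.0 - p_j)
    b = (n_i * alpha_i + n_j * alpha_j) / (n_i + n_j - 1.0)
    num = 4.0 * n_i * (p_i - p_bar) ** 2 + 4.0 * n_j * (p_j - p_bar) ** 2 - b
    a = num / (2.0 * (2.0 * n_i * n_j / (n_i + n_j)))
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def site_fst(a, b, tol: float = UNDEF_TOL):
    """F_ST(s) = a/(a+b); NaN when the denominator is within ``tol`` of zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > tol, a / np.where(denom > tol, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def gene_fst(components: Sequence[tuple[float, float]], tol: float = UNDEF_TOL):
    """Aggregate (a_s, b_s) pairs of one gene: ratio of sums.

    Returns ``(fst_g, sum_a, sum_b, m)``; fst_g is NaN when the summed
    denominator is degenerate.
    """
    if len(components) == 0:
        raise ContractError("gene_fst requires at least one SNP")
    arr = np.asarray(components, dtype=float)
    sum_a = float(arr[:, 0].sum())
    sum_b = float(arr[:, 1].sum())
    denom = sum_a + sum_b
    fst = sum_a / denom if denom > tol else float("nan")
    return fst, sum_a, sum_b, len(components)


# ---------------------------------------------------------------------------
# bulk paths over pooled tables
# ---------------------------------------------------------------------------

def compute_site_stats(
    pooled: pd.DataFrame,
    groups: Sequence[str],
    n: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-SNP statistics for a pooled count table (``filtering.filter_sites``).

    Adds, for each group g: ``p_g``, ``cov_g``, ``hexp_g``; plus ``a``, ``b``
    and ``fst`` columns.
    """
    if len(groups) != 2:
        raise ContractError("exactly two groups required")
    g1, g2 = groups
    n = n or {}
    out = pooled[["chrom", "pos", "ref", "variant"]].copy()
    counts = {g: pooled[[f"{g}_{b}" for b in BASES]].to_numpy(dtype=float) for g in groups}
    vidx = pooled["variant"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    rows = np.arange(len(pooled))
    cov = {g: counts[g].sum(axis=1) for g in groups}
    for g in groups:
        if np.any(cov[g] <= 0):
            raise ContractError(f"zero coverage in group '{g}' after filtering")
    p = {g: counts[g][rows, vidx] / cov[g] for g in groups}
    for g in groups:
        out[f"p_{g}"] = p[g]
        out[f"cov_{g}"] = cov[g].astype(np.int64)
        out[f"hexp_{g}"] = hexp(p[g])
    a, b = site_components(
        p[g1], p[g2], cov[g1], cov[g2],
        n.get(g1, DEFAULT_N), n.get(g2, DEFAULT_N),
    )
    out["a"] = np.atleast_1d(a)
    out["b"] = np.atleast_1d(b)
    out["fst"] = np.atleast_1d(site_fst(out["a"].to_numpy(), out["b"].to_numpy()))
    return out


def assign_sites_to_genes(
    sites: pd.DataFrame, genes: Sequence[GeneInterval]
) -> pd.DataFrame:
    """Map each site to every gene whose closed span contains its position.

    Genes may overlap; a site inside several genes contributes to each.
    Returns a frame with ``site_index`` (positional index into ``sites``)
    and ``gene_id`` columns.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval trees are half-open; +1 closes the right end
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    pairs: list[tuple[int, str]] = []
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for i in range(len(sites)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        for iv in tree.at(int(positions[i])):
            pairs.append((i, iv.data))
    return pd.DataFrame(pairs, columns=["site_index", "gene_id"])


def compute_gene_stats(
    site_stats: pd.DataFrame,
    genes: Sequence[GeneInterval],
    groups: Sequence[str],
    tol: float = UNDEF_TOL,
) -> pd.DataFrame:
    """Gene-wise ratio-of-sums F_ST and mean per-group H_exp.

    Genes without any retained SNP are omitted. Gene-wise H_exp is the
    arithmetic mean over the gene's SNPs.
    """
    mapping = assign_sites_to_genes(site_stats, genes)
    gene_by_id = {g.gene_id: g for g in genes}
    if len(mapping) == 0:
        cols = ["gene_id", "chrom", "start", "end", "midpoint", "m", "sum_a",
                "sum_b", "fst"] + [f"mean_hexp_{g}" for g in groups]
        return pd.DataFrame(columns=cols)
    joined = mapping.join(
        site_stats[["a", "b"] + [f"hexp_{g}" for g in groups]], on="site_index"
    )
    agg = joined.groupby("gene_id").agg(
        m=("a", "size"), sum_a=("a", "sum"), sum_b=("b", "sum"),
        **{f"mean_hexp_{g}": (f"hexp_{g}", "mean") for g in groups},
    ).reset_index()
    denom = agg["sum_a"] + agg["sum_b"]
    agg["fst"] = np.where(denom > tol, agg["sum_a"] / denom.where(denom > tol, 1.0), np.nan)
    agg["chrom"] = agg["gene_id"].map(lambda i: gene_by_id[i].chrom)
    agg["start"] = agg["gene_id"].map(lambda i: gene_by_id[i].start)
    agg["end"] = agg["gene_id"].map(lambda i: gene_by_id[i].end)
    agg["midpoint"] = (agg["start"] + agg["end"]) // 2
    cols = ["gene_id", "chrom", "start", "end", "midpoint", "m", "sum_a", "sum_b",
            "fst"] + [f"mean_hexp_{g}" for g in groups]
    return agg[cols].sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)


def gene_stats_records(df: pd.DataFrame, groups: Sequence[str]) -> list[GeneStats]:
    """Convert a gene-stats frame to ``GeneStats`` dataclass records."""
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        out.append(GeneStats(
            gene_id=d["gene_id"], chrom=d["chrom"], start=int(d["start"]),
            end=int(d["end"]), m=int(d["m"]), sum_a=float(d["sum_a"]),
            sum_b=float(d["sum_b"]), fst=float(d["fst"]),
            mean_hexp={g: float(d[f"mean_hexp_{g}"]) for g in groups},
        ))
    return out
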
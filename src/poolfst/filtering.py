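"""SNP-site inclusion rules and replicate combination.

The chain applied to every site, in order:

1. **coverage** — every replicate of every group must carry at least
   ``min_coverage`` (default 15) A+C+G+T reads.
2. **replicate concordance** — at least one group must show a shared
   non-reference base (>= 1 read in every one of its replicates).  Requiring
   this of *both* groups would discard exactly the fully sex-linked sites at
   which one sex is fixed for the reference allele, so the rule is
   any-group; ``concordance_mode="coverage"`` relaxes it to coverage only.
3. **monomorphic removal** — sites where both groups place 100% of their
   nucleotide coverage on one identical base (equal to the reference or not)
   carry no differentiation signal and are dropped.

Replicate counts of a group are summed element-wise after the chain;
multi-allelic sites collapse to reference vs the major non-reference base
(ties broken A<C<G<T) for the estimator, while full per-base counts are
kept in the pooled table.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .io_tables import BASES, SiteCounts

DEFAULT_MIN_COVERAGE = 15

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


# -- scalar operations (the contract surface; the bulk path below must agree) --

def filter_min_coverage(counts: Mapping[str, int], min_cov: int = DEFAULT_MIN_COVERAGE) -> bool:
    """One replicate passes iff its total A+C+G+T coverage >= min_cov."""
    if min_cov < 1:
        raise ContractError("min_cov must be >= 1")
    return sum(counts.get(b, 0) for b in BASES) >= min_cov


def replicate_concordance(
    site: SiteCounts,
    group: Sequence[str],
    min_cov: int = DEFAULT_MIN_COVERAGE,
) -> bool:
    """True iff every replicate of the group passes coverage and the group
    shares at least one non-reference base with >= 1 read in all replicates."""
    if len(group) < 2:
        raise ConfigError("replicate concordance requires a group of >= 2 replicates")
    if not all(filter_min_coverage(site.counts[r], min_cov) for r in group):
        return False
    for b in BASES:
        if b == site.ref:
            continue
        if all(site.counts[r].get(b, 0) >= 1 for r in group):
            return True
    return False


def combine_replicates(site: SiteCounts, group: Sequence[str]) -> dict[str, int]:
    """Element-wise sum of a group's replicate counts (A,C,G,T and indel)."""
    out = {k: 0 for k in BASES + ("indel",)}
    for r in group:
        c = site.counts[r]
        if sum(c.get(b, 0) for b in BASES) == 0:
            raise ContractError(f"replicate {r} has zero coverage; filter first")
        for k in out:
            out[k] += c.get(k, 0)
    return out


def classify_site_alleles(
    group_counts: Sequence[Mapping[str, int]], ref: str
) -> str | None:
    """Designate the variant base for a site, or ``None`` for monomorphic.

    Monomorphic: both groups place all nucleotide coverage on one identical
    base (whether or not it equals the reference).  Otherwise the variant is
    the non-reference base with the highest coverage summed over both
    groups; ties break in fixed A<C<G<T order.
    """
    g1, g2 = group_counts
    tot1 = sum(g1.get(b, 0) for b in BASES)
    tot2 = sum(g2.get(b, 0) for b in BASES)
    if tot1 == 0 or tot2 == 0:
        raise ContractError("zero nucleotide coverage in a group; filter first")

    def pure_base(c, tot):
        for b in BASES:
            if c.get(b, 0) == tot:
                return b
        return None

    p1, p2 = pure_base(g1, tot1), pure_base(g2, tot2)
    if p1 is not None and p1 == p2:
        return None  # monomorphic, dropped
    best, best_n = None, -1
    for b in BASES:  # fixed order implements the tie rule
        if b == ref:
            continue
        n = g1.get(b, 0) + g2.get(b, 0)
        if n > best_n:
            best, best_n = b, n
    return best


# -- vectorised chain over a readcount DataFrame ------------------------------

def _count_array(df: pd.DataFrame, reps: Sequence[str]) -> np.ndarray:
    """(n_sites, n_reps, 4) array of ACGT counts."""
    cols = [f"{r}_{b}" for r in reps for b in BASES]
    return df[cols].to_numpy(dtype=np.int64).reshape(len(df), len(reps), 4)


def filter_sites(
    df: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    concordance_mode: str = "shared_variant",
    monomorphic_drop: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the full inclusion chain to a readcount table.

    Parameters
    ----------
    df
        Validated readcount frame (``io_tables.read_readcounts``).
    groups
        Group name -> list of replicate names (>= 2 replicates each).
    concordance_mode
        ``"shared_variant"`` (default) or ``"coverage"``.

    Returns
    -------
    pooled, summary
        ``pooled``: one row per retained site with ``chrom, pos, ref,
        variant`` and per-group summed count columns ``<group>_<base>``.
        ``summary``: counts per filter category (input, coverage_fail,
        concordance_fail, monomorphic, retained).
    """
    if len(groups) != 2:
        raise ConfigError("exactly two groups are required")
    for g, reps in groups.items():
        if len(reps) < 2:
            raise ConfigError(f"group '{g}' must have >= 2 replicates")
    if concordance_mode not in ("shared_variant", "coverage"):
        raise ConfigError(f"unknown concordance_mode '{concordance_mode}'")
    if min_coverage < 1:
        raise ConfigError("min_coverage must be >= 1")

    gnames = list(groups)
    n = len(df)
    ref_idx = df["ref"].map(_BASE_IDX).fillna(-1).to_numpy(dtype=np.int64)

    arrays = {g: _count_array(df, groups[g]) for g in gnames}
    cov_ok = np.ones(n, dtype=bool)
    for g in gnames:
        cov_ok &= (arrays[g].sum(axis=2) >= min_coverage).all(axis=1)

    nonref = np.ones((n, 4), dtype=bool)
    rows = np.arange(n)
    valid_ref = ref_idx >= 0
    nonref[rows[valid_ref], ref_idx[valid_ref]] = False

    if concordance_mode == "shared_variant":
        conc_ok = np.zeros(n, dtype=bool)
        for g in gnames:
            shared = (arrays[g] >= 1).all(axis=1)  # base seen in every replicate
            conc_ok |= (shared & nonref).any(axis=1)
    else:
        conc_ok = np.ones(n, dtype=bool)

    combined = {g: arrays[g].sum(axis=1) for g in gnames}  # (n, 4) per group
    tot = {g: combined[g].sum(axis=1) for g in gnames}
    top = {g: combined[g].argmax(axis=1) for g in gnames}
    pure = {
        g: combined[g][rows, top[g]] == tot[g]
        for g in gnames
    }
    g1, g2 = gnames
    mono = pure[g1] & pure[g2] & (top[g1] == top[g2]) & (tot[g1] > 0) & (tot[g2] > 0)

    keep = cov_ok & conc_ok
    if monomorphic_drop:
        keep &= ~mono

    summary = {
        "input": int(n),
        "coverage_fail": int((~cov_ok).sum()),
        "concordance_fail": int((cov_ok & ~conc_ok).sum()),
        "monomorphic": int((cov_ok & conc_ok & mono).sum()) if monomorphic_drop else 0,
        "retained": int(keep.sum()),
    }

    # variant base: argmax over non-reference bases of two-group summed counts;
    # np.argmax returns the first maximum, which in A,C,G,T column order is
    # exactly the A<C<G<T tie rule
    both = combined[g1] + combined[g2]
    masked = np.where(nonref, both, -1)
    variant_idx = masked.argmax(axis=1)

    out = df.loc[keep, ["chrom", "pos", "ref"]].reset_index(drop=True)
    out["variant"] = np.array(BASES)[variant_idx[keep]]
    for g in gnames:
        sub = combined[g][keep]
        for i, b in enumerate(BASES):
            out[f"{g}_{b}"] = sub[:, i]
        indel_cols = [f"{r}_indel" for r in groups[g]]
        out[f"{g}_indel"] = df.loc[keep, indel_cols].sum(axis=1).to_numpy()
    return out, summary
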
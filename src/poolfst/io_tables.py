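"""Readers and writers for every on-disk table the pipeline touches.

Formats
-------
readcount TSV
    One row per genomic site. Required columns: ``chrom``, ``pos`` (1-based),
    ``ref``; then, for every pool replicate ``R`` named in the run
    configuration, five count columns ``R_A``, ``R_C``, ``R_G``, ``R_T`` and
    ``R_indel``. Column discovery is header-driven, so column order is free.
    This is the dialect emitted by pileup-to-readcount converters after
    renaming their per-library count blocks.

gene annotation
    BED4+ (0-based half-open) or GFF3 (1-based closed). Both are normalised
    on input to the package-wide convention: **1-based closed** intervals,
    matching the readcount position column.

output TSV
    Site-level and gene-level statistics tables, tab-separated, preceded by
    ``#`` comment lines recording the tool version and the parameter set.
    Floats are printed with 6 significant digits; row order is deterministic
    (chrom, then position / gene start).
"""

from __future__ import annotations

import io
import urllib.parse
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParseError

__version__ = "0.1.0"

BASES = ("A", "C", "G", "T")
#: count keys carried per replicate; indels are tracked but excluded from
#: all frequency arithmetic (they are neither reference nor variant coverage)
COUNT_KEYS = BASES + ("indel",)

GFF_GENE_TYPES = {"gene", "mRNA", "transcript", "protein_coding_gene"}


@dataclass(frozen=True)
class SiteCounts:
    """Read counts for one genomic site, per pool replicate."""

    chrom: str
    pos: int  # 1-based
    ref: str  # one of A,C,G,T,N
    counts: Mapping[str, Mapping[str, int]]  # replicate -> base -> count

    def replicate_total(self, rep: str) -> int:
        """Total nucleotide (A+C+G+T) coverage of one replicate."""
        c = self.counts[rep]
        return sum(c[b] for b in BASES)


@dataclass(frozen=True)
class GeneInterval:
    """A gene/transcript span (UTRs and introns included), 1-based closed."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: end <= start after normalization "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def expected_count_columns(pools: Sequence[str]) -> list[str]:
    return [f"{rep}_{k}" for rep in pools for k in COUNT_KEYS]


def read_readcounts(path, pools: Sequence[str]) -> pd.DataFrame:
    """Read a readcount TSV into a validated DataFrame (bulk entry point).

    Parameters
    ----------
    path
        TSV file with a header row; ``#`` lines are comments.
    pools
        Replicate names; each must own a full ``_A.._indel`` column block.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = ["chrom", "pos", "ref"] + expected_count_columns(pools)
    for col in required:
        if col not in df.columns:
            raise ConfigError(f"readcount table is missing required column '{col}'")
    count_cols = expected_count_columns(pools)
    if df.empty:
        df["pos"] = df["pos"].astype(np.int64)
        df[count_cols] = df[count_cols].astype(np.int64)
        df["ref"] = df["ref"].astype(str)
        return df[required]
    for col in count_cols + ["pos"]:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ParseError(f"non-numeric value in column '{col}'", line=line)
    neg = (df[count_cols] < 0).any(axis=1)
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise ParseError("negative read count", line=line)
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 2
        raise ParseError("position must be >= 1", line=line)
    df["ref"] = df["ref"].astype(str).str.upper().where(
        df["ref"].astype(str).str.upper().isin(BASES), "N"
    )
    df["pos"] = df["pos"].astype(np.int64)
    df[count_cols] = df[count_cols].astype(np.int64)
    return df[required]


def parse_readcounts(path, pools: Sequence[str]) -> Iterator[SiteCounts]:
    """Stream ``SiteCounts`` records from a readcount TSV, in file order."""
    df = read_readcounts(path, pools)
    for row in df.itertuples(index=False):
        d = row._asdict()
        counts = {
            rep: {k: int(d[f"{rep}_{k}"]) for k in COUNT_KEYS} for rep in pools
        }
        yield SiteCounts(chrom=d["chrom"], pos=int(d["pos"]), ref=d["ref"], counts=counts)


def _parse_bed(path) -> tuple[list[GeneInterval], int]:
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"line {ln}: BED4+ requires at least 4 columns")
            chrom, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            # BED 0-based half-open -> 1-based closed
            genes.append(GeneInterval(name, chrom, start0 + 1, end0, strand))
    return genes, 0


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return urllib.parse.unquote(part[len(key) + 1 :])
    return None


def _parse_gff3(path) -> tuple[list[GeneInterval], int]:
    genes: list[GeneInterval] = []
    skipped = 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"line {ln}: GFF3 requires 9 columns")
            if f[2] not in GFF_GENE_TYPES:
                skipped += 1
                continue
            gid = _gff_attr(f[8], "ID") or _gff_attr(f[8], "Name")
            if gid is None:
                raise FormatError(f"line {ln}: gene feature lacks ID attribute")
            strand = f[6] if f[6] in "+-" else "."
            genes.append(GeneInterval(gid, f[0], int(f[3]), int(f[4]), strand))
    return genes, skipped


def parse_gene_intervals(path, format: str = "BED") -> list[GeneInterval]:
    """Read gene intervals from BED4+ or GFF3, normalised to 1-based closed.

    Non-gene GFF3 features (exons, CDS...) are skipped. Duplicate gene ids
    are rejected.
    """
    fmt = format.upper()
    if fmt == "BED":
        genes, _ = _parse_bed(path)
    elif fmt == "GFF3":
        genes, _ = _parse_gff3(path)
    else:
        raise ConfigError(f"unknown annotation format '{format}' (use BED or GFF3)")
    seen: dict[str, GeneInterval] = {}
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"duplicate gene_id '{g.gene_id}' in annotation")
        seen[g.gene_id] = g
    return genes


# ---------------------------------------------------------------------------
# statistic records and their writers
# ---------------------------------------------------------------------------

@dataclass
class SiteStats:
    """Per-SNP estimator output: frequencies, variance components, F_ST."""

    chrom: str
    pos: int
    ref: str
    variant_base: str
    p: dict[str, float] = field(default_factory=dict)  # group -> variant freq
    cov: dict[str, int] = field(default_factory=dict)  # group -> ACGT coverage
    hexp: dict[str, float] = field(default_factory=dict)  # group -> 2p(1-p)
    a: float = float("nan")
    b: float = float("nan")
    fst: float = float("nan")  # NaN encodes "undefined"


@dataclass
class GeneStats:
    """Gene-wise aggregate: ratio-of-sums F_ST over the gene's SNPs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    m: int
    sum_a: float
    sum_b: float
    fst: float
    mean_hexp: dict[str, float] = field(default_factory=dict)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _fmt(x) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def _write_table(df: pd.DataFrame, path, params: Mapping | None) -> None:
    buf = io.StringIO()
    buf.write(f"# poolfst {__version__}\n")
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        buf.write(f"# params: {kv}\n")
    buf.write("\t".join(df.columns) + "\n")
    for row in df.itertuples(index=False):
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def site_stats_frame(stats: Iterable[SiteStats], groups: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "variant": s.variant_base}
        for g in groups:
            row[f"p_{g}"] = s.p.get(g, float("nan"))
            row[f"cov_{g}"] = s.cov.get(g, 0)
            row[f"hexp_{g}"] = s.hexp.get(g, float("nan"))
        row.update(a=s.a, b=s.b, fst=s.fst)
        rows.append(row)
    cols = (
        ["chrom", "pos", "ref", "variant"]
        + [f"{p}_{g}" for g in groups for p in ("p", "cov", "hexp")]
        + ["a", "b", "fst"]
    )
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def gene_stats_frame(stats: Iterable[GeneStats], groups: Sequence[str]) -> pd.DataFrame:
    rows = []
    for g in stats:
        row = {
            "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "midpoint": g.midpoint, "m": g.m, "sum_a": g.sum_a, "sum_b": g.sum_b,
            "fst": g.fst,
        }
        for grp in groups:
            row[f"mean_hexp_{grp}"] = g.mean_hexp.get(grp, float("nan"))
        rows.append(row)
    cols = ["gene_id", "chrom", "start", "end", "midpoint", "m", "sum_a", "sum_b",
            "fst"] + [f"mean_hexp_{g}" for g in groups]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)


def write_site_table(stats, path, groups: Sequence[str], params: Mapping | None = None) -> None:
    """Write per-SNP statistics as TSV. Accepts SiteStats or a prepared frame."""
    df = stats if isinstance(stats, pd.DataFrame) else site_stats_frame(stats, groups)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    _write_table(df, path, params)


def write_gene_table(stats, path, groups: Sequence[str], params: Mapping | None = None) -> None:
    """Write gene-wise statistics as TSV (sorted by chrom, then gene start)."""
    df = stats if isinstance(stats, pd.DataFrame) else gene_stats_frame(stats, groups)
    df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
    _write_table(df, path, params)


def read_stats_table(path) -> pd.DataFrame:
    """Read back a site/gene TSV written by this module ('NA' -> NaN)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], dtype={"chrom": str})


def write_plain_table(df: pd.DataFrame, path, params: Mapping | None = None) -> None:
    """Write any report frame with the standard comment header."""
    _write_table(df.reset_index(drop=True), path, params)
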
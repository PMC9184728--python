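"""Readers and writers for the plain-text genomic formats the pipeline exchanges.

All coordinates are BED-style 0-based half-open internally.  Any 1-based
dialect is converted at the I/O boundary; every reader/writer pair round-trips
canonical files losslessly.

Formats handled here:

* BED3 / BED6, optionally with trailing per-condition count columns, for
  binding sites;
* BEDPE for chromatin-loop records;
* header-ed TSV for gene models and expression summaries;
* sparse-triple TSV (``chrom_i  bin_i  chrom_j  bin_j  count``) for binned
  contact maps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file: message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Peak summit: midpoint unless a summit is supplied elsewhere."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class Gene:
    """Gene model reduced to TSS/TES.  On the minus strand tss > tes."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin interaction between two anchors (Hi-C or ChIA-PET)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source: str = "hic"
    score: float | None = None

    def __post_init__(self) -> None:
        # canonical order for intra-chromosomal loops: anchor1 leftmost
        if (self.anchor1.chrom == self.anchor2.chrom
                and self.anchor1.start > self.anchor2.start):
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


@dataclass
class ContactMapStore:
    """Symmetric binned contact counts, stored canonically (i <= j per pair).

    ``matrices`` maps an ordered chromosome pair ``(c1, c2)`` (declaration
    order, c1 before or equal to c2) to a dense float array of shape
    ``(nbins(c1), nbins(c2))``.  Intra-chromosomal matrices keep the full
    symmetric square; the canonical sparse serialization emits the upper
    triangle only.
    """

    resolution: int
    chrom_sizes: dict[str, int]
    matrices: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self._order = {c: k for k, c in enumerate(self.chrom_sizes)}

    def nbins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def _key(self, c1: str, c2: str) -> tuple[str, str]:
        if self._order[c1] <= self._order[c2]:
            return (c1, c2)
        return (c2, c1)

    def matrix(self, c1: str, c2: str) -> np.ndarray:
        """Dense matrix for the pair, allocated lazily, oriented (c1, c2)."""
        key = self._key(c1, c2)
        if key not in self.matrices:
            self.matrices[key] = np.zeros(
                (self.nbins(key[0]), self.nbins(key[1])))
        m = self.matrices[key]
        return m if key == (c1, c2) else m.T

    def add(self, c1: str, b1: int, c2: str, b2: int, count: float) -> None:
        if count < 0 or not np.isfinite(count):
            raise ValueError(f"count must be finite and >= 0, got {count}")
        for c, b in ((c1, b1), (c2, b2)):
            if not 0 <= b < self.nbins(c):
                raise ValueError(f"bin {b} out of range for {c}")
        key = self._key(c1, c2)
        if key != (c1, c2):
            c1, b1, c2, b2 = c2, b2, c1, b1
        m = self.matrix(c1, c2)
        m[b1, b2] += count
        if c1 == c2 and b1 != b2:
            m[b2, b1] += count

    def total(self) -> float:
        """Total count, each canonical pair counted once."""
        tot = 0.0
        for (c1, c2), m in self.matrices.items():
            if c1 == c2:
                tot += np.triu(m).sum()
            else:
                tot += m.sum()
        return tot

    def copy(self) -> "ContactMapStore":
        out = ContactMapStore(self.resolution, dict(self.chrom_sizes))
        out.matrices = {k: m.copy() for k, m in self.matrices.items()}
        return out


@dataclass
class ExpressionTable:
    """Per-gene expression summary for a two-condition comparison."""

    frame: pd.DataFrame  # gene_id, mean_a, mean_b, log2fc, significant

    REQUIRED = ("gene_id", "mean_a", "mean_b", "log2fc", "significant")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"expression table missing columns: {missing}")
        if (self.frame[["mean_a", "mean_b"]].to_numpy() < 0).any():
            raise FormatError("expression values must be >= 0")
        if not np.isfinite(self.frame["log2fc"].to_numpy(float)).all():
            raise FormatError("log2 fold changes must be finite")
        if self.frame["gene_id"].duplicated().any():
            dup = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise FormatError(f"duplicate gene_id: {dup.iloc[0]}")


# ---------------------------------------------------------------------------
# BED sites
# ---------------------------------------------------------------------------

SITE_BASE_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, has_counts: bool = False,
             count_names: Sequence[str] = ("count_a", "count_b")) -> pd.DataFrame:
    """Read BED3/BED6(+counts) into a site table.

    Returns a DataFrame with columns chrom/start/end (always), name, score,
    strand when present, and the declared count columns when ``has_counts``.
    Input line order is preserved; extra numeric columns beyond the declared
    counts are kept as ``extra_0`` ... in file order.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{ln}: invalid interval [{start}, {end})")
            rows.append((ln, parts))
    if not rows:
        raise FormatError(f"{path}: no intervals")

    ncols = max(len(p) for _, p in rows)
    data: dict[str, list] = {c: [] for c in SITE_BASE_COLS[:min(ncols, 6)]}
    n_extra = ncols - 6 if ncols > 6 else 0
    if has_counts and ncols < 6 + len(count_names):
        raise FormatError(
            f"{path}: has_counts requires {6 + len(count_names)} columns")
    extra_names = list(count_names)[:n_extra] if has_counts else []
    extra_names += [f"extra_{k}" for k in range(n_extra - len(extra_names))]
    for nm in extra_names:
        data[nm] = []

    for ln, parts in rows:
        data["chrom"].append(parts[0])
        data["start"].append(int(parts[1]))
        data["end"].append(int(parts[2]))
        if "name" in data:
            data["name"].append(parts[3] if len(parts) > 3 else ".")
        if "score" in data:
            data["score"].append(float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0)
        if "strand" in data:
            data["strand"].append(parts[5] if len(parts) > 5 else ".")
        for k, nm in enumerate(extra_names):
            try:
                data[nm].append(float(parts[6 + k]))
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}:{ln}: bad numeric column {6 + k + 1}") from exc
    return pd.DataFrame(data)


def write_bed(sites: pd.DataFrame, path) -> None:
    """Write a site table back to BED; inverse of :func:`read_bed`."""
    cols = [c for c in SITE_BASE_COLS if c in sites.columns]
    extra = [c for c in sites.columns if c not in SITE_BASE_COLS]
    with open(path, "w") as fh:
        for _, row in sites.iterrows():
            out = []
            for c in cols:
                v = row[c]
                if c == "score":
                    out.append(_fmt_num(v))
                else:
                    out.append(str(v))
            for c in extra:
                out.append(_fmt_num(row[c]))
            fh.write("\t".join(out) + "\n")


def _fmt_num(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_bedpe(path, source: str = "hic") -> list[LoopRecord]:
    """Read loops from BEDPE; intra-chromosomal anchors are canonicalized."""
    loops = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: BEDPE needs >= 6 columns")
            try:
                a1 = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                a2 = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            score = float(parts[7]) if len(parts) > 7 and parts[7] != "." else None
            loops.append(LoopRecord(a1, a2, source=source, score=score))
    return loops


def write_bedpe(loops: Iterable[LoopRecord], path) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            score = "." if lp.score is None else _fmt_num(lp.score)
            fh.write("\t".join([
                lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
                f"loop_{i}", score]) + "\n")


# ---------------------------------------------------------------------------
# Contact maps (sparse triple TSV)
# ---------------------------------------------------------------------------

def read_contact_map(path, resolution: int,
                     chrom_sizes: Mapping[str, int]) -> ContactMapStore:
    """Read a sparse-triple contact map (chrom_i bin_i chrom_j bin_j count)."""
    store = ContactMapStore(resolution, dict(chrom_sizes))
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{ln}: expected 5 columns")
            c1, c2 = parts[0], parts[2]
            for c in (c1, c2):
                if c not in store.chrom_sizes:
                    raise FormatError(f"{path}:{ln}: unknown chromosome {c}")
            try:
                b1, b2, count = int(parts[1]), int(parts[3]), float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad numeric field") from exc
            try:
                store.add(c1, b1, c2, b2, count)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return store


def write_contact_map(store: ContactMapStore, path) -> None:
    """Write canonical sparse triples (upper triangle for intra pairs)."""
    with open(path, "w") as fh:
        for (c1, c2), m in store.matrices.items():
            if c1 == c2:
                ii, jj = np.nonzero(np.triu(m))
            else:
                ii, jj = np.nonzero(m)
            for i, j in zip(ii.tolist(), jj.tolist()):
                fh.write(f"{c1}\t{i}\t{c2}\t{j}\t{_fmt_num(m[i, j])}\n")


# ---------------------------------------------------------------------------
# Gene / expression tables
# ---------------------------------------------------------------------------

def read_gene_table(path) -> list[Gene]:
    """Read a header-ed TSV gene model (gene_id chrom strand tss tes)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {row.gene_id}: bad strand {row.strand!r}")
        try:
            genes.append(Gene(row.gene_id, row.chrom, row.strand,
                              int(row.tss), int(row.tes)))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[Gene], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "tes"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def sites_to_intervals(sites: pd.DataFrame) -> list[GenomicInterval]:
    """Convert a site table to interval objects (names filled if absent)."""
    names = sites["name"] if "name" in sites.columns else (
        pd.Series([f"site_{i}" for i in range(len(sites))], index=sites.index))
    strands = sites["strand"] if "strand" in sites.columns else "."
    out = []
    for k, (_, row) in enumerate(sites.iterrows()):
        strand = row["strand"] if "strand" in sites.columns else "."
        out.append(GenomicInterval(row["chrom"], int(row["start"]),
                                   int(row["end"]), strand=strand,
                                   name=str(names.iloc[k])))
    return out
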
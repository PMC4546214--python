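"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
* SNP/site-count tables use 1-based positions (VCF-like); BED/BED12 and all
  internal intervals are 0-based half-open.  Converters are centralized here.
* All text outputs are UTF-8, tab-delimited; header lines begin with ``#``.
* Site-count tables come in two dialects: the *long* dialect
  ``chrom  pos  sample  count_129  count_cast`` (what the generator emits)
  and a *wide* dialect ``chrom  pos  <sample>_129  <sample>_cast ...``.
* Readers validate and reject malformed input; they never silently coerce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "GeneModel",
    "ParseError",
    "read_snp_table",
    "read_allele_counts",
    "write_allele_counts",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
    "read_contact_triplets",
    "write_contact_triplets",
    "read_bed",
    "write_bed",
    "read_wig",
    "write_wig",
    "load_table1_fixture",
    "TABLE1_LINES",
]

SITE_COLUMNS = ["chrom", "pos", "sample", "count_129", "count_cast"]

#: NPC line labels used by the packaged escape-gene table and the escape stage.
TABLE1_LINES = ("*NPC_129-Xi", "NPC_Cast-Xi", "NPC_129-Xi")
_LINE_KEYS = {"*NPC_129-Xi": "star129", "NPC_Cast-Xi": "cast", "NPC_129-Xi": "129"}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path, self.lineno = str(path), lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class SnpRecord:
    """One polymorphic site distinguishing the 129 and Cast genomes."""

    chrom: str
    pos: int  # 1-based
    allele_129: str
    allele_cast: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.allele_129 == self.allele_cast:
            raise ValueError("the two alleles must differ")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure (0-based half-open coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        last = self.start
        for s, e in self.exons:
            if s < last or e <= s or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and within [{self.start}, {self.end})"
                )
            last = e

    @property
    def tss(self) -> int:
        """Transcription start (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def exon_length(self) -> int:
        return int(sum(e - s for s, e in self.exons))


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------

def read_snp_table(path) -> list[SnpRecord]:
    """Read a 4-column SNP table: chrom, 1-based pos, 129 allele, Cast allele."""
    records: list[SnpRecord] = []
    seen: set[tuple[str, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(parts)}")
            chrom, pos_s, a129, acast = parts
            if lineno == 1 and not pos_s.isdigit():
                continue  # optional header row
            try:
                rec = SnpRecord(chrom, int(pos_s), a129, acast)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise ParseError(path, lineno, f"duplicate site {chrom}:{pos_s}")
            seen.add(key)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# allele count tables
# ---------------------------------------------------------------------------

def read_allele_counts(path) -> pd.DataFrame:
    """Read per-site allele counts (long or wide dialect) into a long table.

    Returns a DataFrame with columns ``chrom, pos, sample, count_129,
    count_cast`` (1-based positions), one row per (site, sample).
    """
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, header=None,
                     skip_blank_lines=True)
    if df.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    first = str(df.iloc[0, 0])
    header = first.startswith("#") or not str(df.iloc[0, 1]).isdigit()
    if header:
        cols = [str(c).lstrip("#").strip() for c in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
        df.columns = cols
    else:
        if df.shape[1] != 5:
            raise ParseError(path, 1, "headerless table must use the 5-column long dialect")
        df.columns = SITE_COLUMNS

    if set(SITE_COLUMNS) <= set(df.columns):  # long dialect
        long = df[SITE_COLUMNS].copy()
    else:  # wide dialect: chrom, pos, then <sample>_129 / <sample>_cast pairs
        value_cols = [c for c in df.columns if c not in ("chrom", "pos")]
        samples: dict[str, dict[str, str]] = {}
        for c in value_cols:
            for suffix in ("_129", "_cast"):
                if c.endswith(suffix):
                    samples.setdefault(c[: -len(suffix)], {})[suffix[1:]] = c
                    break
            else:
                raise ParseError(path, 1, f"column {c!r} lacks a _129/_cast suffix")
        frames = []
        for sample, pair in sorted(samples.items()):
            if set(pair) != {"129", "cast"}:
                raise ParseError(path, 1, f"sample {sample!r} misses a _129/_cast column")
            frames.append(pd.DataFrame({
                "chrom": df["chrom"], "pos": df["pos"], "sample": sample,
                "count_129": df[pair["129"]], "count_cast": df[pair["cast"]],
            }))
        long = pd.concat(frames, ignore_index=True)

    for col in ("pos", "count_129", "count_cast"):
        vals = pd.to_numeric(long[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            bad = long.index[pd.to_numeric(long[col], errors="coerce").isna()]
            raise ParseError(path, None, f"non-integer value in column {col!r}"
                             + (f" (row {bad[0]})" if len(bad) else ""))
        long[col] = vals.astype(np.int64)
    if (long[["count_129", "count_cast"]] < 0).any().any():
        raise ParseError(path, None, "negative counts are not allowed")
    if (long["pos"] < 1).any():
        raise ParseError(path, None, "positions are 1-based and must be >= 1")
    if long.duplicated(["chrom", "pos", "sample"]).any():
        raise ParseError(path, None, "duplicate (chrom, pos, sample) entry")
    return long.reset_index(drop=True)


def write_allele_counts(table: pd.DataFrame, path) -> None:
    """Write a long-dialect site count table (``#``-prefixed header)."""
    out = table[SITE_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(SITE_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models (BED12)
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read BED12 gene models, expanding blocks into exon intervals."""
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(path, lineno, f"BED12 needs 12 fields, got {len(parts)}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    path, lineno,
                    f"blockCount={n_blocks} but {len(sizes)} sizes / {len(offsets)} starts")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                genes.append(GeneModel(name, chrom, strand, start, end, exons))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as BED12."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                g.start, g.end, "0,0,0", len(g.exons), sizes, offsets,
            ])) + "\n")


# ---------------------------------------------------------------------------
# expression tables (RPKM, wide: gene x samples)
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a wide RPKM table (rows = genes, columns = samples)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).lstrip("#").strip() for c in df.columns]
    if "gene" not in df.columns:
        raise ParseError(path, 1, "expression table needs a 'gene' column")
    return df.set_index("gene")


def write_expression(table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\t" + "\t".join(map(str, table.columns)) + "\n")
        table.to_csv(fh, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Hi-C triplets + bins
# ---------------------------------------------------------------------------

def read_contact_triplets(path_bins, path_triplets):
    """Read a bin BED + (i, j, count) triplet TSV into a contact matrix.

    (i, j) and (j, i) triplets are merged; duplicates are summed.
    """
    from .tads import BinnedContactMatrix

    bins = []
    with open(path_bins, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path_bins, lineno, "bin BED needs chrom/start/end/id")
            bins.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    if not bins:
        raise ParseError(path_bins, None, "no bins found")
    bins.sort(key=lambda b: b[3])
    if [b[3] for b in bins] != list(range(len(bins))):
        raise ParseError(path_bins, None, "bin ids must be 0..n-1")
    chrom = bins[0][0]
    bin_size = bins[0][2] - bins[0][1]
    n = len(bins)

    matrix = np.zeros((n, n), dtype=float)
    with open(path_triplets, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path_triplets, lineno, "triplet rows are bin_i, bin_j, count")
            i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            if not (0 <= i < n and 0 <= j < n):
                raise ParseError(path_triplets, lineno, f"bin id out of range ({i},{j})")
            matrix[i, j] += c
            if i != j:
                matrix[j, i] += c
    return BinnedContactMatrix(chrom=chrom, bin_size=bin_size, matrix=matrix)


def write_contact_triplets(cmat, path_bins, path_triplets) -> None:
    """Write a contact matrix as a bin BED plus upper-triangle triplets."""
    n = cmat.n_bins
    with open(path_bins, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tbin\n")
        for i in range(n):
            s, e = cmat.bin_interval(i)
            fh.write(f"{cmat.chrom}\t{s}\t{e}\t{i}\n")
    with open(path_triplets, "w", encoding="utf-8") as fh:
        fh.write("#bin_i\tbin_j\tcount\n")
        iu, ju = np.nonzero(np.triu(cmat.matrix))
        for i, j in zip(iu, ju):
            v = cmat.matrix[i, j]
            fh.write(f"{i}\t{j}\t{v:g}\n")


# ---------------------------------------------------------------------------
# BED / WIG
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[tuple], path) -> None:
    """Write (chrom, start, end[, name]) intervals as BED; sorts if needed."""
    rows = [tuple(iv) for iv in intervals]
    ordered = sorted(rows, key=lambda r: (r[0], r[1], r[2]))
    if rows != ordered:
        warnings.warn("unsorted intervals: sorting on write", stacklevel=2)
    with open(path, "w", encoding="utf-8") as fh:
        for row in ordered:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path) -> list[tuple]:
    """Read a BED3+ file back into (chrom, start, end[, name]) tuples."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED needs at least 3 columns")
            row = [parts[0], int(parts[1]), int(parts[2])] + parts[3:]
            out.append(tuple(row))
    return out


def write_wig(track: dict, path) -> None:
    """Write a fixedStep WIG track.

    ``track`` carries ``chrom``, ``start`` (0-based internal; written 1-based),
    ``step`` and ``values``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"fixedStep chrom={track['chrom']} start={track['start'] + 1} "
            f"step={track['step']} span={track['step']}\n")
        for v in track["values"]:
            fh.write(f"{v:g}\n")


def read_wig(path) -> dict:
    """Read a single fixedStep WIG track written by :func:`write_wig`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if not header or header[0] != "fixedStep":
            raise ParseError(path, 1, "expected a fixedStep declaration")
        kv = dict(item.split("=") for item in header[1:])
        values = [float(line) for line in fh if line.strip()]
    return {
        "chrom": kv["chrom"],
        "start": int(kv["start"]) - 1,
        "step": int(kv["step"]),
        "values": np.asarray(values),
    }


# ---------------------------------------------------------------------------
# packaged escape-gene table
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged table of genes escaping XCI in the three NPC lines.

    One row per gene with its strand, Mb start position on chrX, and — per
    NPC line — the printed Xi/Xa log2 ratio plus a status code: ``E`` escape,
    ``S`` subject to XCI (a dash in the original means no Xi signal, the
    ratio is then missing), ``I`` insufficient allelic coverage to classify.
    ``region`` is 1-3 for genes inside the three distal escape regions
    (0 otherwise) and ``validated`` flags escape confirmed by cDNA Sanger
    sequencing.
    """
    ref = resources.files("xcidyn").joinpath("data/table1_escape_genes.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    df["validated"] = df["validated"].astype(bool)
    return df


def table1_line_columns(line: str) -> tuple[str, str]:
    """Map an NPC line label to its (ratio, status) fixture columns."""
    key = _LINE_KEYS[line]
    return f"ratio_{key}", f"status_{key}"
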
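"""Readers and writers for the plain-text formats the pipeline exchanges.

All internal coordinates are 0-based half-open.  BED is native; GTF is
1-based closed on disk and converted on read/write.  The readers are
strict: malformed lines raise ``ParseError`` naming the file and line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd


class ParseError(ValueError):
    """Raised when an input file fails validation."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open; strand '.' when unstranded."""

    contig: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.contig}:{self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.contig == other.contig
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """A gene with strand, coordinates and at least one exon."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """TSS coordinate: gene start on +, gene end on - (half-open edge)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tss_position(self) -> int:
        """0-based index of the TSS base."""
        return self.start if self.strand == "+" else self.end - 1


# ----------------------------------------------------------------- BED I/O

def read_bed(path: str | Path) -> List[Interval]:
    """Read BED3/BED6 into intervals (0-based half-open, as on disk)."""
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            strand = f[5] if len(f) > 5 else "."
            if strand not in "+-.":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            out.append(Interval(f[0], start, end, name, score, strand))
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                     f"{iv.score:g}\t{iv.strand}\n")


# ----------------------------------------------------------------- GTF I/O

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> List[GeneModel]:
    """Read gene/exon features from GTF into gene models.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Exons are attached to genes via ``gene_id``.
    """
    genes: Dict[str, GeneModel] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            contig, _src, feature, start1, end1, _score, strand, _frame, attrs = f
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: coordinate < 1")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            m = dict(_GTF_ATTR.findall(attrs))
            gene_id = m.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                if gene_id in genes:
                    raise ParseError(f"{path}:{lineno}: duplicate gene {gene_id}")
                genes[gene_id] = GeneModel(gene_id, contig, start, end, strand)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append((start, end))
    for gene_id, gene in genes.items():
        gene.exons = sorted(exons.get(gene_id, [(gene.start, gene.end)]))
    return list(genes.values())


def write_gtf(genes: Sequence[GeneModel], path: str | Path,
              source: str = "g4access") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (es, ee) in enumerate(g.exons, 1):
                ex_attrs = (f'gene_id "{g.gene_id}"; '
                            f'transcript_id "{g.gene_id}.t1"; '
                            f'exon_number "{i}";')
                fh.write(f"{g.contig}\t{source}\texon\t{es + 1}\t{ee}\t.\t"
                         f"{g.strand}\t.\t{ex_attrs}\n")


def load_intervals(path: str | Path, fmt: str | None = None) -> List[Interval]:
    """Load intervals from BED or GTF (gene records), by extension if
    ``fmt`` is not given."""
    fmt = fmt or ("GTF" if str(path).lower().endswith((".gtf", ".gff")) else "BED")
    fmt = fmt.upper()
    if fmt == "BED":
        return read_bed(path)
    if fmt == "GTF":
        return [Interval(g.contig, g.start, g.end, g.gene_id, 0.0, g.strand)
                for g in read_gtf_genes(path)]
    raise ValueError(f"unknown interval format {fmt!r}")


# --------------------------------------------------------------- count I/O

def load_counts(counts_path: str | Path,
                samples_path: str | Path) -> "CountMatrix":
    """Load a region x sample integer count TSV plus a sample sheet.

    The counts file has a header row of sample ids and region ids in the
    first column; the sample sheet maps every sample to a condition.
    """
    from .differential import CountMatrix  # local import to avoid a cycle

    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{counts_path}: duplicated region id {dup!r}")
    for col in df.columns:
        bad = df[col][~df[col].apply(
            lambda v: isinstance(v, (int,)) or float(v).is_integer())]
        if len(bad):
            raise ParseError(
                f"{counts_path}: non-integer count {bad.iloc[0]!r} in "
                f"sample {col!r}")
    df = df.astype(int)
    if (df.values < 0).any():
        raise ParseError(f"{counts_path}: negative counts")

    sheet = pd.read_csv(samples_path, sep="\t")
    if not {"sample", "condition"} <= set(sheet.columns):
        raise ParseError(
            f"{samples_path}: needs 'sample' and 'condition' columns")
    cond = dict(zip(sheet["sample"].astype(str), sheet["condition"].astype(str)))
    missing = [s for s in df.columns if s not in cond]
    if missing:
        raise ParseError(f"{samples_path}: samples {missing} not mapped to a "
                         f"condition")
    return CountMatrix(counts=df, conditions={s: cond[s] for s in df.columns})


def write_counts(counts: "pd.DataFrame", path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="region_id")


def write_samples(conditions: Dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, condition in conditions.items():
            fh.write(f"{sample}\t{condition}\n")
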
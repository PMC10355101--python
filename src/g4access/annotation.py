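"""Feature annotation of accessibility peaks.

Each (unstranded) peak is assigned exactly one feature class by priority:
Promoter > Exon > Intron > Downstream > Intergenic.  Promoters are windows
around each gene's TSS (default 2 kb upstream, 500 bp downstream, in gene
orientation); Downstream covers a fixed extent past the 3' end.  Overlap
means >=1 shared bp under half-open arithmetic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

from intervaltree import IntervalTree

from .io import GeneModel, Interval

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("Promoter", "Exon", "Intron", "Downstream", "Intergenic")


@dataclass(frozen=True)
class AnnotationParams:
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    downstream_extent: int = 3000

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream,
               self.downstream_extent) < 0:
            raise ValueError("annotation extents must be non-negative")
        if self.promoter_upstream + self.promoter_downstream == 0:
            raise ValueError("promoter window must be non-empty")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Interval
    feature_class: str
    nearest_gene: str
    distance_to_tss: int


def build_promoters(genes: Sequence[GeneModel],
                    params: AnnotationParams | None = None,
                    contig_lengths: Dict[str, int] | None = None,
                    ) -> List[Interval]:
    """Promoter windows around each TSS, in gene orientation.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand:
    ``[tss - downstream, tss + upstream)`` with ``tss`` the gene end.
    Clamped to ``[0, contig length)`` when lengths are supplied.
    """
    params = params or AnnotationParams()
    out: List[Interval] = []
    for g in genes:
        if g.strand == "+":
            start = g.tss - params.promoter_upstream
            end = g.tss + params.promoter_downstream
        elif g.strand == "-":
            start = g.tss - params.promoter_downstream
            end = g.tss + params.promoter_upstream
        else:
            raise ValueError(f"gene {g.gene_id}: unknown strand {g.strand!r}")
        start = max(0, start)
        if contig_lengths and g.contig in contig_lengths:
            end = min(end, contig_lengths[g.contig])
        if end > start:
            out.append(Interval(g.contig, start, end, g.gene_id, 0.0, g.strand))
    return out


class _GeneIndex:
    """Per-contig interval trees over promoters, exons, gene bodies and
    downstream windows, plus TSS positions for distance queries."""

    def __init__(self, genes: Sequence[GeneModel],
                 params: AnnotationParams,
                 promoters: Sequence[Interval] | None = None) -> None:
        self.params = params
        self.genes = {g.gene_id: g for g in genes}
        if promoters is None:
            promoters = build_promoters(genes, params)
        self.promoter_trees: Dict[str, IntervalTree] = {}
        self.exon_trees: Dict[str, IntervalTree] = {}
        self.gene_trees: Dict[str, IntervalTree] = {}
        self.downstream_trees: Dict[str, IntervalTree] = {}
        for p in promoters:
            self.promoter_trees.setdefault(p.contig, IntervalTree()).addi(
                p.start, p.end, p.name)
        for g in genes:
            self.gene_trees.setdefault(g.contig, IntervalTree()).addi(
                g.start, g.end, g.gene_id)
            for es, ee in (g.exons or [(g.start, g.end)]):
                self.exon_trees.setdefault(g.contig, IntervalTree()).addi(
                    es, ee, g.gene_id)
            if params.downstream_extent > 0:
                if g.strand == "+":
                    ds, de = g.end, g.end + params.downstream_extent
                else:
                    ds, de = max(0, g.start - params.downstream_extent), g.start
                if de > ds:
                    self.downstream_trees.setdefault(
                        g.contig, IntervalTree()).addi(ds, de, g.gene_id)

    def hits(self, trees: Dict[str, IntervalTree], peak: Interval) -> List[str]:
        tree = trees.get(peak.contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(peak.start, peak.end)]


def _tss_distance(gene: GeneModel, peak: Interval) -> int:
    """Signed bp from TSS to the nearest point of the peak, in gene
    orientation (positive = downstream of the TSS); 0 when the peak
    covers the TSS base."""
    t = gene.tss_position
    if peak.start <= t < peak.end:
        return 0
    d = peak.start - t if peak.start > t else peak.end - 1 - t
    return d if gene.strand == "+" else -d


def assign_feature(peak: Interval, index: _GeneIndex) -> AnnotatedPeak:
    """Classify one peak; ties broken by |distance to TSS| then gene id."""
    for cls, trees in (("Promoter", index.promoter_trees),
                       ("Exon", index.exon_trees),
                       ("Intron", index.gene_trees),
                       ("Downstream", index.downstream_trees)):
        gene_ids = index.hits(trees, peak)
        if gene_ids:
            best = min(gene_ids, key=lambda gid: (
                abs(_tss_distance(index.genes[gid], peak)), gid))
            return AnnotatedPeak(peak, cls, best,
                                 _tss_distance(index.genes[best], peak))
    # intergenic: nearest gene on the contig, if any
    on_contig = [g for g in index.genes.values() if g.contig == peak.contig]
    if not on_contig:
        logger.warning("peak %s:%d-%d on contig absent from annotation",
                       peak.contig, peak.start, peak.end)
        return AnnotatedPeak(peak, "Intergenic", ".", 0)
    best = min(on_contig, key=lambda g: (abs(_tss_distance(g, peak)), g.gene_id))
    return AnnotatedPeak(peak, "Intergenic", best.gene_id,
                         _tss_distance(best, peak))


def annotate_peaks(peaks: Sequence[Interval], genes: Sequence[GeneModel],
                   params: AnnotationParams | None = None,
                   promoters: Sequence[Interval] | None = None,
                   ) -> List[AnnotatedPeak]:
    params = params or AnnotationParams()
    index = _GeneIndex(genes, params, promoters)
    return [assign_feature(p, index) for p in peaks]


def feature_distribution(annotated: Iterable[AnnotatedPeak]) -> Dict[str, float]:
    """Fraction of peaks per feature class (sums to 1)."""
    annotated = list(annotated)
    if not annotated:
        raise ValueError("feature_distribution requires at least one peak")
    counts = Counter(a.feature_class for a in annotated)
    n = len(annotated)
    return {cls: counts.get(cls, 0) / n for cls in FEATURE_CLASSES}


def write_annotated(annotated: Sequence[AnnotatedPeak],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpeak_id\tfeature_class\tnearest_gene\t"
                 "distance_to_tss\n")
        for a in annotated:
            fh.write(f"{a.peak.contig}\t{a.peak.start}\t{a.peak.end}\t"
                     f"{a.peak.name or '.'}\t{a.feature_class}\t"
                     f"{a.nearest_gene}\t{a.distance_to_tss}\n")


def read_annotated(path: str | Path) -> List[AnnotatedPeak]:
    out: List[AnnotatedPeak] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peak = Interval(f[idx["chrom"]], int(f[idx["start"]]),
                            int(f[idx["end"]]), f[idx["peak_id"]])
            out.append(AnnotatedPeak(peak, f[idx["feature_class"]],
                                     f[idx["nearest_gene"]],
                                     int(f[idx["distance_to_tss"]])))
    return out
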
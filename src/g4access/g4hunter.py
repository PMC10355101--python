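"""G4Hunter-style prediction of G-quadruplex-prone sequence (pG4s).

The scorer assigns every base in a maximal run of n guanines the score
+min(n, 4) and every base in a maximal cytosine run -min(n, 4); all other
bases score 0.  Sliding-window means of these base scores are thresholded,
overlapping same-signed windows are merged, merged regions are extended to
complete any G-run (or C-run, for negative regions) crossing their
boundaries, and each refined region is kept only if the mean base score
over the final interval still clears the threshold.  Positive regions are
reported on the + strand (G-rich on the given sequence), negative regions
on the - strand.

Coordinates are 0-based half-open throughout; BED output is native.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np

from .genome import GenomeSequence

logger = logging.getLogger(__name__)

# per-base score lookup over ASCII codes; -128 marks a rejected character
_BASE_CODE = np.full(256, -128, dtype=np.int8)
for _ch in b"ACGTNRYSWKMBDHVacgtnryswkmbdhv":
    _BASE_CODE[_ch] = 0
for _ch in b"Gg":
    _BASE_CODE[_ch] = 1
for _ch in b"Cc":
    _BASE_CODE[_ch] = -1


@dataclass(frozen=True)
class G4HunterParams:
    """Window size, score threshold and merge behaviour for pG4 calling."""

    window: int = 25
    threshold: float = 1.2
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")


@dataclass(frozen=True)
class PG4Region:
    """A predicted G4-forming interval.

    ``score`` is the mean base score over the interval with the sign
    stripped; the strand carries the sign (+ for G-rich, - for C-rich).
    """

    contig: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("PG4Region requires end > start")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def base_scores(sequence: str | bytes | bytearray) -> np.ndarray:
    """Per-base G4Hunter scores of a DNA sequence.

    Bases in a maximal G-run of length n score +min(n, 4); bases in a
    C-run score -min(n, 4); A, T, N and ambiguity codes score 0 and break
    runs.  Case-insensitive.
    """
    if isinstance(sequence, str):
        sequence = sequence.encode()
    arr = np.frombuffer(bytes(sequence), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    bad = np.flatnonzero(codes == -128)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-IUPAC character {chr(arr[pos])!r} at position {pos}")
    if arr.size == 0:
        return np.zeros(0, dtype=float)
    # boundaries of maximal runs of identical codes
    edges = np.flatnonzero(np.diff(codes.astype(np.int16)) != 0) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [arr.size]))
    lengths = ends - starts
    run_vals = codes[starts].astype(float) * np.minimum(lengths, 4)
    return np.repeat(run_vals, lengths)


def window_scores(scores: Sequence[float] | np.ndarray, window: int) -> np.ndarray:
    """Sliding-window arithmetic means (step 1) of per-base scores."""
    scores = np.asarray(scores, dtype=float)
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    if window > scores.size:
        raise ValueError(
            f"window {window} exceeds sequence length {scores.size}")
    cs = np.concatenate(([0.0], np.cumsum(scores)))
    return (cs[window:] - cs[:-window]) / window


def _merge_hit_windows(idx: np.ndarray, window: int,
                       merge_adjacent: bool) -> List[tuple[int, int]]:
    """Union overlapping/adjacent hit windows [i, i+window) into spans."""
    if idx.size == 0:
        return []
    spans: List[tuple[int, int]] = []
    start = int(idx[0])
    end = start + window
    for i in idx[1:]:
        i = int(i)
        if merge_adjacent and i <= end:
            end = i + window
        else:
            spans.append((start, end))
            start, end = i, i + window
    spans.append((start, end))
    return spans


def _extend_to_runs(codes: np.ndarray, start: int, end: int,
                    target: int) -> tuple[int, int]:
    """Extend [start, end) to complete target-base runs crossing its ends."""
    if codes[start] == target:
        while start > 0 and codes[start - 1] == target:
            start -= 1
    if codes[end - 1] == target:
        n = codes.size
        while end < n and codes[end] == target:
            end += 1
    return start, end


def call_pg4(genome: GenomeSequence,
             params: G4HunterParams | None = None) -> List[PG4Region]:
    """Call pG4 regions over every contig of a genome.

    Contigs shorter than the window are skipped with a warning.  Regions
    are emitted in (contig, start) order; + strand for G-rich regions,
    - strand for C-rich regions, with ``score`` the absolute mean base
    score over the final interval.
    """
    params = params or G4HunterParams()
    regions: List[PG4Region] = []
    for name, seq in genome.items():
        if len(seq) < params.window:
            logger.warning(
                "contig %s (%d bp) shorter than window %d; skipped",
                name, len(seq), params.window)
            continue
        regions.extend(_call_contig(name, seq, params))
    return regions


def _call_contig(name: str, seq: bytes | bytearray,
                 params: G4HunterParams) -> List[PG4Region]:
    scores = base_scores(seq)
    codes = np.sign(scores).astype(np.int8)
    wmeans = window_scores(scores, params.window)
    cs = np.concatenate(([0.0], np.cumsum(scores)))
    out: List[PG4Region] = []
    candidates: List[tuple[int, int, int]] = []
    for sign in (1, -1):
        hits = np.flatnonzero(sign * wmeans >= params.threshold)
        for start, end in _merge_hit_windows(hits, params.window,
                                             params.merge_adjacent):
            candidates.append((start, end, sign))
    for start, end, sign in sorted(candidates):
        start, end = _extend_to_runs(codes, start, end, sign)
        mean = (cs[end] - cs[start]) / (end - start)
        if sign * mean >= params.threshold:
            spans = [(start, end)]
        else:
            # flanking sequence swept up by the window union dilutes a
            # strong core below threshold: fall back to the densest
            # subregion(s) around the best window(s)
            spans = _dense_subregions(cs, wmeans, start, end, sign, params)
        for s, e in spans:
            mean = (cs[e] - cs[s]) / (e - s)
            out.append(PG4Region(contig=name, start=s, end=e,
                                 strand="+" if sign > 0 else "-",
                                 score=abs(mean)))
    out.sort(key=lambda r: (r.start, r.end, r.strand))
    return out


def _dense_subregions(cs: np.ndarray, wmeans: np.ndarray, start: int,
                      end: int, sign: int,
                      params: G4HunterParams) -> list[tuple[int, int]]:
    """Best-scoring window(s) within [start, end), each grown greedily
    outward one base at a time toward the higher resulting mean while
    the region mean stays at or above the threshold.

    All rules are mirror-symmetric so that calls commute with reverse
    complementation: growth extends both ends on an exact tie (only if
    the doubly extended mean still clears the threshold), and when the
    best window score is tied the leftmost and rightmost tied windows
    are both grown (their grown regions coincide in all but degenerate
    cases)."""
    w = params.window

    def mean_of(a: int, b: int) -> float:
        return sign * (cs[b] - cs[a]) / (b - a)

    def grow(best: int) -> tuple[int, int]:
        lo, hi = best, best + w
        while True:
            left = mean_of(lo - 1, hi) if lo > start else -np.inf
            right = mean_of(lo, hi + 1) if hi < end else -np.inf
            if max(left, right) < params.threshold:
                return lo, hi
            if left == right:
                if mean_of(lo - 1, hi + 1) < params.threshold:
                    return lo, hi
                lo -= 1
                hi += 1
            elif left > right:
                lo -= 1
            else:
                hi += 1

    idx = np.arange(start, end - w + 1)
    vals = sign * wmeans[idx]
    ties = idx[vals == vals.max()]
    spans = {grow(int(ties[0])), grow(int(ties[-1]))}
    return sorted(spans)


# ---------------------------------------------------------------------- I/O

def write_pg4_bed(regions: Iterable[PG4Region], path: str | Path) -> None:
    """Write calls as BED6; score column is 1000*min(|score|/4, 1), rounded."""
    with open(path, "w") as fh:
        for r in regions:
            bed_score = round(1000 * min(r.score / 4.0, 1.0))
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tpG4\t{bed_score}\t{r.strand}\n")


def write_pg4_scores(regions: Iterable[PG4Region], path: str | Path) -> None:
    """Write calls as TSV with exact float scores."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tscore\n")
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.strand}\t{r.score:.10g}\n")


def read_pg4_bed(path: str | Path) -> List[PG4Region]:
    """Read pG4 calls from BED6 (score rescaled back from the 0-1000 column)."""
    regions: List[PG4Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6, got "
                                 f"{len(fields)} fields")
            contig, start, end, _name, score, strand = fields[:6]
            regions.append(PG4Region(contig=contig, start=int(start),
                                     end=int(end), strand=strand,
                                     score=float(score) * 4.0 / 1000.0))
    return regions
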
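"""Shared fixtures and independent reference implementations.

The ``naive_*`` helpers are deliberately written as plain-Python loops,
independent of the vectorised library code, and serve as oracles in the
equivalence tests.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
import pytest

from g4access.io import GeneModel, Interval


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


# ---------------------------------------------------------- G4Hunter oracle

def naive_base_scores(seq: str) -> List[float]:
    seq = seq.upper()
    scores = [0.0] * len(seq)
    i = 0
    while i < len(seq):
        c = seq[i]
        if c in "GC":
            j = i
            while j < len(seq) and seq[j] == c:
                j += 1
            val = float(min(j - i, 4)) * (1.0 if c == "G" else -1.0)
            for k in range(i, j):
                scores[k] = val
            i = j
        else:
            i += 1
    return scores


def naive_call_pg4(seq: str, window: int,
                   threshold: float) -> List[Tuple[int, int, str, float]]:
    """O(L*W) reference caller: windowed means, same-sign merge,
    run extension, full-span re-check with densest-subregion fallback."""
    sc = naive_base_scores(seq)
    n = len(sc)
    if n < window:
        return []
    ws = [sum(sc[i:i + window]) / window for i in range(n - window + 1)]

    def runs_extend(start: int, end: int, sign: int) -> Tuple[int, int]:
        def code(k: int) -> int:
            return 0 if sc[k] == 0 else (1 if sc[k] > 0 else -1)
        if code(start) == sign:
            while start > 0 and code(start - 1) == sign:
                start -= 1
        if code(end - 1) == sign:
            while end < n and code(end) == sign:
                end += 1
        return start, end

    def mean(a: int, b: int) -> float:
        return sum(sc[a:b]) / (b - a)

    out = []
    candidates = []
    for sign in (1, -1):
        hits = [i for i in range(len(ws)) if sign * ws[i] >= threshold]
        spans: List[List[int]] = []
        for i in hits:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = i + window
            else:
                spans.append([i, i + window])
        candidates += [(s, e, sign) for s, e in spans]
    for start, end, sign in sorted(candidates):
        start, end = runs_extend(start, end, sign)
        if sign * mean(start, end) >= threshold:
            final = [(start, end)]
        else:
            def grow(best: int) -> Tuple[int, int]:
                lo, hi = best, best + window
                while True:
                    left = sign * mean(lo - 1, hi) if lo > start else -math.inf
                    right = sign * mean(lo, hi + 1) if hi < end else -math.inf
                    if max(left, right) < threshold:
                        return lo, hi
                    if left == right:
                        if sign * mean(lo - 1, hi + 1) < threshold:
                            return lo, hi
                        lo -= 1
                        hi += 1
                    elif left > right:
                        lo -= 1
                    else:
                        hi += 1

            best_val = max(sign * ws[i] for i in range(start, end - window + 1))
            ties = [i for i in range(start, end - window + 1)
                    if sign * ws[i] == best_val]
            final = sorted({grow(ties[0]), grow(ties[-1])})
        for s, e in final:
            out.append((s, e, "+" if sign > 0 else "-", abs(mean(s, e))))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


# ------------------------------------------------------- interval utilities

def random_intervals(rng: np.random.Generator, n: int, span: int,
                     max_len: int, contig: str = "chr1") -> List[Interval]:
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    return [Interval(contig, int(s), int(s + l), f"iv_{i}")
            for i, (s, l) in enumerate(zip(starts, lengths))]


def random_sequence(rng: np.random.Generator, length: int,
                    gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


# ----------------------------------------------------------- tiny gene sets

@pytest.fixture
def toy_genes() -> List[GeneModel]:
    return [
        GeneModel("gene_a", "chr1", 10_000, 13_000, "+",
                  exons=[(10_000, 10_400), (12_500, 13_000)]),
        GeneModel("gene_b", "chr1", 30_000, 33_000, "-",
                  exons=[(30_000, 30_400), (32_500, 33_000)]),
    ]
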
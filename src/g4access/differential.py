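"""Differential accessibility / expression from replicated count matrices.

The model is a two-condition negative-binomial (NB) comparison in the
classic exact-test style: per-sample size factors by median-of-ratios,
log2 counts-per-million with a 0.5 prior count, a moment-based dispersion
estimate shrunk toward the across-region mean, an exact conditional test
on library-equalised group sums, and Benjamini-Hochberg FDR.  Regions are
flagged as differentially accessible at FDR < 0.1, and as differentially
expressed at FDR < 0.05 with |log2 FC| > 2, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-6


@dataclass
class CountMatrix:
    """Region x sample integer counts with a two-condition sample map.

    The reference condition (the "A" side of log2 fold changes) is the
    condition of the first sample.
    """

    counts: pd.DataFrame
    conditions: Dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition labels: {missing}")
        levels = self.condition_levels
        if len(levels) != 2:
            raise ValueError(
                f"expected exactly two conditions, got {levels}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def condition_levels(self) -> List[str]:
        seen: List[str] = []
        for s in self.counts.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> List[str]:
        return [s for s in self.counts.columns
                if self.conditions[s] == condition]


@dataclass(frozen=True)
class DifferentialResult:
    region_id: str
    log2fc: float
    mean_log_cpm: float
    p_value: float
    fdr: float
    direction: str
    is_significant_dar: bool = False
    is_significant_deg: bool = False


# ------------------------------------------------------------ normalisation

def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Ratios are taken against the per-region geometric mean over samples,
    using only regions with no zero count; with fewer than 50 usable
    regions the factors fall back to total-count ratios.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    usable = (mat > 0).all(axis=1)
    if usable.sum() >= 50:
        logmat = np.log(mat[usable])
        log_geo = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - log_geo, axis=0))
    else:
        factors = totals
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


def effective_libraries(counts: pd.DataFrame | np.ndarray,
                        factors: np.ndarray) -> np.ndarray:
    """Effective library size per sample.

    The geometric-mean total count times the sample's size factor: the
    factors carry all relative depth (median-of-ratios), so depth is
    corrected exactly once and identical columns give identical
    effective libraries equal to their totals.
    """
    mat = np.asarray(counts, dtype=float)
    totals = mat.sum(axis=0)
    return float(np.exp(np.mean(np.log(totals)))) * np.asarray(factors, float)


def log_cpm(counts: pd.DataFrame | np.ndarray,
            factors: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with a 0.5 prior count.

    ``log2((count + 0.5) / (effective library + 1) * 1e6)`` where the
    effective library is the sample total times its size factor.
    """
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    mat = np.asarray(counts, dtype=float)
    lib = effective_libraries(mat, factors)
    return np.log2((mat + 0.5) / (lib + 1.0) * 1e6)


# -------------------------------------------------------------- dispersion

def estimate_dispersion(counts: pd.DataFrame | np.ndarray,
                        conditions: Sequence[str],
                        factors: np.ndarray | None = None) -> np.ndarray:
    """Per-region NB dispersion by the method of moments, with shrinkage.

    Counts are depth-normalised to the geometric-mean effective library;
    within each condition with >=2 replicates the raw estimate is
    ``max(0, (s^2 - m) / m^2)``; condition estimates are pooled by
    degrees of freedom, shrunk halfway toward the across-region mean of
    the raw estimates, and floored at 1e-6.
    """
    mat = np.asarray(counts, dtype=float)
    conditions = np.asarray(conditions)
    if factors is None:
        factors = size_factors(mat)
    lib = effective_libraries(mat, factors)
    norm = mat * (np.exp(np.mean(np.log(lib))) / lib)

    raw = np.zeros(mat.shape[0])
    weight = 0
    any_replicated = False
    for cond in np.unique(conditions):
        cols = conditions == cond
        n = int(cols.sum())
        if n < 2:
            continue
        any_replicated = True
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        raw += np.maximum(est, 0.0) * (n - 1)
        weight += n - 1
    if not any_replicated:
        import warnings
        warnings.warn("no condition has >=2 replicates; dispersion set to 0",
                      stacklevel=2)
        return np.zeros(mat.shape[0])
    raw /= weight
    pooled = raw.mean()
    return np.maximum(0.5 * raw + 0.5 * pooled, DISPERSION_FLOOR)


# --------------------------------------------------------------- exact test

def _group_pseudo_sum(counts: np.ndarray, libs: np.ndarray,
                      common: float) -> int:
    """Sum of counts after scaling every sample to the common library."""
    return int(round(float(np.sum(counts * (common / libs)))))


def nb_exact_test(counts_a: Sequence[int], counts_b: Sequence[int],
                  factors_a: Sequence[float] | None = None,
                  factors_b: Sequence[float] | None = None,
                  dispersion: float = 0.0,
                  libs_a: Sequence[float] | None = None,
                  libs_b: Sequence[float] | None = None,
                  ) -> tuple[float, float]:
    """Exact conditional two-group NB test on one region.

    Group pseudo-counts ``a`` and ``b`` are the group sums after scaling
    each sample to the common (geometric mean) effective library.  Given
    the total T = a + b, every split (i, T - i) is scored by its NB
    probability (binomial when dispersion is 0); the two-sided p-value is
    the total probability of splits no more probable than the observed
    one.  Returns ``(p_value, log2fc)`` with
    ``log2fc = log2((b + 0.5) / (a + 0.5))`` corrected for unequal group
    sizes.
    """
    a_arr = np.asarray(counts_a, dtype=float)
    b_arr = np.asarray(counts_b, dtype=float)
    if (a_arr < 0).any() or (b_arr < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    n_a, n_b = a_arr.size, b_arr.size

    # effective libraries; bare factors act as relative libraries when no
    # totals are available (e.g. single-region calls in tests)
    if libs_a is None:
        libs_a = np.ones(n_a) if factors_a is None else np.asarray(factors_a, float)
    if libs_b is None:
        libs_b = np.ones(n_b) if factors_b is None else np.asarray(factors_b, float)
    libs_a = np.asarray(libs_a, dtype=float)
    libs_b = np.asarray(libs_b, dtype=float)

    common = float(np.exp(np.mean(np.log(np.concatenate([libs_a, libs_b])))))
    a = _group_pseudo_sum(a_arr, libs_a, common)
    b = _group_pseudo_sum(b_arr, libs_b, common)

    log2fc = float(np.log2((b + 0.5) / (a + 0.5) * (n_a / n_b)))
    p = _exact_conditional_p(a, b, n_a, n_b, dispersion)
    return p, log2fc


def _exact_conditional_p(a: int, b: int, n_a: int, n_b: int,
                         dispersion: float) -> float:
    total = a + b
    if total == 0:
        return 1.0
    i = np.arange(total + 1)
    frac_a = n_a / (n_a + n_b)
    if dispersion <= 0:
        logp = stats.binom.logpmf(i, total, frac_a)
    else:
        mu_a = total * frac_a
        mu_b = total - mu_a
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        logp = (stats.nbinom.logpmf(i, r_a, r_a / (r_a + mu_a))
                + stats.nbinom.logpmf(total - i, r_b, r_b / (r_b + mu_b)))
    # normalise over the conditional support
    logz = np.logaddexp.reduce(logp)
    logp = logp - logz
    keep = logp <= logp[a] + 1e-10
    p = float(np.exp(np.logaddexp.reduce(logp[keep])))
    return min(p, 1.0)


# ---------------------------------------------------------------------- BH

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ orchestration

def run_differential(matrix: CountMatrix,
                     dar_fdr: float = 0.1,
                     deg_fdr: float = 0.05,
                     deg_lfc: float = 2.0) -> List[DifferentialResult]:
    """Full differential analysis of a two-condition count matrix.

    Log2 fold changes are condition B versus A, where A is the reference
    (first-seen) condition.
    """
    cond_a, cond_b = matrix.condition_levels
    samples_a = matrix.samples_of(cond_a)
    samples_b = matrix.samples_of(cond_b)
    mat = matrix.counts
    factors = size_factors(mat)
    libs = effective_libraries(mat, factors)
    lib_by_sample = dict(zip(mat.columns, libs))
    cond_vec = [matrix.conditions[s] for s in mat.columns]
    disp = estimate_dispersion(mat, cond_vec, factors)
    lcpm = log_cpm(mat, factors)
    mean_lcpm = lcpm.mean(axis=1)

    libs_a = np.array([lib_by_sample[s] for s in samples_a])
    libs_b = np.array([lib_by_sample[s] for s in samples_b])
    a_mat = mat[samples_a].to_numpy()
    b_mat = mat[samples_b].to_numpy()

    results: List[DifferentialResult] = []
    pvals = np.empty(len(mat))
    lfcs = np.empty(len(mat))
    for r in range(len(mat)):
        pvals[r], lfcs[r] = nb_exact_test(
            a_mat[r], b_mat[r], dispersion=float(disp[r]),
            libs_a=libs_a, libs_b=libs_b)
    fdrs = bh_adjust(pvals)
    for r, region_id in enumerate(mat.index):
        results.append(DifferentialResult(
            region_id=str(region_id), log2fc=float(lfcs[r]),
            mean_log_cpm=float(mean_lcpm[r]), p_value=float(pvals[r]),
            fdr=float(fdrs[r]),
            direction="increased" if lfcs[r] > 0 else "reduced"))
    return call_differential(results, dar_fdr, deg_fdr, deg_lfc)


def call_differential(results: Sequence[DifferentialResult],
                      dar_fdr: float = 0.1,
                      deg_fdr: float = 0.05,
                      deg_lfc: float = 2.0) -> List[DifferentialResult]:
    """Apply significance thresholds: DAR at FDR < ``dar_fdr``; DEG at
    FDR < ``deg_fdr`` and |log2 FC| > ``deg_lfc``."""
    out: List[DifferentialResult] = []
    for r in results:
        out.append(DifferentialResult(
            region_id=r.region_id, log2fc=r.log2fc,
            mean_log_cpm=r.mean_log_cpm, p_value=r.p_value, fdr=r.fdr,
            direction="increased" if r.log2fc > 0 else "reduced",
            is_significant_dar=r.fdr < dar_fdr,
            is_significant_deg=r.fdr < deg_fdr and abs(r.log2fc) > deg_lfc))
    return out


# ---------------------------------------------------------------------- I/O

def write_results(results: Sequence[DifferentialResult], path: str | Path,
                  mode: str = "dar") -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tlog2fc\tmean_log_cpm\tp_value\tfdr\tdirection\t"
                 "significant\n")
        for r in results:
            sig = r.is_significant_dar if mode == "dar" else r.is_significant_deg
            fh.write(f"{r.region_id}\t{r.log2fc:.6g}\t{r.mean_log_cpm:.6g}\t"
                     f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.direction}\t"
                     f"{int(sig)}\n")


def read_results(path: str | Path, mode: str = "dar") -> List[DifferentialResult]:
    out: List[DifferentialResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sig = bool(int(f[idx["significant"]]))
            out.append(DifferentialResult(
                region_id=f[idx["region_id"]],
                log2fc=float(f[idx["log2fc"]]),
                mean_log_cpm=float(f[idx["mean_log_cpm"]]),
                p_value=float(f[idx["p_value"]]), fdr=float(f[idx["fdr"]]),
                direction=f[idx["direction"]],
                is_significant_dar=sig if mode == "dar" else False,
                is_significant_deg=sig if mode == "deg" else False))
    return out
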
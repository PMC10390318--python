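"""Windowed nucleotide diversity, Weir-Cockerham Fst and IBS distance.

Window diversity follows the VCFtools windowed-pi convention: the per-site
unbiased estimator 2c(n-c)/(n(n-1)) summed over variant sites and divided
by the full window length in bp (monomorphic positions contribute zero
diversity), which puts values on the familiar ~1e-3 scale for crop
resequencing panels. Fst is the Weir & Cockerham (1984) estimator with
ratio-of-sums window averaging (the "weighted" Fst); negative windows are
reported as computed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .variantio import MISSING, GenomicInterval, VariantTable


@dataclass
class WindowStat:
    """One genomic window with a statistic value and supporting counts."""

    interval: GenomicInterval
    value: float
    n_sites: int
    components: Optional[Tuple[float, float]] = None  # (numerator, denominator)


@dataclass
class DistanceMatrix:
    sample_ids: List[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1] or NaN


def make_windows(
    chrom_lengths: Dict[str, int],
    size: int = 1_000_000,
    step: int = 500_000,
) -> List[GenomicInterval]:
    """Sliding windows [k*step, k*step+size) per chromosome.

    The final window is truncated at the chromosome end; windows are
    generated while their start lies inside the chromosome.
    """
    if not chrom_lengths:
        raise ValueError("empty chromosome length table")
    if not (size >= step > 0):
        raise ValueError("need size >= step > 0")
    out: List[GenomicInterval] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        start = 0
        while start < length:
            out.append(GenomicInterval(chrom, start, min(start + size, length)))
            start += step
    return out


def _window_site_slices(
    table: VariantTable, windows: Sequence[GenomicInterval]
) -> List[np.ndarray]:
    """Site indices per window (pos is 1-based; windows 0-based half-open)."""
    pos0_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == chrom)
        pos0_by_chrom[str(chrom)] = (table.pos[idx] - 1, idx)
    slices = []
    for w in windows:
        if w.chrom not in pos0_by_chrom:
            slices.append(np.array([], dtype=np.intp))
            continue
        pos0, idx = pos0_by_chrom[w.chrom]
        lo = np.searchsorted(pos0, w.start, side="left")
        hi = np.searchsorted(pos0, w.end, side="left")
        slices.append(idx[lo:hi])
    return slices


def _per_site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi: 2c(n-c)/(n(n-1)) on non-missing allele counts."""
    called = genotypes != MISSING
    n = 2.0 * called.sum(axis=1)
    c = np.where(called, genotypes, 0).sum(axis=1).astype(float)
    pi = np.zeros(len(genotypes))
    ok = n >= 2
    nn = n[ok]
    cc = c[ok]
    pi[ok] = 2.0 * cc * (nn - cc) / (nn * (nn - 1.0))
    return pi


def nucleotide_diversity(
    table: VariantTable,
    pop: Sequence[str],
    windows: Sequence[GenomicInterval],
) -> List[WindowStat]:
    """Windowed pi for one population (per-bp, full window length denominator)."""
    if len(pop) < 2:
        raise ValueError("nucleotide diversity needs at least 2 samples")
    sub = table.genotypes[:, table.sample_indices(pop)]
    pi_site = _per_site_pi(sub)
    out = []
    for w, idx in zip(windows, _window_site_slices(table, windows)):
        total = float(pi_site[idx].sum())
        out.append(
            WindowStat(
                interval=w,
                value=total / w.length,
                n_sites=int(len(idx)),
                components=(total, float(w.length)),
            )
        )
    return out


def _wc84_site_components(
    g_a: np.ndarray, g_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Returns (a, b, c, defined) where a is the among-population component and
    the estimator is a / (a + b + c). Heterozygote frequencies are observed,
    not HWE-expected.
    """
    def pop_stats(g):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)             # diploids
        p = np.where(called, g, 0).sum(axis=1) / np.maximum(2.0 * n, 1.0)
        h = (np.where(called, g, 0) == 1).sum(axis=1) / np.maximum(n, 1.0)
        return n, p, h

    n1, p1, h1 = pop_stats(g_a)
    n2, p2, h2 = pop_stats(g_b)
    defined = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    n1 = np.maximum(n1, 1e-12)
    n2 = np.maximum(n2, 1e-12)
    nbar = (n1 + n2) / 2.0
    nc = n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)       # (r-1) = 1
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    defined &= np.isfinite(a) & np.isfinite(b) & (nc > 0)
    return a, b, c, defined


def fst_weir_cockerham(
    table: VariantTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    windows: Sequence[GenomicInterval],
) -> List[WindowStat]:
    """Windowed Weir-Cockerham Fst (ratio of sums over per-site components).

    Windows with zero denominator carry NaN.
    """
    if set(pop_a) & set(pop_b):
        raise ValueError("populations overlap")
    g_a = table.genotypes[:, table.sample_indices(pop_a)]
    g_b = table.genotypes[:, table.sample_indices(pop_b)]
    a, b, c, defined = _wc84_site_components(g_a, g_b)
    num = np.where(defined, a, 0.0)
    den = np.where(defined, a + b + c, 0.0)
    out = []
    for w, idx in zip(windows, _window_site_slices(table, windows)):
        s_num = float(num[idx].sum())
        s_den = float(den[idx].sum())
        n_used = int(defined[idx].sum())
        value = s_num / s_den if s_den != 0 else float("nan")
        out.append(WindowStat(w, value, n_used, components=(s_num, s_den)))
    return out


def fst_site(table: VariantTable, pop_a, pop_b) -> np.ndarray:
    """Per-site WC84 Fst a/(a+b+c); NaN where undefined."""
    g_a = table.genotypes[:, table.sample_indices(pop_a)]
    g_b = table.genotypes[:, table.sample_indices(pop_b)]
    a, b, c, defined = _wc84_site_components(g_a, g_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = a / (a + b + c)
    return np.where(defined, f, np.nan)


def ibs_distance_matrix(table: VariantTable) -> DistanceMatrix:
    """Pairwise identity-by-state distance: mean |g_i - g_j| / 2 over
    co-called sites; NaN for pairs with zero co-called sites."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = table.genotypes.astype(np.int16)
    called = g != MISSING
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                val = np.abs(g[both, i] - g[both, j]).sum() / (2.0 * m)
                d[i, j] = d[j, i] = val
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=d)


def subsampled_diversity(
    table: VariantTable,
    pop: Sequence[str],
    windows: Optional[Sequence[GenomicInterval]] = None,
    n_sub: int = 19,
    reps: int = 100,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Mean genome-wide window pi over repeated subsamples of a population.

    Each rep draws ``n_sub`` samples without replacement and computes the
    mean window pi; returns (mean over reps, per-rep values). With windows
    omitted, 1 Mb / 500 kb windows over the table's chromosome lengths are
    used (falling back to max observed position).
    """
    pop = list(pop)
    if len(pop) < n_sub:
        raise ValueError(f"population has {len(pop)} samples < n_sub={n_sub}")
    if windows is None:
        lengths = table.chrom_lengths or {
            str(c): int(table.pos[table.chrom == c].max())
            for c in np.unique(table.chrom)
        }
        windows = make_windows(lengths)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        chosen = [pop[i] for i in rng.choice(len(pop), size=n_sub, replace=False)]
        stats = nucleotide_diversity(table, chosen, windows)
        values[r] = float(np.mean([s.value for s in stats]))
    return float(values.mean()), values
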
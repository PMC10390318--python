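"""LD decay, PLINK-style runs of homozygosity, and candidate-gene haplotypes.

LD is genotype r-squared (squared Pearson correlation of diploid dosage
vectors), the PopLDdecay convention; it needs no phasing and is sign-free
under allele relabeling. The ROH scanner transcribes the PLINK sliding
50-SNP window heuristic with the oat-panel parameters (window het 0,
window missing 2, min 50 SNPs / 500 kb / <= 50 kb per SNP); unprinted
knobs keep the PLINK defaults (hit threshold 0.05, max gap 1,000 kb).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variantio import MISSING, GeneModel, GenomicInterval, VariantTable


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDBin:
    distance_low: int    # exclusive
    distance_high: int   # inclusive
    mean_r2: float
    n_pairs: int


def ld_decay(
    table: VariantTable,
    pop: Sequence[str],
    max_dist: int = 1_000_000,
    bin_size: int = 500,
    min_pair_samples: int = 4,
) -> List[LDBin]:
    """Mean genotype r^2 of same-chromosome SNP pairs, binned by distance.

    Pairs with fewer than ``min_pair_samples`` co-called samples or zero
    dosage variance at either site are skipped. Bins tile (0, max_dist]
    with width ``bin_size``; empty bins are omitted.
    """
    idx = table.sample_indices(pop)
    g = table.genotypes[:, idx].astype(np.float64)
    called = g != MISSING
    g0 = np.where(called, g, 0.0)
    n_bins = (max_dist + bin_size - 1) // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in np.unique(table.chrom):
        rows = np.flatnonzero(table.chrom == chrom)
        pos = table.pos[rows]
        G = g0[rows]
        M = called[rows]
        for i in range(len(rows) - 1):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            if j_hi <= i + 1:
                continue
            J = slice(i + 1, j_hi)
            V = M[J] & M[i]                              # (nJ, n_samples)
            n = V.sum(axis=1).astype(float)
            xi = G[i]
            sx = (xi * V).sum(axis=1)
            sy = (G[J] * V).sum(axis=1)
            sxx = (xi * xi * V).sum(axis=1)
            syy = (G[J] * G[J] * V).sum(axis=1)
            sxy = (G[J] * xi * V).sum(axis=1)
            varx = n * sxx - sx * sx
            vary = n * syy - sy * sy
            cov = n * sxy - sx * sy
            ok = (n >= min_pair_samples) & (varx > 0) & (vary > 0)
            if not ok.any():
                continue
            r2 = np.zeros(len(n))
            r2[ok] = (cov[ok] ** 2) / (varx[ok] * vary[ok])
            dist = pos[J] - pos[i]
            bins = (dist - 1) // bin_size
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)
    out = [
        LDBin(b * bin_size, (b + 1) * bin_size, sums[b] / counts[b], int(counts[b]))
        for b in range(n_bins)
        if counts[b] > 0
    ]
    if not out:
        warnings.warn("no usable SNP pairs: empty LD profile")
    return out


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass
class ROHSegment:
    sample_id: str
    interval: GenomicInterval
    n_snps: int
    kb_length: float
    snp_density: float  # kb per SNP

    def satisfies(self, min_snp=50, min_kb=500.0, density_kb=50.0) -> bool:
        return (
            self.n_snps >= min_snp
            and self.kb_length >= min_kb
            and self.snp_density <= density_kb
        )


def roh_scan(
    table: VariantTable,
    window_snp: int = 50,
    window_missing: int = 2,
    window_het: int = 0,
    min_snp: int = 50,
    min_kb: float = 500.0,
    density_kb: float = 50.0,
    hit_threshold: float = 0.05,
    max_gap_kb: float = 1000.0,
) -> Dict[str, List[ROHSegment]]:
    """Sliding-window ROH detection per sample.

    A window of ``window_snp`` consecutive SNPs is permissible if it holds
    at most ``window_het`` heterozygous and ``window_missing`` missing
    calls. Each SNP's hit rate is the fraction of permissible windows
    among those covering it; SNPs with hit rate >= ``hit_threshold`` and a
    non-heterozygous call are run-eligible. Maximal eligible runs are
    split at inter-SNP gaps > ``max_gap_kb`` and kept iff they have
    >= ``min_snp`` SNPs, span >= ``min_kb`` and average <= ``density_kb``
    kb per SNP.
    """
    out: Dict[str, List[ROHSegment]] = {s: [] for s in table.sample_ids}
    for chrom in np.unique(table.chrom):
        rows = np.flatnonzero(table.chrom == chrom)
        if len(rows) < window_snp:
            warnings.warn(
                f"chromosome {chrom} has {len(rows)} SNPs < window size: skipped"
            )
            continue
        pos = table.pos[rows]
        G = table.genotypes[rows]
        S = len(rows)
        n_win = S - window_snp + 1
        for si, sample in enumerate(table.sample_ids):
            g = G[:, si]
            het = (g == 1).astype(np.int32)
            miss = (g == MISSING).astype(np.int32)
            chet = np.concatenate([[0], np.cumsum(het)])
            cmiss = np.concatenate([[0], np.cumsum(miss)])
            w_het = chet[window_snp:] - chet[:-window_snp]
            w_miss = cmiss[window_snp:] - cmiss[:-window_snp]
            permissible = (w_het <= window_het) & (w_miss <= window_missing)
            cperm = np.concatenate([[0], np.cumsum(permissible.astype(np.int64))])
            i = np.arange(S)
            w_lo = np.maximum(0, i - window_snp + 1)
            w_hi = np.minimum(i, n_win - 1)
            covering = (w_hi - w_lo + 1).astype(float)
            hits = cperm[w_hi + 1] - cperm[w_lo]
            rate = hits / covering
            eligible = (rate >= hit_threshold) & (g != 1)
            out[sample].extend(
                _runs_to_segments(
                    sample, str(chrom), pos, eligible,
                    min_snp, min_kb, density_kb, max_gap_kb,
                )
            )
    return out


def _runs_to_segments(
    sample, chrom, pos, eligible, min_snp, min_kb, density_kb, max_gap_kb
) -> List[ROHSegment]:
    segs: List[ROHSegment] = []
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return segs
    # break runs at ineligible SNPs or large physical gaps
    gap_bp = max_gap_kb * 1000.0
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > gap_bp)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for a, b in zip(starts, ends):
        first, last = idx[a], idx[b]
        n_snps = int(b - a + 1)
        kb = (pos[last] - pos[first] + 1) / 1000.0
        seg = ROHSegment(
            sample_id=sample,
            interval=GenomicInterval(chrom, int(pos[first]) - 1, int(pos[last])),
            n_snps=n_snps,
            kb_length=float(kb),
            snp_density=float(kb / n_snps),
        )
        if seg.satisfies(min_snp, min_kb, density_kb):
            segs.append(seg)
    return segs


def roh_table(segments: Dict[str, List[ROHSegment]]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.interval.chrom,
            "pos1": s.interval.start + 1,
            "pos2": s.interval.end,
            "kb": s.kb_length,
            "nsnp": s.n_snps,
            "density": s.snp_density,
        }
        for segs in segments.values()
        for s in segs
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos1", "pos2", "kb", "nsnp", "density"]
    )


# ---------------------------------------------------------------------------
# Candidate-gene haplotype grouping and phenotype contrast
# ---------------------------------------------------------------------------

@dataclass
class Haplogroup:
    group_id: str
    members: List[str]
    genotype_vector: Tuple[int, ...]


def gene_region(gene: GeneModel, flank: int = 2_000) -> GenomicInterval:
    """Gene span plus a strand-aware upstream flank (promoter side)."""
    span = gene.span
    if gene.strand == "-":
        return GenomicInterval(span.chrom, span.start, span.end + flank)
    return GenomicInterval(span.chrom, max(0, span.start - flank), span.end)


def group_haplotypes(
    table: VariantTable,
    region: GenomicInterval,
    samples: Optional[Sequence[str]] = None,
    min_group: int = 3,
) -> List[Haplogroup]:
    """Partition samples by exact genotype-vector identity over region SNPs.

    Samples with any missing genotype in the region are excluded. Groups
    with >= min_group members are returned largest first (Hap.1 largest);
    size ties break on the genotype vector for determinism.
    """
    if samples is None:
        samples = list(table.sample_ids)
    idx = table.sample_indices(samples)
    in_region = (
        (table.chrom == region.chrom)
        & (table.pos - 1 >= region.start)
        & (table.pos - 1 < region.end)
    )
    rows = np.flatnonzero(in_region)
    if len(rows) == 0:
        warnings.warn("no SNPs in region: no haplotype groups")
        return []
    G = table.genotypes[np.ix_(rows, idx)]
    complete = ~(G == MISSING).any(axis=0)
    n_excluded = int((~complete).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} samples with missing region calls")
    buckets: Dict[Tuple[int, ...], List[str]] = {}
    for k, s in enumerate(samples):
        if not complete[k]:
            continue
        buckets.setdefault(tuple(int(v) for v in G[:, k]), []).append(s)
    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    groups = [
        Haplogroup(f"Hap.{i + 1}", members, vec)
        for i, (vec, members) in enumerate(ordered)
        if len(members) >= min_group
    ]
    if not groups:
        warnings.warn(f"no haplotype group reaches min_group={min_group}")
    return groups


def compare_haplotype_phenotypes(
    groups: Sequence[Haplogroup],
    phenotypes: pd.DataFrame,
    trait: Optional[str] = None,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests between haplotype groups.

    Welch's unequal-variance test by default (``equal_var=True`` restores
    the pooled-variance Student form). Returns one row per group pair with
    means, t, two-sided p, and a significance flag at ``alpha``; pairs
    where a group has < 2 phenotyped members are skipped with a warning.
    """
    df = phenotypes
    if trait is not None:
        df = df[df["trait"] == trait]
    values = dict(zip(df["sample_id"], df["value"].astype(float)))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            xa = np.asarray([values[s] for s in ga.members if s in values])
            xb = np.asarray([values[s] for s in gb.members if s in values])
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"pair ({ga.group_id}, {gb.group_id}) skipped: "
                    "fewer than 2 phenotyped members"
                )
                continue
            if np.array_equal(np.sort(xa), np.sort(xb)):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
            rows.append(
                {
                    "group_a": ga.group_id,
                    "group_b": gb.group_id,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "n_a", "n_b",
            "mean_a", "mean_b", "t", "p", "significant",
        ],
    )


def significance_letters(
    groups: Sequence[Haplogroup], pairwise: pd.DataFrame
) -> Dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different in the pairwise table (greedy insertion, deterministic)."""
    ids = [g.group_id for g in groups]
    differs = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.significant
    }
    letter_sets: List[set] = []
    for gid in ids:
        placed = False
        for s in letter_sets:
            if all(frozenset((gid, other)) not in differs for other in s):
                s.add(gid)
                placed = True
        if not placed:
            letter_sets.append({gid})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: Dict[str, str] = {gid: "" for gid in ids}
    for letter, s in zip(alphabet, letter_sets):
        for gid in ids:
            if gid in s:
                out[gid] += letter
    return out
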
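"""Synthetic resequencing cohorts with known ancestry, IBD and phenotypes.

The generator uses a founder-mosaic model rather than a coalescent
simulation: each population descends from K founder haplotypes that are
mutated copies of a shared ancestor (a star phylogeny within populations,
population splits between them), and every sampled haplotype is a
recombinant mosaic of its population's founders. This keeps the ground
truth exact — ancestry tracts, true IBD and the causal variant are known
by construction — while reproducing the second-order structure the scans
consume: pairwise divergence proportional to split times, LD blocks at the
founder-tract scale, and IBD sharing through common founders.

Populations follow a hulled/naked oat cohort layout: OH (hulled), ONL
(naked landraces), ONC (naked cultivars), OG (outgroup relatives). The
cultivar group carries an admixture pulse from OH: a single set of donor
intervals (expected fraction ``admix_fraction`` of the genome, tract
lengths set by ``recomb_rate`` and ``admix_age``) shared by a small pool of
admixed cultivar founders, emulating introgressed segments that entered
the cultivar gene pool through a few historical crosses and are therefore
common to the cultivars.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variantio import (
    MISSING,
    GenomicInterval,
    IBDSegment,
    PopulationSpec,
    VariantTable,
    write_ibd_segments,
    write_sample_sheet,
    write_vcf,
)

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# Configuration and truth types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a resequenced oat panel: 22 hulled (OH), 81 naked
    landrace (ONL), 8 naked cultivar (ONC) and 4 outgroup (OG) diploids on
    a 20-Mb chromosome, mutation rate 6.5e-9 per site per generation with
    a 1-year generation time, an OH/ONL split ~51,200 generations ago, an
    outgroup split at the 780,000-generation calibration depth, and a 10%
    admixture pulse from OH into the cultivar founders.
    """

    chrom_name: str = "chr1"
    seq_length: int = 20_000_000
    n_oh: int = 22
    n_onl: int = 81
    n_onc: int = 8
    n_og: int = 4
    founders_per_pop: int = 10
    n_admixed_founders: int = 4
    mu: float = 6.5e-9
    recomb_rate: float = 1e-8           # per bp per generation
    t_split: int = 51_200               # generations since OH/ONL split
    t_og: int = 780_000                 # generations since outgroup split
    t_within: int = 45_000              # founder divergence within a population
    admix_fraction: float = 0.1
    admix_age: int = 45                 # generations of recombination since founders
    transition_bias: float = 2.0        # expected Ts/Tv site-count ratio
    error_rate: float = 5e-4            # per haploid allele miscall probability
    selfing: float = 0.7                # P(sample's two haplotypes are copies)
    gq_correct_mean: float = 60.0
    gq_correct_sd: float = 12.0
    gq_error_mean: float = 4.0
    low_qual_rate: float = 0.03         # fraction of sites with failing QUAL
    high_fs_rate: float = 0.02
    low_mq_rate: float = 0.02
    min_ibd_length: int = 100_000       # bp, for the derived true-IBD table
    causal_effect: float = 2.0          # trait units per causal allele copy
    pheno_noise_sd: float = 1.0
    baseline: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.admix_fraction <= 1.0:
            raise ValueError("admix_fraction must lie in [0, 1]")
        if not (self.t_og > self.t_split > self.admix_age >= 1):
            raise ValueError("need t_og > t_split > admix_age >= 1")
        if not 0 < self.t_within <= self.t_split:
            raise ValueError("need 0 < t_within <= t_split")
        for name in ("n_oh", "n_onl", "n_onc", "n_og", "founders_per_pop",
                     "n_admixed_founders", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mu", "recomb_rate", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.selfing <= 1.0:
            raise ValueError("selfing must lie in [0, 1]")
        if self.transition_bias <= 0:
            raise ValueError("transition_bias must be positive")


@dataclass(frozen=True)
class AncestryTract:
    """One contiguous stretch of a sample haplotype copied from one founder."""

    sample_id: str
    hap: int
    interval: GenomicInterval
    donor_pop: str
    founder_id: int


@dataclass
class TruthSet:
    """Simulator ground truth: the acceptance surface for every scan."""

    tracts: List[AncestryTract]
    true_ibd: List[IBDSegment]
    causal_region: Optional[GenomicInterval]
    causal_effect: float
    causal_pos: Optional[int]           # 1-based, matches VariantTable.pos
    populations: PopulationSpec
    chrom_lengths: Dict[str, int]
    donor_intervals: List[GenomicInterval] = field(default_factory=list)

    def oh_tracts(self, target_pop: str = "ONC") -> List[AncestryTract]:
        """Planted donor-ancestry tracts inside the target population."""
        return [
            t
            for t in self.tracts
            if t.donor_pop == "OH" and self.populations[t.sample_id] == target_pop
        ]


# ---------------------------------------------------------------------------
# Mosaic machinery
# ---------------------------------------------------------------------------

def _unique_positions(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    """n distinct integers in [lo, hi), sorted. Requires n <= hi - lo."""
    if n > hi - lo:
        raise ValueError("more positions requested than available")
    pos = np.unique(rng.integers(lo, hi, size=n))
    while len(pos) < n:
        extra = rng.integers(lo, hi, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n] if len(pos) > n else pos


def _breakpoints(rng: np.random.Generator, length: int, mean_breaks: float) -> np.ndarray:
    """[0, b1, ..., bk, length] with k ~ Poisson(mean_breaks), uniform bi."""
    k = rng.poisson(mean_breaks)
    k = min(k, length - 1)
    if k <= 0:
        return np.array([0, length], dtype=np.int64)
    inner = _unique_positions(rng, k, 1, length)
    return np.concatenate([[0], inner, [length]]).astype(np.int64)


def _merge_tracts(breaks: np.ndarray, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    if len(values) <= 1:
        return breaks, values
    keep = np.concatenate([[True], values[1:] != values[:-1]])
    new_breaks = np.concatenate([breaks[:-1][keep], breaks[-1:]])
    return new_breaks, values[keep]


def _slice_mosaic(
    breaks: np.ndarray, values: np.ndarray, start: int, end: int
) -> List[Tuple[int, int, int]]:
    """Tracts of (breaks, values) clipped to [start, end)."""
    out = []
    i = int(np.searchsorted(breaks, start, side="right") - 1)
    while i < len(values) and breaks[i] < end:
        s = max(int(breaks[i]), start)
        e = min(int(breaks[i + 1]), end)
        if s < e:
            out.append((s, e, int(values[i])))
        i += 1
    return out


def _compose(
    outer_breaks: np.ndarray,
    outer_values: np.ndarray,
    pool: Sequence[Tuple[np.ndarray, np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Resolve a mosaic over pool indices into a mosaic over founder ids."""
    tracts: List[Tuple[int, int, int]] = []
    for i, idx in enumerate(outer_values):
        pb, pv = pool[idx]
        tracts.extend(_slice_mosaic(pb, pv, int(outer_breaks[i]), int(outer_breaks[i + 1])))
    breaks = np.array([t[0] for t in tracts] + [tracts[-1][1]], dtype=np.int64)
    values = np.array([t[2] for t in tracts], dtype=np.int64)
    return _merge_tracts(breaks, values)


def _overlay(
    base: Tuple[np.ndarray, np.ndarray],
    donor: Tuple[np.ndarray, np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Donor mosaic wins wherever its value is >= 0, else base shows through."""
    bb, bv = base
    db, dv = donor
    cuts = np.unique(np.concatenate([bb, db]))
    vals = []
    for s in cuts[:-1]:
        di = int(np.searchsorted(db, s, side="right") - 1)
        if 0 <= di < len(dv) and dv[di] >= 0:
            vals.append(int(dv[di]))
        else:
            bi = int(np.searchsorted(bb, s, side="right") - 1)
            vals.append(int(bv[bi]))
    return _merge_tracts(cuts, np.asarray(vals, dtype=np.int64))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Tuple[VariantTable, TruthSet]:
    """Generate one cohort: a VariantTable plus its TruthSet.

    Deterministic for a fixed ``config.seed``; only polymorphic biallelic
    sites are emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    K = config.founders_per_pop

    # Founder ids: OH 0..K-1, ONL K..2K-1, OG 2K..3K-1.
    founder_pop = np.array(["OH"] * K + ["ONL"] * K + ["OG"] * K, dtype=object)
    oh_f = np.arange(0, K)
    onl_f = np.arange(K, 2 * K)
    og_f = np.arange(2 * K, 3 * K)
    n_founders = 3 * K

    # --- mutations on the founder phylogeny (infinite sites) ---------------
    branches: List[Tuple[float, np.ndarray]] = [
        (config.t_og - config.t_within, og_f),
        (config.t_og - config.t_split, np.concatenate([oh_f, onl_f])),
        (config.t_split - config.t_within, oh_f),
        (config.t_split - config.t_within, onl_f),
    ]
    for f in range(n_founders):
        branches.append((config.t_within, np.array([f])))
    counts = [rng.poisson(config.mu * L * t) for t, _ in branches]
    total = int(sum(counts))
    positions = _unique_positions(rng, total, 1, L + 1)  # 1-based
    rng.shuffle(positions)

    F = np.zeros((total, n_founders), dtype=np.uint8)
    off = 0
    for (t, carriers), c in zip(branches, counts):
        F[off:off + c][:, carriers] = 1
        off += c

    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    F = F[order]

    # --- ref/alt with transition bias --------------------------------------
    # base order A C G T; transitions A<->G, C<->T
    ref_idx = rng.integers(0, 4, size=total)
    ts_map = np.array([2, 3, 0, 1])
    tv_table = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
    is_ts = rng.random(total) < config.transition_bias / (config.transition_bias + 1.0)
    tv_choice = rng.integers(0, 2, size=total)
    alt_idx = np.where(
        is_ts, ts_map[ref_idx], tv_table[ref_idx, tv_choice]
    )
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)

    # --- sample haplotype mosaics ------------------------------------------
    mean_breaks = config.recomb_rate * L * config.admix_age
    mean_tract = L / (mean_breaks + 1.0)

    # Shared admixture pulse: donor intervals from OH totalling fraction f of
    # the genome, exponential-ish lengths at the recombination tract scale,
    # one OH founder per interval.
    donor_intervals = _planted_donor_intervals(
        rng, L, config.admix_fraction, mean_tract, config.chrom_name
    )
    donor_founders = rng.choice(oh_f, size=len(donor_intervals))
    pulse_breaks, pulse_vals = _intervals_to_mosaic(
        donor_intervals, donor_founders, L
    )

    admixed_pool: List[Tuple[np.ndarray, np.ndarray]] = []
    for _ in range(config.n_admixed_founders):
        bb = _breakpoints(rng, L, mean_breaks)
        bv = rng.choice(onl_f, size=len(bb) - 1)
        admixed_pool.append(_overlay((bb, bv), (pulse_breaks, pulse_vals)))

    samples: List[str] = []
    populations: PopulationSpec = {}
    for pop, n in (("OH", config.n_oh), ("ONL", config.n_onl),
                   ("ONC", config.n_onc), ("OG", config.n_og)):
        for i in range(n):
            name = f"{pop}{i + 1:03d}"
            samples.append(name)
            populations[name] = pop

    pools = {"OH": oh_f, "ONL": onl_f, "OG": og_f}

    def draw_hap(pop: str) -> Tuple[np.ndarray, np.ndarray]:
        bb = _breakpoints(rng, L, mean_breaks)
        if pop == "ONC":
            idx = rng.integers(0, config.n_admixed_founders, size=len(bb) - 1)
            return _compose(bb, idx, admixed_pool)
        bv = rng.choice(pools[pop], size=len(bb) - 1)
        return _merge_tracts(bb, bv)

    hap_mosaics: List[Tuple[np.ndarray, np.ndarray]] = []
    for s in samples:
        pop = populations[s]
        h1 = draw_hap(pop)
        h2 = h1 if rng.random() < config.selfing else draw_hap(pop)
        hap_mosaics.extend([h1, h2])

    tracts: List[AncestryTract] = []
    for si, s in enumerate(samples):
        for h in (1, 2):
            bb, bv = hap_mosaics[2 * si + (h - 1)]
            for i, fid in enumerate(bv):
                tracts.append(
                    AncestryTract(
                        sample_id=s,
                        hap=h,
                        interval=GenomicInterval(
                            config.chrom_name, int(bb[i]), int(bb[i + 1])
                        ),
                        donor_pop=str(founder_pop[fid]),
                        founder_id=int(fid),
                    )
                )

    # --- haplotype alleles --------------------------------------------------
    pos0 = positions - 1
    n_haps = 2 * len(samples)
    H = np.zeros((total, n_haps), dtype=np.int8)
    for hi, (bb, bv) in enumerate(hap_mosaics):
        for i, fid in enumerate(bv):
            lo = np.searchsorted(pos0, bb[i], side="left")
            hi_ = np.searchsorted(pos0, bb[i + 1], side="left")
            if hi_ > lo:
                H[lo:hi_, hi] = F[lo:hi_, fid]

    # --- genotype-call noise -------------------------------------------------
    n_cells = total * n_haps
    n_err = rng.binomial(n_cells, config.error_rate) if config.error_rate > 0 else 0
    err_flat = np.unique(rng.integers(0, n_cells, size=n_err)) if n_err else np.array([], dtype=np.int64)
    err_mask = np.zeros(n_cells, dtype=bool)
    err_mask[err_flat] = True
    err_mask = err_mask.reshape(total, n_haps)
    H[err_mask] ^= 1

    genotypes = (H[:, 0::2] + H[:, 1::2]).astype(np.int8)
    phased = np.stack([H[:, 0::2], H[:, 1::2]], axis=2).astype(np.int8)

    call_err = err_mask[:, 0::2] | err_mask[:, 1::2]
    gq = (
        rng.standard_normal((total, len(samples)), dtype=np.float32)
        * config.gq_correct_sd
        + config.gq_correct_mean
    )
    n_bad = int(call_err.sum())
    if n_bad:
        gq[call_err] = rng.exponential(config.gq_error_mean, size=n_bad)
    gq = np.clip(np.rint(gq), 0, 99).astype(np.int16)

    # --- site-level annotations (integer-valued so VCF round-trips exactly) --
    qual = np.rint(rng.gamma(4.0, 75.0, size=total))
    bad_q = rng.random(total) < config.low_qual_rate
    qual[bad_q] = np.rint(rng.uniform(5, 29, size=int(bad_q.sum())))
    fs = np.rint(rng.exponential(7.0, size=total))
    bad_fs = rng.random(total) < config.high_fs_rate
    fs[bad_fs] = np.rint(rng.uniform(61, 150, size=int(bad_fs.sum())))
    mq = np.rint(rng.normal(55.0, 4.0, size=total))
    bad_mq = rng.random(total) < config.low_mq_rate
    mq[bad_mq] = np.rint(rng.uniform(20, 39, size=int(bad_mq.sum())))

    # --- drop monomorphic sites ----------------------------------------------
    ac = genotypes.sum(axis=1)
    poly = (ac > 0) & (ac < 2 * len(samples))
    table = VariantTable(
        chrom=np.full(int(poly.sum()), config.chrom_name, dtype=object),
        pos=positions[poly],
        ref=ref[poly].astype(object),
        alt=alt[poly],
        qual=qual[poly].astype(float),
        fs=fs[poly].astype(float),
        mq=mq[poly].astype(float),
        genotypes=genotypes[poly],
        gq=gq[poly],
        phased_haplotypes=phased[poly],
        sample_ids=samples,
        chrom_lengths={config.chrom_name: L},
    )

    causal_pos, causal_region = _pick_causal_site(table, L)
    truth = TruthSet(
        tracts=tracts,
        true_ibd=[],
        causal_region=causal_region,
        causal_effect=config.causal_effect,
        causal_pos=causal_pos,
        populations=populations,
        chrom_lengths={config.chrom_name: L},
        donor_intervals=donor_intervals,
    )
    truth.true_ibd = derive_true_ibd(truth, min_length=config.min_ibd_length)
    return table, truth


def _planted_donor_intervals(
    rng: np.random.Generator, L: int, f: float, mean_tract: float, chrom: str
) -> List[GenomicInterval]:
    """Non-overlapping donor intervals totalling round(f*L) bp.

    Tract count targets the recombination tract scale (mean_tract bp per
    tract); lengths are exponential draws rescaled to hit the total, and
    placements are uniform over the remaining slack. This plants the
    admixture pulse so the realized donor fraction equals f regardless of
    seed, as befits a ground-truth generator.
    """
    total = int(round(f * L))
    if total <= 0:
        return []
    if total >= L:
        return [GenomicInterval(chrom, 0, L)]
    n = max(1, int(round(total / max(mean_tract, 1.0))))
    lens = rng.exponential(max(mean_tract, 1.0), size=n)
    lens = np.maximum(1, np.round(lens * total / lens.sum()).astype(np.int64))
    lens[0] = max(1, lens[0] + (total - int(lens.sum())))
    slack = L - int(lens.sum())
    if slack < 0:  # rounding pushed past L: trim the largest tract
        lens[int(np.argmax(lens))] += slack
        slack = 0
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    starts = offsets + np.concatenate([[0], np.cumsum(lens[:-1])])
    return [
        GenomicInterval(chrom, int(s), int(s + ln))
        for s, ln in zip(starts, lens)
    ]


def _intervals_to_mosaic(
    intervals: Sequence[GenomicInterval],
    founders: np.ndarray,
    L: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise map: founder id inside each interval, -1 elsewhere."""
    breaks = [0]
    vals: List[int] = []
    cur = 0
    for iv, fid in zip(intervals, founders):
        if iv.start > cur:
            vals.append(-1)
            breaks.append(iv.start)
        vals.append(int(fid))
        breaks.append(iv.end)
        cur = iv.end
    if cur < L:
        vals.append(-1)
        breaks.append(L)
    return np.asarray(breaks, dtype=np.int64), np.asarray(vals, dtype=np.int64)


def _pick_causal_site(table: VariantTable, L: int) -> Tuple[Optional[int], Optional[GenomicInterval]]:
    """Pick the highest-MAF site, ties broken nearest the chromosome middle."""
    if table.n_sites == 0:
        return None, None
    g = table.genotypes
    called = g != MISSING
    n = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, g, 0).sum(axis=1) / n, np.nan)
    maf = np.nan_to_num(np.fmin(p, 1 - p), nan=-1.0)
    if maf.max() <= 0:
        return None, None
    cand = np.flatnonzero(maf >= maf.max() - 1e-9)
    best = cand[np.argmin(np.abs(table.pos[cand] - L // 2))]
    pos = int(table.pos[best])
    region = GenomicInterval(
        str(table.chrom[best]), max(0, pos - 1 - 10_000), min(L, pos - 1 + 10_000)
    )
    return pos, region


# ---------------------------------------------------------------------------
# True IBD from ancestry tracts
# ---------------------------------------------------------------------------

def derive_true_ibd(truth: TruthSet, min_length: int = 100_000) -> List[IBDSegment]:
    """Maximal same-founder intervals >= min_length between haplotype pairs.

    lod is set to the interval length in kb. The sweep is exact: two
    haplotypes are IBD wherever their ancestry tracts carry the same
    founder.
    """
    haps: Dict[Tuple[str, int], List[Tuple[int, int, int]]] = {}
    for t in truth.tracts:
        haps.setdefault((t.sample_id, t.hap), []).append(
            (t.interval.start, t.interval.end, t.founder_id)
        )
    keys = sorted(haps)
    chrom = next(iter(truth.chrom_lengths))
    for k in keys:
        haps[k].sort()
    segments: List[IBDSegment] = []
    for i in range(len(keys)):
        sa, ha = keys[i]
        ta = haps[keys[i]]
        for j in range(i + 1, len(keys)):
            sb, hb = keys[j]
            tb = haps[keys[j]]
            run_start = None
            run_end = None
            ai = bi = 0
            while ai < len(ta) and bi < len(tb):
                s = max(ta[ai][0], tb[bi][0])
                e = min(ta[ai][1], tb[bi][1])
                if s < e and ta[ai][2] == tb[bi][2]:
                    if run_end == s:
                        run_end = e
                    else:
                        if run_start is not None and run_end - run_start >= min_length:
                            segments.append(
                                IBDSegment(sa, ha, sb, hb,
                                           GenomicInterval(chrom, run_start, run_end),
                                           (run_end - run_start) / 1000.0)
                            )
                        run_start, run_end = s, e
                elif s < e:
                    if run_start is not None and run_end - run_start >= min_length:
                        segments.append(
                            IBDSegment(sa, ha, sb, hb,
                                       GenomicInterval(chrom, run_start, run_end),
                                       (run_end - run_start) / 1000.0)
                        )
                    run_start = run_end = None
                if ta[ai][1] <= tb[bi][1]:
                    ai += 1
                else:
                    bi += 1
            if run_start is not None and run_end - run_start >= min_length:
                segments.append(
                    IBDSegment(sa, ha, sb, hb,
                               GenomicInterval(chrom, run_start, run_end),
                               (run_end - run_start) / 1000.0)
                )
    return segments


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    table: VariantTable,
    truth: TruthSet,
    noise_sd: float = 1.0,
    seed: int = 0,
    trait: str = "grain_yield",
    baseline: float = 100.0,
) -> pd.DataFrame:
    """baseline + causal_effect x (causal allele copies) + N(0, noise_sd).

    The causal variant is the one the simulator designated inside
    ``truth.causal_region``; a cohort where it is monomorphic cannot carry
    a planted effect and must be re-simulated.
    """
    if truth.causal_pos is None or truth.causal_region is None:
        raise ValueError("causal region monomorphic in this cohort: re-simulate")
    row = np.flatnonzero(
        (table.pos == truth.causal_pos) & (table.chrom == truth.causal_region.chrom)
    )
    if len(row) == 0:
        raise ValueError("causal site absent from table: re-simulate")
    g = table.genotypes[row[0]].astype(float)
    copies = np.where(g == MISSING, 0.0, g)
    if copies.min() == copies.max():
        raise ValueError("causal region monomorphic in this cohort: re-simulate")
    rng = np.random.default_rng(seed)
    values = baseline + truth.causal_effect * copies + rng.normal(0, noise_sd, len(copies))
    return pd.DataFrame(
        {"sample_id": table.sample_ids, "trait": trait, "value": values}
    )


# ---------------------------------------------------------------------------
# Disk output (CLI surface)
# ---------------------------------------------------------------------------

def write_truth_tracts(tracts: Sequence[AncestryTract], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in tracts],
            "hap": [t.hap for t in tracts],
            "chrom": [t.interval.chrom for t in tracts],
            "start": [t.interval.start for t in tracts],
            "end": [t.interval.end for t in tracts],
            "donor_pop": [t.donor_pop for t in tracts],
            "founder_id": [t.founder_id for t in tracts],
        }
    ).to_csv(path, sep="\t", index=False)


def run_simulation(config: SimConfig, out_dir) -> Tuple[VariantTable, TruthSet]:
    """Simulate and write cohort.vcf, truth_tracts.tsv, true_ibd.tsv,
    phenotypes.tsv, samples.tsv and truth_summary.json under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_cohort(config)
    write_vcf(table, out / "cohort.vcf")
    write_truth_tracts(truth.tracts, out / "truth_tracts.tsv")
    write_ibd_segments(truth.true_ibd, out / "true_ibd.tsv")
    write_sample_sheet(truth.populations, out / "samples.tsv")
    try:
        pheno = simulate_phenotypes(
            table, truth, noise_sd=config.pheno_noise_sd,
            seed=config.seed + 1, baseline=config.baseline,
        )
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    except ValueError as exc:
        warnings.warn(str(exc))
    summary = {
        "causal_pos": truth.causal_pos,
        "causal_effect": truth.causal_effect,
        "causal_region": None
        if truth.causal_region is None
        else [truth.causal_region.chrom, truth.causal_region.start, truth.causal_region.end],
        "donor_intervals": [
            [iv.chrom, iv.start, iv.end] for iv in truth.donor_intervals
        ],
        "config": dataclasses.asdict(config),
    }
    (out / "truth_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return table, truth
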
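"""File formats and the SNP-set filter engine.

Coordinate conventions
----------------------
VCF positions stay 1-based at the I/O boundary (``VariantTable.pos``).
Every interval type used internally (:class:`GenomicInterval`, BED output,
IBD segments) is 0-based half-open, so window arithmetic and overlap tests
are unambiguous.

Genotypes are diploid dosage codes: 0 (hom ref), 1 (het), 2 (hom alt),
``MISSING`` (= -1). Phased haplotypes, when present, are per-sample pairs
of haploid alleles in {0, 1} that sum to the dosage code.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MISSING = -1

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class IBDSegment:
    """A pairwise identical-by-descent tract between two haplotypes."""

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    interval: GenomicInterval
    lod: float

    def __post_init__(self) -> None:
        if self.hap_a not in (1, 2) or self.hap_b not in (1, 2):
            raise ValueError("haplotype index must be 1 or 2")
        if self.sample_a == self.sample_b and self.hap_a == self.hap_b:
            raise ValueError("IBD segment between a haplotype and itself")


@dataclass
class GeneModel:
    """Strand-aware CDS structure of one transcript.

    ``cds_parts`` are ordered 5'->3' in transcript orientation (descending
    genomic coordinate on the minus strand); each part carries its GFF phase.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_parts: List[Tuple[GenomicInterval, int]]

    @property
    def span(self) -> GenomicInterval:
        starts = [iv.start for iv, _ in self.cds_parts]
        ends = [iv.end for iv, _ in self.cds_parts]
        return GenomicInterval(self.chrom, min(starts), max(ends))

    def cds_length(self) -> int:
        return sum(iv.length for iv, _ in self.cds_parts)

    def is_malformed(self) -> bool:
        if not self.cds_parts:
            return True
        if self.strand not in "+-":
            return True
        ivs = sorted(iv for iv, _ in self.cds_parts)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                return True
        phase = self.cds_parts[0][1]
        return (self.cds_length() - phase) % 3 != 0


@dataclass
class SiteStats:
    """Per-site summaries backing the filter engine (arrays over all sites)."""

    maf: np.ndarray
    missing_rate: np.ndarray
    pass_fraction: np.ndarray
    is_transition: np.ndarray


@dataclass
class VariantTable:
    """Biallelic SNP sites x samples: the substrate of every scan.

    Arrays are indexed [site] or [site, sample]; ``pos`` is 1-based (VCF
    convention); ``genotypes`` uses dosage codes with ``MISSING`` = -1.
    """

    chrom: np.ndarray              # str per site
    pos: np.ndarray                # int64, 1-based
    ref: np.ndarray                # single-base str per site
    alt: np.ndarray
    qual: np.ndarray               # float per site (NaN if absent)
    fs: np.ndarray                 # INFO/FS, NaN if unannotated
    mq: np.ndarray                 # INFO/MQ, NaN if unannotated
    genotypes: np.ndarray          # int8 [site, sample]
    sample_ids: List[str]
    gq: Optional[np.ndarray] = None                 # int16 [site, sample]
    phased_haplotypes: Optional[np.ndarray] = None  # int8 [site, sample, 2]
    chrom_lengths: Optional[Dict[str, int]] = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.asarray([lookup[s] for s in ids], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            fs=self.fs[mask],
            mq=self.mq[mask],
            genotypes=self.genotypes[mask],
            gq=None if self.gq is None else self.gq[mask],
            phased_haplotypes=(
                None
                if self.phased_haplotypes is None
                else self.phased_haplotypes[mask]
            ),
        )

    def subset_samples(self, ids: Sequence[str]) -> "VariantTable":
        idx = self.sample_indices(ids)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            phased_haplotypes=(
                None
                if self.phased_haplotypes is None
                else self.phased_haplotypes[:, idx]
            ),
            sample_ids=list(ids),
        )

    def validate(self) -> None:
        """Raise if any structural invariant is broken."""
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        g = self.genotypes
        if not np.all((g >= MISSING) & (g <= 2)):
            raise ValueError("genotype codes outside {missing,0,1,2}")
        if self.phased_haplotypes is not None:
            h = self.phased_haplotypes
            called = np.all(h >= 0, axis=2)
            if not np.array_equal(h[called].sum(axis=1), g[called]):
                raise ValueError("phased haplotypes inconsistent with genotypes")


# PopulationSpec: mapping sample_id -> population label.
PopulationSpec = Dict[str, str]


def population_members(spec: PopulationSpec, label: str) -> List[str]:
    """Sample ids carrying ``label`` in a sample sheet, in sheet order."""
    out = [s for s, p in spec.items() if p == label]
    if not out:
        raise KeyError(f"no samples with population label {label!r}")
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Optional[Sequence[str]] = None) -> VariantTable:
    """Read biallelic SNPs from a VCF into a :class:`VariantTable`.

    Multiallelic and non-SNP records are skipped (counted in a warning).
    Diploid GT parses to dosage codes; phased calls populate
    ``phased_haplotypes``.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(path, samples=list(sample_subset) if sample_subset else None)
    samples = list(vcf.samples)

    chroms, poss, refs, alts, quals, fss, mqs = [], [], [], [], [], [], []
    gts, gqs, haps = [], [], []
    n_skipped = 0
    any_gq = False
    any_phase = False
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        arr = v.genotype.array()  # (n_samples, ploidy+1): alleles..., phased
        a, b, ph = arr[:, 0], arr[:, 1], arr[:, -1].astype(bool)
        called = (a >= 0) & (b >= 0)
        g = np.where(called, a + b, MISSING).astype(np.int8)
        h = np.full((len(samples), 2), MISSING, dtype=np.int8)
        phased = called & ph
        h[phased, 0] = a[phased]
        h[phased, 1] = b[phased]
        any_phase = any_phase or bool(phased.any())
        gq = v.format("GQ")
        if gq is not None:
            any_gq = True
            gq = np.nan_to_num(
                np.asarray(gq, dtype=float).reshape(len(samples)), nan=-1
            ).astype(np.int16)
        gqs.append(gq)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        fs = v.INFO.get("FS")
        mq = v.INFO.get("MQ")
        fss.append(float(fs) if fs is not None else np.nan)
        mqs.append(float(mq) if mq is not None else np.nan)
        gts.append(g)
        haps.append(h)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/non-SNP records")
    chrom_lengths = None
    try:
        if vcf.seqnames:
            chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lengths
        chrom_lengths = None
    vcf.close()
    if not gts:
        warnings.warn("no biallelic SNPs in VCF: returning empty table")
        return _empty_table(samples, chrom_lengths)

    n = len(gts)
    gq_arr = None
    if any_gq:
        gq_arr = np.full((n, len(samples)), -1, dtype=np.int16)
        for i, gq in enumerate(gqs):
            if gq is not None:
                gq_arr[i] = gq
    return VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        fs=np.asarray(fss, dtype=float),
        mq=np.asarray(mqs, dtype=float),
        genotypes=np.asarray(gts, dtype=np.int8),
        gq=gq_arr,
        phased_haplotypes=np.asarray(haps, dtype=np.int8) if any_phase else None,
        sample_ids=samples,
        chrom_lengths=chrom_lengths,
    )


def _empty_table(samples: List[str], chrom_lengths=None) -> VariantTable:
    n = len(samples)
    return VariantTable(
        chrom=np.asarray([], dtype=object),
        pos=np.asarray([], dtype=np.int64),
        ref=np.asarray([], dtype=object),
        alt=np.asarray([], dtype=object),
        qual=np.asarray([], dtype=float),
        fs=np.asarray([], dtype=float),
        mq=np.asarray([], dtype=float),
        genotypes=np.zeros((0, n), dtype=np.int8),
        sample_ids=samples,
        chrom_lengths=chrom_lengths,
    )


def write_vcf(table: VariantTable, path) -> None:
    """Write a VariantTable as uncompressed VCF 4.2 (GT:GQ, INFO FS/MQ)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if table.chrom_lengths:
            for c, ln in table.chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        has_gq = table.gq is not None
        fmt = "GT:GQ" if has_gq else "GT"
        H = table.phased_haplotypes
        for i in range(table.n_sites):
            info = []
            if not math.isnan(table.fs[i]):
                info.append(f"FS={_fmt_float(table.fs[i])}")
            if not math.isnan(table.mq[i]):
                info.append(f"MQ={_fmt_float(table.mq[i])}")
            qual = "." if math.isnan(table.qual[i]) else _fmt_float(table.qual[i])
            cells = []
            for j in range(table.n_samples):
                g = table.genotypes[i, j]
                if H is not None and H[i, j, 0] >= 0:
                    gt = f"{H[i, j, 0]}|{H[i, j, 1]}"
                elif g == MISSING:
                    gt = "./."
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(g)]
                cells.append(f"{gt}:{table.gq[i, j]}" if has_gq else gt)
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t{qual}\tPASS\t{';'.join(info) or '.'}\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def _fmt_float(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


# ---------------------------------------------------------------------------
# Genotype masking and the site filter
# ---------------------------------------------------------------------------

def mask_low_gq(table: VariantTable, gq_min: int = 10) -> VariantTable:
    """Set every call with genotype quality below ``gq_min`` to missing.

    This mirrors the masking step applied before site filtering: low-GQ
    calls are unreliable and must not feed allele-frequency estimates.
    """
    if gq_min < 0:
        raise ValueError("gq_min must be non-negative")
    if table.gq is None:
        warnings.warn("table has no GQ field: mask_low_gq is a no-op")
        return table
    low = table.gq < gq_min
    g = table.genotypes.copy()
    g[low] = MISSING
    h = table.phased_haplotypes
    if h is not None:
        h = h.copy()
        h[low] = MISSING
    return replace(table, genotypes=g, phased_haplotypes=h)


def compute_site_stats(table: VariantTable, gq_min: int = 10) -> SiteStats:
    """Per-site MAF, missing rate, GQ pass fraction and transition flag."""
    g = table.genotypes
    n_samp = max(table.n_samples, 1)
    called = g != MISSING
    n_called = called.sum(axis=1)
    alt_count = np.where(called, g, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.fmin(p, 1.0 - p)
    missing_rate = 1.0 - n_called / n_samp
    if table.gq is not None:
        ok = called & (table.gq >= gq_min)
    else:
        ok = called
    pass_fraction = ok.sum(axis=1) / n_samp
    is_transition = np.asarray(
        [(r, a) in _TRANSITION_PAIRS for r, a in zip(table.ref, table.alt)],
        dtype=bool,
    )
    return SiteStats(
        maf=maf,
        missing_rate=missing_rate,
        pass_fraction=pass_fraction,
        is_transition=is_transition,
    )


def filter_sites(
    table: VariantTable,
    qual_min: float = 30.0,
    fs_max: float = 60.0,
    mq_min: float = 40.0,
    pass_frac_min: float = 0.8,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
    gq_min: int = 10,
) -> Tuple[VariantTable, SiteStats]:
    """Apply the joint site filter; returns survivors plus stats for all sites.

    A site survives iff qual >= qual_min AND fs <= fs_max AND mq <= ... AND
    pass_fraction >= pass_frac_min AND maf >= maf_min AND
    missing_rate <= missing_max. Boundary values survive (removal clauses
    are strict inequalities). Sites with unannotated FS or MQ pass those
    clauses: annotation absence is not evidence of failure. Assumes low-GQ
    calls were already masked (``mask_low_gq``); MAF and missing rate are
    computed on the genotypes as given.
    """
    if not (0 <= pass_frac_min <= 1 and 0 <= missing_max <= 1):
        raise ValueError("fractional thresholds must lie in [0, 1]")
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if qual_min < 0 or fs_max < 0 or mq_min < 0:
        raise ValueError("quality thresholds must be non-negative")
    stats = compute_site_stats(table, gq_min=gq_min)
    if table.n_sites == 0:
        return table, stats
    qual_ok = ~(np.nan_to_num(table.qual, nan=np.inf) < qual_min)
    fs_ok = ~(np.nan_to_num(table.fs, nan=-np.inf) > fs_max)
    mq_ok = ~(np.nan_to_num(table.mq, nan=np.inf) < mq_min)
    pass_ok = stats.pass_fraction >= pass_frac_min
    maf_ok = np.nan_to_num(stats.maf, nan=-1.0) >= maf_min
    miss_ok = stats.missing_rate <= missing_max
    keep = qual_ok & fs_ok & mq_ok & pass_ok & maf_ok & miss_ok
    return table.subset_sites(keep), stats


def ts_tv_ratio(table: VariantTable) -> float:
    """Transitions / transversions over the table's sites (inf if no Tv)."""
    if table.n_sites == 0:
        raise ValueError("ts/tv undefined on an empty table")
    is_ts = compute_site_stats(table).is_transition
    n_ts = int(is_ts.sum())
    n_tv = int((~is_ts).sum())
    return math.inf if n_tv == 0 else n_ts / n_tv


# ---------------------------------------------------------------------------
# IBD segment tables (RefinedIBD-style 8-column TSV)
# ---------------------------------------------------------------------------

IBD_COLUMNS = ("sample_a", "hap_a", "sample_b", "hap_b", "chrom", "start", "end", "lod")


def read_ibd_segments(path) -> List[IBDSegment]:
    """Parse an 8-column IBD TSV (1-based inclusive coords in the file).

    Coordinates convert to the internal 0-based half-open convention.
    Malformed lines (wrong column count, non-numeric fields, end < start)
    are skipped with a warning; a file with zero parseable lines is a
    format error.
    """
    segments: List[IBDSegment] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 8:
                n_bad += 1
                continue
            try:
                sa, ha, sb, hb, chrom, start, end, lod = parts
                ha, hb = int(ha), int(hb)
                start, end = int(start), int(end)
                lod = float(lod)
                if end < start:
                    raise ValueError("end < start")
                seg = IBDSegment(
                    sa, ha, sb, hb, GenomicInterval(chrom, start - 1, end), lod
                )
            except (ValueError, KeyError):
                n_bad += 1
                continue
            segments.append(seg)
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed IBD lines")
    if not segments:
        raise ValueError(f"no parseable IBD segments in {path}")
    return segments


def write_ibd_segments(segments: Iterable[IBDSegment], path) -> None:
    """Write segments in the same 8-column dialect read_ibd_segments expects."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.sample_a}\t{s.hap_a}\t{s.sample_b}\t{s.hap_b}\t"
                f"{s.interval.chrom}\t{s.interval.start + 1}\t{s.interval.end}\t"
                f"{_fmt_float(s.lod)}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 + FASTA gene models
# ---------------------------------------------------------------------------

def read_gene_models(gff_path, fasta_path) -> Tuple[List[GeneModel], object]:
    """Load per-mRNA CDS structures and the genome they index into.

    Returns ``(models, genome)`` where genome is a pyfaidx.Fasta. Transcripts
    whose CDS length (after phase adjustment) is not a multiple of 3, or whose
    parts overlap, are excluded with a warning.
    """
    import gffutils
    import pyfaidx

    genome = pyfaidx.Fasta(str(fasta_path))
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: List[GeneModel] = []
    n_malformed = 0
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        if mrna.seqid not in genome:
            raise ValueError(f"GFF contig {mrna.seqid!r} absent from FASTA")
        parts = [
            (
                GenomicInterval(c.seqid, c.start - 1, c.end),
                int(c.frame) if c.frame in ("0", "1", "2") else 0,
            )
            for c in cds
        ]
        if mrna.strand == "-":
            parts = parts[::-1]
        model = GeneModel(
            gene_id=mrna.id, chrom=mrna.seqid, strand=mrna.strand, cds_parts=parts
        )
        if model.is_malformed():
            n_malformed += 1
            continue
        models.append(model)
    if n_malformed:
        warnings.warn(f"excluded {n_malformed} malformed gene models")
    return models, genome


# ---------------------------------------------------------------------------
# BED and small TSV tables
# ---------------------------------------------------------------------------

def write_bed(records: Iterable, path) -> None:
    """Write intervals (optionally with value columns) as BED.

    Accepts GenomicInterval objects, ``(GenomicInterval, value, ...)`` tuples,
    or objects with ``interval`` and ``value`` attributes (WindowStat-like).
    Rows are sorted by (chrom, start) for deterministic output.
    """
    rows = []
    for r in records:
        if isinstance(r, GenomicInterval):
            iv, extra = r, ()
        elif isinstance(r, tuple):
            iv, extra = r[0], tuple(r[1:])
        else:
            iv = r.interval
            extra = (r.value,) if hasattr(r, "value") else ()
        rows.append((iv.chrom, iv.start, iv.end, extra))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for chrom, start, end, extra in rows:
            cols = [chrom, str(start), str(end)] + [_format_value(v) for v in extra]
            fh.write("\t".join(cols) + "\n")


def _format_value(v) -> str:
    if isinstance(v, float):
        return "nan" if math.isnan(v) else f"{v:.10g}"
    return str(v)


def read_bed(path) -> List[Tuple[GenomicInterval, Tuple[str, ...]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(
                (GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                 tuple(parts[3:]))
            )
    return out


def read_sample_sheet(path) -> PopulationSpec:
    """Two-column TSV (sample_id, population) -> ordered mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        df = pd.read_csv(
            path, sep="\t", dtype=str, header=None, names=["sample_id", "population"]
        )
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    if (df["population"].fillna("") == "").any():
        raise ValueError("empty population label in sample sheet")
    return dict(zip(df["sample_id"], df["population"]))


def write_sample_sheet(spec: PopulationSpec, path) -> None:
    pd.DataFrame(
        {"sample_id": list(spec), "population": [spec[s] for s in spec]}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV with columns sample_id, trait, value."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "trait", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(need)}")
    return df
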
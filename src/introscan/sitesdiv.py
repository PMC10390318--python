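"""Fourfold-degenerate sites and a calibration-ratio divergence clock.

A fourfold-degenerate site is a codon third position where all four bases
encode the same amino acid; such sites evolve approximately neutrally and
are the standard substrate for molecular-clock dating. The divergence
estimator here is a strict-clock calibration ratio: with d_target the
per-site distance between the two focal samples and d_calib the distance
of the focal pair to a calibration outgroup of known split time t_calib,

    t_estimate = t_calib * d_target / d_calib.

This is a deliberately simple stand-in for Bayesian relaxed-clock dating:
it is exact under a strict clock and scale-invariant in the distances.
Distances are per fourfold site (invariant sites count as zero-difference
sites in the denominator), matching how per-site divergence is defined
for clock calibration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .variantio import MISSING, GeneModel, GenomicInterval, VariantTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _fourfold_prefixes() -> Set[str]:
    """Dinucleotide prefixes whose four codons are synonymous (standard code)."""
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {fwd.get(b1 + b2 + b3) for b3 in "ACGT"}
            if None not in aas and len(aas) == 1:
                prefixes.add(b1 + b2)
    return prefixes


FOURFOLD_PREFIXES = _fourfold_prefixes()


@dataclass(frozen=True)
class FourfoldSite:
    chrom: str
    pos: int          # 0-based genomic coordinate of the codon third position
    gene_id: str
    codon: str        # transcript orientation
    strand: str


@dataclass
class DivergenceEstimate:
    d_target: float
    d_calib: float
    t_calib: float
    t_estimate: float
    n_sites: int


# ---------------------------------------------------------------------------
# Fourfold-degenerate site extraction
# ---------------------------------------------------------------------------

def _contig_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) uppercase from a pyfaidx.Fasta or a plain dict."""
    if isinstance(genome, dict):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def fourfold_sites(
    gene_models: Sequence[GeneModel], genome
) -> List[FourfoldSite]:
    """Genomic coordinates of all fourfold-degenerate third positions.

    For every translatable transcript, codons whose first two bases fix the
    amino acid contribute their third position, mapped back to genomic
    coordinates strand-aware. Positions claimed as fourfold by one
    transcript but covered in a non-fourfold role by another are excluded;
    duplicates across transcripts collapse to one site. Codons containing
    ambiguity codes are skipped.
    """
    proposals: Dict[Tuple[str, int], List[FourfoldSite]] = {}
    covered_other: Set[Tuple[str, int]] = set()
    for gm in gene_models:
        if gm.is_malformed():
            warnings.warn(f"gene model {gm.gene_id} malformed: skipped")
            continue
        if isinstance(genome, dict):
            if gm.chrom not in genome:
                raise ValueError(f"contig {gm.chrom!r} absent from genome")
        elif gm.chrom not in genome:
            raise ValueError(f"contig {gm.chrom!r} absent from genome")
        seq_parts: List[str] = []
        coord_parts: List[np.ndarray] = []
        for iv, _phase in gm.cds_parts:
            raw = _contig_seq(genome, gm.chrom, iv.start, iv.end)
            coords = np.arange(iv.start, iv.end)
            if gm.strand == "-":
                raw = "".join(_COMPLEMENT.get(b, "N") for b in reversed(raw))
                coords = coords[::-1]
            seq_parts.append(raw)
            coord_parts.append(coords)
        seq = "".join(seq_parts)
        coords = np.concatenate(coord_parts)
        offset = gm.cds_parts[0][1]
        usable = (len(seq) - offset) // 3
        for k in range(usable):
            i = offset + 3 * k
            codon = seq[i:i + 3]
            gpos = coords[i:i + 3]
            keys = [(gm.chrom, int(p)) for p in gpos]
            if "N" in codon:
                covered_other.update(keys)
                continue
            if codon[:2] in FOURFOLD_PREFIXES:
                covered_other.update(keys[:2])
                proposals.setdefault(keys[2], []).append(
                    FourfoldSite(gm.chrom, int(gpos[2]), gm.gene_id, codon, gm.strand)
                )
            else:
                covered_other.update(keys)
    out = [
        min(sites, key=lambda s: s.gene_id)
        for key, sites in proposals.items()
        if key not in covered_other
    ]
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


# ---------------------------------------------------------------------------
# Strict genotype filter and pairwise divergence
# ---------------------------------------------------------------------------

def strict_site_filter(
    table: VariantTable,
    sites: Sequence[FourfoldSite],
    qual_min: float = 60.0,
    gq_min: int = 30,
) -> Tuple[List[FourfoldSite], Dict[Tuple[str, int], int]]:
    """High-confidence subset of ``sites`` for clock dating.

    A site present in the table is retained iff its QUAL >= qual_min and
    every sample's call is non-missing with GQ >= gq_min (removal clauses
    are strict "less than", so boundary values survive). Sites absent from
    the table are invariant and retained. Returns (retained sites, map of
    (chrom, 0-based pos) -> table row for the retained variant sites).
    """
    row_of = {
        (str(c), int(p) - 1): i
        for i, (c, p) in enumerate(zip(table.chrom, table.pos))
    }
    if table.gq is None:
        warnings.warn("table has no GQ field: GQ clause not applied")
    retained: List[FourfoldSite] = []
    rows: Dict[Tuple[str, int], int] = {}
    for s in sites:
        key = (s.chrom, s.pos)
        i = row_of.get(key)
        if i is None:
            retained.append(s)
            continue
        if np.nan_to_num(table.qual[i], nan=np.inf) < qual_min:
            continue
        if (table.genotypes[i] == MISSING).any():
            continue
        if table.gq is not None and (table.gq[i] < gq_min).any():
            continue
        retained.append(s)
        rows[key] = i
    return retained, rows


def _diploid_expected_diff(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Mean difference over the 2x2 haploid comparisons of two diploids."""
    return (gx * (2.0 - gy) + gy * (2.0 - gx)) / 4.0


def pairwise_divergence(
    table: VariantTable,
    sample_x: str,
    sample_y: str,
    sites: Sequence[FourfoldSite],
    rows: Optional[Dict[Tuple[str, int], int]] = None,
) -> float:
    """Mean per-site difference between two diploids over retained sites.

    Sites absent from the table contribute zero difference; the
    denominator is the full retained site count.
    """
    if len(sites) == 0:
        raise ValueError("no retained sites")
    if rows is None:
        rows = {
            (str(c), int(p) - 1): i
            for i, (c, p) in enumerate(zip(table.chrom, table.pos))
        }
    ix, iy = table.sample_indices([sample_x, sample_y])
    total = 0.0
    for s in sites:
        i = rows.get((s.chrom, s.pos))
        if i is None:
            continue
        gx = float(table.genotypes[i, ix])
        gy = float(table.genotypes[i, iy])
        if gx < 0 or gy < 0:
            continue
        total += float(_diploid_expected_diff(np.float64(gx), np.float64(gy)))
    return total / len(sites)


def calibrated_split_time(
    d_target: float,
    d_calib: float,
    t_calib: float = 780_000.0,
    n_sites: int = 0,
) -> DivergenceEstimate:
    """t_estimate = t_calib * d_target / d_calib (strict-clock ratio)."""
    if d_calib <= 0:
        raise ValueError("calibration distance must be positive")
    return DivergenceEstimate(
        d_target=float(d_target),
        d_calib=float(d_calib),
        t_calib=float(t_calib),
        t_estimate=float(t_calib) * float(d_target) / float(d_calib),
        n_sites=int(n_sites),
    )


def estimate_divergence_time(
    table: VariantTable,
    sample_x: str,
    sample_y: str,
    outgroup_sample: str,
    sites: Sequence[FourfoldSite],
    t_calib: float = 780_000.0,
    qual_min: float = 60.0,
    gq_min: int = 30,
) -> DivergenceEstimate:
    """Full clock pipeline: strict filter, distances, calibration ratio.

    ``d_calib`` is the mean of the two focal-vs-outgroup distances.
    """
    sub = table.subset_samples([sample_x, sample_y, outgroup_sample])
    retained, rows = strict_site_filter(sub, sites, qual_min=qual_min, gq_min=gq_min)
    if not retained:
        raise ValueError("strict filter removed every site")
    d_t = pairwise_divergence(sub, sample_x, sample_y, retained, rows)
    d_cx = pairwise_divergence(sub, sample_x, outgroup_sample, retained, rows)
    d_cy = pairwise_divergence(sub, sample_y, outgroup_sample, retained, rows)
    return calibrated_split_time(
        d_t, (d_cx + d_cy) / 2.0, t_calib=t_calib, n_sites=len(retained)
    )


def divergence_time_from_cohort(
    table: VariantTable,
    sample_x: str,
    sample_y: str,
    outgroup_sample: str,
    total_sites: int,
    t_calib: float = 780_000.0,
    qual_min: float = 60.0,
    gq_min: int = 30,
) -> DivergenceEstimate:
    """Clock estimate treating every non-variant position as an invariant
    retained site: the table's variant rows are strict-filtered, distances
    use ``total_sites`` minus the filtered-out rows as denominator.

    Suited to neutral whole-cohort variant tables (e.g. simulated ones)
    where no gene-model extraction step applies.
    """
    sub = table.subset_samples([sample_x, sample_y, outgroup_sample])
    qual_ok = ~(np.nan_to_num(sub.qual, nan=np.inf) < qual_min)
    call_ok = ~(sub.genotypes == MISSING).any(axis=1)
    if sub.gq is not None:
        call_ok &= ~(sub.gq < gq_min).any(axis=1)
    keep = qual_ok & call_ok
    n_denom = total_sites - int((~keep).sum())
    if n_denom <= 0:
        raise ValueError("strict filter removed every site")
    g = sub.genotypes[keep].astype(float)
    ix, iy, io = sub.sample_indices([sample_x, sample_y, outgroup_sample])
    d_t = float(_diploid_expected_diff(g[:, ix], g[:, iy]).sum()) / n_denom
    d_cx = float(_diploid_expected_diff(g[:, ix], g[:, io]).sum()) / n_denom
    d_cy = float(_diploid_expected_diff(g[:, iy], g[:, io]).sum()) / n_denom
    return calibrated_split_time(
        d_t, (d_cx + d_cy) / 2.0, t_calib=t_calib, n_sites=n_denom
    )
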
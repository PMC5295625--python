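"""Per-pool allele read counting and pooled frequency estimation.

In pooled resequencing the read counts at a variant site are the only
genotype signal: with N diploid samples per pool, a single heterozygous
carrier contributes an expected allele fraction of 1/(2N), so at depth d
its allele should appear in about d/(2N) reads.  Frequencies here are
estimated directly as count ratios; the "adjusted" frequency restricts
the denominator to reads supporting the two predicted alleles so that
sequencing-error reads on the other nucleotides do not deflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .callset import VariantSite

NUCLEOTIDES = ("A", "C", "G", "T")

#: Phred cutoff below which a base call is excluded from counting
DEFAULT_MIN_BASE_QUALITY = 20


@dataclass(frozen=True)
class PoolDesign:
    """Composition of one DNA pool."""

    pool_id: str
    n_samples: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.ploidy < 1:
            raise ValueError("n_samples and ploidy must be >= 1")

    @property
    def n_haploids(self) -> int:
        return self.n_samples * self.ploidy


@dataclass
class PoolAlleleCounts:
    """Read counts per allele at one site within one pool.

    For SNP sites ``counts`` carries all four nucleotides with zeros
    included; for indel sites it carries the ref and alt allele strings.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    pool_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")
        if len(self.ref) == 1 and len(self.alt) == 1:
            for nt in NUCLEOTIDES:
                self.counts.setdefault(nt, 0)

    @property
    def total_depth(self) -> int:
        return sum(self.counts.values())

    @property
    def site_key(self) -> tuple[str, int]:
        return self.chrom, self.pos


def theoretical_min_maf(design: PoolDesign) -> float:
    """Within-pool allele frequency of a single heterozygous carrier."""
    return 1.0 / design.n_haploids


def expected_minor_reads(depth: float, freq: float) -> float:
    """Expected reads supporting an allele at the given frequency and depth."""
    if depth < 0 or not 0.0 <= freq <= 1.0:
        raise ValueError("depth must be >= 0 and freq in [0, 1]")
    return depth * freq


def allele_frequency(counts: PoolAlleleCounts, allele: str) -> Optional[float]:
    """Raw allele frequency count/total_depth; None (missing) at zero depth."""
    total = counts.total_depth
    if total == 0:
        return None
    return counts.counts.get(allele, 0) / total


def adjusted_frequency(
    counts: PoolAlleleCounts,
    ref_allele: Optional[str] = None,
    alt_allele: Optional[str] = None,
) -> Optional[float]:
    """Alt frequency over reads of the two predicted alleles only.

    Error-allele reads are excluded from the denominator; missing (None)
    when neither predicted allele has read support."""
    ref_allele = counts.ref if ref_allele is None else ref_allele
    alt_allele = counts.alt if alt_allele is None else alt_allele
    ref_n = counts.counts.get(ref_allele, 0)
    alt_n = counts.counts.get(alt_allele, 0)
    if ref_n + alt_n == 0:
        return None
    return alt_n / (ref_n + alt_n)


def pool_frequency_range(
    frequencies: Iterable[Optional[float]],
    thresholds: Sequence[float] = (0.05, 0.1),
) -> Optional[tuple[float, dict[float, bool]]]:
    """Max minus min of per-pool frequencies, with flags at each threshold.

    Pools with missing (None) frequency are excluded; fewer than two
    informative pools yield None (missing), never an artificial zero."""
    vals = [f for f in frequencies if f is not None]
    if len(vals) < 2:
        return None
    rng = max(vals) - min(vals)
    return rng, {t: rng > t for t in thresholds}


# ---------------------------------------------------------------------------
# Read counting from alignments

def count_alleles(
    alignment_path: str | Path,
    sites: Sequence[VariantSite],
    pool_id: str,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    reference_length: Optional[Mapping[str, int]] = None,
) -> list[PoolAlleleCounts]:
    """Count reads per allele at each site from a SAM/BAM alignment.

    SNP sites count the base observed at the position per read, excluding
    base calls below ``min_base_quality``.  Indel sites count reads whose
    aligned query sequence across the reference span of the ref allele
    exactly matches the ref or the alt allele; reads not spanning the
    interval (plus one anchor base) or matching neither are ignored.
    Multiallelic sites are counted against their first alt allele.
    """
    import pysam

    out: list[PoolAlleleCounts] = []
    with pysam.AlignmentFile(str(alignment_path), "r", check_sq=False) as sam:
        has_index = False
        try:
            has_index = sam.has_index()
        except (AttributeError, ValueError):
            has_index = False
        reads_by_chrom: dict[str, list] = {}
        if not has_index:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                reads_by_chrom.setdefault(read.reference_name, []).append(read)
        for site in sites:
            if reference_length is not None:
                ln = reference_length.get(site.chrom)
                if ln is None or site.pos + len(site.ref) - 1 > ln or site.pos < 1:
                    raise ValueError(
                        f"site {site.chrom}:{site.pos} outside reference bounds"
                    )
            alt = site.alts[0]
            pac = PoolAlleleCounts(site.chrom, site.pos, site.ref, alt, pool_id)
            if has_index:
                reads = sam.fetch(site.chrom, site.pos - 1, site.pos + len(site.ref))
            else:
                reads = reads_by_chrom.get(site.chrom, [])
            if site.vtype == "biallelic_SNP" or (
                len(site.ref) == 1 and all(len(a) == 1 for a in site.alts)
            ):
                pac.counts = {nt: 0 for nt in NUCLEOTIDES}
                for read in reads:
                    base, qual = _base_at(read, site.pos - 1)
                    if base is None or base not in pac.counts:
                        continue
                    if qual is not None and qual < min_base_quality:
                        continue
                    pac.counts[base] += 1
            else:
                pac.counts = {site.ref: 0, alt: 0}
                for read in reads:
                    obs = _span_allele(read, site.pos - 1, len(site.ref))
                    if obs is None:
                        continue
                    if obs == site.ref:
                        pac.counts[site.ref] += 1
                    elif obs == alt:
                        pac.counts[alt] += 1
            out.append(pac)
    return out


def _base_at(read, ref_pos0: int):
    """Base and quality of ``read`` aligned at 0-based reference position."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos0:
            qual = read.query_qualities[qpos] if read.query_qualities is not None else None
            return read.query_sequence[qpos].upper(), qual
    return None, None


def _span_allele(read, ref_start0: int, ref_len: int) -> Optional[str]:
    """Query sequence aligned across [ref_start0, ref_start0+ref_len) with an
    anchor base required on both sides; None if the read does not span."""
    pairs = read.get_aligned_pairs()
    q_start = q_anchor = None
    for qpos, rpos in pairs:
        if rpos == ref_start0 and qpos is not None:
            q_start = qpos
        if rpos == ref_start0 + ref_len and qpos is not None:
            q_anchor = qpos
            break
    if q_start is None or q_anchor is None:
        return None
    return read.query_sequence[q_start:q_anchor].upper()


# ---------------------------------------------------------------------------
# Long-format TSV I/O and table helpers

COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "pool_id", "A", "C", "G", "T", "depth"]


def counts_to_dataframe(counts: Iterable[PoolAlleleCounts]) -> pd.DataFrame:
    rows = []
    for c in counts:
        row = {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "pool_id": c.pool_id,
            "depth": c.total_depth,
        }
        if len(c.ref) == 1 and len(c.alt) == 1:
            for nt in NUCLEOTIDES:
                row[nt] = c.counts.get(nt, 0)
            row["ref_count"] = c.counts.get(c.ref, 0)
            row["alt_count"] = c.counts.get(c.alt, 0)
        else:
            for nt in NUCLEOTIDES:
                row[nt] = 0
            row["ref_count"] = c.counts.get(c.ref, 0)
            row["alt_count"] = c.counts.get(c.alt, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS + ["ref_count", "alt_count"])


def dataframe_to_counts(df: pd.DataFrame) -> list[PoolAlleleCounts]:
    out = []
    for row in df.itertuples():
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) == 1 and len(alt) == 1:
            counts = {nt: int(getattr(row, nt)) for nt in NUCLEOTIDES}
        else:
            counts = {ref: int(row.ref_count), alt: int(row.alt_count)}
        out.append(
            PoolAlleleCounts(str(row.chrom), int(row.pos), ref, alt, str(row.pool_id), counts)
        )
    return out


def write_counts_tsv(counts: Iterable[PoolAlleleCounts], path: str | Path) -> None:
    counts_to_dataframe(counts).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[PoolAlleleCounts]:
    return dataframe_to_counts(pd.read_csv(path, sep="\t", dtype={"chrom": str, "pool_id": str}))


def counts_by_site(
    counts: Iterable[PoolAlleleCounts],
) -> dict[tuple[str, int], dict[str, PoolAlleleCounts]]:
    """Index counts as site_key -> pool_id -> PoolAlleleCounts."""
    table: dict[tuple[str, int], dict[str, PoolAlleleCounts]] = {}
    for c in counts:
        table.setdefault(c.site_key, {})[c.pool_id] = c
    return table


def summed_counts(per_pool: Mapping[str, PoolAlleleCounts]) -> PoolAlleleCounts:
    """Aggregate one site's counts across pools."""
    pools = list(per_pool.values())
    first = pools[0]
    agg: dict[str, int] = {}
    for c in pools:
        for allele, n in c.counts.items():
            agg[allele] = agg.get(allele, 0) + n
    return PoolAlleleCounts(first.chrom, first.pos, first.ref, first.alt, "ALL", agg)
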
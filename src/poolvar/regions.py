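"""Primer-defined target regions and fragment-assignment QC.

A pooled amplicon experiment targets a set of primer-pair-defined regions
(here ~600 bp exonic segments).  Sequenced fragments are assigned to a
region only under stringent reciprocal overlap: the overlap must cover at
least 90% of the fragment AND at least 90% of the region.  The fraction of
fragments that can be assigned to exactly one region is the capture
success rate of the experiment.

Coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: reads assigned to a (region, pool) below this are flagged as low coverage
DEFAULT_LOW_COVERAGE_THRESHOLD = 20

#: fragments longer than this are treated as improperly paired
DEFAULT_MAX_FRAGMENT_LENGTH = 800


@dataclass(frozen=True)
class TargetRegion:
    """Genomic interval targeted by one primer pair (1-based inclusive)."""

    region_id: str
    chrom: str
    start: int
    end: int
    primer_pair: str = ""
    expected_amplicon_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(
                f"malformed region interval {self.region_id}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignedFragment:
    """Span of a sequenced fragment inferred from a read pair.

    ``proper_pair`` and ``unique`` mirror the aligner's judgement; fragments
    failing either flag are never assigned to a region but still count in
    the capture-rate denominator.
    """

    chrom: str
    start: int
    end: int
    pool_id: str = "pool"
    proper_pair: bool = True
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(
                f"malformed fragment interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


class RegionIndex:
    """Interval index over target regions for fragment assignment."""

    def __init__(
        self,
        regions: Iterable[TargetRegion],
        min_reciprocal_overlap: float = 0.9,
    ) -> None:
        self.regions: dict[str, TargetRegion] = {}
        self._trees: dict[str, IntervalTree] = {}
        # exact rational threshold so the 90% boundary is inclusive
        self._threshold = Fraction(str(min_reciprocal_overlap))
        for region in regions:
            if region.region_id in self.regions:
                raise ValueError(f"duplicate region_id {region.region_id!r}")
            self.regions[region.region_id] = region
            tree = self._trees.setdefault(region.chrom, IntervalTree())
            tree.addi(region.start, region.end + 1, region.region_id)

    def __len__(self) -> int:
        return len(self.regions)

    def assign(self, frag: AlignedFragment) -> Optional[str]:
        """Assign a fragment to a region by reciprocal overlap.

        Returns the region_id iff overlap/len(frag) >= threshold and
        overlap/len(region) >= threshold (both inclusive).  When several
        regions qualify, the one with the larger product of the two overlap
        fractions wins; an exact tie yields no assignment.  Fragments that
        are not properly paired or not uniquely mapped are never assigned.
        """
        if not (frag.proper_pair and frag.unique):
            return None
        tree = self._trees.get(frag.chrom)
        if tree is None:
            return None
        best_id: Optional[str] = None
        best_score: Optional[Fraction] = None
        tied = False
        for iv in tree.overlap(frag.start, frag.end + 1):
            region = self.regions[iv.data]
            ov = _overlap(frag.start, frag.end, region.start, region.end)
            if ov <= 0:
                continue
            frac_frag = Fraction(ov, frag.length)
            frac_region = Fraction(ov, region.length)
            if frac_frag < self._threshold or frac_region < self._threshold:
                continue
            score = frac_frag * frac_region
            if best_score is None or score > best_score:
                best_id, best_score, tied = iv.data, score, False
            elif score == best_score:
                tied = True
        if tied:
            return None
        return best_id


def assign_fragment(
    frag: AlignedFragment,
    regions: "RegionIndex | Iterable[TargetRegion]",
    min_reciprocal_overlap: float = 0.9,
) -> Optional[str]:
    """Functional wrapper around :meth:`RegionIndex.assign`."""
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions, min_reciprocal_overlap)
    return regions.assign(frag)


def assign_fragments(
    frags: Iterable[AlignedFragment],
    regions: "RegionIndex | Iterable[TargetRegion]",
) -> list[tuple[AlignedFragment, Optional[str]]]:
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    return [(f, regions.assign(f)) for f in frags]


def capture_success_rate(
    frags: Sequence[AlignedFragment],
    regions: "RegionIndex | Iterable[TargetRegion]",
) -> float:
    """Fraction of fragments uniquely assignable to a single target region."""
    frags = list(frags)
    if not frags:
        raise ValueError("no fragments")
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    assigned = sum(1 for f in frags if regions.assign(f) is not None)
    return assigned / len(frags)


def region_depth_table(
    assignments: Iterable[tuple[AlignedFragment, Optional[str]]],
    regions: "RegionIndex | Iterable[TargetRegion]",
    pools: Optional[Sequence[str]] = None,
    low_coverage_threshold: int = DEFAULT_LOW_COVERAGE_THRESHOLD,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-(region, pool) assigned-fragment counts plus low-coverage flags.

    The table is complete over all (region, pool) pairs with zeros
    included; pairs with fewer than ``low_coverage_threshold`` fragments
    (strictly less) are flagged, sorted by region_id then pool_id.
    """
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    assignments = list(assignments)
    pool_ids = sorted(pools) if pools is not None else sorted(
        {f.pool_id for f, _ in assignments}
    )
    region_ids = sorted(regions.regions)
    table = pd.DataFrame(0, index=region_ids, columns=pool_ids, dtype=int)
    table.index.name = "region_id"
    for frag, region_id in assignments:
        if region_id is not None and frag.pool_id in table.columns:
            table.loc[region_id, frag.pool_id] += 1
    flags = [
        (r, p)
        for r in region_ids
        for p in pool_ids
        if table.loc[r, p] < low_coverage_threshold
    ]
    return table, flags


def expected_depth(total_fragments: int, n_regions: int) -> float:
    """Expected per-base read depth if fragments distribute evenly and each
    fragment reads its entire region."""
    if n_regions <= 0:
        raise ValueError("n_regions must be positive")
    if total_fragments < 0:
        raise ValueError("total_fragments must be non-negative")
    return total_fragments / n_regions


def coverage_gap(amplicon_len: int, read1_len: int, read2_len: int) -> int:
    """Central bp of an amplicon left uncovered after read trimming."""
    if min(amplicon_len, read1_len, read2_len) <= 0:
        raise ValueError("lengths must be positive")
    return max(0, amplicon_len - read1_len - read2_len)


# ---------------------------------------------------------------------------
# I/O

def read_regions(bed_path: str | Path, meta_path: str | Path | None = None) -> list[TargetRegion]:
    """Read target regions from BED (0-based half-open) plus an optional
    metadata TSV (region_id, primer_pair, expected_amplicon_len)."""
    meta: dict[str, dict] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype={"region_id": str})
        meta = {str(r.region_id): r for r in mdf.itertuples()}
    regions = []
    with open(bed_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            region_id = fields[3] if len(fields) > 3 else f"region_{i}"
            m = meta.get(region_id)
            regions.append(
                TargetRegion(
                    region_id=region_id,
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    primer_pair=str(getattr(m, "primer_pair", "")) if m is not None else "",
                    expected_amplicon_len=int(getattr(m, "expected_amplicon_len"))
                    if m is not None and hasattr(m, "expected_amplicon_len")
                    else None,
                )
            )
    return regions


def write_regions(regions: Sequence[TargetRegion], bed_path: str | Path, meta_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\n")
    pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "primer_pair": [r.primer_pair for r in regions],
            "expected_amplicon_len": [
                r.expected_amplicon_len if r.expected_amplicon_len is not None else r.length
                for r in regions
            ],
        }
    ).to_csv(meta_path, sep="\t", index=False)


_FRAGMENT_COLUMNS = ["chrom", "start", "end", "pool_id", "proper_pair", "unique"]


def read_fragments_tsv(path: str | Path) -> list[AlignedFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pool_id": str})
    return [
        AlignedFragment(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            pool_id=str(row.pool_id),
            proper_pair=bool(row.proper_pair),
            unique=bool(row.unique),
        )
        for row in df.itertuples()
    ]


def write_fragments_tsv(frags: Sequence[AlignedFragment], path: str | Path) -> None:
    pd.DataFrame(
        [(f.chrom, f.start, f.end, f.pool_id, f.proper_pair, f.unique) for f in frags],
        columns=_FRAGMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def fragments_from_sam(
    path: str | Path,
    pool_id: str = "pool",
    min_mapq: int = 20,
    max_fragment_length: int = DEFAULT_MAX_FRAGMENT_LENGTH,
) -> list[AlignedFragment]:
    """Derive fragment spans from SAM/BAM read pairs.

    Each mapped read-1 record yields one fragment spanning the outer
    template coordinates.  ``unique`` is mapping_quality >= min_mapq;
    fragments exceeding ``max_fragment_length`` are demoted to
    proper_pair=False, matching typical aligner insert limits.
    """
    import pysam

    frags: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired and not read.is_read1:
                continue
            tlen = abs(read.template_length)
            if read.is_paired and tlen > 0:
                start = min(read.reference_start, read.next_reference_start) + 1
                end = start + tlen - 1
            else:
                start = read.reference_start + 1
                end = read.reference_end
            proper = bool(read.is_proper_pair) if read.is_paired else True
            length = end - start + 1
            if length > max_fragment_length:
                proper = False
            frags.append(
                AlignedFragment(
                    chrom=read.reference_name,
                    start=start,
                    end=end,
                    pool_id=pool_id,
                    proper_pair=proper,
                    unique=read.mapping_quality >= min_mapq,
                )
            )
    return frags
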
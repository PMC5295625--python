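"""Curation filter cascade for pooled variant calls.

The cascade removes, in order: (1) SNPs embedded in the reference span of
an indel; (2) everything but biallelic SNPs; (3) sites below a minimum
read depth; (4) sites not present in a minimum number of pools; and
(5) sites whose minor-allele support cannot be separated from sequencing
errors.  The error statistic at a SNP site is the mean of the two
smallest of the four nucleotide read counts (ranks 3 and 4 in descending
order); the site is rejected when the second-ranked count is less than
``error_ratio_threshold`` times that estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .callset import VTYPE_SNP, VariantSite
from .counts import PoolAlleleCounts, adjusted_frequency, counts_by_site, summed_counts

AGGREGATE_SUMMED = "summed_across_pools"
AGGREGATE_PER_POOL = "per_pool_any"


@dataclass
class FilterConfig:
    """Thresholds of the curation cascade.

    ``aggregate_mode`` controls whether the depth filter and the error
    statistic operate on counts summed across pools (default) or pass if
    any single pool passes.
    """

    min_total_depth: int = 10000
    min_pools_present: int = 2
    min_alt_reads_presence: int = 1
    error_ratio_threshold: float = 5.0
    error_rank_lo: int = 3
    error_rank_hi: int = 4
    aggregate_mode: str = AGGREGATE_SUMMED

    def __post_init__(self) -> None:
        if min(self.min_total_depth, self.min_alt_reads_presence) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_pools_present < 1:
            raise ValueError("min_pools_present must be >= 1")
        if self.error_ratio_threshold < 0:
            raise ValueError("error_ratio_threshold must be >= 0")
        if not 1 <= self.error_rank_lo <= self.error_rank_hi:
            raise ValueError("invalid error ranks")
        if self.aggregate_mode not in (AGGREGATE_SUMMED, AGGREGATE_PER_POOL):
            raise ValueError(f"unknown aggregate_mode {self.aggregate_mode!r}")


@dataclass
class FilterReport:
    """Ordered per-stage attrition; stages chain exactly."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, sites_in: int, sites_out: int) -> None:
        if self.stages and self.stages[-1][3] != sites_in:
            raise ValueError("filter stages do not chain")
        self.stages.append((name, sites_in, sites_in - sites_out, sites_out))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["filter_name", "sites_in", "sites_removed", "sites_out"]
        )


def estimate_errors(
    counts: "PoolAlleleCounts | Mapping[str, int]",
    rank_lo: int = 3,
    rank_hi: int = 4,
) -> float:
    """Sequencing-error estimate at a SNP site.

    Mean of the allele read counts at descending ranks ``rank_lo`` through
    ``rank_hi`` (defaults: the two smallest of the four nucleotide counts).
    Ties are broken by lexicographic allele order for determinism.
    """
    mapping = counts.counts if isinstance(counts, PoolAlleleCounts) else counts
    if len(mapping) < rank_hi:
        raise ValueError(
            f"error estimate needs >= {rank_hi} allele categories, got {len(mapping)}"
        )
    ranked = sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))
    window = [n for _, n in ranked[rank_lo - 1 : rank_hi]]
    return sum(window) / len(window)


def error_ratio(
    counts: "PoolAlleleCounts | Mapping[str, int]",
    rank_lo: int = 3,
    rank_hi: int = 4,
) -> float:
    """Second-ranked allele count over the sequencing-error estimate.

    A zero error estimate with minor support yields +inf (clearly above
    any threshold); zero over zero yields 0 (no minor support at all).
    """
    mapping = counts.counts if isinstance(counts, PoolAlleleCounts) else counts
    ranked = sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))
    second = ranked[1][1]
    est = estimate_errors(mapping, rank_lo, rank_hi)
    if est == 0:
        return inf if second > 0 else 0.0
    return second / est


def remove_embedded_in_indels(sites: Sequence[VariantSite]) -> list[VariantSite]:
    """Drop SNPs whose position lies within the reference span of any indel
    site in the same set.  Non-SNP sites pass through unchanged."""
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        is_indel = any(len(a) != len(s.ref) for a in s.alts)
        if is_indel:
            lo, hi = s.ref_span
            trees.setdefault(s.chrom, IntervalTree()).addi(lo, hi + 1)
    kept = []
    for s in sites:
        if s.vtype == VTYPE_SNP:
            tree = trees.get(s.chrom)
            if tree is not None and tree.overlaps_point(s.pos):
                continue
        kept.append(s)
    return kept


@dataclass
class CuratedSite:
    """A SNP surviving the cascade, with its pooled frequency estimates."""

    site: VariantSite
    adjusted_frequencies: dict[str, Optional[float]]
    summed_counts: PoolAlleleCounts
    error_ratio: float

    @property
    def frequency_range(self) -> Optional[float]:
        vals = [f for f in self.adjusted_frequencies.values() if f is not None]
        if len(vals) < 2:
            return None
        return max(vals) - min(vals)


def apply_cascade(
    sites: Sequence[VariantSite],
    counts: "Iterable[PoolAlleleCounts] | Mapping[tuple[str, int], Mapping[str, PoolAlleleCounts]]",
    config: Optional[FilterConfig] = None,
) -> tuple[list[CuratedSite], FilterReport]:
    """Run the full curation cascade and report per-stage attrition.

    ``counts`` may be a flat iterable of per-pool counts or the nested
    site_key -> pool_id -> counts index.  Every SNP site reaching the
    count-based stages must have counts; a missing site is an error.
    """
    if config is None:
        config = FilterConfig()
    if not isinstance(counts, Mapping):
        counts = counts_by_site(counts)
    report = FilterReport()

    stage0 = list(sites)
    stage1 = remove_embedded_in_indels(stage0)
    report.add("embedded_in_indel", len(stage0), len(stage1))

    stage2 = [s for s in stage1 if s.vtype == VTYPE_SNP]
    report.add("biallelic_snp_only", len(stage1), len(stage2))

    per_site: dict[VariantSite, dict[str, PoolAlleleCounts]] = {}
    for s in stage2:
        site_counts = counts.get((s.chrom, s.pos))
        if not site_counts:
            raise ValueError(f"no read counts for site {s.chrom}:{s.pos}")
        per_site[s] = dict(site_counts)

    def total_depth_ok(s: VariantSite) -> bool:
        pools = per_site[s].values()
        if config.aggregate_mode == AGGREGATE_PER_POOL:
            return any(c.total_depth >= config.min_total_depth for c in pools)
        return sum(c.total_depth for c in pools) >= config.min_total_depth

    stage3 = [s for s in stage2 if total_depth_ok(s)]
    report.add("min_depth", len(stage2), len(stage3))

    def pools_present(s: VariantSite) -> int:
        alt = s.alts[0]
        return sum(
            1
            for c in per_site[s].values()
            if c.counts.get(alt, 0) >= config.min_alt_reads_presence
        )

    stage4 = [s for s in stage3 if pools_present(s) >= config.min_pools_present]
    report.add("min_pools_present", len(stage3), len(stage4))

    def site_error_ratio(s: VariantSite) -> float:
        pools = per_site[s]
        if config.aggregate_mode == AGGREGATE_PER_POOL:
            return max(
                error_ratio(c, config.error_rank_lo, config.error_rank_hi)
                for c in pools.values()
            )
        return error_ratio(
            summed_counts(pools), config.error_rank_lo, config.error_rank_hi
        )

    ratios = {s: site_error_ratio(s) for s in stage4}
    stage5 = [s for s in stage4 if ratios[s] >= config.error_ratio_threshold]
    report.add("error_ratio", len(stage4), len(stage5))

    curated = []
    for s in stage5:
        pools = per_site[s]
        freqs = {
            pool_id: adjusted_frequency(c, s.ref, s.alts[0])
            for pool_id, c in sorted(pools.items())
        }
        curated.append(CuratedSite(s, freqs, summed_counts(pools), ratios[s]))
    return curated, report
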
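"""Multi-caller callset merging with normalization and provenance.

Variant sites reported by several discovery pipelines (aligner x caller
combinations) are unioned after allele normalization: multi-allelic
records are split, indels are left-aligned against the reference and
minimally represented, and the matching key is (chrom, pos, ref, alt).
Alleles meeting at the same locus are re-fused into one site, so a locus
that is biallelic in each caller but with different alternative alleles
across callers becomes multiallelic in the merged set.  Provenance — the
set of pipelines that called each site — drives the intersection and
aligner-consistency summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PipelineId = Hashable  # conventionally a (aligner_label, caller_label) tuple

VTYPE_SNP = "biallelic_SNP"
VTYPE_INDEL = "biallelic_indel"
VTYPE_MULTI = "multiallelic"


@dataclass(frozen=True, order=True)
class AlleleKey:
    """Minimal normalized representation of a single ref->alt change."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantSite:
    """Normalized variant site; one locus, possibly several alt alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alts:
            raise ValueError("site needs at least one alt allele")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        if len(self.alts) > 1:
            return VTYPE_MULTI
        if len(self.ref) == 1 and len(self.alts[0]) == 1:
            return VTYPE_SNP
        return VTYPE_INDEL

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference interval occupied by the ref allele."""
        return self.pos, self.pos + len(self.ref) - 1

    @property
    def key(self) -> tuple[str, int]:
        return self.chrom, self.pos


def trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared leading/trailing bases without reference context.

    Leaves at least one base on each allele; does not left-shift."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_allele(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    fetch_base: Optional[Callable[[str, int], str]] = None,
) -> AlleleKey:
    """Left-align and minimally represent one ref->alt change.

    ``fetch_base(chrom, pos)`` returns the reference base at a 1-based
    position; without it only prefix/suffix trimming is performed.
    Algorithm: repeatedly truncate shared terminal bases, extending to the
    left with the previous reference base whenever an allele would become
    empty, then truncate shared leading bases.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref equals alt at {chrom}:{pos}")
    if fetch_base is None:
        pos, ref, alt = trim_allele(pos, ref, alt)
        return AlleleKey(chrom, pos, ref, alt)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if (not ref or not alt) and pos > 1:
            base = fetch_base(chrom, pos - 1).upper()
            pos -= 1
            ref, alt = base + ref, base + alt
        elif not ref or not alt:
            # at contig start: re-anchor on the first reference base
            base = fetch_base(chrom, pos).upper()
            ref, alt = base + ref, base + alt
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return AlleleKey(chrom, pos, ref, alt)


def fasta_fetcher(fasta_path: str | Path) -> Callable[[str, int], str]:
    """Return a fetch_base(chrom, pos1) closure backed by an indexed FASTA."""
    import pysam

    fa = pysam.FastaFile(str(fasta_path))

    def fetch(chrom: str, pos1: int) -> str:
        return fa.fetch(chrom, pos1 - 1, pos1)

    return fetch


@dataclass
class Callset:
    """Normalized allele calls from one discovery pipeline."""

    pipeline_id: PipelineId
    alleles: set[AlleleKey] = field(default_factory=set)
    maf: dict[AlleleKey, float] = field(default_factory=dict)

    @property
    def sites(self) -> list[VariantSite]:
        return fuse_alleles(self.alleles)


def read_callset(
    vcf_path: str | Path,
    pipeline_id: PipelineId,
    reference_fasta: str | Path | None = None,
) -> Callset:
    """Read one pipeline's VCF into a normalized callset.

    Multi-alt records are split per allele; each allele is left-aligned
    when a reference is supplied.  REF disagreement with the reference is
    a hard error naming the record; unknown header fields are tolerated.
    When the caller reports an allele frequency (INFO/AF or MAF) it is
    retained for MAF-stratified comparisons.
    """
    import pysam

    fetch = fasta_fetcher(reference_fasta) if reference_fasta is not None else None
    cs = Callset(pipeline_id=pipeline_id)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                continue
            if fetch is not None:
                expected = "".join(
                    fetch(rec.chrom, rec.pos + i) for i in range(len(rec.ref))
                ).upper()
                if expected != rec.ref.upper():
                    raise ValueError(
                        f"REF mismatch at {rec.chrom}:{rec.pos} in {vcf_path}: "
                        f"VCF has {rec.ref!r}, reference has {expected!r}"
                    )
            af = None
            for key in ("AF", "MAF"):
                try:
                    if key in rec.info:
                        af = rec.info[key]
                        break
                except ValueError:
                    continue
            if isinstance(af, (tuple, list)):
                afs = list(af)
            else:
                afs = [af] * len(rec.alts)
            for alt, allele_af in zip(rec.alts, afs):
                if alt is None or alt in {"*", "."} or alt.startswith("<"):
                    logger.warning("skipping symbolic allele at %s:%s", rec.chrom, rec.pos)
                    continue
                key = normalize_allele(rec.chrom, rec.pos, rec.ref, alt, fetch)
                cs.alleles.add(key)
                if allele_af is not None:
                    cs.maf[key] = float(allele_af)
    return cs


def fuse_alleles(
    alleles: Iterable[AlleleKey],
) -> list[VariantSite]:
    """Group normalized alleles by locus into sites, unifying REF padding."""
    sites, _ = _fuse_with_members(alleles)
    return sites


def _fuse_with_members(
    alleles: Iterable[AlleleKey],
) -> tuple[list[VariantSite], dict[VariantSite, list[AlleleKey]]]:
    by_locus: dict[tuple[str, int], list[AlleleKey]] = {}
    for a in alleles:
        by_locus.setdefault((a.chrom, a.pos), []).append(a)
    sites: list[VariantSite] = []
    members: dict[VariantSite, list[AlleleKey]] = {}
    for (chrom, pos), group in sorted(by_locus.items()):
        longest_ref = max((g.ref for g in group), key=len)
        padded_alts = []
        for g in group:
            if not longest_ref.startswith(g.ref):
                raise ValueError(
                    f"inconsistent REF alleles at {chrom}:{pos}: "
                    f"{g.ref!r} vs {longest_ref!r}"
                )
            padded_alts.append(g.alt + longest_ref[len(g.ref):])
        site = VariantSite(chrom, pos, longest_ref, tuple(sorted(set(padded_alts))))
        sites.append(site)
        members[site] = sorted(set(group))
    return sites, members


def merge_union(
    callsets: Sequence[Callset],
) -> tuple[list[VariantSite], dict[VariantSite, frozenset]]:
    """Union callsets from several pipelines, tracking provenance.

    Returns the fused site list (sorted by locus) and a provenance map
    site -> frozenset of pipeline_ids that called any allele of the site.
    """
    if not callsets:
        raise ValueError("need at least one callset")
    seen_ids = set()
    for cs in callsets:
        if cs.pipeline_id in seen_ids:
            raise ValueError(f"duplicate pipeline_id {cs.pipeline_id!r}")
        seen_ids.add(cs.pipeline_id)
    allele_prov: dict[AlleleKey, set] = {}
    for cs in callsets:
        for a in cs.alleles:
            allele_prov.setdefault(a, set()).add(cs.pipeline_id)
    sites, members = _fuse_with_members(allele_prov)
    provenance = {
        site: frozenset().union(*(allele_prov[a] for a in members[site]))
        for site in sites
    }
    return sites, provenance


def classify_sites(sites: Iterable[VariantSite]) -> dict[str, int]:
    """Counts of biallelic SNPs / biallelic indels / multiallelic sites."""
    counts = {VTYPE_SNP: 0, VTYPE_INDEL: 0, VTYPE_MULTI: 0}
    for s in sites:
        counts[s.vtype] += 1
    return counts


@dataclass
class IntersectionSummary:
    per_pipeline: dict
    pairwise: pd.DataFrame
    exclusive_by_k: dict[int, int]


def intersection_summary(provenance: Mapping[VariantSite, frozenset]) -> IntersectionSummary:
    """Per-pipeline counts, symmetric pairwise shared counts, and counts of
    sites called by exactly k pipelines (which partition the union)."""
    if not provenance:
        raise ValueError("empty provenance")
    pipelines = sorted({p for prov in provenance.values() for p in prov}, key=repr)
    per = {p: 0 for p in pipelines}
    labels = [repr(p) if not isinstance(p, str) else p for p in pipelines]
    pairwise = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    exclusive: dict[int, int] = {}
    for prov in provenance.values():
        k = len(prov)
        exclusive[k] = exclusive.get(k, 0) + 1
        idx = [pipelines.index(p) for p in prov]
        for i in idx:
            per[pipelines[i]] += 1
            for j in idx:
                pairwise.iloc[i, j] += 1
    return IntersectionSummary(per, pairwise, exclusive)


def aligner_consistency(
    provenance: Mapping[VariantSite, frozenset],
    caller_label: str,
) -> float:
    """Jaccard consistency of one caller's sites between the two aligners."""
    by_aligner: dict[str, set[VariantSite]] = {}
    for site, prov in provenance.items():
        for pid in prov:
            if isinstance(pid, tuple) and len(pid) == 2 and pid[1] == caller_label:
                by_aligner.setdefault(pid[0], set()).add(site)
    if len(by_aligner) < 2:
        raise ValueError(
            f"caller {caller_label!r} not present under two aligners "
            f"(found {sorted(by_aligner)})"
        )
    sets = list(by_aligner.values())
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return len(inter) / len(union)


@dataclass
class OverlapResult:
    n_overlap: int
    fraction: float
    by_maf_bin: Optional[pd.DataFrame] = None


def overlap_with_reference_callset(
    merged: Sequence[VariantSite],
    external: Iterable[AlleleKey],
    maf: Optional[Mapping[VariantSite, float]] = None,
    bins: Sequence[float] = (0.0, 0.01, 0.05, 0.1, 0.5),
) -> OverlapResult:
    """Overlap of the merged set with an external reference callset.

    A merged site overlaps when any of its alleles (minimally trimmed)
    matches an external (chrom, pos, ref, alt) allele.  With per-site MAF
    supplied, the overlap is also stratified by MAF bin.
    """
    external_set = set(external)
    merged = list(merged)
    hits: list[bool] = []
    for site in merged:
        matched = False
        for alt in site.alts:
            pos, ref, a = trim_allele(site.pos, site.ref, alt)
            if AlleleKey(site.chrom, pos, ref, a) in external_set:
                matched = True
                break
        hits.append(matched)
    n = sum(hits)
    frac = n / len(merged) if merged else 0.0
    by_bin = None
    if maf is not None and merged:
        df = pd.DataFrame(
            {
                "maf": [maf.get(s, float("nan")) for s in merged],
                "hit": hits,
            }
        )
        df["bin"] = pd.cut(df["maf"], bins=list(bins), include_lowest=True)
        by_bin = df.groupby("bin", observed=False)["hit"].agg(["sum", "count"])
        by_bin["fraction"] = by_bin["sum"] / by_bin["count"].where(by_bin["count"] > 0)
    return OverlapResult(n, frac, by_bin)


# ---------------------------------------------------------------------------
# VCF output

def write_vcf(
    sites: Sequence[VariantSite],
    path: str | Path,
    provenance: Optional[Mapping[VariantSite, frozenset]] = None,
    info_extra: Optional[Mapping[VariantSite, Mapping[str, str]]] = None,
    extra_info_headers: Sequence[tuple[str, str, str, str]] = (),
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write sites as a VCF 4.2 file with per-site pipeline provenance.

    ``extra_info_headers`` entries are (ID, Number, Type, Description)."""

    def fmt_pid(pid) -> str:
        if isinstance(pid, tuple):
            return ":".join(str(x) for x in pid)
        return str(pid)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PIPELINES,Number=.,Type=String,'
                 'Description="Discovery pipelines that called this site">\n')
        for hid, num, typ, desc in extra_info_headers:
            fh.write(f'##INFO=<ID={hid},Number={num},Type={typ},Description="{desc}">\n')
        chroms = sorted({s.chrom for s in sites})
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos, s.ref)):
            info_parts = []
            if provenance is not None and site in provenance:
                pids = ",".join(sorted(fmt_pid(p) for p in provenance[site]))
                info_parts.append(f"PIPELINES={pids}")
            if info_extra is not None and site in info_extra:
                info_parts.extend(f"{k}={v}" for k, v in info_extra[site].items())
            info = ";".join(info_parts) if info_parts else "."
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t{info}\n"
            )
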
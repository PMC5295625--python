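"""Synthetic pooled-amplicon sequencing data with known truth.

The generator emulates the statistical structure the curation pipeline
assumes: 8 pools of ~200 diploid samples, ~100 amplicon regions of 600 bp,
per-pool read depths of order 10^4, a site-frequency spectrum dominated by
rare alleles, uniform base-call substitution errors, and multi-caller
callsets whose sensitivity depends on pooled minor allele frequency.
Read counts are simulated directly (they are the sufficient statistic for
every downstream stage); fragment simulation exercises the region-QC path.
All outputs are deterministic functions of the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .callset import VariantSite, write_vcf
from .counts import NUCLEOTIDES, PoolAlleleCounts
from .filters import FilterConfig, apply_cascade
from .regions import AlignedFragment, TargetRegion

_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture of rare and common population allele frequencies.

    Rare sites (frequency <= 0.01) dominate pooled germplasm surveys; the
    default plants 65% of sites in the rare range, uniformly between the
    single-carrier floor 1/400 and 0.01, the rest uniform up to 0.5.
    """

    fraction_rare: float = 0.65
    rare_range: tuple[float, float] = (0.0025, 0.01)
    common_range: tuple[float, float] = (0.01, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_rare <= 1.0:
            raise ValueError("fraction_rare must be in [0, 1]")
        for lo, hi in (self.rare_range, self.common_range):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("invalid frequency range")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        rare = rng.random(n) < self.fraction_rare
        freqs = np.where(
            rare,
            rng.uniform(*self.rare_range, size=n),
            rng.uniform(*self.common_range, size=n),
        )
        return freqs


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one discovery pipeline."""

    pipeline_id: tuple[str, str]
    maf_detection_floor: float = 0.0
    false_positive_rate: float = 0.0


#: twelve pipelines mirroring a 2-aligner x 7-caller roster in which the
#: pool-aware callers have the lowest detection floors and two callers run
#: from one aligner only
DEFAULT_CALLER_PROFILES: tuple[CallerProfile, ...] = tuple(
    CallerProfile(pid, floor, fp)
    for pid, floor, fp in [
        (("bowtie2", "vipr"), 0.001, 0.02),
        (("bwa", "vipr"), 0.001, 0.02),
        (("bowtie2", "snver"), 0.005, 0.01),
        (("bwa", "snver"), 0.005, 0.01),
        (("bowtie2", "ngsep"), 0.02, 0.005),
        (("bwa", "ngsep"), 0.02, 0.005),
        (("bowtie2", "samtools"), 0.1, 0.001),
        (("bwa", "samtools"), 0.1, 0.001),
        (("bowtie2", "varscan"), 0.05, 0.001),
        (("bwa", "varscan"), 0.05, 0.001),
        (("bwa", "gatk"), 0.05, 0.002),
        (("bwa", "freebayes"), 0.05, 0.002),
    ]
)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    seed: int
    n_pools: int = 8
    samples_per_pool: int = 200
    ploidy: int = 2
    n_regions: int = 100
    region_len: int = 600
    region_gap: int = 400
    n_sites: int = 400
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    depth_per_pool: int = 20000
    base_error_rate: float = 0.002
    caller_profiles: tuple[CallerProfile, ...] = DEFAULT_CALLER_PROFILES
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0, 1]")
        if self.depth_per_pool < 0:
            raise ValueError("depth_per_pool must be >= 0")
        if self.n_sites > self.n_regions * self.region_len:
            raise ValueError("more sites than targetable bases")

    @property
    def n_haploids(self) -> int:
        return self.samples_per_pool * self.ploidy

    @property
    def pool_ids(self) -> list[str]:
        return [f"pool{i + 1}" for i in range(self.n_pools)]


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated counts."""

    sites: pd.DataFrame  # site_id, chrom, pos, ref, alt, true_freq, max_pool_fraction
    pools: pd.DataFrame  # site_id, pool_id, carrier_copies, pool_fraction


@dataclass
class SimResult:
    counts: list[PoolAlleleCounts]
    truth: SimTruth
    reference: dict[str, str]
    regions: list[TargetRegion]
    sites: list[VariantSite]


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def simulate_reference(cfg: SimConfig) -> tuple[dict[str, str], list[TargetRegion]]:
    """Random reference chromosome with evenly spaced target regions."""
    rng = _rng(cfg.seed, 0)
    total = cfg.region_gap + cfg.n_regions * (cfg.region_len + cfg.region_gap)
    seq = "".join(rng.choice(list(NUCLEOTIDES), size=total))
    regions = []
    for i in range(cfg.n_regions):
        start = cfg.region_gap + i * (cfg.region_len + cfg.region_gap) + 1
        regions.append(
            TargetRegion(
                region_id=f"amp{i + 1:03d}",
                chrom=cfg.chrom,
                start=start,
                end=start + cfg.region_len - 1,
                primer_pair=f"primer{i + 1:03d}",
                expected_amplicon_len=cfg.region_len,
            )
        )
    return {cfg.chrom: seq}, regions


def _observed_base_probs(pf: np.ndarray, ref_idx: np.ndarray, alt_idx: np.ndarray,
                         error_rate: float) -> np.ndarray:
    """Per-(site, pool) probabilities over ACGT after uniform substitution
    errors: each sampled read base is corrupted to one of the three other
    bases with total probability error_rate."""
    n_sites, n_pools = pf.shape
    true_p = np.zeros((n_sites, n_pools, 4))
    rows = np.arange(n_sites)
    true_p[rows, :, ref_idx] = (1.0 - pf)
    # alt may equal ref only if alleles were mis-specified; indices differ here
    for s in range(n_sites):
        true_p[s, :, alt_idx[s]] += pf[s]
    return true_p * (1.0 - error_rate) + (1.0 - true_p) * (error_rate / 3.0)


def simulate_pools(
    cfg: SimConfig,
    fixed_pool_fraction: Optional[float] = None,
) -> SimResult:
    """Simulate per-pool allele read counts at planted SNP sites.

    Per site, the population frequency is drawn from the MAF spectrum; per
    pool, carrier alt copies ~ Binomial(ploidy x samples, f) set the true
    pool allele fraction; reads are a multinomial over the four bases at
    that fraction, each read independently corrupted to a uniform other
    base with probability ``base_error_rate``.  ``fixed_pool_fraction``
    bypasses carrier sampling and plants the same allele fraction in every
    pool (fraction 0 plants pure-error sites).
    """
    reference, regions = simulate_reference(cfg)
    rng = _rng(cfg.seed, 1)
    seq = reference[cfg.chrom]

    targetable = np.concatenate(
        [np.arange(r.start, r.end + 1) for r in regions]
    )
    positions = np.sort(rng.choice(targetable, size=cfg.n_sites, replace=False))
    ref_bases = np.array([seq[p - 1] for p in positions])
    ref_idx = np.array([_NT_INDEX[b] for b in ref_bases])
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_sites)) % 4
    alt_bases = np.array([NUCLEOTIDES[i] for i in alt_idx])

    if fixed_pool_fraction is not None:
        if not 0.0 <= fixed_pool_fraction <= 1.0:
            raise ValueError("fixed_pool_fraction must be in [0, 1]")
        freqs = np.full(cfg.n_sites, fixed_pool_fraction)
        copies = np.full(
            (cfg.n_sites, cfg.n_pools),
            int(round(fixed_pool_fraction * cfg.n_haploids)),
        )
        pf = np.full((cfg.n_sites, cfg.n_pools), fixed_pool_fraction)
    else:
        freqs = cfg.maf_spectrum.draw(rng, cfg.n_sites)
        copies = rng.binomial(cfg.n_haploids, freqs[:, None], size=(cfg.n_sites, cfg.n_pools))
        pf = copies / cfg.n_haploids

    probs = _observed_base_probs(pf, ref_idx, alt_idx, cfg.base_error_rate)
    counts = rng.multinomial(cfg.depth_per_pool, probs)  # (sites, pools, 4)

    pool_ids = cfg.pool_ids
    out_counts: list[PoolAlleleCounts] = []
    sites: list[VariantSite] = []
    for s in range(cfg.n_sites):
        site = VariantSite(cfg.chrom, int(positions[s]), str(ref_bases[s]), (str(alt_bases[s]),))
        sites.append(site)
        for p, pool_id in enumerate(pool_ids):
            out_counts.append(
                PoolAlleleCounts(
                    site.chrom,
                    site.pos,
                    site.ref,
                    site.alts[0],
                    pool_id,
                    {nt: int(counts[s, p, i]) for i, nt in enumerate(NUCLEOTIDES)},
                )
            )

    sites_df = pd.DataFrame(
        {
            "site_id": np.arange(cfg.n_sites),
            "chrom": cfg.chrom,
            "pos": positions,
            "ref": ref_bases,
            "alt": alt_bases,
            "true_freq": freqs,
            "max_pool_fraction": pf.max(axis=1),
        }
    )
    pools_df = pd.DataFrame(
        {
            "site_id": np.repeat(np.arange(cfg.n_sites), cfg.n_pools),
            "pool_id": pool_ids * cfg.n_sites,
            "carrier_copies": copies.reshape(-1),
            "pool_fraction": pf.reshape(-1),
        }
    )
    return SimResult(out_counts, SimTruth(sites_df, pools_df), reference, regions, sites)


def simulate_fragments(
    cfg: SimConfig,
    regions: Sequence[TargetRegion],
    n_fragments: int = 10000,
    on_target_rate: float = 0.91,
    max_jitter: int = 30,
) -> list[AlignedFragment]:
    """Fragments with a planted on-target fraction.

    On-target fragments span a region shifted by at most ``max_jitter`` bp
    (well inside the 90% reciprocal-overlap criterion); off-target ones
    either fall in inter-region gaps or carry improper-pair / non-unique
    flags, so the measured capture rate estimates ``on_target_rate``.
    """
    rng = _rng(cfg.seed, 2)
    pools = cfg.pool_ids
    frags: list[AlignedFragment] = []
    regions = list(regions)
    for _ in range(n_fragments):
        pool_id = pools[int(rng.integers(len(pools)))]
        region = regions[int(rng.integers(len(regions)))]
        if rng.random() < on_target_rate:
            shift = int(rng.integers(-max_jitter, max_jitter + 1))
            frags.append(
                AlignedFragment(
                    chrom=region.chrom,
                    start=max(1, region.start + shift),
                    end=region.end + shift,
                    pool_id=pool_id,
                    proper_pair=True,
                    unique=True,
                )
            )
        else:
            mode = rng.random()
            if mode < 0.5 and cfg.region_gap > 250 and region.start > cfg.region_gap:
                # gap fragment: no overlap with any region
                gap_start = region.start - cfg.region_gap
                start = gap_start + int(rng.integers(0, cfg.region_gap - 200))
                frags.append(
                    AlignedFragment(region.chrom, start, start + 199, pool_id, True, True)
                )
            else:
                improper = rng.random() < 0.5
                frags.append(
                    AlignedFragment(
                        region.chrom,
                        region.start,
                        region.end,
                        pool_id,
                        proper_pair=not improper,
                        unique=improper,
                    )
                )
    return frags


def simulate_callsets(
    truth: SimTruth,
    cfg: SimConfig,
    outdir: str | Path,
    reference: Optional[dict[str, str]] = None,
) -> dict[tuple[str, str], Path]:
    """Write one VCF per caller profile from the truth table.

    A pipeline calls a true site iff the site's largest per-pool minor
    allele frequency (min of alt and ref fraction) reaches the pipeline's
    detection floor; false positives are added at random non-variant
    positions at the profile's rate (expected fp_rate x n_sites calls).
    """
    rng = _rng(cfg.seed, 3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_pool_maf = truth.pools.assign(
        maf=lambda d: np.minimum(d.pool_fraction, 1.0 - d.pool_fraction)
        .where(d.pool_fraction > 0, 0.0)
    )
    site_maf = per_pool_maf.groupby("site_id")["maf"].max()
    carrier = truth.pools.groupby("site_id")["carrier_copies"].max() > 0
    seq = reference[cfg.chrom] if reference else None
    contig_lengths = {cfg.chrom: len(seq)} if seq else None
    truth_positions = set(truth.sites.pos.astype(int))

    paths: dict[tuple[str, str], Path] = {}
    for profile in cfg.caller_profiles:
        called = truth.sites[
            carrier.reindex(truth.sites.site_id).to_numpy()
            & (site_maf.reindex(truth.sites.site_id).to_numpy() >= profile.maf_detection_floor)
        ]
        sites = [
            VariantSite(str(r.chrom), int(r.pos), str(r.ref), (str(r.alt),))
            for r in called.itertuples()
        ]
        info = {
            s: {"AF": f"{float(af):.6g}"}
            for s, af in zip(
                sites, site_maf.reindex(called.site_id).to_numpy()
            )
        }
        n_fp = rng.poisson(profile.false_positive_rate * cfg.n_sites)
        if seq is not None:
            for _ in range(int(n_fp)):
                for _attempt in range(100):
                    pos = int(rng.integers(1, len(seq) + 1))
                    if pos not in truth_positions:
                        break
                ref = seq[pos - 1]
                alt = NUCLEOTIDES[(_NT_INDEX[ref] + int(rng.integers(1, 4))) % 4]
                fp_site = VariantSite(cfg.chrom, pos, ref, (alt,))
                sites.append(fp_site)
                info[fp_site] = {"AF": "0.001"}
        path = outdir / f"{profile.pipeline_id[0]}_{profile.pipeline_id[1]}.vcf"
        write_vcf(
            sites,
            path,
            info_extra=info,
            extra_info_headers=[("AF", "A", "Float", "Caller-estimated allele frequency")],
            contig_lengths=contig_lengths,
        )
        paths[profile.pipeline_id] = path
    return paths


@dataclass
class PowerEstimate:
    power: float
    standard_error: float
    n_reps: int


def detection_power(
    depth: int,
    true_freq: float,
    error_rate: float,
    filter_cfg: Optional[FilterConfig] = None,
    n_reps: int = 200,
    seed: int = 0,
    n_pools: int = 8,
    samples_per_pool: int = 200,
    ploidy: int = 2,
) -> PowerEstimate:
    """Monte-Carlo probability that a planted SNP survives the cascade.

    Each replicate plants one site at population frequency ``true_freq``
    across ``n_pools`` pools of the given design at per-pool ``depth`` and
    runs the full filter cascade; power is the surviving fraction with its
    binomial standard error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    rng = np.random.default_rng([seed, 4])
    n_haploids = samples_per_pool * ploidy
    copies = rng.binomial(n_haploids, true_freq, size=(n_reps, n_pools))
    pf = copies / n_haploids
    ref_idx = np.zeros(n_reps, dtype=int)  # A
    alt_idx = np.full(n_reps, 2, dtype=int)  # G
    probs = _observed_base_probs(pf, ref_idx, alt_idx, error_rate)
    counts = rng.multinomial(depth, probs)
    sites = [VariantSite("sim", 100 + 10 * i, "A", ("G",)) for i in range(n_reps)]
    pool_counts: list[PoolAlleleCounts] = []
    for i, site in enumerate(sites):
        for p in range(n_pools):
            pool_counts.append(
                PoolAlleleCounts(
                    site.chrom, site.pos, "A", "G", f"pool{p + 1}",
                    {nt: int(counts[i, p, j]) for j, nt in enumerate(NUCLEOTIDES)},
                )
            )
    curated, _ = apply_cascade(sites, pool_counts, filter_cfg)
    power = len(curated) / n_reps
    se = math.sqrt(power * (1.0 - power) / n_reps)
    return PowerEstimate(power, se, n_reps)


# ---------------------------------------------------------------------------
# Bundle output: every artifact the pipeline consumes, in its native format

def write_fasta(reference: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_models_gff3(
    regions: Sequence[TargetRegion], path: str | Path
) -> None:
    """Toy gene models: one single-exon coding gene per target region,
    alternating strand, phase 0 (region length must be a codon multiple)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(regions):
            strand = "+" if i % 2 == 0 else "-"
            gid = f"gene_{r.region_id}"
            tid = f"mRNA_{r.region_id}"
            base = f"{r.chrom}\tpoolvar_sim"
            fh.write(f"{base}\tgene\t{r.start}\t{r.end}\t.\t{strand}\t.\tID={gid}\n")
            fh.write(f"{base}\tmRNA\t{r.start}\t{r.end}\t.\t{strand}\t.\tID={tid};Parent={gid}\n")
            fh.write(f"{base}\texon\t{r.start}\t{r.end}\t.\t{strand}\t.\tID=exon_{r.region_id};Parent={tid}\n")
            fh.write(f"{base}\tCDS\t{r.start}\t{r.end}\t.\t{strand}\t0\tID=cds_{r.region_id};Parent={tid}\n")


def simulate_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle.

    Emits reference FASTA, regions BED + metadata TSV, fragments TSV,
    per-pool allele-count TSV, truth tables, toy gene models GFF3 and one
    VCF per caller profile, all byte-deterministic given the seed.
    """
    from .counts import write_counts_tsv
    from .regions import write_fragments_tsv, write_regions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_pools(cfg)
    frags = simulate_fragments(cfg, result.regions)

    paths = {
        "reference": outdir / "reference.fa",
        "regions_bed": outdir / "regions.bed",
        "regions_meta": outdir / "regions_meta.tsv",
        "fragments": outdir / "fragments.tsv",
        "counts": outdir / "counts.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_pools": outdir / "truth_pools.tsv",
        "gff3": outdir / "genes.gff3",
    }
    write_fasta(result.reference, paths["reference"])
    write_regions(result.regions, paths["regions_bed"], paths["regions_meta"])
    write_fragments_tsv(frags, paths["fragments"])
    vcf_paths = simulate_callsets(result.truth, cfg, outdir / "callsets", result.reference)
    # false-positive calls arise from sequencing noise: re-genotyping them
    # yields pure-error read counts, which the cascade is expected to remove
    fp_sites = _false_positive_sites(vcf_paths.values(), result.sites)
    all_counts = result.counts + _error_only_counts(cfg, fp_sites)
    write_counts_tsv(all_counts, paths["counts"])
    result.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    result.truth.pools.to_csv(paths["truth_pools"], sep="\t", index=False)
    write_gene_models_gff3(result.regions, paths["gff3"])
    for pid, p in vcf_paths.items():
        paths[f"vcf:{pid[0]}:{pid[1]}"] = p
    return paths


def _false_positive_sites(
    vcf_paths, truth_sites: Sequence[VariantSite]
) -> list[VariantSite]:
    """Sites present in any simulated callset but absent from the truth."""
    from .callset import read_callset

    truth_keys = {(s.chrom, s.pos) for s in truth_sites}
    seen: dict[tuple[str, int], VariantSite] = {}
    for i, path in enumerate(sorted(str(p) for p in vcf_paths)):
        for site in read_callset(path, pipeline_id=f"sim{i}").sites:
            if (site.chrom, site.pos) not in truth_keys:
                seen.setdefault((site.chrom, site.pos), site)
    return [seen[k] for k in sorted(seen)]


def _error_only_counts(cfg: SimConfig, sites: Sequence[VariantSite]) -> list[PoolAlleleCounts]:
    """Pure-error read counts (true allele fraction 0) at the given SNP sites."""
    if not sites:
        return []
    rng = _rng(cfg.seed, 5)
    n = len(sites)
    pf = np.zeros((n, cfg.n_pools))
    ref_idx = np.array([_NT_INDEX[s.ref] for s in sites])
    alt_idx = np.array([_NT_INDEX[s.alts[0]] for s in sites])
    probs = _observed_base_probs(pf, ref_idx, alt_idx, cfg.base_error_rate)
    counts = rng.multinomial(cfg.depth_per_pool, probs)
    out = []
    for i, site in enumerate(sites):
        for p, pool_id in enumerate(cfg.pool_ids):
            out.append(
                PoolAlleleCounts(
                    site.chrom, site.pos, site.ref, site.alts[0], pool_id,
                    {nt: int(counts[i, p, j]) for j, nt in enumerate(NUCLEOTIDES)},
                )
            )
    return out
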
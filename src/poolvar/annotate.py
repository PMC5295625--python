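"""Consequence annotation of variants against gene models.

Coding SNPs are classified by translating the reference and alternative
codons (reverse-complemented on minus-strand transcripts, with the codon
frame taken from CDS phase): synonymous, missense, nonsense (stop gained)
or stop_lost.  Coding indels are frameshift when the net length change is
not a multiple of three, otherwise in-frame deletions/insertions.  SNPs
inside a gene but outside its CDS (introns and untranslated exon
portions) are reported as intron; everything else is intergenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .callset import VariantSite

CAT_SYNONYMOUS = "synonymous"
CAT_MISSENSE = "missense"
CAT_NONSENSE = "nonsense"
CAT_STOP_LOST = "stop_lost"
CAT_INTRON = "intron"
CAT_FRAMESHIFT = "frameshift"
CAT_INFRAME_DEL = "inframe_deletion"
CAT_INFRAME_INS = "inframe_insertion"
CAT_INTERGENIC = "intergenic"

#: most-severe-first ordering used to summarize per variant / per gene
SEVERITY_ORDER = (
    CAT_FRAMESHIFT,
    CAT_NONSENSE,
    CAT_STOP_LOST,
    CAT_MISSENSE,
    CAT_INFRAME_DEL,
    CAT_INFRAME_INS,
    CAT_SYNONYMOUS,
    CAT_INTRON,
    CAT_INTERGENIC,
)

CODING_CATEGORIES = frozenset(SEVERITY_ORDER[:7])


@dataclass(frozen=True)
class Consequence:
    category: str
    gene_id: str = ""
    transcript_id: str = ""
    codon_change: str = ""
    aa_change: str = ""
    alt: str = ""

    @property
    def severity_rank(self) -> int:
        return SEVERITY_ORDER.index(self.category)


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure: exons and phased CDS segments, 1-based inclusive."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int, int], ...]  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.transcript_id}")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.transcript_id}")
            prev_end = e
        for s, e, phase in self.cds_segments:
            if phase not in (0, 1, 2):
                raise ValueError(f"bad CDS phase in {self.transcript_id}")
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"CDS outside exons in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def frame_offset(self) -> int:
        """Phase of the first CDS segment in translation order."""
        if not self.cds_segments:
            return 0
        seg = self.cds_segments[0] if self.strand == "+" else self.cds_segments[-1]
        return seg[2]

    def cds_position(self, pos: int) -> Optional[int]:
        """0-based position within the spliced CDS (translation orientation),
        or None when pos is not inside any CDS segment."""
        seg_idx = None
        for i, (s, e, _) in enumerate(self.cds_segments):
            if s <= pos <= e:
                seg_idx = i
                break
        if seg_idx is None:
            return None
        if self.strand == "+":
            before = sum(e - s + 1 for s, e, _ in self.cds_segments[:seg_idx])
            return before + (pos - self.cds_segments[seg_idx][0])
        after = sum(e - s + 1 for s, e, _ in self.cds_segments[seg_idx + 1:])
        return after + (self.cds_segments[seg_idx][1] - pos)

    def spliced_cds(self, fetch_seq) -> str:
        """Spliced CDS sequence in translation orientation."""
        seq = "".join(fetch_seq(self.chrom, s, e) for s, e, _ in self.cds_segments)
        seq = seq.upper()
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def translate_codon(codon: str) -> str:
    """Standard nuclear-code amino acid (one letter; '*' for stop)."""
    return str(Seq(codon).translate())


def _most_severe(consequences: Sequence[Consequence]) -> Consequence:
    return min(consequences, key=lambda c: c.severity_rank)


def annotate_variant(
    variant: VariantSite,
    models: Sequence[GeneModel],
    fetch_seq,
) -> tuple[list[Consequence], Consequence]:
    """Predict consequences of a variant against every overlapping transcript.

    ``fetch_seq(chrom, start, end)`` returns the 1-based inclusive
    reference sequence.  Returns one consequence per (transcript, alt
    allele) plus the single most severe summary; a variant overlapping no
    transcript yields a single intergenic consequence.
    """
    v_lo, v_hi = variant.ref_span
    out: list[Consequence] = []
    for model in models:
        if model.chrom != variant.chrom:
            continue
        t_lo, t_hi = model.span
        if v_hi < t_lo or v_lo > t_hi:
            continue
        for alt in variant.alts:
            out.append(_annotate_one(variant, alt, model, fetch_seq))
    if not out:
        out = [Consequence(CAT_INTERGENIC, alt=variant.alts[0])]
    return out, _most_severe(out)


def _annotate_one(
    variant: VariantSite, alt: str, model: GeneModel, fetch_seq
) -> Consequence:
    ref = variant.ref
    if len(ref) == 1 and len(alt) == 1:
        return _annotate_snp(variant.pos, ref, alt, model, fetch_seq)
    return _annotate_indel(variant.pos, ref, alt, model)


def _annotate_snp(
    pos: int, ref: str, alt: str, model: GeneModel, fetch_seq
) -> Consequence:
    cds_pos = model.cds_position(pos)
    if cds_pos is None:
        return Consequence(CAT_INTRON, model.gene_id, model.transcript_id, alt=alt)
    offset = model.frame_offset
    eff = cds_pos - offset
    if eff < 0:
        # inside the partial leading codon implied by a nonzero phase
        return Consequence(CAT_INTRON, model.gene_id, model.transcript_id, alt=alt)
    spliced = model.spliced_cds(fetch_seq)
    if (len(spliced) - offset) % 3 != 0:
        raise ValueError(
            f"CDS of {model.transcript_id} is not codon-complete given its phase"
        )
    codon_idx = eff // 3
    within = eff % 3
    codon_start = offset + 3 * codon_idx
    ref_codon = spliced[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return Consequence(CAT_INTRON, model.gene_id, model.transcript_id, alt=alt)
    tx_alt = alt if model.strand == "+" else str(Seq(alt).reverse_complement())
    alt_codon = ref_codon[:within] + tx_alt + ref_codon[within + 1:]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        category = CAT_SYNONYMOUS
    elif alt_aa == "*":
        category = CAT_NONSENSE
    elif ref_aa == "*":
        category = CAT_STOP_LOST
    else:
        category = CAT_MISSENSE
    return Consequence(
        category,
        model.gene_id,
        model.transcript_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{codon_idx + 1}{alt_aa}",
        alt=alt,
    )


def _annotate_indel(pos: int, ref: str, alt: str, model: GeneModel) -> Consequence:
    lo, hi = pos, pos + len(ref) - 1
    in_cds = any(s <= hi and lo <= e for s, e, _ in model.cds_segments)
    if not in_cds:
        t_lo, t_hi = model.span
        if hi < t_lo or lo > t_hi:
            return Consequence(CAT_INTERGENIC, alt=alt)
        return Consequence(CAT_INTRON, model.gene_id, model.transcript_id, alt=alt)
    net = len(alt) - len(ref)
    # affected residue: first coding base touched by the change
    first_changed = pos + 1 if len(ref) > 1 or len(alt) > 1 else pos
    cds_pos = model.cds_position(min(max(first_changed, lo), hi))
    residue = ""
    if cds_pos is not None:
        eff = cds_pos - model.frame_offset
        if eff >= 0:
            residue = str(eff // 3 + 1)
    if net % 3 != 0:
        category = CAT_FRAMESHIFT
        aa_change = f"fs@{residue}" if residue else "fs"
    elif net < 0:
        category = CAT_INFRAME_DEL
        aa_change = f"del{-net // 3}aa@{residue}" if residue else "del"
    elif net > 0:
        category = CAT_INFRAME_INS
        aa_change = f"ins{net // 3}aa@{residue}" if residue else "ins"
    else:
        category = CAT_MISSENSE
        aa_change = f"sub@{residue}" if residue else "sub"
    return Consequence(
        category, model.gene_id, model.transcript_id, aa_change=aa_change, alt=alt
    )


def gene_variant_summary(
    annotated: Iterable[tuple[VariantSite, Sequence[Consequence]]],
    covered_exonic_bp: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene coding-variant counts by category and density per kbp.

    Each variant contributes its most severe consequence per gene; density
    is coding-variant count x 1000 / covered exonic bp.  Genes lacking
    coverage information are omitted with a warning.
    """
    per_gene: dict[str, list[str]] = {}
    for _, consequences in annotated:
        by_gene: dict[str, list[Consequence]] = {}
        for c in consequences:
            if c.gene_id:
                by_gene.setdefault(c.gene_id, []).append(c)
        for gene_id, cons in by_gene.items():
            per_gene.setdefault(gene_id, []).append(_most_severe(cons).category)
    rows = []
    genes = sorted(set(per_gene) | set(covered_exonic_bp))
    for gene_id in genes:
        if gene_id not in covered_exonic_bp:
            warnings.warn(f"gene {gene_id} has no coverage information; omitted")
            continue
        cats = per_gene.get(gene_id, [])
        coding = [c for c in cats if c in CODING_CATEGORIES]
        row = {"gene_id": gene_id}
        for cat in SEVERITY_ORDER:
            row[cat] = sum(1 for c in cats if c == cat)
        row["n_coding"] = len(coding)
        bp = covered_exonic_bp[gene_id]
        row["density_per_kbp"] = len(coding) * 1000.0 / bp if bp > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


def genome_snp_density(n_variants: int, total_bp: float) -> float:
    """Base pairs per variant over a surveyed length."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    return total_bp / n_variants


# ---------------------------------------------------------------------------
# GFF3 input

def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse transcript models (gene -> mRNA -> exon/CDS) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(mrna, featuretype="CDS")
            )
            if not exons:
                exons = [(c[0], c[1]) for c in cds]
            try:
                models.append(
                    GeneModel(
                        gene_id=gene.id,
                        transcript_id=mrna.id,
                        chrom=gene.seqid,
                        strand=mrna.strand,
                        exons=tuple(exons),
                        cds_segments=tuple(cds),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"invalid gene model {mrna.id}: {exc}") from exc
    return models


def fasta_seq_fetcher(fasta_path: str | Path):
    """fetch_seq(chrom, start1, end1) closure over an indexed FASTA."""
    import pysam

    fa = pysam.FastaFile(str(fasta_path))

    def fetch(chrom: str, start1: int, end1: int) -> str:
        return fa.fetch(chrom, start1 - 1, end1)

    return fetch
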
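import textwrap
from pathlib import Path

import pytest

from poolvar.regions import TargetRegion


@pytest.fixture
def write_fasta(tmp_path):
    """Write a {chrom: seq} dict as an uncompressed FASTA and return its path."""

    def _write(reference: dict, name: str = "ref.fa") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, seq in reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        return path

    return _write


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write minimal VCF text from (chrom, pos, ref, alts) records."""

    def _write(records, name="calls.vcf", contigs=None) -> Path:
        path = tmp_path / name
        lines = ["##fileformat=VCFv4.2"]
        for c, ln in (contigs or {}).items():
            lines.append(f"##contig=<ID={c},length={ln}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for chrom, pos, ref, alts in records:
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t.")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def ten_regions():
    """Ten disjoint 600 bp regions on one chromosome."""
    return [
        TargetRegion(f"amp{i:02d}", "chr1", 1000 + i * 1000, 1000 + i * 1000 + 599)
        for i in range(10)
    ]
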
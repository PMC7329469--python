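"""Shared fixtures: hand-written VCF/PED text and record builders.

VCF fixtures for reader tests are raw strings (not produced by the package's
own writer) so parsing is checked against independently constructed input.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from varobs.formats_io import Individual, Pedigree
from varobs.variant_model import (
    Category,
    GenotypeCall,
    VariantRecord,
    categorize,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_raw_vcf(path: Path, body_lines: list[str], samples: list[str]) -> Path:
    contigs = sorted({line.split("\t")[0] for line in body_lines})
    header = VCF_HEADER + "".join(f"##contig=<ID={c}>\n" for c in contigs)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT", *samples]
    text = header + "\t".join(cols) + "\n"
    if body_lines:
        text += "\n".join(body_lines) + "\n"
    path.write_text(text)
    return path


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    info=None,
    genotypes=None,
) -> VariantRecord:
    """Build a VariantRecord; genotypes maps sample -> ("0/1", gq)."""
    info = dict(info or {})
    calls = {}
    for sample, (gt, gq) in (genotypes or {"S1": ("0/1", 99)}).items():
        sep = "|" if "|" in gt else "/"
        calls[sample] = GenotypeCall(tuple(gt.split(sep)), gq)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        info=info,
        genotypes=calls,
        category=categorize(ref, alt, info),
    )


def singleton_ped(case_id: str = "F1", ind_id: str = "S1") -> Pedigree:
    return Pedigree(case_id, [Individual(ind_id, None, None, "1", "2")])


def trio_ped(case_id: str = "F1") -> Pedigree:
    return Pedigree(
        case_id,
        [
            Individual("FA", None, None, "1", "1"),
            Individual("MO", None, None, "2", "1"),
            Individual("CH", "FA", "MO", "1", "2"),
        ],
    )


@pytest.fixture
def tmp_vcf(tmp_path):
    def _write(body_lines, samples=("S1",), name="input.vcf"):
        return write_raw_vcf(tmp_path / name, body_lines, list(samples))

    return _write


@pytest.fixture
def trio():
    return trio_ped()


@pytest.fixture
def singleton():
    return singleton_ped()
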
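"""VCF and PED input/output.

Reading goes through cyvcf2 (htslib); the decomposition precondition —
exactly one alternative allele per record — is enforced, never repaired,
because silent in-place splitting would hide non-normalized alleles from the
upstream pipeline.  Writing is a minimal deterministic text emitter so that
annotation can pass untouched records through byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from cyvcf2 import VCF

from .variant_model import (
    Category,
    GenotypeCall,
    VariantRecord,
    categorize,
)

logger = logging.getLogger(__name__)


class VcfError(ValueError):
    """Malformed or non-decomposed VCF input."""


class PedError(ValueError):
    """Malformed PED input."""


@dataclass(frozen=True)
class Individual:
    ind_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    affected: str


@dataclass
class Pedigree:
    """One family (case) parsed from a PLINK 6-column PED file."""

    case_id: str
    individuals: list[Individual] = field(default_factory=list)

    @property
    def ind_ids(self) -> list[str]:
        return [ind.ind_id for ind in self.individuals]

    def dangling_parents(self) -> list[str]:
        """Parent ids referenced but not present as individuals (allowed)."""
        present = set(self.ind_ids)
        out = []
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in present:
                    out.append(pid)
        return out


_MISSING_PARENT = {"0", "", ".", "-9"}


def read_ped(path: str | Path, case_id: Optional[str] = None) -> Pedigree:
    """Parse a whitespace-delimited 6+ column PED file into one Pedigree.

    All rows must share one family id unless ``case_id`` overrides it.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedError(
                    f"{path}: line {lineno} has {len(cols)} columns, expected >= 6"
                )
            rows.append(cols)
    if not rows:
        raise PedError(f"{path}: no individuals found")

    family_ids = sorted({r[0] for r in rows})
    if case_id is None:
        if len(family_ids) > 1:
            raise PedError(
                f"{path}: multiple family ids {family_ids}; "
                "pass an explicit case id to override"
            )
        case_id = family_ids[0]

    individuals = []
    seen = set()
    for cols in rows:
        ind_id = cols[1]
        if ind_id in seen:
            raise PedError(f"{path}: duplicate individual id {ind_id!r}")
        seen.add(ind_id)
        father = None if cols[2] in _MISSING_PARENT else cols[2]
        mother = None if cols[3] in _MISSING_PARENT else cols[3]
        individuals.append(Individual(ind_id, father, mother, cols[4], cols[5]))
    ped = Pedigree(case_id=case_id, individuals=individuals)
    dangling = ped.dangling_parents()
    if dangling:
        logger.warning(
            "pedigree %s references absent parents: %s", case_id, dangling
        )
    return ped


def _call_from_cyvcf2(gt_row: list, gq: float) -> GenotypeCall:
    # cyvcf2 genotype rows are [allele, allele, phased] (last entry bool);
    # haploid rows are [allele, phased].
    alleles = []
    for a in gt_row[:-1]:
        if a < 0:
            alleles.append(".")
        elif a == 0:
            alleles.append("0")
        else:
            # decomposed input: any non-reference index is the single ALT
            alleles.append("1")
    gq_int = None if gq is None or gq < 0 else int(gq)
    return GenotypeCall(alleles=tuple(alleles), gq=gq_int)


def read_vcf(
    path: str | Path,
    mode: str = "auto",
    skip_bad_records: bool = False,
) -> Iterator[VariantRecord]:
    """Stream decomposed VariantRecords from a VCF (plain or bgzipped).

    ``mode`` forces the small-variant ("snv") or structural ("sv") dialect or
    detects per record ("auto"); in forced modes a record of the other kind
    is a :class:`VcfError`.  Multi-allelic lines are rejected (or logged and
    skipped with ``skip_bad_records``) — input must be decomposed upstream.
    """
    if mode not in {"snv", "sv", "auto"}:
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # htslib reports malformed headers this way
        raise VcfError(f"{path}: cannot parse VCF header: {exc}") from exc

    for variant in vcf:
        where = f"{path}: {variant.CHROM}:{variant.POS}"
        alts = variant.ALT
        if len(alts) != 1:
            msg = (
                f"{where} carries {len(alts)} ALT alleles ({','.join(alts)}); "
                "input must be decomposed into single alternative alleles"
            )
            if skip_bad_records:
                logger.warning("skipping: %s", msg)
                continue
            raise VcfError(msg)
        alt = alts[0]
        info = {}
        for key, value in variant.INFO:
            if isinstance(value, tuple) and len(value) == 1:
                value = value[0]
            info[key] = value

        category = categorize(variant.REF, alt, info)
        if mode == "snv" and category is Category.SV:
            msg = f"{where} is a structural variant in snv-mode input"
            if skip_bad_records:
                logger.warning("skipping: %s", msg)
                continue
            raise VcfError(msg)
        if mode == "sv" and category is not Category.SV:
            msg = f"{where} is a small variant in sv-mode input"
            if skip_bad_records:
                logger.warning("skipping: %s", msg)
                continue
            raise VcfError(msg)

        gqs = variant.gt_quals if samples else []
        gts = variant.genotypes if samples else []
        genotypes = {
            sample: _call_from_cyvcf2(gts[i], gqs[i] if len(gqs) > i else -1)
            for i, sample in enumerate(samples)
        }
        yield VariantRecord(
            chrom=variant.CHROM,
            pos=variant.POS,
            ref=variant.REF,
            alt=alt,
            info=info,
            genotypes=genotypes,
            category=category,
        )


def format_info(info: dict) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is True:
            parts.append(key)
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


@dataclass
class OutputRecord:
    """One body line for the text VCF writer."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict = field(default_factory=dict)
    record_id: str = "."
    qual: str = "."
    filter: str = "."
    format: Optional[str] = None
    sample_fields: Sequence[str] = ()


def write_vcf(
    records: Iterable[OutputRecord],
    path: str | Path,
    info_defs: Sequence[tuple[str, str, str, str]] = (),
    contigs: Sequence[str] = (),
    samples: Sequence[str] = (),
    extra_header_lines: Sequence[str] = (),
    format_defs: Sequence[tuple[str, str, str, str]] = (),
) -> None:
    """Write a deterministic VCF 4.2 file.

    ``info_defs``/``format_defs`` are (ID, Number, Type, Description) tuples;
    every INFO key used by a record must be declared.
    """
    declared = {d[0] for d in info_defs}
    lines = ["##fileformat=VCFv4.2"]
    lines.extend(extra_header_lines)
    for cid, number, vtype, desc in info_defs:
        lines.append(
            f'##INFO=<ID={cid},Number={number},Type={vtype},Description="{desc}">'
        )
    for cid, number, vtype, desc in format_defs:
        lines.append(
            f'##FORMAT=<ID={cid},Number={number},Type={vtype},Description="{desc}">'
        )
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT", *samples]
    lines.append("\t".join(header_cols))

    for rec in records:
        undeclared = set(rec.info) - declared
        if undeclared:
            raise VcfError(
                f"record {rec.chrom}:{rec.pos} uses undeclared INFO "
                f"key(s) {sorted(undeclared)}"
            )
        cols = [
            rec.chrom,
            str(rec.pos),
            rec.record_id,
            rec.ref,
            rec.alt,
            rec.qual,
            rec.filter,
            format_info(rec.info),
        ]
        if samples:
            cols.append(rec.format or "GT")
            cols.extend(rec.sample_fields)
        lines.append("\t".join(cols))

    Path(path).write_text("\n".join(lines) + "\n")
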
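"""Canonical variant identity and structural-variant endpoint geometry.

Small variants (SNV/INDEL) are identified by an exact string key built from
chromosome, position, reference and alternative allele.  Structural variants
are reduced to an SV type plus two endpoint coordinates (position A and
position B); an interchromosomal event has, by definition, infinite length.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

#: Sentinel length of an interchromosomal variant.
INFINITE = math.inf

KEY_SEPARATOR = "_"

_BND_RE = re.compile(
    r"^(?P<leading>[A-Za-z.]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>[0-9]+)(?P<b2>[\[\]])"
    r"(?P<trailing>[A-Za-z.]*)$"
)
_SYMBOLIC_RE = re.compile(r"^<(?P<name>[^<>]+)>$")


class Category(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SV = "SV"


class VariantModelError(ValueError):
    """Raised for records that violate the variant model's preconditions."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call on a decomposed record.

    ``alleles`` holds string allele indices over {"0", "1", "."}; a haploid
    call has a single entry.  ``gq`` is the FORMAT/GQ value, or ``None`` when
    the caller reported none.
    """

    alleles: tuple[str, ...]
    gq: Optional[int] = None

    @property
    def has_alt(self) -> bool:
        return "1" in self.alleles

    @property
    def is_hom_alt(self) -> bool:
        # Hemizygous calls written "1" are NOT homozygous; only a literal 1/1
        # counts (no ploidy inference).
        return self.alleles == ("1", "1")


@dataclass
class VariantRecord:
    """One decomposed VCF line with per-individual genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    category: Category = Category.SNV

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantModelError(f"pos must be >= 1, got {self.pos}")
        if not self.alt or "," in self.alt:
            raise VariantModelError(
                f"record {self.chrom}:{self.pos} must carry exactly one ALT "
                f"(got {self.alt!r}); input is not decomposed"
            )
        if not self.ref and not is_sv_alt(self.alt, self.info):
            raise VariantModelError(
                f"record {self.chrom}:{self.pos} has an empty REF"
            )


@dataclass(frozen=True)
class SvCoordinates:
    """SV type plus endpoint pair.

    ``pos_a`` is always on the chromosome that sorts first (for
    interchromosomal events) or is the smaller position (intrachromosomal);
    ``length`` is inclusive of both endpoints, and ``INFINITE`` for
    interchromosomal variants.
    """

    sv_type: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    length: float

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            if self.pos_a > self.pos_b:
                raise VariantModelError(
                    "intrachromosomal SV requires pos_a <= pos_b"
                )
        elif not math.isinf(self.length):
            raise VariantModelError("interchromosomal SV must have INFINITE length")

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Deterministic chromosome ordering: 1..22, X, Y, MT, then others
    lexicographically.  Tolerates a "chr" prefix."""
    stripped = name[3:] if name.lower().startswith("chr") else name
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if stripped.isdigit():
        return (0, int(stripped), "")
    if stripped.upper() in special:
        return (0, special[stripped.upper()], "")
    return (1, 0, name)


def is_breakend(alt: str) -> bool:
    return bool(_BND_RE.match(alt))


def is_symbolic(alt: str) -> bool:
    return bool(_SYMBOLIC_RE.match(alt))


def is_sv_alt(alt: str, info: Mapping | None = None) -> bool:
    """A record is an SV iff its ALT is symbolic or break-end notation, or
    INFO declares SVTYPE."""
    if is_symbolic(alt) or is_breakend(alt):
        return True
    return info is not None and "SVTYPE" in info


def categorize(ref: str, alt: str, info: Mapping | None = None) -> Category:
    if is_sv_alt(alt, info):
        return Category.SV
    if len(ref) == 1 and len(alt) == 1:
        return Category.SNV
    return Category.INDEL


def snv_key(record: VariantRecord) -> str:
    """Canonical document id for a small variant: chrom_pos_ref_alt.

    A separator is used because raw concatenation is ambiguous
    ("1" + "2300..." vs "12" + "300...").
    """
    if record.category is Category.SV:
        raise VariantModelError(
            f"snv_key is undefined for SV record {record.chrom}:{record.pos}"
        )
    return KEY_SEPARATOR.join(
        (record.chrom, str(record.pos), record.ref, record.alt)
    )


def _info_int(info: Mapping, key: str) -> Optional[int]:
    value = info.get(key)
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0]
    return int(value)


def parse_breakend(alt: str) -> tuple[str, int]:
    """Mate chromosome and 1-based position from a break-end ALT."""
    m = _BND_RE.match(alt)
    if m is None:
        raise VariantModelError(f"unparseable break-end ALT {alt!r}")
    return m.group("chrom"), int(m.group("pos"))


def sv_coordinates(record: VariantRecord) -> SvCoordinates:
    """Reduce an SV record to its type and endpoint pair.

    Position A comes from CHROM/POS.  Position B comes from the break-end
    mate in the ALT column, or from INFO/END, or from POS + |SVLEN|.
    Insertions with no END collapse to a point (pos_b == pos_a) and take
    their length from |SVLEN|.  Break-end types are normalized to "BND";
    mate orientation is not part of cluster identity.
    """
    if record.category is not Category.SV:
        raise VariantModelError(
            f"sv_coordinates is undefined for {record.category.value} record "
            f"{record.chrom}:{record.pos}"
        )
    chrom, pos = record.chrom, record.pos
    alt = record.alt

    if is_breakend(alt):
        mate_chrom, mate_pos = parse_breakend(alt)
        if mate_chrom == chrom:
            a, b = sorted((pos, mate_pos))
            return SvCoordinates("BND", chrom, a, chrom, b, float(b - a + 1))
        # Order the chromosome pair deterministically; paired records of the
        # same adjacency then normalize to identical coordinates.
        if chrom_sort_key(chrom) <= chrom_sort_key(mate_chrom):
            return SvCoordinates("BND", chrom, pos, mate_chrom, mate_pos, INFINITE)
        return SvCoordinates("BND", mate_chrom, mate_pos, chrom, pos, INFINITE)

    if is_symbolic(alt):
        name = _SYMBOLIC_RE.match(alt).group("name")
        sv_type = name.split(":")[0].upper()
    else:
        sv_type = str(record.info.get("SVTYPE", "")).upper()
        if not sv_type:
            raise VariantModelError(
                f"cannot derive SV type for {chrom}:{pos} ALT {alt!r}"
            )

    end = _info_int(record.info, "END")
    svlen = _info_int(record.info, "SVLEN")

    if sv_type == "INS" and end is None:
        if svlen is None:
            raise VariantModelError(
                f"insertion at {chrom}:{pos} has neither END nor SVLEN"
            )
        return SvCoordinates("INS", chrom, pos, chrom, pos, float(abs(svlen)))

    if end is None:
        if svlen is None:
            raise VariantModelError(
                f"symbolic SV at {chrom}:{pos} has neither END nor SVLEN"
            )
        end = pos + abs(svlen)
    if end < pos:
        raise VariantModelError(
            f"SV at {chrom}:{pos} has END {end} before POS"
        )
    return SvCoordinates(sv_type, chrom, pos, chrom, end, float(end - pos + 1))
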
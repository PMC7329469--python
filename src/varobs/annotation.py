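"""Decorate query VCFs with local observation counts and export the store.

Two interoperability surfaces, mirroring how a local frequency database is
consumed downstream:

* ``annotate_vcf`` — stream a query VCF through the store, adding
  ``Obs``/``Hom``/``Frq`` INFO fields to every record with a database hit.
  Small variants hit by exact key lookup; structural variants hit by the
  same read-only interval matching used at load time.  Records without a
  hit pass through byte-identical; the store is never mutated.
* ``export_vcf`` — emit the whole database as a frequency VCF (one line per
  small-variant observation at its true coordinates; one line per SV
  cluster at its rounded mean endpoints) for use with external annotation
  tools such as vcfanno.

``Frq`` is observation count over total cases in the store — a per-case
observation frequency, not an allele frequency — printed to 4 significant
digits.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path

from .formats_io import OutputRecord, write_vcf
from .observation_store import ObservationStore
from .variant_model import (
    Category,
    VariantRecord,
    categorize,
    chrom_sort_key,
    snv_key,
    sv_coordinates,
)

INFO_DEFS = (
    ("Obs", "1", "Integer", "Number of cases in the local database with this variant"),
    ("Hom", "1", "Integer", "Number of those cases with a homozygous-alternative call"),
    ("Frq", "1", "Float", "Obs divided by the total number of cases in the database"),
)
SV_EXTRA_INFO_DEFS = (
    ("SVTYPE", "1", "String", "Structural variant type of the cluster"),
    ("END", "1", "Integer", "Rounded mean end position of the cluster"),
    ("CHR2", "1", "String", "Mate chromosome for interchromosomal clusters"),
    ("PadBp", "1", "Integer", "Fixed endpoint padding interval of the cluster (bp)"),
)


@dataclass
class AnnotateReport:
    n_records: int = 0
    n_annotated_snv: int = 0
    n_annotated_sv: int = 0


def _format_frq(frequency: float) -> str:
    return f"{frequency:.4g}"


def _parse_info_text(text: str) -> dict:
    info: dict = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = value
        else:
            info[item] = True
    return info


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def annotate_vcf(
    query: str | Path, store: ObservationStore, out: str | Path
) -> AnnotateReport:
    """Annotate every record of ``query`` that the store knows about.

    Operates line-wise on the VCF text so untouched records are passed
    through byte-identical; only matched records gain INFO fields, and the
    header gains their definitions plus the database size.  Purely
    per-record, so unsorted input and undeclared contigs are handled
    permissively.
    """
    report = AnnotateReport()
    out_lines: list[str] = []
    header_extras = [
        f'##INFO=<ID={i},Number={n},Type={t},Description="{d}">'
        for i, n, t, d in INFO_DEFS
    ]
    header_extras.append(f"##varobs_nCases={store.n_cases}")

    saw_header = False
    with _open_text(Path(query)) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if line.startswith("##"):
                out_lines.append(line)
                continue
            if line.startswith("#CHROM"):
                out_lines.extend(header_extras)
                out_lines.append(line)
                saw_header = True
                continue
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{query}: malformed VCF body line: {line[:80]!r}"
                )
            chrom, pos, _, ref, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            if "," in alt:
                raise ValueError(
                    f"{query}: {chrom}:{pos} is multi-allelic; "
                    "annotation requires decomposed input"
                )
            info = _parse_info_text(cols[7])
            category = categorize(ref, alt, info)
            record = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, info=info, category=category
            )
            report.n_records += 1

            hit = None
            if category is Category.SV:
                hit = store.query_sv(sv_coordinates(record))
                if hit is not None:
                    report.n_annotated_sv += 1
            else:
                obs = store.get_observation(snv_key(record))
                if obs is not None:
                    hit = {
                        "obs_count": obs.obs_count,
                        "hom_count": obs.hom_count,
                        "frequency": obs.obs_count / store.n_cases,
                    }
                    report.n_annotated_snv += 1

            if hit is not None:
                extra = (
                    f"Obs={hit['obs_count']};Hom={hit['hom_count']};"
                    f"Frq={_format_frq(hit['frequency'])}"
                )
                cols[7] = extra if cols[7] in (".", "") else cols[7] + ";" + extra
                out_lines.append("\t".join(cols))
            else:
                out_lines.append(line)
    if not saw_header:
        raise ValueError(f"{query}: no #CHROM header line")
    Path(out).write_text("\n".join(out_lines) + "\n")
    return report


def _round_half_down(x: float) -> int:
    """Mean endpoint positions ending in .5 round down (documented choice)."""
    return int(math.ceil(x - 0.5))


def export_vcf(store: ObservationStore, out: str | Path, which: str) -> int:
    """Export the database as a frequency VCF; returns lines written.

    ``which`` is "snv" (one line per observed small variant at its true
    coordinates) or "sv" (one line per cluster centroid — clusters, not
    member calls, are the unit of SV frequency).  An empty store yields a
    valid header-only file.
    """
    if which not in {"snv", "sv"}:
        raise ValueError(f"which must be 'snv' or 'sv', got {which!r}")
    n_cases = store.n_cases
    rank = {c: i for i, c in enumerate(store.contig_order)}

    def contig_rank(chrom: str):
        return (rank.get(chrom, len(rank)), chrom_sort_key(chrom))

    records: list[OutputRecord] = []
    contigs: set[str] = set()
    if which == "snv":
        info_defs = INFO_DEFS
        for obs in sorted(
            store.snvs.values(), key=lambda o: (contig_rank(o.chrom), o.pos, o.ref, o.alt)
        ):
            contigs.add(obs.chrom)
            records.append(
                OutputRecord(
                    chrom=obs.chrom,
                    pos=obs.pos,
                    ref=obs.ref,
                    alt=obs.alt,
                    info={
                        "Obs": obs.obs_count,
                        "Hom": obs.hom_count,
                        "Frq": _format_frq(obs.obs_count / n_cases),
                    },
                )
            )
    else:
        info_defs = INFO_DEFS + SV_EXTRA_INFO_DEFS
        clusters = sorted(
            store.sv_clusters.clusters.values(),
            key=lambda c: (contig_rank(c.chrom_a), c.mean_a, c.sv_type, c.cluster_id),
        )
        for c in clusters:
            contigs.update((c.chrom_a, c.chrom_b))
            info = {
                "SVTYPE": c.sv_type,
                "END": _round_half_down(c.mean_b),
                "PadBp": c.interval_bp,
                "Obs": c.obs_count,
                "Hom": c.hom_count,
                "Frq": _format_frq(c.obs_count / n_cases),
            }
            if c.chrom_b != c.chrom_a:
                info["CHR2"] = c.chrom_b
            records.append(
                OutputRecord(
                    chrom=c.chrom_a,
                    pos=_round_half_down(c.mean_a),
                    ref="N",
                    alt=f"<{c.sv_type}>",
                    record_id=c.cluster_id,
                    info=info,
                )
            )

    write_vcf(
        records,
        out,
        info_defs=info_defs,
        contigs=sorted(contigs, key=contig_rank),
        extra_header_lines=[
            f"##varobs_nCases={n_cases}",
            f"##varobs_parameters={store.parameters()!r}".replace(" ", ""),
        ],
    )
    return len(records)
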
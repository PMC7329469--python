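"""Synthetic family cohorts with controlled sharing structure.

The generator emulates the inputs a local observations database sees in a
rare-disease lab: per-family VCF+PED uploads containing

* *common* SNVs drawn from a shared site panel whose population frequencies
  follow a truncated power-law (a neutral-spectrum-like excess of rare
  alleles), genotyped per individual under Hardy-Weinberg with Mendelian
  trios,
* *private* SNVs unique to each case,
* *recurrent* SV calls at shared loci whose breakpoints are jittered
  uniformly within a fraction of the locus padding interval — mimicking
  caller imprecision — plus private SVs,
* per-genotype GQ values, mostly high with a small low-quality fraction, so
  the loading GQ gate is exercised.

A truth table records every site's true frequency and every recurrent SV's
true cluster, so database counts and cluster recovery can be checked against
ground truth.  The ``size_experiment`` harness rebuilds databases of
increasing size from disjoint case subsets and measures how much of a
held-out case's variation a common-variant frequency filter removes — the
qualitative size-versus-filtering relationship, at desk scale.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import Individual, OutputRecord, Pedigree, write_vcf
from .observation_store import ObservationStore
from .sv_clustering import PaddingPolicy, padding_interval
from .variant_model import (
    Category,
    GenotypeCall,
    SvCoordinates,
    VariantRecord,
    snv_key,
    sv_coordinates,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale stand-ins for a WGS cohort: a few hundred shared
    SNV sites with a rare-skewed frequency spectrum, a handful of private
    variants per case, and a dozen recurrent SV loci with noisy breakpoints.
    """

    n_common_snv: int = 500
    n_private_snv_per_case: int = 20
    n_recurrent_sv: int = 30
    n_private_sv: int = 3
    sv_jitter_frac: float = 0.25  # breakpoint jitter, fraction of locus padding
    af_exponent: float = 1.0  # site-frequency density ~ f^-exponent
    af_min: float = 0.005
    af_max: float = 0.5
    # per-case carriage probability of recurrent SV loci, same spectrum
    # shape; extends below 1/200 so databases of a few hundred cases still
    # gain filtering power (the logarithmic-relationship regime)
    sv_carrier_min: float = 0.01
    sv_carrier_max: float = 0.8
    trio_fraction: float = 0.2
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    low_gq_frac: float = 0.05  # fraction of calls with GQ in [2, 15]
    hom_sv_frac: float = 0.15
    sv_policy: PaddingPolicy = field(default_factory=PaddingPolicy)


@dataclass
class SyntheticCase:
    case_id: str
    pedigree: Pedigree
    snv_records: list[VariantRecord]
    sv_records: list[VariantRecord]

    @property
    def records(self) -> list[VariantRecord]:
        return self.snv_records + self.sv_records


@dataclass
class Cohort:
    params: CohortParams
    seed: int
    cases: list[SyntheticCase]
    snv_truth: pd.DataFrame  # site, chrom, pos, ref, alt, true_f, is_private
    sv_truth: pd.DataFrame  # truth_id, sv_type, chrom, start, end, length, pad

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    def case(self, case_id: str) -> SyntheticCase:
        return next(c for c in self.cases if c.case_id == case_id)


def sample_site_frequencies(
    n: int, exponent: float, f_min: float, f_max: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw site frequencies with density proportional to f^-exponent on
    [f_min, f_max], by inverse-CDF sampling."""
    if not 0 < f_min < f_max <= 1:
        raise ValueError("need 0 < f_min < f_max <= 1")
    u = rng.random(n)
    if abs(exponent - 1.0) < 1e-12:
        return f_min * (f_max / f_min) ** u
    a = 1.0 - exponent
    return (f_min**a + u * (f_max**a - f_min**a)) ** (1.0 / a)


def _draw_gq(rng: np.random.Generator, params: CohortParams) -> int:
    """Mostly confident calls (clipped normal, always above the default
    gate), with a low-GQ tail that never passes it."""
    if rng.random() < params.low_gq_frac:
        return int(rng.integers(2, 16))
    return int(np.clip(rng.normal(params.gq_mean, params.gq_sd), 21, 99))


def _hw_genotype(f: float, rng: np.random.Generator) -> tuple[str, str]:
    u = rng.random()
    if u < f * f:
        return ("1", "1")
    if u < f * f + 2 * f * (1 - f):
        return ("0", "1")
    return ("0", "0")


def _child_genotype(
    father: tuple[str, str], mother: tuple[str, str], rng: np.random.Generator
) -> tuple[str, str]:
    return tuple(sorted((father[rng.integers(2)], mother[rng.integers(2)])))


def generate_cohort(
    n_cases: int,
    params: CohortParams = CohortParams(),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> Cohort:
    """Generate a cohort of ``n_cases`` family cases, optionally writing one
    VCF pair + PED per case (plus truth tables) to ``out_dir``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)

    # ---- shared SNV site panel
    site_f = sample_site_frequencies(
        params.n_common_snv, params.af_exponent, params.af_min, params.af_max, rng
    )
    common_sites = []
    for i in range(params.n_common_snv):
        chrom = str(i % 22 + 1)
        pos = 1_000_000 + (i // 22) * 1500 + (i % 22)  # spread over a grid
        ref = _BASES[rng.integers(4)]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        common_sites.append((chrom, pos, ref, alt, float(site_f[i])))

    # ---- recurrent SV loci, spaced far beyond any padding interval
    sv_types = ["DEL", "DUP", "INV"]
    carrier_ps = sample_site_frequencies(
        params.n_recurrent_sv,
        params.af_exponent,
        params.sv_carrier_min,
        params.sv_carrier_max,
        rng,
    )
    sv_loci = []
    for r in range(params.n_recurrent_sv):
        chrom = str(r % 22 + 1)
        start = 10_000_000 + (r // 22) * 2_000_000
        length = int(np.exp(rng.uniform(np.log(1_000), np.log(50_000))))
        end = start + length - 1
        truth_sv = SvCoordinates(
            sv_types[r % 3], chrom, start, chrom, end, float(length)
        )
        pad = padding_interval(truth_sv, params.sv_policy)
        carrier_p = float(carrier_ps[r])
        sv_loci.append(
            {
                "truth_id": f"sv_{r}",
                "sv_type": truth_sv.sv_type,
                "chrom": chrom,
                "start": start,
                "end": end,
                "length": length,
                "pad": pad,
                "carrier_p": carrier_p,
            }
        )

    private_pos = 60_000_000  # allocator for globally unique private sites
    cases: list[SyntheticCase] = []
    snv_truth_rows = []
    for chrom, pos, ref, alt, f in common_sites:
        snv_truth_rows.append(
            {
                "site": f"{chrom}_{pos}_{ref}_{alt}",
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "true_f": f,
                "is_private": False,
            }
        )

    for c in range(n_cases):
        case_id = f"case_{c:03d}"
        is_trio = rng.random() < params.trio_fraction
        if is_trio:
            members = [f"{case_id}_fa", f"{case_id}_mo", f"{case_id}_ch"]
            individuals = [
                Individual(members[0], None, None, "1", "1"),
                Individual(members[1], None, None, "2", "1"),
                Individual(members[2], members[0], members[1], "1", "2"),
            ]
        else:
            members = [f"{case_id}_ind"]
            individuals = [Individual(members[0], None, None, "1", "2")]
        pedigree = Pedigree(case_id, individuals)

        snv_records: list[VariantRecord] = []
        for chrom, pos, ref, alt, f in common_sites:
            if is_trio:
                fa = _hw_genotype(f, rng)
                mo = _hw_genotype(f, rng)
                ch = _child_genotype(fa, mo, rng)
                gts = dict(zip(members, (fa, mo, ch)))
            else:
                gts = {members[0]: _hw_genotype(f, rng)}
            if not any("1" in g for g in gts.values()):
                continue
            genotypes = {
                s: GenotypeCall(g, _draw_gq(rng, params)) for s, g in gts.items()
            }
            snv_records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    genotypes=genotypes,
                    category=Category.SNV if len(ref) == len(alt) == 1 else Category.INDEL,
                )
            )

        for _ in range(params.n_private_snv_per_case):
            chrom = str(int(rng.integers(1, 23)))
            pos, private_pos = private_pos, private_pos + 10
            ref = _BASES[rng.integers(4)]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            carrier = members[int(rng.integers(len(members)))]
            genotypes = {
                s: GenotypeCall(
                    ("0", "1") if s == carrier else ("0", "0"),
                    _draw_gq(rng, params),
                )
                for s in members
            }
            snv_records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    genotypes=genotypes, category=Category.SNV,
                )
            )
            snv_truth_rows.append(
                {
                    "site": f"{chrom}_{pos}_{ref}_{alt}",
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "true_f": 1.0 / n_cases,
                    "is_private": True,
                }
            )

        sv_records: list[VariantRecord] = []

        def _sv_record(sv_type, chrom, start, end, length, hom):
            gt = ("1", "1") if hom else ("0", "1")
            genotypes = {
                s: GenotypeCall(gt if s == members[-1] else ("0", "0"), 60)
                for s in members
            }
            return VariantRecord(
                chrom=chrom,
                pos=start,
                ref="N",
                alt=f"<{sv_type}>",
                info={"SVTYPE": sv_type, "END": end, "SVLEN": length},
                genotypes=genotypes,
                category=Category.SV,
            )

        for locus in sv_loci:
            if rng.random() >= locus["carrier_p"]:
                continue
            j = params.sv_jitter_frac * locus["pad"]
            start = locus["start"] + int(round(rng.uniform(-j, j)))
            end = locus["end"] + int(round(rng.uniform(-j, j)))
            if end < start:
                start, end = end, start
            hom = rng.random() < params.hom_sv_frac
            sv_records.append(
                _sv_record(
                    locus["sv_type"], locus["chrom"], start, end,
                    end - start + 1, hom,
                )
            )

        for _ in range(params.n_private_sv):
            chrom = str(int(rng.integers(1, 23)))
            start, private_pos = private_pos, private_pos + 500_000
            length = int(np.exp(rng.uniform(np.log(1_000), np.log(50_000))))
            sv_records.append(
                _sv_record(
                    sv_types[int(rng.integers(3))], chrom, start,
                    start + length - 1, length, False,
                )
            )

        cases.append(SyntheticCase(case_id, pedigree, snv_records, sv_records))

    cohort = Cohort(
        params=params,
        seed=seed,
        cases=cases,
        snv_truth=pd.DataFrame(snv_truth_rows),
        sv_truth=pd.DataFrame(sv_loci),
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _sample_field(call: GenotypeCall) -> str:
    gt = "/".join(call.alleles)
    gq = "." if call.gq is None else str(call.gq)
    return f"{gt}:{gq}"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write one SNV VCF, one SV VCF and one PED per case, plus truth
    tables, as plain deterministic text (no timestamps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    info_defs = (
        ("SVTYPE", "1", "String", "Structural variant type"),
        ("END", "1", "Integer", "End position"),
        ("SVLEN", "1", "Integer", "Variant length"),
    )
    format_defs = (
        ("GT", "1", "String", "Genotype"),
        ("GQ", "1", "Integer", "Genotype quality"),
    )
    for case in cohort.cases:
        samples = case.pedigree.ind_ids
        for kind, records in (("snv", case.snv_records), ("sv", case.sv_records)):
            rows = [
                OutputRecord(
                    chrom=r.chrom,
                    pos=r.pos,
                    ref=r.ref,
                    alt=r.alt,
                    info=dict(r.info),
                    format="GT:GQ",
                    sample_fields=[_sample_field(r.genotypes[s]) for s in samples],
                )
                for r in records
            ]
            contigs = sorted(
                {r.chrom for r in records}, key=lambda c: (len(c), c)
            )
            write_vcf(
                rows,
                out_dir / f"{case.case_id}.{kind}.vcf",
                info_defs=info_defs,
                contigs=contigs,
                samples=samples,
                format_defs=format_defs,
            )
        ped_lines = [
            "\t".join(
                (
                    case.case_id,
                    ind.ind_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    ind.sex,
                    ind.affected,
                )
            )
            for ind in case.pedigree.individuals
        ]
        (out_dir / f"{case.case_id}.ped").write_text("\n".join(ped_lines) + "\n")
    cohort.snv_truth.to_csv(out_dir / "snv_truth.tsv", sep="\t", index=False)
    cohort.sv_truth.to_csv(out_dir / "sv_truth.tsv", sep="\t", index=False)


def build_store(
    cohort: Cohort,
    case_ids: Optional[Sequence[str]] = None,
    gq_threshold: int = 0,
) -> ObservationStore:
    """Load a subset of cohort cases into a fresh store.

    The default threshold 0 loads everything; pass 20 to exercise the GQ
    gate as at the CLI.
    """
    store = ObservationStore(
        gq_threshold=gq_threshold, sv_policy=cohort.params.sv_policy
    )
    wanted = cohort.case_ids if case_ids is None else list(case_ids)
    by_id = {c.case_id: c for c in cohort.cases}
    for case_id in wanted:
        case = by_id[case_id]
        store.load_case(case.records, case.pedigree, gq_threshold=gq_threshold)
    return store


def _case_filtered_fractions(
    case: SyntheticCase, store: ObservationStore, af_cutoff: float
) -> tuple[float, float]:
    """Fraction of this case's SNV and SV lines at or above the frequency
    cutoff in the store (i.e. removed by a common-variant filter)."""
    n = store.n_cases

    def frq_snv(record):
        obs = store.get_observation(snv_key(record))
        return 0.0 if obs is None else obs.obs_count / n

    def frq_sv(record):
        hit = store.query_sv(sv_coordinates(record))
        return 0.0 if hit is None else hit["frequency"]

    snvs = case.snv_records
    svs = case.sv_records
    f_snv = (
        sum(1 for r in snvs if frq_snv(r) >= af_cutoff) / len(snvs) if snvs else 0.0
    )
    f_sv = sum(1 for r in svs if frq_sv(r) >= af_cutoff) / len(svs) if svs else 0.0
    return f_snv, f_sv


def size_experiment(
    cohort: Cohort,
    db_sizes: Sequence[int],
    test_cases: Sequence[str],
    af_cutoff: float = 0.01,
    n_replicates: int = 20,
    seed: int = 0,
    paired: bool = True,
) -> pd.DataFrame:
    """Measure common-variant filtering power versus database size.

    For every size and replicate, a database is built from a random subset of
    the non-test cases; each held-out test case is then annotated against it
    and the mean fraction of its variant lines with observation frequency
    >= ``af_cutoff`` (hence filtered) is recorded.  With ``paired`` (default)
    the subsets are nested across sizes within a replicate, which makes the
    expected curve monotone non-decreasing replicate by replicate.

    Returns a tidy frame with columns db_size, replicate, frac_filtered_snv,
    frac_filtered_sv.
    """
    test_set = set(test_cases)
    pool = [cid for cid in cohort.case_ids if cid not in test_set]
    missing = test_set - set(cohort.case_ids)
    if missing:
        raise ValueError(f"unknown test case ids: {sorted(missing)}")
    sizes = sorted(set(int(s) for s in db_sizes))
    if sizes and sizes[-1] > len(pool):
        raise ValueError(
            f"largest database size {sizes[-1]} exceeds the {len(pool)} "
            "cases available outside the test set"
        )
    rng = np.random.default_rng(seed)
    by_id = {c.case_id: c for c in cohort.cases}
    held_out = [by_id[cid] for cid in test_cases]

    rows = []
    for rep in range(n_replicates):
        order = list(rng.permutation(pool))
        for size in sizes:
            db_ids = order[:size] if paired else list(rng.permutation(pool))[:size]
            overlap = test_set & set(db_ids)
            if overlap:  # defensive; pool already excludes test cases
                raise ValueError(f"database/test overlap: {sorted(overlap)}")
            if size == 0:
                store = ObservationStore(sv_policy=cohort.params.sv_policy)
            else:
                store = build_store(cohort, db_ids)
            fr_snv, fr_sv = [], []
            for case in held_out:
                fs, fv = _case_filtered_fractions(case, store, af_cutoff)
                fr_snv.append(fs)
                fr_sv.append(fv)
            rows.append(
                {
                    "db_size": size,
                    "replicate": rep,
                    "frac_filtered_snv": float(np.mean(fr_snv)),
                    "frac_filtered_sv": float(np.mean(fr_sv)),
                }
            )
    return pd.DataFrame(rows)


def default_size_experiment(
    seed: int = 0,
    db_sizes: Sequence[int] = (10, 50, 200),
    n_test: int = 20,
    n_replicates: int = 20,
    af_cutoff: float = 0.01,
) -> pd.DataFrame:
    """The package's standard size experiment: a 220-case cohort split into
    a 200-case database pool and 20 held-out test cases."""
    n_cases = max(db_sizes) + n_test
    cohort = generate_cohort(n_cases, CohortParams(), seed=seed)
    test_cases = cohort.case_ids[-n_test:]
    return size_experiment(
        cohort,
        db_sizes,
        test_cases,
        af_cutoff=af_cutoff,
        n_replicates=n_replicates,
        seed=seed + 1,
    )
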
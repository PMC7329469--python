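"""Case-aware observation counting with incremental, idempotent updates.

A *case* is one family (or singleton) uploaded as a unit.  Every variant line
that passes the genotype-quality gate contributes exactly one observation for
its case, no matter how many family members carry the allele — that
once-per-family rule is what keeps frequencies from being inflated by large
families and by the over-representation of affected individuals in a
diagnostic lab.  Small variants are counted under their exact canonical key;
structural variants are routed to the on-the-fly cluster store.

The store updates continuously: new cases are appended without any rebuild,
a duplicate upload is refused atomically (zero counters touched), and a case
can be deleted, exactly reversing its contribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Optional

from .formats_io import Individual, Pedigree
from .identity_profile import (
    DEFAULT_MIN_COMPARED,
    DEFAULT_SIMILARITY_THRESHOLD,
    GenotypeProfile,
    profile_similarity,
)
from .sv_clustering import PaddingPolicy, SvCluster, SvClusterStore, SvMember
from .variant_model import (
    Category,
    SvCoordinates,
    VariantRecord,
    snv_key,
    sv_coordinates,
)

DEFAULT_GQ_THRESHOLD = 20


class StoreError(RuntimeError):
    pass


class DuplicateCaseError(StoreError):
    def __init__(self, case_id: str, mode: str, matched: Optional[str] = None):
        self.case_id = case_id
        self.mode = mode  # "id" or "profile"
        self.matched = matched
        detail = f" (matches stored case {matched})" if matched else ""
        super().__init__(f"case {case_id!r} already exists by {mode}{detail}")


class ExistsStatus(str, Enum):
    ABSENT = "absent"
    PRESENT_BY_ID = "present_by_id"
    PRESENT_BY_PROFILE = "present_by_profile"


class ExistsCheck(NamedTuple):
    status: ExistsStatus
    matched_case: Optional[str]


@dataclass
class Case:
    case_id: str
    individuals: list[Individual]
    profiles: dict[str, GenotypeProfile] = field(default_factory=dict)
    vcf_paths: list[str] = field(default_factory=list)
    loaded_at: str = ""


@dataclass
class SnvObservation:
    """Stored document for one small variant."""

    key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    obs_count: int = 0
    hom_count: int = 0
    case_ids: list[str] = field(default_factory=list)
    # which cases contributed the hom increment — needed to reverse a delete
    hom_case_ids: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    case_id: str
    n_loaded: int = 0
    n_filtered_gq: int = 0
    n_rejected: int = 0
    n_no_carrier: int = 0
    n_snv: int = 0
    n_sv: int = 0


@dataclass
class DeleteReport:
    case_id: str
    n_snv_removed: int = 0
    n_sv_removed: int = 0


def _gate(record: VariantRecord, threshold: int) -> str:
    """Load gate: "pass", "gq" (carriers exist but none passes GQ), or
    "no_carrier".

    A line passes iff at least one individual carries a non-reference allele
    and that same individual has GQ strictly greater than the threshold.
    Threshold 0 disables the gate (all carried variants load, GQ or not);
    otherwise a carrier with missing GQ never passes.
    """
    carriers = [c for c in record.genotypes.values() if c.has_alt]
    if not carriers:
        return "no_carrier"
    if threshold == 0:
        return "pass"
    if any(c.gq is not None and c.gq > threshold for c in carriers):
        return "pass"
    return "gq"


class ObservationStore:
    """In-memory document store with deterministic JSONL dump/restore.

    Single-writer contract; readers always see a consistent state because
    every load is validated fully before any counter is touched.
    """

    def __init__(
        self,
        gq_threshold: int = DEFAULT_GQ_THRESHOLD,
        sv_policy: PaddingPolicy = PaddingPolicy(),
        profile_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
        profile_min_compared: int = DEFAULT_MIN_COMPARED,
    ):
        self.gq_threshold = gq_threshold
        self.sv_policy = sv_policy
        self.profile_threshold = profile_threshold
        self.profile_min_compared = profile_min_compared
        self.cases: dict[str, Case] = {}
        self.snvs: dict[str, SnvObservation] = {}
        self.sv_clusters = SvClusterStore(sv_policy)
        self.contig_order: list[str] = []
        self._contig_seen: set[str] = set()

    # ------------------------------------------------------------------ meta

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def parameters(self) -> dict:
        return {
            "gq_threshold": self.gq_threshold,
            "sv_policy": self.sv_policy.as_dict(),
            "profile_threshold": self.profile_threshold,
            "profile_min_compared": self.profile_min_compared,
        }

    def _note_contig(self, chrom: str) -> None:
        if chrom not in self._contig_seen:
            self._contig_seen.add(chrom)
            self.contig_order.append(chrom)

    # ---------------------------------------------------------------- lookup

    def case_exists(
        self, case_id: str, profiles: Optional[dict[str, GenotypeProfile]] = None
    ) -> ExistsCheck:
        if case_id in self.cases:
            return ExistsCheck(ExistsStatus.PRESENT_BY_ID, case_id)
        if profiles:
            for stored in self.cases.values():
                for profile in profiles.values():
                    for other in stored.profiles.values():
                        if profile.site_list_id != other.site_list_id:
                            continue
                        sim = profile_similarity(
                            profile, other, self.profile_min_compared
                        )
                        if not sim.insufficient and sim.value >= self.profile_threshold:
                            return ExistsCheck(
                                ExistsStatus.PRESENT_BY_PROFILE, stored.case_id
                            )
        return ExistsCheck(ExistsStatus.ABSENT, None)

    def get_observation(self, key: str) -> Optional[SnvObservation]:
        return self.snvs.get(key)

    def snv_frequency(self, key: str) -> Optional[float]:
        obs = self.snvs.get(key)
        if obs is None:
            return None
        return obs.obs_count / self.n_cases if self.n_cases else 0.0

    def query_sv(self, sv: SvCoordinates) -> Optional[dict]:
        return self.sv_clusters.query_sv(sv, self.n_cases)

    # ------------------------------------------------------------------ load

    def load_case(
        self,
        records: Iterable[VariantRecord],
        pedigree: Pedigree,
        gq_threshold: Optional[int] = None,
        profiles: Optional[dict[str, GenotypeProfile]] = None,
        check_profile: bool = False,
        vcf_paths: Iterable[str] = (),
        now: Callable[[], str] = lambda: datetime.now(timezone.utc).isoformat(),
    ) -> LoadReport:
        """Count one case's variants into the store, atomically.

        Refused (with zero state change) when the case id is already present
        or, under ``check_profile``, when any supplied genotype profile is
        near-identical to a stored one.
        """
        threshold = self.gq_threshold if gq_threshold is None else gq_threshold
        case_id = pedigree.case_id

        check = self.case_exists(case_id, profiles if check_profile else None)
        if check.status is ExistsStatus.PRESENT_BY_ID:
            raise DuplicateCaseError(case_id, "id")
        if check.status is ExistsStatus.PRESENT_BY_PROFILE:
            raise DuplicateCaseError(case_id, "profile", check.matched_case)

        records = list(records)
        ped_ids = set(pedigree.ind_ids)
        vcf_samples = set()
        for record in records:
            vcf_samples.update(record.genotypes)
        unmatched = sorted(vcf_samples - ped_ids)
        if unmatched:
            raise StoreError(
                f"case {case_id!r}: VCF sample(s) {unmatched} absent from PED "
                f"(pedigree has {sorted(ped_ids)})"
            )

        report = LoadReport(case_id=case_id)
        # Stage every action first so a malformed record aborts with zero
        # counters touched; then apply.
        staged: list[tuple[str, object, bool]] = []
        for record in records:
            verdict = _gate(record, threshold)
            if verdict == "no_carrier":
                report.n_no_carrier += 1
                continue
            if verdict == "gq":
                report.n_filtered_gq += 1
                continue
            is_hom = any(c.is_hom_alt for c in record.genotypes.values())
            if record.category is Category.SV:
                staged.append(("sv", sv_coordinates(record), is_hom))
            else:
                staged.append(("snv", record, is_hom))

        for kind, payload, is_hom in staged:
            if kind == "snv":
                record = payload
                key = snv_key(record)
                obs = self.snvs.get(key)
                if obs is None:
                    obs = SnvObservation(
                        key=key,
                        chrom=record.chrom,
                        pos=record.pos,
                        ref=record.ref,
                        alt=record.alt,
                    )
                    self.snvs[key] = obs
                obs.obs_count += 1
                obs.case_ids.append(case_id)
                if is_hom:
                    obs.hom_count += 1
                    obs.hom_case_ids.append(case_id)
                self._note_contig(record.chrom)
                report.n_snv += 1
            else:
                sv = payload
                self.sv_clusters.insert_sv(sv, case_id, is_hom)
                self._note_contig(sv.chrom_a)
                self._note_contig(sv.chrom_b)
                report.n_sv += 1
            report.n_loaded += 1

        self.cases[case_id] = Case(
            case_id=case_id,
            individuals=list(pedigree.individuals),
            profiles=dict(profiles or {}),
            vcf_paths=list(vcf_paths),
            loaded_at=now(),
        )
        return report

    # ---------------------------------------------------------------- delete

    def delete_case(self, case_id: str) -> DeleteReport:
        """Exactly reverse one case's contribution."""
        if case_id not in self.cases:
            raise StoreError(f"case {case_id!r} not in store")
        report = DeleteReport(case_id=case_id)
        doomed = []
        for key, obs in self.snvs.items():
            while case_id in obs.case_ids:
                obs.case_ids.remove(case_id)
                obs.obs_count -= 1
                report.n_snv_removed += 1
            while case_id in obs.hom_case_ids:
                obs.hom_case_ids.remove(case_id)
                obs.hom_count -= 1
            if obs.obs_count == 0:
                doomed.append(key)
        for key in doomed:
            del self.snvs[key]
        report.n_sv_removed = self.sv_clusters.remove_case(case_id)
        del self.cases[case_id]
        return report

    # ----------------------------------------------------------- persistence

    def dump(self, directory: str | Path) -> None:
        """Write the store as diff-friendly JSONL with deterministic order."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        meta = {
            "n_cases": self.n_cases,
            "parameters": self.parameters(),
            "contig_order": self.contig_order,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

        with open(directory / "cases.jsonl", "w") as fh:
            for case_id in sorted(self.cases):
                case = self.cases[case_id]
                fh.write(
                    json.dumps(
                        {
                            "case_id": case.case_id,
                            "individuals": [
                                {
                                    "ind_id": i.ind_id,
                                    "father_id": i.father_id,
                                    "mother_id": i.mother_id,
                                    "sex": i.sex,
                                    "affected": i.affected,
                                }
                                for i in case.individuals
                            ],
                            "profiles": {
                                s: {
                                    "site_list_id": p.site_list_id,
                                    "calls": "".join(p.calls),
                                }
                                for s, p in sorted(case.profiles.items())
                            },
                            "vcf_paths": case.vcf_paths,
                            "loaded_at": case.loaded_at,
                        }
                    )
                    + "\n"
                )

        with open(directory / "snv.jsonl", "w") as fh:
            for key in sorted(self.snvs):
                obs = self.snvs[key]
                fh.write(
                    json.dumps(
                        {
                            "key": obs.key,
                            "chrom": obs.chrom,
                            "pos": obs.pos,
                            "ref": obs.ref,
                            "alt": obs.alt,
                            "obs_count": obs.obs_count,
                            "hom_count": obs.hom_count,
                            "case_ids": obs.case_ids,
                            "hom_case_ids": obs.hom_case_ids,
                        }
                    )
                    + "\n"
                )

        with open(directory / "sv_clusters.jsonl", "w") as fh:
            for cid in sorted(self.sv_clusters.clusters):
                c = self.sv_clusters.clusters[cid]
                fh.write(
                    json.dumps(
                        {
                            "cluster_id": c.cluster_id,
                            "ordinal": c.ordinal,
                            "sv_type": c.sv_type,
                            "chrom_a": c.chrom_a,
                            "chrom_b": c.chrom_b,
                            "interval_bp": c.interval_bp,
                            "pos_sum_a": c.pos_sum_a,
                            "pos_sum_b": c.pos_sum_b,
                            "obs_count": c.obs_count,
                            "hom_count": c.hom_count,
                            "case_ids": c.case_ids,
                            "members": [
                                [m.case_id, m.pos_a, m.pos_b, m.is_hom]
                                for m in c.members
                            ],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def restore(cls, directory: str | Path) -> "ObservationStore":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        params = meta["parameters"]
        store = cls(
            gq_threshold=params["gq_threshold"],
            sv_policy=PaddingPolicy(**params["sv_policy"]),
            profile_threshold=params["profile_threshold"],
            profile_min_compared=params["profile_min_compared"],
        )
        for chrom in meta.get("contig_order", []):
            store._note_contig(chrom)

        with open(directory / "cases.jsonl") as fh:
            for line in fh:
                doc = json.loads(line)
                store.cases[doc["case_id"]] = Case(
                    case_id=doc["case_id"],
                    individuals=[
                        Individual(
                            i["ind_id"],
                            i["father_id"],
                            i["mother_id"],
                            i["sex"],
                            i["affected"],
                        )
                        for i in doc["individuals"]
                    ],
                    profiles={
                        s: GenotypeProfile(p["site_list_id"], tuple(p["calls"]))
                        for s, p in doc["profiles"].items()
                    },
                    vcf_paths=doc["vcf_paths"],
                    loaded_at=doc["loaded_at"],
                )

        with open(directory / "snv.jsonl") as fh:
            for line in fh:
                doc = json.loads(line)
                store.snvs[doc["key"]] = SnvObservation(**doc)

        max_ordinal = 0
        with open(directory / "sv_clusters.jsonl") as fh:
            for line in fh:
                doc = json.loads(line)
                cluster = SvCluster(
                    cluster_id=doc["cluster_id"],
                    ordinal=doc["ordinal"],
                    sv_type=doc["sv_type"],
                    chrom_a=doc["chrom_a"],
                    chrom_b=doc["chrom_b"],
                    interval_bp=doc["interval_bp"],
                    pos_sum_a=doc["pos_sum_a"],
                    pos_sum_b=doc["pos_sum_b"],
                    obs_count=doc["obs_count"],
                    hom_count=doc["hom_count"],
                    case_ids=doc["case_ids"],
                    members=[SvMember(*m) for m in doc["members"]],
                )
                store.sv_clusters.clusters[cluster.cluster_id] = cluster
                store.sv_clusters._index.setdefault(
                    (cluster.sv_type, cluster.chrom_a, cluster.chrom_b), []
                ).append(cluster.cluster_id)
                max_ordinal = max(max_ordinal, cluster.ordinal)
        store.sv_clusters._next_ordinal = max_ordinal + 1

        if meta["n_cases"] != store.n_cases:
            raise StoreError(
                f"{directory}: meta records {meta['n_cases']} cases, "
                f"found {store.n_cases}"
            )
        return store

    def check_invariants(self) -> None:
        """Internal consistency: raise if any documented invariant is broken."""
        for obs in self.snvs.values():
            assert obs.obs_count == len(obs.case_ids), obs.key
            assert 0 <= obs.hom_count <= obs.obs_count, obs.key
            assert obs.obs_count <= self.n_cases, obs.key
        for c in self.sv_clusters.clusters.values():
            assert c.obs_count == len(c.case_ids) == len(c.members), c.cluster_id
            assert c.pos_sum_a == sum(m.pos_a for m in c.members), c.cluster_id
            assert c.pos_sum_b == sum(m.pos_b for m in c.members), c.cluster_id
            assert 0 <= c.hom_count <= c.obs_count, c.cluster_id
            assert not math.isnan(c.mean_a)
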
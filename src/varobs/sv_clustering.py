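"""On-the-fly clustering of similar structural variants.

Recurring SV calls rarely reproduce breakpoints exactly: callers and the
underlying biology both jitter the reported positions.  The database
therefore groups similar SVs into clusters.  A cluster is an SV type plus two
mean endpoint coordinates, with a fixed padding interval around each
endpoint.  An incoming SV joins a cluster when its type and chromosome pair
match and both endpoints fall within the cluster's intervals; among several
candidates it joins the closest one only.  On join, the cluster endpoints
move to the arithmetic mean of all member positions — held as exact integer
accumulators, so means never drift — while the interval size stays fixed at
its creation value.

The padding interval is 2 kb for variants longer than 10 kb (an
interchromosomal variant counts as infinitely long) and 10% of the variant
length for smaller ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .variant_model import SvCoordinates


@dataclass(frozen=True)
class PaddingPolicy:
    """Endpoint-interval sizing. Users may tune these for their callers."""

    max_pad_bp: int = 2000
    small_frac: float = 0.10
    large_threshold_bp: int = 10000

    def as_dict(self) -> dict:
        return {
            "max_pad_bp": self.max_pad_bp,
            "small_frac": self.small_frac,
            "large_threshold_bp": self.large_threshold_bp,
        }


def padding_interval(sv: SvCoordinates, policy: PaddingPolicy = PaddingPolicy()) -> int:
    """Interval size in bp for a cluster founded on ``sv``.

    The >10 kb boundary is strict: a 10,000 bp variant takes the 10% branch.
    Fractional paddings round half away from zero, floor 1 bp.
    """
    length = sv.length
    if not math.isinf(length) and length <= 0:
        raise ValueError(f"non-positive SV length {length}")
    if math.isinf(length) or length > policy.large_threshold_bp:
        return policy.max_pad_bp
    return max(1, int(math.floor(policy.small_frac * length + 0.5)))


@dataclass
class SvMember:
    case_id: str
    pos_a: int
    pos_b: int
    is_hom: bool


@dataclass
class SvCluster:
    cluster_id: str
    ordinal: int  # creation sequence, used only for deterministic tie-breaks
    sv_type: str
    chrom_a: str
    chrom_b: str
    interval_bp: int  # fixed at creation, never updated
    pos_sum_a: int = 0
    pos_sum_b: int = 0
    obs_count: int = 0
    hom_count: int = 0
    case_ids: list[str] = field(default_factory=list)
    members: list[SvMember] = field(default_factory=list)

    @property
    def mean_a(self) -> float:
        return self.pos_sum_a / self.obs_count

    @property
    def mean_b(self) -> float:
        return self.pos_sum_b / self.obs_count

    def _add(self, sv: SvCoordinates, case_id: str, is_hom: bool) -> None:
        self.pos_sum_a += sv.pos_a
        self.pos_sum_b += sv.pos_b
        self.obs_count += 1
        if is_hom:
            self.hom_count += 1
        self.case_ids.append(case_id)
        self.members.append(SvMember(case_id, sv.pos_a, sv.pos_b, is_hom))


class SvClusterStore:
    """Cluster collection with (sv_type, chromosome-pair) indexing."""

    def __init__(self, policy: PaddingPolicy = PaddingPolicy()):
        self.policy = policy
        self.clusters: dict[str, SvCluster] = {}
        self._index: dict[tuple[str, str, str], list[str]] = {}
        self._next_ordinal = 1

    def __len__(self) -> int:
        return len(self.clusters)

    @staticmethod
    def _bucket(sv: SvCoordinates) -> tuple[str, str, str]:
        return (sv.sv_type, sv.chrom_a, sv.chrom_b)

    def match_cluster(self, sv: SvCoordinates) -> SvCluster | None:
        """Closest matching cluster, or None.

        Match predicate: same type, same chromosome pair, and both endpoints
        within the cluster's interval of the (real-valued) cluster means.
        "Closest" is the Manhattan sum of the two endpoint offsets; ties go
        to the earliest-created cluster so replays are deterministic.
        """
        best: tuple[float, int] | None = None
        best_cluster = None
        for cid in self._index.get(self._bucket(sv), ()):  # candidates
            cluster = self.clusters[cid]
            da = abs(sv.pos_a - cluster.mean_a)
            db = abs(sv.pos_b - cluster.mean_b)
            if da <= cluster.interval_bp and db <= cluster.interval_bp:
                rank = (da + db, cluster.ordinal)
                if best is None or rank < best:
                    best = rank
                    best_cluster = cluster
        return best_cluster

    def _new_cluster_id(self, sv: SvCoordinates) -> str:
        base = f"{sv.sv_type}_{sv.chrom_a}_{sv.pos_a}_{sv.chrom_b}_{sv.pos_b}"
        cid, n = base, 1
        while cid in self.clusters:
            n += 1
            cid = f"{base}_{n}"
        return cid

    def insert_sv(
        self, sv: SvCoordinates, case_id: str, is_hom: bool = False
    ) -> tuple[str, str]:
        """Add one SV observation; returns ("created"|"joined", cluster_id)."""
        cluster = self.match_cluster(sv)
        if cluster is not None:
            cluster._add(sv, case_id, is_hom)
            return "joined", cluster.cluster_id
        cid = self._new_cluster_id(sv)
        cluster = SvCluster(
            cluster_id=cid,
            ordinal=self._next_ordinal,
            sv_type=sv.sv_type,
            chrom_a=sv.chrom_a,
            chrom_b=sv.chrom_b,
            interval_bp=padding_interval(sv, self.policy),
        )
        self._next_ordinal += 1
        cluster._add(sv, case_id, is_hom)
        self.clusters[cid] = cluster
        self._index.setdefault(self._bucket(sv), []).append(cid)
        return "created", cid

    def query_sv(self, sv: SvCoordinates, n_cases: int) -> dict | None:
        """Read-only lookup: observation counts and frequency, or None.

        Never mutates cluster state; repeated identical queries return
        identical results.
        """
        cluster = self.match_cluster(sv)
        if cluster is None:
            return None
        return {
            "cluster_id": cluster.cluster_id,
            "obs_count": cluster.obs_count,
            "hom_count": cluster.hom_count,
            "frequency": cluster.obs_count / n_cases if n_cases else 0.0,
        }

    def remove_case(self, case_id: str) -> int:
        """Withdraw every observation contributed by one case.

        Accumulators are decremented by the member's exact recorded
        positions, so remaining means stay exact; clusters reaching zero
        observations are removed.  Returns the number of observations
        withdrawn.
        """
        removed = 0
        empty: list[str] = []
        for cluster in self.clusters.values():
            keep: list[SvMember] = []
            for member in cluster.members:
                if member.case_id == case_id:
                    cluster.pos_sum_a -= member.pos_a
                    cluster.pos_sum_b -= member.pos_b
                    cluster.obs_count -= 1
                    if member.is_hom:
                        cluster.hom_count -= 1
                    cluster.case_ids.remove(member.case_id)
                    removed += 1
                else:
                    keep.append(member)
            cluster.members = keep
            if cluster.obs_count == 0:
                empty.append(cluster.cluster_id)
        for cid in empty:
            cluster = self.clusters.pop(cid)
            bucket = (cluster.sv_type, cluster.chrom_a, cluster.chrom_b)
            self._index[bucket].remove(cid)
            if not self._index[bucket]:
                del self._index[bucket]
        return removed
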
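"""Counting semantics, idempotency, reversibility, persistence."""

import itertools
import json
from pathlib import Path

import pytest

from varobs.observation_store import (
    DuplicateCaseError,
    ExistsStatus,
    ObservationStore,
    StoreError,
)
from varobs.variant_model import snv_key
from .conftest import make_record, singleton_ped, trio_ped


def dump_text(store, directory: Path, strip_timestamps=True) -> str:
    store.dump(directory)
    parts = []
    for name in ("meta.json", "cases.jsonl", "snv.jsonl", "sv_clusters.jsonl"):
        text = (directory / name).read_text()
        if strip_timestamps and name == "cases.jsonl":
            lines = []
            for line in text.splitlines():
                doc = json.loads(line)
                doc["loaded_at"] = ""
                lines.append(json.dumps(doc))
            text = "\n".join(lines)
        parts.append(text)
    return "\n===\n".join(parts)


class TestOncePerFamilyCounting:
    def test_trio_all_carriers_counts_once(self, trio):
        store = ObservationStore()
        rec = make_record(
            genotypes={"FA": ("0/1", 99), "MO": ("0/1", 99), "CH": ("0/1", 99)}
        )
        store.load_case([rec], trio)
        obs = store.get_observation(snv_key(rec))
        assert obs.obs_count == 1
        assert obs.hom_count == 0
        assert obs.case_ids == ["F1"]

    def test_singleton_homozygote_increments_both_counters(self, singleton):
        store = ObservationStore()
        rec = make_record(genotypes={"S1": ("1/1", 99)})
        store.load_case([rec], singleton)
        obs = store.get_observation(snv_key(rec))
        assert (obs.obs_count, obs.hom_count) == (1, 1)

    def test_hemizygous_single_allele_is_not_homozygous(self, singleton):
        store = ObservationStore()
        rec = make_record(chrom="Y", genotypes={"S1": ("1", 99)})
        store.load_case([rec], singleton)
        obs = store.get_observation(snv_key(rec))
        assert (obs.obs_count, obs.hom_count) == (1, 0)

    def test_three_cases_give_three_observations(self):
        store = ObservationStore()
        for i in range(3):
            rec = make_record(genotypes={f"S{i}": ("0/1", 99)})
            store.load_case([rec], singleton_ped(f"F{i}", f"S{i}"))
        obs = store.get_observation("1_100_A_T")
        assert obs.obs_count == 3
        assert sorted(obs.case_ids) == ["F0", "F1", "F2"]

    def test_reference_only_genotypes_never_count(self, trio):
        store = ObservationStore()
        rec = make_record(
            genotypes={"FA": ("0/0", 99), "MO": ("./.", 99), "CH": ("0/0", 99)}
        )
        report = store.load_case([rec], trio)
        assert report.n_loaded == 0
        assert report.n_no_carrier == 1
        assert store.get_observation(snv_key(rec)) is None


class TestGqGate:
    def test_low_gq_carrier_is_filtered(self, singleton):
        store = ObservationStore()
        rec = make_record(genotypes={"S1": ("0/1", 15)})
        report = store.load_case([rec], singleton)
        assert report.n_filtered_gq == 1
        assert store.get_observation(snv_key(rec)) is None

    def test_threshold_is_strict_gq_20_fails_21_passes(self):
        for gq, expected in ((20, 0), (21, 1)):
            store = ObservationStore()
            rec = make_record(genotypes={"S1": ("0/1", gq)})
            store.load_case([rec], singleton_ped())
            count = 0 if store.get_observation(snv_key(rec)) is None else 1
            assert count == expected, f"GQ {gq}"

    def test_threshold_zero_disables_gate(self, singleton):
        store = ObservationStore(gq_threshold=0)
        low = make_record(pos=100, genotypes={"S1": ("0/1", 3)})
        nogq = make_record(pos=200, genotypes={"S1": ("0/1", None)})
        report = store.load_case([low, nogq], singleton)
        assert report.n_loaded == 2
        assert report.n_filtered_gq == 0

    def test_missing_gq_fails_under_default_threshold(self, singleton):
        store = ObservationStore()
        rec = make_record(genotypes={"S1": ("0/1", None)})
        report = store.load_case([rec], singleton)
        assert report.n_filtered_gq == 1

    def test_one_passing_carrier_rescues_the_family_line(self, trio):
        # one confident carrier suffices even if another carrier is poor
        store = ObservationStore()
        rec = make_record(
            genotypes={"FA": ("0/1", 5), "MO": ("0/1", 99), "CH": ("0/0", 99)}
        )
        report = store.load_case([rec], trio)
        assert report.n_loaded == 1

    def test_only_noncarrier_passes_gq_line_filtered(self, trio):
        # the confident sample is hom-ref; the carrier itself fails the gate
        store = ObservationStore()
        rec = make_record(
            genotypes={"FA": ("0/1", 5), "MO": ("0/0", 99), "CH": ("0/0", 99)}
        )
        report = store.load_case([rec], trio)
        assert report.n_filtered_gq == 1


class TestCaseLifecycle:
    def test_case_exists_states(self, singleton):
        store = ObservationStore()
        assert store.case_exists("F1").status is ExistsStatus.ABSENT
        store.load_case([make_record()], singleton)
        assert store.case_exists("F1").status is ExistsStatus.PRESENT_BY_ID

    def test_duplicate_load_refused_with_zero_state_change(self, tmp_path, singleton):
        store = ObservationStore()
        store.load_case([make_record()], singleton)
        before = dump_text(store, tmp_path / "before", strip_timestamps=False)
        with pytest.raises(DuplicateCaseError, match="F1"):
            store.load_case([make_record(pos=999)], singleton)
        after = dump_text(store, tmp_path / "after", strip_timestamps=False)
        assert before == after

    def test_vcf_ped_sample_mismatch_lists_samples(self, singleton):
        store = ObservationStore()
        rec = make_record(genotypes={"STRANGER": ("0/1", 99)})
        with pytest.raises(StoreError, match="STRANGER"):
            store.load_case([rec], singleton)
        assert store.n_cases == 0

    def test_failed_load_is_atomic(self, singleton):
        store = ObservationStore()
        good = make_record(pos=100)
        bad = make_record(pos=200, ref="N", alt="<DEL>")  # no END/SVLEN
        with pytest.raises(Exception):
            store.load_case([good, bad], singleton)
        assert store.n_cases == 0
        assert store.get_observation(snv_key(good)) is None

    def test_delete_on_empty_store_is_an_error(self):
        with pytest.raises(StoreError):
            ObservationStore().delete_case("F1")

    def test_load_then_delete_restores_prior_dump(self, tmp_path):
        store = ObservationStore()
        shared = lambda s: make_record(pos=100, genotypes={s: ("0/1", 99)})
        sv = lambda s, a: make_record(
            pos=a, ref="N", alt="<DEL>",
            info={"END": a + 20_000}, genotypes={s: ("0/1", 99)},
        )
        store.load_case([shared("A1"), sv("A1", 10_000)], singleton_ped("FA", "A1"))
        before = dump_text(store, tmp_path / "before")
        store.load_case(
            [shared("B1"), sv("B1", 10_500), sv("B1", 500_000)],
            singleton_ped("FB", "B1"),
        )
        store.delete_case("FB")
        store.check_invariants()
        after = dump_text(store, tmp_path / "after")
        assert before == after

    def test_delete_A_equals_load_B_only(self, tmp_path):
        def records(sample):
            return [
                make_record(pos=100, genotypes={sample: ("0/1", 99)}),
                make_record(
                    pos=50_000, ref="N", alt="<DUP>",
                    info={"END": 80_000}, genotypes={sample: ("1/1", 99)},
                ),
            ]

        both = ObservationStore()
        both.load_case(records("A1"), singleton_ped("FA", "A1"))
        both.load_case(records("B1"), singleton_ped("FB", "B1"))
        both.delete_case("FA")

        only_b = ObservationStore()
        only_b.load_case(records("B1"), singleton_ped("FB", "B1"))

        # same SNV state and same cluster content (ordinals may differ)
        assert {k: (o.obs_count, o.hom_count, o.case_ids)
                for k, o in both.snvs.items()} == {
            k: (o.obs_count, o.hom_count, o.case_ids)
            for k, o in only_b.snvs.items()
        }
        state = lambda s: sorted(
            (c.sv_type, c.chrom_a, c.chrom_b, c.interval_bp, c.pos_sum_a,
             c.pos_sum_b, c.obs_count, c.hom_count, tuple(c.case_ids))
            for c in s.sv_clusters.clusters.values()
        )
        assert state(both) == state(only_b)

    def test_delete_sole_cluster_member_removes_cluster(self, singleton):
        store = ObservationStore()
        rec = make_record(
            pos=10_000, ref="N", alt="<DEL>", info={"END": 50_000},
            genotypes={"S1": ("0/1", 99)},
        )
        store.load_case([rec], singleton)
        assert len(store.sv_clusters) == 1
        store.delete_case("F1")
        assert len(store.sv_clusters) == 0
        assert store.n_cases == 0


class TestInvariants:
    def cases(self):
        recs = {
            "F0": [make_record(pos=p, genotypes={"S0": ("0/1", 99)}) for p in (100, 200)],
            "F1": [make_record(pos=p, genotypes={"S1": ("1/1", 99)}) for p in (100, 300)],
            "F2": [make_record(pos=p, genotypes={"S2": ("0/1", 99)}) for p in (200, 300)],
        }
        return recs

    def test_snv_state_is_load_order_invariant(self):
        recs = self.cases()
        states = []
        for order in itertools.permutations(recs):
            store = ObservationStore()
            for cid in order:
                store.load_case(
                    recs[cid], singleton_ped(cid, f"S{cid[-1]}")
                )
            states.append(
                {
                    k: (o.obs_count, o.hom_count, sorted(o.case_ids))
                    for k, o in store.snvs.items()
                }
            )
        assert all(s == states[0] for s in states)

    def test_conservation_of_observation_counts(self):
        recs = self.cases()
        store = ObservationStore()
        for cid, rr in recs.items():
            store.load_case(rr, singleton_ped(cid, f"S{cid[-1]}"))
        total = sum(o.obs_count for o in store.snvs.values())
        assert total == sum(len(rr) for rr in recs.values())
        store.check_invariants()

    def test_counter_bounds_hold_after_every_operation(self):
        recs = self.cases()
        store = ObservationStore()
        for cid, rr in recs.items():
            store.load_case(rr, singleton_ped(cid, f"S{cid[-1]}"))
            store.check_invariants()
        store.delete_case("F1")
        store.check_invariants()
        for obs in store.snvs.values():
            assert obs.hom_count <= obs.obs_count <= store.n_cases


class TestPersistence:
    def test_dump_restore_round_trip_is_byte_identical(self, tmp_path, trio):
        store = ObservationStore()
        recs = [
            make_record(pos=100, genotypes={"FA": ("0/1", 99), "MO": ("0/0", 99), "CH": ("1/1", 99)}),
            make_record(
                pos=10_000, ref="N", alt="<INV>", info={"END": 30_000},
                genotypes={"FA": ("0/1", 99), "MO": ("0/0", 99), "CH": ("0/0", 99)},
            ),
        ]
        store.load_case(recs, trio)
        first = dump_text(store, tmp_path / "a", strip_timestamps=False)
        restored = ObservationStore.restore(tmp_path / "a")
        restored.check_invariants()
        second = dump_text(restored, tmp_path / "b", strip_timestamps=False)
        assert first == second

    def test_restored_store_keeps_counting_consistently(self, tmp_path):
        store = ObservationStore()
        store.load_case(
            [make_record(genotypes={"S1": ("0/1", 99)})], singleton_ped("F1", "S1")
        )
        store.dump(tmp_path / "db")
        restored = ObservationStore.restore(tmp_path / "db")
        restored.load_case(
            [make_record(genotypes={"S2": ("0/1", 99)})], singleton_ped("F2", "S2")
        )
        assert restored.get_observation("1_100_A_T").obs_count == 2
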
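"""Load a trio and a singleton, then inspect observation counts.

Shows the once-per-family rule: a variant carried by all three trio members
still counts as a single observation for that case, and the homozygote
counter tracks whether *any* family member was called 1/1.
"""

from varobs import GenotypeCall, ObservationStore, VariantRecord, snv_key
from varobs.formats_io import Individual, Pedigree

trio = Pedigree(
    "family_1",
    [
        Individual("father", None, None, "1", "1"),
        Individual("mother", None, None, "2", "1"),
        Individual("child", "father", "mother", "1", "2"),
    ],
)
singleton = Pedigree("family_2", [Individual("proband", None, None, "1", "2")])

shared_by_all = VariantRecord(
    chrom="1", pos=874_501, ref="G", alt="A",
    genotypes={
        "father": GenotypeCall(("0", "1"), 99),
        "mother": GenotypeCall(("0", "1"), 97),
        "child": GenotypeCall(("1", "1"), 99),
    },
)
low_quality = VariantRecord(
    chrom="1", pos=990_004, ref="T", alt="C",
    genotypes={
        "father": GenotypeCall(("0", "1"), 12),  # only carrier, GQ below 20
        "mother": GenotypeCall(("0", "0"), 99),
        "child": GenotypeCall(("0", "0"), 99),
    },
)

store = ObservationStore()  # default GQ gate: carriers need GQ > 20
report = store.load_case([shared_by_all, low_quality], trio)
print(f"trio load: {report.n_loaded} loaded, {report.n_filtered_gq} below GQ gate")

store.load_case(
    [VariantRecord(
        chrom="1", pos=874_501, ref="G", alt="A",
        genotypes={"proband": GenotypeCall(("0", "1"), 88)},
    )],
    singleton,
)

obs = store.get_observation(snv_key(shared_by_all))
print(f"variant {obs.key}: Obs={obs.obs_count} Hom={obs.hom_count} "
      f"cases={obs.case_ids}")
print(f"store frequency: {obs.obs_count}/{store.n_cases} = "
      f"{obs.obs_count / store.n_cases:.2f}")
# Obs=2 (one per case, despite three trio carriers); Hom=1 (the child's 1/1).
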
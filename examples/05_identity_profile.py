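"""Catch the same individual re-uploaded under a new case id.

Profiles are genotype-class vectors over a fixed panel of common SNV sites;
a re-upload of the same sample is near-perfectly concordant with its stored
profile, so the load is refused when profile checking is enforced.
"""

from varobs import ObservationStore, build_profiles, profile_similarity
from varobs.formats_io import Individual, Pedigree
from varobs.identity_profile import SitePanel
from varobs.variant_model import GenotypeCall, VariantRecord

panel = SitePanel(tuple((str(i % 4 + 1), 5_000 + 10 * i, "A", "G")
                        for i in range(20)))

def case_records(sample, genotypes):
    return [
        VariantRecord(chrom=c, pos=p, ref=r, alt=a,
                      genotypes={sample: GenotypeCall(tuple(gt.split("/")), 99)})
        for (c, p, r, a), gt in zip(panel.sites, genotypes)
    ]

genotypes = ["0/1", "1/1", "0/0", "0/1"] * 5
original = case_records("sampleX", genotypes)
reupload = case_records("sampleX_renamed", genotypes)

p = build_profiles(original, panel)["sampleX"]
q = build_profiles(reupload, panel)["sampleX_renamed"]
sim = profile_similarity(p, q)
print(f"profile concordance: {sim.value:.3f} over {sim.n_compared} sites")

store = ObservationStore()
store.load_case(original, Pedigree("case_1", [Individual("sampleX", None, None, "1", "2")]),
                profiles=build_profiles(original, panel), check_profile=True)
try:
    store.load_case(
        reupload,
        Pedigree("case_2", [Individual("sampleX_renamed", None, None, "1", "2")]),
        profiles=build_profiles(reupload, panel),
        check_profile=True,
    )
except Exception as exc:
    print(f"second load refused: {exc}")
# Concordance 1.000 -> the store refuses case_2 as a duplicate of case_1.
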
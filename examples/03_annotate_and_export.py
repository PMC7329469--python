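"""Build a small database from a synthetic cohort, annotate a held-out
case's VCF, and export the database as a frequency VCF.

Records known to the database gain Obs/Hom/Frq INFO fields; everything else
passes through untouched.  The export is one line per small variant and one
line per SV cluster centroid, ready for vcfanno-style annotation.
"""

import tempfile
from pathlib import Path

from varobs.annotation import annotate_vcf, export_vcf
from varobs.synthetic_cohort import CohortParams, build_store, generate_cohort, write_cohort

workdir = Path(tempfile.mkdtemp(prefix="varobs_example_"))
params = CohortParams(n_common_snv=40, n_private_snv_per_case=3,
                      n_recurrent_sv=5, n_private_sv=1)
cohort = generate_cohort(12, params, seed=7)
write_cohort(cohort, workdir / "cohort")

# database from the first 11 cases; the last case is the query patient
store = build_store(cohort, cohort.case_ids[:-1])
query_vcf = workdir / "cohort" / f"{cohort.case_ids[-1]}.snv.vcf"

out = workdir / "annotated.vcf"
report = annotate_vcf(query_vcf, store, out)
print(f"annotated {report.n_annotated_snv} of {report.n_records} query records")
for line in out.read_text().splitlines():
    if "Frq=" in line and not line.startswith("#"):
        cols = line.split("\t")
        print(f"  {cols[0]}:{cols[1]} {cols[3]}>{cols[4]}  {cols[7]}")
        break  # show one annotated record

n = export_vcf(store, workdir / "db.snv.vcf", "snv")
m = export_vcf(store, workdir / "db.sv.vcf", "sv")
print(f"exported {n} snv observations and {m} sv clusters to {workdir}")
# Records seen in the database carry Obs (cases observed), Hom (cases with a
# 1/1 call) and Frq = Obs / total cases; Frq >= 0.01 marks local common
# variation a rare-disease analysis would filter out.
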
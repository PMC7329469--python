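# Methods

## Scope and data model

`varobs` maintains an observation-count database over three variant
categories — SNV, INDEL and SV (DEL, DUP, INS, INV, BND and any other type a
caller emits) — as reported by upstream callers; it makes no attempt to
re-unify or subdivide them.  Input VCFs must be decomposed (one ALT per
line) and normalized upstream (e.g. with `vt`): a multi-allelic line is an
error, never silently split, because in-place splitting would hide
non-normalized alleles.  Only decomposition is validated; left-alignment is
taken on trust.

Coordinates follow VCF semantics throughout: 1-based positions, `END`
inclusive, SV length = `pos_b − pos_a + 1` (so a `<DEL>` at 10,000 with
`END=50,000` spans 40,001 bp).  Chromosome names are matched as exact
strings; no `chr`-prefix harmonization is attempted (mixing dialects
surfaces as zero annotation overlap, which is reported).

## Counting rules

* One observation per variant line per **case** (family or singleton),
  regardless of carrier count within the family.  This is the guard against
  pathogenic enrichment from affected-rich families; PED affected status is
  parsed but deliberately not used in counting.
* GQ gate: a line loads iff at least one individual both carries a
  non-reference allele and has GQ **strictly greater** than the threshold
  (default 20).  One confident carrier rescues the line for the family;
  conversely a line whose only carrier fails the gate is filtered even if a
  hom-ref sample is confident — the confidence must belong to the carrier.
  Threshold 0 disables the gate entirely, including for carriers with
  missing GQ; under any positive threshold a missing GQ never passes.
* Homozygote counter: increments iff any family member is written `1/1` on
  the record that loaded.  The 1/1 individual is not separately required to
  pass the GQ gate (the gate admits the line; the hom flag describes the
  family's genotypes).  Haploid calls written `1` are not homozygous — no
  ploidy inference is attempted.
* Loads are atomic per case: duplicate-case refusal, VCF/PED sample
  reconciliation and record validation all happen before any counter is
  touched.  `delete_case` exactly reverses a load (per-observation case
  lists, per-cluster member lists with exact positions), so
  load-then-delete restores the previous dump byte-for-byte apart from
  timestamps.

## SV representation and clustering

An SV reduces to `(type, position A, position B)`.  Position B comes from
the break-end mate coordinate in the ALT, from `INFO/END`, or from
`POS + |SVLEN|`; an insertion without `END` collapses to a point and takes
its length from `|SVLEN|` (a 1 bp span would make fractional padding
degenerate).  Interchromosomal variants have infinite length, and their
chromosome pair is ordered deterministically (natural chromosome order) so
the two VCF lines of one adjacency reduce to identical coordinates; paired
records are still counted as two observations, on the assumption that
callers represent the same biological event the same way in every sample.
Break-end types are normalized to `BND`; mate orientation is not part of
cluster identity.

Clusters are created or updated on the fly as SVs arrive:

* padding interval: 2000 bp if length > 10,000 bp (strict) or infinite;
  otherwise 10% of length, rounded half away from zero, floor 1 bp.  All
  three constants are user-tunable (`sv.max_pad_bp`, `sv.small_frac`,
  `sv.large_threshold_bp`), and the policy is frozen into the store
  metadata so later loads with a conflicting policy are refused — cluster
  geometry must stay consistent.
* match: same type, same chromosome pair, both endpoint offsets from the
  cluster means within the interval; among candidates the smallest
  Manhattan sum of offsets wins, ties broken by earliest-created cluster so
  replays are deterministic.  "Closest" had to be given a metric; Manhattan
  over the two endpoints is the simplest one consistent with the per-endpoint
  interval test.
* update: means are the exact arithmetic average of all member positions,
  held as integer accumulators plus a count (no floating drift, dump/restore
  safe).  The interval is fixed at creation from the *founding* SV's length
  and never resized.

Sequential clustering is order-sensitive by construction for adversarial
chains of SVs each within reach of its neighbour only; the guarantees the
package documents (and tests) are: separated SVs never merge, copies
jittered within a quarter interval always coalesce, centroids always equal
brute-force member means, and the whole procedure is replay-identical to an
independent sequential reference implementation.

## Annotation and export

`annotate_vcf` streams a query VCF line-wise, adding `Obs`, `Hom` and `Frq`
INFO fields to records with a database hit — exact key lookup for small
variants, read-only cluster matching for SVs — and leaving everything else
byte-identical.  `Frq = Obs / n_cases` (cases, not alleles: the denominator
matches the per-family counting unit) and is printed to 4 significant
digits.  `export_vcf` writes the database as a frequency VCF: one line per
small-variant observation at its true coordinates, one line per SV cluster
at its centroid (clusters are the unit of SV frequency), positions rounded
half-down, sorted by first-ingest chromosome order.  The INFO schema is
declared in the header together with the database size and parameters.

## Identity profiling

Re-uploads of one individual under a new case id are detected by a genotype
fingerprint: genotype classes (hom-ref / het / hom-alt / missing) over a
panel of common SNV sites, compared by concordance fraction over sites
non-missing in both, requiring at least 10 jointly covered sites and
flagging anything below that as uninformative.  Similarity ≥ 0.95 marks a
duplicate; detection is advisory (warning) unless enforcement is requested
(`--check-profile`).  The shipped 50-site panel is synthetic and
user-replaceable; the mechanism, threshold and panel are this package's own
design choices, and false positives on monozygotic twins or close relatives
are possible by construction.

## Storage

The store is an in-memory document collection (keyed by SNV key, cluster
id and case id) with deterministic JSONL dump/restore
(`cases.jsonl`, `snv.jsonl`, `sv_clusters.jsonl`, `meta.json`; sorted keys,
fixed field order) so database states diff cleanly and round-trip
byte-identically modulo load timestamps.  Single-writer contract; a
server-backed document store could sit behind the same interface but is not
required at this scale.

## Synthetic cohorts

The generator emulates the upload stream of a diagnostic lab, per seed:

* **Common SNVs** — 500 shared sites, population frequencies drawn from a
  truncated power-law density `p(f) ∝ f^-1` on [0.005, 0.5] (a
  neutral-spectrum-like excess of rare alleles); singleton genotypes by
  Hardy-Weinberg, trio children by Mendelian inheritance (20% of cases are
  trios).
* **Private SNVs** — 20 per case at globally unique positions.
* **Recurrent SVs** — 30 loci (DEL/DUP/INV, log-uniform lengths 1–50 kb)
  with per-case carriage probabilities drawn from the same power-law shape
  on [0.01, 0.8]; the lower bound sits below 1/200 so databases of a few
  hundred cases still gain filtering power — the regime in which the
  filtered fraction grows logarithmically with size.  Observed breakpoints
  are jittered uniformly within ±0.25 × the locus padding interval,
  mimicking caller imprecision while staying in the regime where
  coalescence into one cluster is guaranteed.  3 private SVs per case.
* **GQ** — N(60, 15) clipped to [21, 99], with a 5% fraction drawn from
  [2, 15], so the default gate passes confident calls and rejects the tail.

A truth table records each site's true frequency and each recurrent locus's
coordinates and padding, enabling cluster-recovery and count-tracking
checks.  What the generator does *not* emulate: linkage disequilibrium,
demography and relatedness across cases, caller-specific artifact spectra,
multi-allelic/complex loci, and real SV type mixtures.  Passing tests
therefore demonstrate the counting and clustering machinery, not real-data
filtering percentages, which depend on real allele-frequency spectra.

## Standard study conditions

The size experiment runs on a 220-case cohort: 200 cases form the database
pool, 20 are held out (echoing, at desk scale, a large-background/test-set
split).  For sizes {10, 50, 200} and 20 replicates, databases are drawn
nested within a replicate (paired draws make the size effect monotone in
expectation), held-out cases are annotated, and the mean fraction of their
variant lines at observation frequency ≥ 1% is reported separately for SNVs
and SVs.  Cluster recovery runs 40 independently seeded 12-case cohorts
with 10 recurrent loci at carriage probabilities ≥ 0.35 (so loci are
near-certainly observed) and checks that every observed truth locus maps to
exactly one cluster.  These sizes keep the full study in the tens of
seconds on one core while leaving the qualitative relationships
well-resolved.

## Numerical and degenerate-input choices

* Padding rounding: half away from zero, minimum 1 bp; the >10 kb boundary
  is strict (a 10,000 bp variant takes the 10% branch).
* Export position rounding: half-down (`ceil(x − 0.5)`), documented in the
  tests that pin it.
* Cluster ids derive from the founding SV's coordinates (with a numeric
  suffix on the rare collision), so equivalent stores built along different
  case histories get comparable ids; a creation ordinal is kept only for
  the deterministic tie-break.
* Empty stores export valid header-only VCFs; a case with zero passing
  records still registers (and counts in the frequency denominator).
* Genotypes `./.` and `0/0` never contribute observations even when other
  samples carry the allele.

## Known limitations

Sequential clustering can fragment adversarial SV chains differently under
different load orders (documented, not hidden).  Cluster frequency uses the
case count as denominator, so a case contributing two same-cluster calls
(e.g. both lines of an inversion pair) can push `Frq` above the fraction of
carrier cases.  The profiling panel is synthetic and must be replaced for
real use.  The GQ gate reads only `FORMAT/GQ`; callers that omit it (common
for SVs) require threshold 0 on that input.
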
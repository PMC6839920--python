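# Methods

## The problem being modelled

A consanguineous nuclear family segregating a fully penetrant autosomal
recessive trait: three of five children are affected, the parents are first
cousins. Each affected child carries two copies of the causal allele
identical by descent, so the causal locus lies inside a genomic tract that
is (i) autozygous in every affected child and (ii) not autozygous in either
unaffected sibling. The package maps those tracts from dense genotype data
and filters annotated variants down to candidates compatible with the trait
model.

## Run-of-homozygosity detection

The scan is run-based, not HMM- or sliding-window-based: an ROH is a
*maximal* run of consecutive markers containing at most `max_het`
heterozygous calls and at most `max_missing` missing calls. Maximality is
two-sided (neither one-marker extension stays within budget), which makes
the definition exactly testable against an O(n²) brute-force enumeration of
all sub-runs; the implementation is an O(n) two-pointer scan and the test
suite proves the equivalence on random panels. Runs shorter than
`min_markers` (default 50) or spanning less than `min_length_bp` (default
1 Mb) are discarded; surviving runs that overlap (possible when two runs
share a het-call budget boundary) are coalesced, so output segments are
sorted and disjoint. Ties at a boundary het call resolve rightward by scan
order. A run over markers i..j becomes the half-open segment
`[pos_i − 1, pos_j)`.

Defaults assume array-like densities of 50–100 markers/Mb. The het budget is
*per run*, so isolated genotyping errors split very long runs when two
error-induced het calls fall close together. This fragmentation is by
design repaired downstream by `merge_segments(max_gap_bp)`, which unions
segments separated by at most the gap (idempotent for a fixed gap) —
sequencing-based re-mapping of array-derived LOH segments shows more
continuity than the array scan, and the merge step models exactly that.
Parameter-recovery checks therefore measure reciprocal overlap between true
autozygous tracts and detected-then-merged (100 kb gap) segments.

## Shared-LOH mapping

Per-base set algebra on half-open intervals: the intersection of all
affected samples' ROH sets minus the union of the unaffected samples' ROH
sets (strictest reading of "not shared by unaffected siblings"; a flag
switches the subtraction to the intersection of unaffected sets), then
pieces shorter than `min_shared_bp` are dropped. The algebra is verified
against a per-base boolean-mask oracle.

## Windowed heterozygosity

Fixed windows (default 100 kb) anchored at the start of a user-supplied
region (chromosome-arm tiling is arm-relative; arm boundaries are inputs),
last window truncated. `n_het` counts heterozygous and `n_hom`
homozygous-alt variant calls; hom-ref sites carry no evidence in
variant-only call sets and are excluded, and a window with no variant calls
reports a missing average rather than 0. Output is per-sample; callers may
average across samples if desired.

## The filter cascade

Four independent predicates, applied in a fixed order only so that each
failure is charged to one named filter (the survivor set is provably
order-invariant, and a permutation test asserts it):

1. *functional*: consequence in {missense, stop gained/lost, start lost,
   frameshift, in-frame indel, splice acceptor/donor}. Splice classes are
   included by default because predicted splice alleles are potentially
   deleterious under a recessive model; the set is configurable.
   Unannotated variants fail by default (configurable).
2. *rare*: AF strictly < `max_maf` (default 0.01) in every configured
   database (default ExAC, 1000 Genomes, TOPMED). A variant absent from a
   database is treated as rare — absence is itself evidence of rarity — with
   a strict mode for sensitivity analysis.
3. *recessive pattern*: every affected sibling hom-alt, every unaffected
   sibling at most het. A missing genotype in any required sample fails
   (conservative: no-calls must not create candidates).
4. *region restriction*: variant position inside any shared-LOH segment.

Each variant accumulates a trail of (filter, pass/fail/not-evaluated,
detail) verdicts; every input variant ends up either a survivor or charged
to exactly one failing filter. The parental segregation check (both parents
het) is reported per survivor, never used as a hard filter — in the study
design it is a post-hoc confirmation.

## The synthetic-data generator

Gene dropping with labelled founder haplotypes. Each founder receives two
unique labels; each meiosis draws crossovers as a Poisson process at
`recomb_rate` (default 0.01 Morgan/Mb — the Haldane no-interference model,
sufficient for segment-length statistics) and a random starting phase, and
transmits the resulting mosaic. An offspring is autozygous wherever its two
labels coincide; those tracts, recorded per child before any error
injection, are the ground truth.

The default pedigree realizes "consanguineous" as first-cousin parents (the
degree is a default, not an inference): a shared grandparental couple, their
two children married to unrelated founders, the two first-cousin parents,
and 3 affected + 2 unaffected children — 13 individuals. The default genome
is 4 × 25 Mb at 100 markers/Mb (~10,000 markers), a deliberate scale-down
of a 3 Gb genome at array density chosen to keep simulation-heavy tests and
calibrations fast while leaving segment statistics meaningful; marker
alt-allele frequencies are Uniform(0.05, 0.5) so heterozygosity is dense
enough for LOH contrast. Background variants (0.5/Mb) get consequences from
a fixed categorical mix, 60%/40% common/rare AFs jittered per database
(each database entry present with probability 0.9), and genotypes by
transmission from Bernoulli-chosen carrier founder haplotypes.

The causal variant is planted inside a tract autozygous *for the same
founder label* in every affected child and clear of any unaffected
autozygosity; by construction all affected children are hom-alt, both
parents are het carriers, and unaffected siblings are het or hom-ref. Its
default annotation profile is an ultra-rare missense allele (AFs 0.014%,
0%, 0.02%; CDS offset 230 = codon 77). Planting requires a tract of at
least `min_causal_tract_bp` (default 2 Mb): shorter tracts would be
invisible to ROH scans at array density and are not how recessive disease
segments present in first-cousin offspring.

On a ~1 Morgan scaled genome only a small fraction of haplotype drops
contain such a tract (three-way same-label sharing is a rare event when the
genome holds only a handful of independently segregating blocks, although
it is near-certain at whole-genome scale). `simulate()` therefore walks a
deterministic sequence of sub-seeds derived from the base seed, checking
feasibility on the (cheap) haplotype drop before generating markers and
variants, and also rejecting drops in which a background variant
coincidentally satisfies the functional+rare+recessive predicates — the
planted variant is a *guaranteed-positive, guaranteed-unique* control, and
that contract is enforced by construction, not by test-time luck. All
stochastic operations are pure functions of (inputs, seed).

Genotyping error corrupts each panel call independently with probability
`genotyping_error_rate`, replacing it with a uniform choice among the other
three codes in {-1, 0, 1, 2}. The causal variant lives in the variant list,
not the marker panel, so it is never corrupted; error robustness is a
property of ROH detection over background markers.

What the generator does *not* emulate: linkage disequilibrium and realistic
allele-frequency spectra in founders (haplotypes are label-exchangeable),
crossover interference, X-linked inheritance, de novo mutation, population
stratification in the AF databases, and platform-specific error structure
(errors are i.i.d. uniform). Passing the end-to-end tests therefore shows
the *logic* of the pipeline is correct under the recessive model, not that
the default thresholds are optimal for any particular array or caller.

## Population-genetic computations

* Allele frequency from a carrier screen: `(n_het + 2 n_homalt) / (2
  n_typed)`, missing genotypes excluded from the denominator; display
  formatting uses percent (4 significant digits), matching the convention
  of reporting e.g. one heterozygote among 2,000 individuals as 0.025%.
* Hardy–Weinberg expectations `((1−q)², 2q(1−q), q²)`; the homozygote
  prevalence of a 2.8%-frequency allele prints as 0.08% at two-decimal
  percent rounding.
* Inbreeding coefficient by Wright's path counting over common ancestors
  with vertex-disjoint path pairs and recursive (memoized) ancestor
  inbreeding. The test oracle is an independent single-locus Monte-Carlo
  gene drop on five canonical pedigrees (first cousins 1/16, second cousins
  1/64, half-sibs 1/8, avuncular 1/8, double first cousins 1/8).

## Protein burden and codon arithmetic

CDS offset `c` maps to codon `⌈c/3⌉`, base `((c−1) mod 3) + 1`; single-base
substitutions translate through the standard genetic code (Biopython), with
three-letter HGVS-style names (stop = `Ter`). The burden track sums (or
takes the max of) per-database allele frequencies of coding variants at
each residue; under summation total mass is conserved. Domain intervals
(e.g. EF-hands) are configuration inputs — the example boundaries shipped
with tests are placeholders, not curated annotations — and the TSV is the
tested surface; the figure is a convenience.

## Assay arithmetic

ΔΔCt assumes perfect doubling per cycle (efficiency 2, no correction);
fold change is `2^(−ΔΔCt)` and is antisymmetric in log space under swapping
test and control. Membrane/total fluorescence ratio validates
`total > 0` and warns (optionally clamps) when segmentation yields
membrane > total. Disease-activity index is the sum of stool-consistency,
blood and weight-change subscores; the composite histology score is the sum
of component scores times an involvement score. Subscale ranges default to
0–4 (the common DSS-colitis convention) and are configuration-driven, since
exact scale definitions vary between studies.

## Numerical and convention choices

* One coordinate convention internally (0-based half-open); conversion to
  1-based display coordinates happens in exactly one tested function pair.
* Genotype codes: 0 hom-ref, 1 het, 2 hom-alt, −1 missing; any GT
  containing `.` maps to −1.
* Multi-allelic VCF records decompose per ALT; scalar INFO values are
  duplicated across the decomposed records, array-valued (`Number=A`) keys
  split positionally.
* MAF comparison is strict `<`.
* Interval algebra results are coalesced and disjoint; per-sample
  provenance survives only operations on a single track (merge), not set
  algebra across samples.

## Problem sizes used by tests and the acceptance script

Brute-force ROH equivalence on 200-marker panels (120 random cases in the
property test, 200 in the headline check); per-base shared-LOH algebra on
10–100 kb coordinate spaces (100 cases); 3,000–5,000 replicate offspring
for the autozygosity calibration (3σ agreement with F = 1/16); 3–5
simulated datasets at 0.5% genotyping error for segment recovery. These
sizes make the full suite run in seconds while keeping Monte-Carlo standard
errors far below the tested tolerances.
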
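# rohmap

Autozygosity mapping and recessive-variant prioritization for consanguineous
pedigrees.

When the parents of a sibship are related (e.g. first cousins), an affected
child with a recessive disease is typically *autozygous* at the disease
locus: both chromosome copies descend from a single ancestral haplotype
through the pedigree loop. On genotype data this shows up as a long run of
homozygosity (ROH). `rohmap` implements the classic gene-discovery workflow
for such families:

1. **ROH detection** — per-sample scan of a dense genotype panel for maximal
   marker runs that are (almost) entirely homozygous;
2. **shared-LOH mapping** — per-base interval algebra: regions homozygous in
   *all* affected siblings and in *no* unaffected sibling;
3. **recessive filter cascade** — reduce annotated variants to candidates
   that are functional (non-synonymous in the broad sense, including splice
   classes), rare (AF < 1% in every configured population database),
   homozygous-alt in all affected and at most heterozygous in unaffected
   siblings, and located inside the shared-LOH regions — with a per-variant
   audit trail and a parental segregation check;
4. **synthetic data** — a gene-dropping simulator (Poisson/Haldane
   crossovers through a first-cousin loop) that produces PED/VCF/panel files
   with known ground truth: the autozygous tracts of every child and a
   planted causal variant that the pipeline must rediscover.

It also ships the small companion computations such a study reports:
Hardy–Weinberg genotype frequencies, carrier-screen allele frequencies,
Wright's path-counting inbreeding coefficient, CDS→codon→amino-acid mapping
and per-residue variant-burden tracks with protein-domain annotation, and
bench-assay arithmetic (ΔΔCt fold change, membrane/total intensity ratio,
secretion normalization, colitis disease-activity and histology scores).

## Core definitions

* ROH: a maximal run of consecutive markers containing at most `max_het`
  heterozygous and `max_missing` missing calls, with at least `min_markers`
  markers spanning at least `min_length_bp` (defaults 1/5/50/1 Mb).
* Shared LOH: `(∩ ROH of affected) \ (∪ ROH of unaffected)`, computed
  per base on half-open intervals.
* Recessive pattern: every affected sample coded hom-alt (2), every
  unaffected sibling ≤ het (1); missing genotypes fail conservatively.
* Wright's inbreeding coefficient:
  `F = Σ_A Σ_paths (1/2)^(n1+n2+1) (1 + F_A)` over common ancestors `A` and
  vertex-disjoint parent-to-ancestor path pairs; `F = 1/16` for offspring of
  first cousins.
* Hardy–Weinberg: genotype frequencies `((1−q)², 2q(1−q), q²)` at alt-allele
  frequency `q`.

All internal coordinates are 0-based half-open (BED convention); PED, VCF
and table-style coordinates are 1-based and converted at the I/O boundary.

## Worked example

Simulate the default family — first-cousin parents, three affected and two
unaffected children, a 100 Mb genome at 1 cM/Mb with ~10,000 markers — then
map shared autozygosity and run the filter cascade:

```console
$ rohmap simulate --out demo --seed 11
wrote dataset to demo
planted causal variant at chr3:1138457 G>A

$ rohmap shared-loh --panel demo/panel.tsv --affected P1,P2,P3 \
      --unaffected S1,S2 --out shared.bed
1 shared segments (2300730 bp) -> shared.bed

$ rohmap filter --vcf demo/variants.vcf --ped demo/family.ped \
      --regions shared.bed --out report.tsv
1 surviving candidates -> report.tsv
  chr3:1138457 G>A GENE_CAUSAL segregation=consistent
```

Of the ~60 annotated variants, exactly one survives the cascade: the planted
causal variant, inside the single 2.3 Mb region autozygous in all three
affected siblings and neither unaffected sibling, with both parents
heterozygous carriers — the textbook recessive discovery. Companion
calculations:

```console
$ rohmap kinship --ped demo/family.ped --individual P1
F(P1) = 0.0625

$ rohmap hwe --q 0.028
{"f_homref": 0.944784, "f_het": 0.054432, "f_homalt": 0.000784, "homalt_percent": 0.08}
```

`F = 0.0625 = 1/16` is the expected autozygous genome fraction for a child
of first cousins, and a 2.8%-frequency allele is expected to occur
homozygous in 0.08% of individuals.

Every command is also available as a library call (`rohmap.autozygosity`,
`rohmap.variant_prioritization`, `rohmap.synthetic_pedigree`,
`rohmap.popgen_stats`, `rohmap.protein_burden`, `rohmap.assay_quant`).

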
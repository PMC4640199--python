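# enumapper

Positional cloning of ENU-induced mutations in inbred mice from pooled
sequencing — using the induced variants themselves as mapping markers.

## The problem

Phenotype-driven ENU mutagenesis screens recover recessive mutants on an
inbred background, where no strain-specific polymorphisms exist to map
against. But ENU itself supplies the markers: a mutagenized founder's G1 son
carries ~3000 private single-base variants (~1/Mb). In the G1 × G2 backcross
scheme (G1 male × wild-type females; G2 daughters backcrossed to the G1),
a recessive mutation surfaces in G3 offspring, and every G1 variant
segregates like an ordinary marker.

For any single G3 mouse, an unlinked G1 variant is homozygous with
probability

    P(hom) = P(G2 dam carries) × P(hom | carrier dam) = 1/2 × 1/4 = 0.125,

so a fully penetrant recessive affects 12.5 % of G3 progeny, and the chance
that *all N* mice of a sequencing pool are homozygous at an unlinked locus
is 0.125^N (≈ 2 × 10⁻⁴ at N = 4). Sequencing a pool of affected mice
(un-barcoded) therefore exposes the causal locus as the one genomic interval
where the pooled non-reference allele frequency (NAF) is ~1 and nearly every
marker is classed homozygous, against a background of ~50 % NAF (carrier-dam
loci) elsewhere.

`enumapper` implements the full method:

* **variant_model** — VCF/BED/TSV I/O, variant and interval containers;
* **variant_filter** — the marker filtering cascade (known databases,
  repeats, qual < 30, depth < 5, multiallelic, sex chromosomes) and the
  virtual-exome restriction;
* **homozygosity_mapper** — sliding-window statistics (hom count, hom %,
  average NAF), region calling by the homozygosity or NAF criterion, and
  genome-track plots;
* **candidate_caller** — damaging-category candidate extraction
  (non-synonymous, stop gain/loss, splice-site within 10 bp of an exon) and
  segregation-concordance scoring;
* **cross_genetics** — exact backcross transmission probabilities with
  Monte-Carlo cross-checks;
* **enu_cross_simulator** — a forward simulator of the breeding scheme
  (Haldane meiosis, pooled read sampling) with a truth channel, standing in
  for real pooled data.

## Worked example

Simulate a default screen (19 × 130 Mb autosomes, 1.2 variants/Mb, pool of
4 affected mice at 15× pooled coverage), filter, map and call candidates:

```sh
enumapper run-all --seed 1 -o demo/
```

prints (log lines abridged):

```
simulate: 2969 variants, causal 19:49918857
filter: 2605 -> 2605 variants
map: 1 region(s) by homozygosity criterion
candidates: 2
{
  "criterion_used": "homozygosity",
  "threshold": 75.0,
  "n_regions": 1,
  "regions": [
    {"chrom": "19", "start": 40000000, "end": 65000000, "peak": 100.0}
  ]
}
```

One 25 Mb region on chromosome 19 reaches 100 % window homozygosity, and it
contains the causal variant (19:49918857). The candidate table holds two
coding/splice variants, both at NAF 1.0 and therefore tied at rank 1 —
markers riding the same intact recombinant haplotype are indistinguishable
from pooled reads alone, so the final discrimination is by genotyping
further mice (`enumapper concordance`). With `--spike`, one pooled mouse is
replaced by a non-homozygote; the homozygosity criterion then finds nothing
and the pipeline falls back to the NAF criterion (windows with average
NAF > 0.7).

The closed-form genetics are available directly:

```sh
$ enumapper power --pool-size 4 --penetrance 1.0
p_homozygous_unlinked                      0.125
p_spurious_region                          0.000244141
expected_affected_fraction                 0.125
expected_pool_naf_unlinked_dam_carrier     0.5
expected_pool_naf_unlinked_marginal        0.375
```

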
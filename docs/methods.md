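# Methods

## Model and assumptions

The package models a standard three-generation ENU screen on an inbred
background. A G0 male is mutagenized; his G1 son inherits one mutagenized
gamete and therefore carries every induced variant on a single haplotype per
chromosome (the other homolog is wild type). The G1 male is crossed to
wild-type females and backcrossed to his G2 daughters; recessive phenotypes
appear in G3 offspring homozygous for the causal variant.

Transmission probabilities follow from Mendelian segregation: a G2 daughter
carries a given G1 variant with probability 1/2, and the het × het backcross
offspring of a carrier dam is homozygous with probability 1/4, giving 1/8
per G3 mouse at any G1 variant (causal or unlinked). All closed forms in
`cross_genetics` are exact rationals; floats only enter through a non-dyadic
penetrance. Two unlinked-locus NAF expectations are exposed: conditioning on
a carrier dam gives 1/2 (the "random 50 %" background the mapping contrast
relies on), while the unconditional expectation is 3/8 — the two differ and
both are computed by explicit enumeration rather than assumed.

Zygosity of a pooled site cannot be observed per mouse; it is defined from
the read fraction: a site is classed homozygous iff its NAF ≥ 0.9
(configurable `hom_naf_threshold`). This is consistent with validated causal
candidates being reported at NAF ≈ 1 and with the ~0.5 background at
heterozygous loci.

## Synthetic data

`enu_cross_simulator` draws the founder's variants as Poisson(1.2/Mb) with
uniform positions on a desk-scale genome of 19 × 130 Mb autosomes (~2.47 Gb,
mouse-like; configurable). 5 % of variants are exon-resident, split
50 % non-synonymous / 25 % synonymous / 20 % splice-site / 5 % stop-gain;
the remainder are intronic (35 %) or intergenic (65 %). One damaging-category
variant (non-synonymous, stop-gain or splicing) is designated causal — a
recessive phenotype implies a deleterious allele, and a synonymous "causal"
would be invisible to the candidate filter by design.

Meiosis uses the Haldane model: crossover counts Poisson in map length at
0.5 cM/Mb, uniform breakpoints, no interference. G3 offspring are drawn from
4 G2 dams until the pool (default N = 4) of affected mice — homozygous
causal and penetrant (default penetrance 1) — is filled. Dam sets with no
carrier of the causal variant are redrawn: such pedigrees produce no
affected mice and would never be sequenced. This conditioning slightly
inflates the affected fraction among screened offspring in pooled runs
(~0.133 at 4 dams), so the 12.5 % expectation is checked with
`simulate_screen`, which draws pedigrees unconditionally.

Pooled reads are sampled per site as depth ~ Poisson(15) and alt reads ~
Binomial(depth, dosage/2N), with an optional per-read error flip (default
10⁻³). Sites with no alt reads are not emitted — a pooled caller would not
report them — which reproduces the ascertainment that raises the observed
marginal unlinked NAF above 3/8. `spike_outlier` replaces one pooled mouse
with a non-homozygote (het or wild type at the causal locus), the failure
mode that defeats strict homozygosity mapping.

What the simulator does *not* emulate: real mouse chromosome lengths and
recombination maps, non-uniform mutation spectra, alignment and calling
artefacts, indels, structural variants, strain contamination, or X/Y (the
breeding scheme cannot maintain sex-linked mutations). Passing recovery
tests therefore demonstrate the statistical logic of the method under its
own assumptions, not robustness to upstream bioinformatic error.

## Filtering and mapping parameters

| parameter | default | meaning |
|---|---|---|
| `min_qual` | 30 | site quality floor (strict: qual = 30 passes) |
| `min_depth` | 5 | read-depth floor (strict: depth = 5 passes) |
| window `size` | 20 Mb (library) / 10 Mb (pipeline) | sliding-window width |
| window `step` | 1 Mb | slide between window starts |
| `hom_naf_threshold` | 0.9 | pooled NAF at/above which a site is "hom" |
| `min_snps` | 5 | markers required before a window may call a region |
| hom region threshold | hom_pct > 75 | primary (homozygosity) criterion |
| NAF region threshold | avg_naf > 0.7 | fallback criterion |

Removal rules are attributed in a fixed order (known → repeat → qual →
depth → multiallelic → sex chromosome), so the filter report is a
deterministic partition of the input. Known-variant matching requires
chrom+pos+ref+alt identity; a novel alt allele at a known SNP position is
still treated as novel.

Window geometry: windows start at multiples of the step; the final window is
truncated at the chromosome end so every autosomal bp is covered. The "1 Mb
overlap" of the window scheme is implemented as a 1 Mb *step* (consecutive
20 Mb windows share 19 Mb); the step is configurable so the literal reading
(step = size − 1 Mb) is also available. Windows with no markers carry
undefined metrics, are excluded from region calling, and are dropped from
plots rather than drawn as zero.

Region calling: a window qualifies iff it has ≥ `min_snps` markers and its
metric strictly exceeds the threshold; overlapping or abutting qualifying
windows merge (no gap-bridging); regions are ranked by peak metric with ties
in genome order. A region's `n_snps` is the maximum marker count among its
member windows (a lower bound on distinct markers in the span).

### Calibration of the region thresholds

No homozygote-percentage threshold is inherent to the method, and the
recombinant interval shared by N pooled mice is frequently shorter than
20 Mb (its half-width is roughly exponential with rate ≈ (8+d) × r per side
for N = 4 mice from d carrier dams at recombination rate r), so a 20 Mb
window demanding > 90 % homozygous markers misses truncated intervals. The
pipeline defaults were chosen by simulation at the default study conditions
*before* the recovery tests were frozen: 10 Mb windows with hom_pct > 75
recover a causal-containing region in ~0.98 of clean pools while still
calling *no* region in most spiked pools (a het outlier caps interval sites
at NAF ≈ 7/8, i.e. ~40 % of sites classed hom), which is what lets the auto
pipeline fall back to the NAF criterion. On the test replicates the measured
rates are 0.975 clean-pool recovery (200 replicates), with the causal
mutation at rank 1 in all recovered cases, and 0.70 spiked-pool fallback
with 0.68 joint fallback-and-recovery (100 replicates; regression threshold
frozen at 0.5).

### Candidate ranking

Candidates are damaging-category variants inside a mapped region, kept
either by zygosity (hom mode) or by a NAF floor (default 0.7, fallback
mode), ordered by descending NAF. Markers on the same intact recombinant
haplotype have identical pooled NAF (exactly 1.0 in the error-free limit),
so ties are genuine: candidates carry a competition rank (1224-style; tied
candidates share a rank). Discrimination among tied candidates is by
segregation concordance in individually genotyped mice; a single discordant
mouse (affected non-homozygote or unaffected homozygote) excludes a
candidate.

## Numerical and degenerate-input choices

* Coordinates are 1-based in VCF, 0-based half-open everywhere internally;
  conversions happen only at I/O boundaries.
* Window scoring uses O(V + W) difference arrays over the regular window
  grid and is verified against a naive per-window rescan.
* Zygosity at depth 0 is an error (the default pipeline guarantees
  depth ≥ 5); parsing records without depth fields yields depth 0 with a
  warning (or an error in strict mode).
* Multiallelic records are parsed losslessly (NAF from the first alt) and
  removed by the filter, not the parser.
* Pre-attached annotations always win over interval-based annotation; the
  interval annotator returns exon-resident hits as category `unknown`
  because coding sub-categories require sequence-level annotation, which is
  out of scope.
* `draw_mutations` redraws once if no damaging exon-resident variant was
  drawn, then errors; `spike_outlier` requires a pool of ≥ 2.
* All randomness flows from one `numpy` generator seeded by the
  configuration; identical config + seed reproduces every output byte except
  timestamps.

## Problem sizes used in the checks

Recovery rates are measured over 200 clean and 100 spiked replicates at the
default genome (19 × 130 Mb, ~3000 variants); Monte-Carlo cross-checks of
the closed forms use 10⁵–10⁶ single-locus transmission draws, and the
affected-fraction check screens 20 000 simulated G3 offspring. These sizes
put the sampling error well below the tested margins.

## Known limitations

* The homozygosity-threshold calibration is specific to the default study
  conditions (N = 4, 15×, 0.5 cM/Mb); other designs should re-run the
  calibration (`find_regions` takes any threshold).
* Pooled NAF cannot separate tightly linked candidates; the package ranks
  and reports ties honestly rather than pretending resolution it lacks.
* No statistical significance model beyond the threshold rules; region
  calls are descriptive, as in the underlying method.
* Functional annotation is consumed, never computed: no codon-table logic,
  no effect prediction (external predictor scores are display-only).
* No indels, no multi-pool contrasts, no read-level (FASTQ) simulation.
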
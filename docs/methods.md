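# Methods

This note records the model assumptions, parameter defaults and numerical
choices behind `ciliaseek`, and the scope of the synthetic-cohort
generator used for validation.

## Coordinate model

A transcript is a strand-aware list of 1-based inclusive genomic exon
intervals plus the spliced cDNA sequence and the CDS span in transcript
coordinates. Three coordinate systems are linked by total, invertible
maps over the transcribed bases:

- **genomic** (1-based contig position),
- **transcript** (1-based spliced cDNA position),
- **coding (HGVS c.)**: position 1 is the A of the initiator ATG; 5′-UTR
  positions are negative, 3′-UTR positions are `*n`, and intronic bases
  carry a signed offset from the nearest exonic base (`+d` past a donor,
  `−d` before an acceptor). Intron midpoints are assigned to the donor
  side (ties break toward the 5′ exon).

The codon ordinal of coding position `c` is `⌊(c−1)/3⌋ + 1` with in-codon
offset `((c−1) mod 3) + 1`; hence c.281 → codon 94 (offset 2) and c.85 →
codon 29 (offset 1).

## Consequence classes

Single-nucleotide variants are classified by rebuilding the affected
codon and comparing translations: `synonymous`, `missense`,
`stop_gained`, `stop_lost`, `start_lost`. Intronic SNVs are
`canonical_splice` at offsets ±1/±2 (no protein-level name is assigned),
`splice_region` at offsets 3–8, and `intronic` beyond. Exonic bases near
a boundary keep their coding class and carry a separate splice-region
flag rather than being reclassified. Insertions and deletions within the
CDS are `frameshift` when the length change is not a multiple of three,
`inframe_indel` otherwise; deletions straddling an exon boundary are
`canonical_splice`. Indel names are 3′-shifted per HGVS convention and
duplications are reported as `dup`. Reference alleles are checked against
the genome/cDNA and any disagreement raises an error naming the position.

The *functional* set used by the cascade is {missense, stop_gained,
stop_lost, start_lost, canonical_splice, frameshift, inframe_indel}.

## The rare-recessive cascade

Per sample, in order, with per-step counts recorded:

1. **Region restriction**: keep variants within the panel BED intervals
   padded by `window` bases (default **100**, matching typical bait
   flanks).
2. **Frequency filter**: keep variants absent from every population
   resource (novel) or with maximum reported minor allele frequency
   `< 0.01` (default threshold; frequencies above 0.5 are folded).
3. **Zygosity partition**: split carriers into heterozygous and
   homozygous-alternate sets; by construction
   `het + hom = maf_filtered`, an identity the report validator enforces
   together with monotonicity along each branch.
4. **Functional filter** per branch.
5. **Gene model**: a gene is a candidate for a sample with ≥ 1 homozygous
   or ≥ 2 distinct heterozygous qualifying variants.
6. **Panel intersection**: case-insensitive intersection with the
   cilia-gene list; an empty list is a configuration error rather than an
   empty result.

## Segregation

Pedigrees are validated (resolvable parents, acyclic ancestry). A trio
genotype is Mendelian-consistent when the child's alleles can be drawn
one from each parent; a missing or ungenotyped parent is unconstrained.
Compound heterozygotes are phased through parental carriage: *trans* when
each parent carries exactly one of the two alleles, *cis* when one parent
carries both and the other neither, otherwise unknown. A gene is
**supported** in a family when every genotyped affected member is
biallelic (homozygous, or double-het — phase-verified when parents
establish *trans*) and no unaffected member is; it is **excluded** when
an unaffected member is homozygous or established-*trans* biallelic, or
when an affected member is not biallelic. An unaffected double
heterozygote of unknown phase does **not** exclude (the alleles may be in
*cis*). Families without informative genotypes are **uninformative**.
Verdicts are deterministic and invariant to member ordering.

## Domain mapping

The bundled RSPH1 annotation holds seven Pfam MORN repeats (residues
26–43, 44–66, 67–89, 90–112, 113–133, 137–152, 159–181; consensus length
23) and a low-complexity region (238–251) on the 309-residue protein.
A premature stop at residue `k` retains fraction `(k−1)/309` and loses
every interval whose end lies at or beyond `k` (an interval containing
`k` counts as lost/truncated). Splice variants have no residue of their
own; they are mapped via the first coding base of the downstream exon and
flagged `inferred`.

## Carrier-frequency check

For a fully penetrant recessive disease with birth prevalence `P` and a
fraction `s` of disease attributable to the locus, Hardy–Weinberg gives
allele frequency `q = √(P·s)` and carrier frequency `2q(1−q)`. Observed
heterozygous carriers among `n` control individuals are tested against
`Binomial(n, 2q(1−q))` at the upper prevalence bound with an exact
two-sided binomial test (`scipy.stats.binomtest`). The verdict is
*consistent* when the observed rate is at or below the expectation or the
p-value exceeds `alpha` (default **0.05**) — only a carrier excess argues
against pathogenicity. Defaults: prevalence 1/30 000–1/15 000 (the PCD
range); `locus_share` **0.04** is an order-of-magnitude placeholder for
one gene among many and should be set explicitly when the attributable
fraction is known. Homozygotes among unaffected controls are flagged
separately, since they contradict full penetrance directly.

## Synthetic cohort generator

The generator's defaults are the study conditions, not tuning knobs.

- **Fixture transcript**: 8 exons, 1400 nt cDNA over 24 000 nt of
  genomic sequence, 100 nt 5′ UTR, 309 coding residues, with residue 29
  pinned to Glu (GAG), residue 94 to Trp (TGG), and exon 4 starting at
  coding position 275 — so c.281G>A → p.Trp94\*, c.85G>T → p.Glu29\*,
  and c.275−2A>C destroys the canonical acceptor AG. A minus-strand twin
  shares the cDNA. All other codons, exon-length compositions (minimum
  30 nt) and intron sequences (minimum 200 nt, GT…AG) are drawn from
  `numpy.random.default_rng(seed)`.
- **Panel**: 24 genes, each on its own contig with alternating strands —
  the fixture plus seven further cilia genes and sixteen background
  genes; bait regions cover full transcript spans. This is a deliberately
  scaled-down stand-in for a production panel of hundreds of genes.
- **Cohort**: defaults of 70 cases (trio families) and 50 unrelated
  controls. Background variants (default 2000, SNVs only) are placed
  uniformly over gene spans with true allele frequencies from a
  Beta(0.15, 1.5) distribution truncated to (0, 0.5] — a rare-skewed
  spectrum — and genotypes sampled per individual as Binomial(2, q)
  (Hardy–Weinberg, independent across samples). Each case is planted
  with a biallelic loss-of-function configuration in the causal gene
  (compound heterozygous in *trans* through obligate-carrier parents by
  default, or homozygous with a consanguineous first-cousin pedigree for
  family 1 in homozygous mode). Controls carry no planted allele.
  Planted alleles have true population frequency 5/13 000 and alternate
  between novel and present in one resource. The population frequency
  table reports each background variant in each of three resources with
  probability 0.7 and 10% multiplicative noise, with 10% of variants
  fully novel. Optional missingness applies to background rows only
  (planted genotypes model confirmed calls).
- **Determinism**: a single integer seed drives everything; identical
  specs yield byte-identical output files.

## Numerical choices

- Exact integer arithmetic throughout the coordinate maps; no floating
  point enters annotation or the cascade.
- Frequency folding (`maf > 0.5 → 1 − maf`) guards against
  major/minor-allele swaps in resource tables.
- The binomial test is exact (no normal approximation); for rare
  prevalence the carrier frequency is within 1% of `2√(P·s)`.
- Interval overlap uses an interval tree; results equal a naive linear
  scan (property-tested).

## Limitations

- Background cohort genotypes are i.i.d. across individuals — parents
  and children are unrelated at background sites; only planted genotypes
  follow Mendelian transmission. Segregation tests therefore see
  realistic planted signal but background "de novo" noise.
- The generator emits SNVs only; indel handling is exercised by unit
  tests rather than cohort simulation.
- One transcript per gene; no alternative splicing.
- The carrier model assumes full penetrance and a single locus share; it
  is a plausibility screen, not an association test.
- The panel and cohort are scaled down (24 genes, 2000 background
  variants) relative to a production design; absolute per-sample counts
  are therefore not comparable to a clinical panel, though every
  internal identity and ordering property is.
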
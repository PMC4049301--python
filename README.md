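# ciliaseek

Rare-recessive variant prioritization for targeted ciliopathy gene panels.

`ciliaseek` implements the analytical core of a gene-panel study design for
primary ciliary dyskinesia (PCD), the recessive disorder of motile cilia:
starting from a multi-sample VCF over a panel of candidate genes, it
annotates variants against transcript models, applies the classic
rare-recessive filtering cascade, tests candidate genes for co-segregation
in pedigrees, maps truncating alleles onto protein domains, and checks
control-population carrier counts against Hardy–Weinberg expectations. A
deterministic synthetic-cohort generator with planted causal genotypes
provides end-to-end validation without any patient data.

## Scientific background

In the central-pair-deficiency subtype of PCD, biallelic loss-of-function
alleles of the radial-spoke-head gene *RSPH1* (309 residues, seven ~23-aa
MORN repeats) are a recurrent cause. The discovery workflow this package
reproduces is:

1. **Consequence annotation.** Each variant is mapped from genomic to
   coding (HGVS c.) coordinates through a transcript model; coding
   substitutions get a codon ordinal `⌈c/3⌉` and a protein-level name
   (e.g. c.281G>A → p.Trp94\*; c.85G>T → p.Glu29\*), and intronic variants
   get a signed offset from the nearest exon boundary (c.275−2A>C is the
   −2 acceptor base of an exon, a canonical splice site).
2. **Rare-recessive cascade.** Per sample: restrict to the panel regions
   (±100 bp), drop alleles with minor allele frequency ≥ 0.01 in any
   population resource, split the survivors by zygosity, keep functional
   classes (missense, nonsense, splice, frameshift, in-frame indel), and
   call a gene a candidate when one sample carries either ≥ 1 homozygous
   or ≥ 2 heterozygous qualifying alleles; finally intersect with the
   cilia-gene list. The het and hom branches partition the
   frequency-filtered set, so per-sample counts obey
   `het + hom = maf_filtered` — an identity the report validator enforces.
3. **Segregation.** Within each family, candidate genotypes are checked
   for Mendelian consistency; compound heterozygotes are phased through
   parental carriage (in *trans* when each parent carries exactly one
   allele), and a gene is *supported* when every affected member is
   biallelic and no unaffected member is, *excluded* when an unaffected
   relative carries the same biallelic configuration.
4. **Domain mapping.** Premature stops are placed on the MORN-repeat
   architecture: p.Glu29\* falls in repeat 1 and removes all seven
   repeats; p.Trp94\* falls in repeat 4 and retains 30% of the protein.
5. **Carrier-frequency check.** Under Hardy–Weinberg, a fully penetrant
   recessive allele with locus-attributable prevalence `P·s` has allele
   frequency `q = √(P·s)` and carrier frequency `2q(1−q)`; an exact
   binomial test asks whether observed control carriers exceed that.

## Worked example

Simulate a small cohort (two trios, four controls) and run the pipeline:

```sh
$ ciliaseek simulate --out-dir demo/inputs --seed 7 --cases 2 --controls 4 \
      --background-variants 300
wrote 8 files to demo/inputs (seed 7)

$ ciliaseek annotate --vcf demo/inputs/cohort.vcf \
      --transcripts demo/inputs/transcripts.json \
      --genome demo/inputs/genome.fa --out demo/annotations.tsv
annotated 304 variants -> demo/annotations.tsv

$ ciliaseek filter --vcf demo/inputs/cohort.vcf \
      --freq demo/inputs/frequencies.tsv --panel-bed demo/inputs/panel.bed \
      --gene-list demo/inputs/cilia_genes.txt \
      --transcripts demo/inputs/transcripts.json \
      --genome demo/inputs/genome.fa \
      --samples CASE001,CTRL001 --report demo/cascade.tsv
CASE001: final candidate genes: RSPH1
CTRL001: final candidate genes: (none)
```

The per-sample cascade report (`demo/cascade.tsv`, shown wide):

```text
step     total  maf_filtered  het  het_functional  genes_compound_het  genes_compound_het_cilia  hom  hom_functional  genes_hom_cilia
CASE001     36             5    4               3                   1                         1    1               1                0
CTRL001     21             2    2               1                   0                         0    0               0                0
```

Note `het + hom = maf_filtered` on every row. Segregation confirms the
candidate in both families (FAM001 with genotyped parents verifying the
*trans* phase, FAM002 supported without phase verification):

```sh
$ ciliaseek segregate --vcf demo/inputs/cohort.vcf --ped demo/inputs/cohort.ped \
      --transcripts demo/inputs/transcripts.json --genome demo/inputs/genome.fa \
      --gene RSPH1 --out demo/segregation.tsv
wrote 6 verdicts -> demo/segregation.tsv
$ grep FAM demo/segregation.tsv
FAM001	RSPH1	supports	yes
FAM002	RSPH1	supports	no
```

The carrier-frequency check for an allele seen heterozygous in 9 of 6500
control exomes, under a disease prevalence of 1/30 000–1/15 000:

```sh
$ ciliaseek carriers --het 9 --n 6500
{
 "verdict": "consistent",
 "p_value": 0.004491293604949173,
 "observed_carrier_rate": 0.0013846153846153845,
 "expected_carrier_low": 0.0023067344100918363,
 "expected_carrier_high": 0.003260652990377571,
 "hom_in_controls": false,
 "locus_share": 0.04,
 "locus_share_note": "locus share defaults to a placeholder; set --share when known"
}
```

The observed rate sits *below* the expected carrier band, so the allele is
compatible with full-penetrance recessive pathogenicity (only a carrier
excess argues against it).

The same arithmetic through the Python API:

```pycon
>>> from ciliaseek.synthetic import FixtureSpec, make_rsph1_fixture
>>> from ciliaseek.consequence import classify_consequence
>>> from ciliaseek.variants import Variant
>>> from ciliaseek.transcripts import CodingCoordinate
>>> from ciliaseek.domains import rsph1_domains, locate_residue, truncation_extent
>>> fx = make_rsph1_fixture(FixtureSpec())
>>> tx = fx.transcript
>>> g = tx.coding_to_genomic(CodingCoordinate(281))
>>> rec = classify_consequence(tx, Variant(tx.contig, g, fx.genome[tx.contig][g-1], "A"), fx.genome)
>>> rec.csq_class.value, rec.c_hgvs, rec.p_hgvs, rec.codon_ordinal
('stop_gained', 'c.281G>A', 'p.Trp94*', 94)
>>> hit = locate_residue(rsph1_domains(), rec.codon_ordinal)[0]
>>> hit.interval.label, hit.ordinal, (hit.interval.start, hit.interval.end)
('MORN', 4, (90, 112))
>>> round(truncation_extent(rsph1_domains(), 94).fraction_retained, 3)
0.301
```

## Package layout

| Module | Contents |
| --- | --- |
| `ciliaseek.transcripts` | transcript model; genomic ↔ transcript ↔ coding coordinate arithmetic |
| `ciliaseek.hgvs` | HGVS c./p. parsing and formatting (substitutions, del/ins/dup) |
| `ciliaseek.consequence` | consequence classification against a transcript and genome |
| `ciliaseek.cascade` | the rare-recessive filtering cascade and its validated report |
| `ciliaseek.segregation` | pedigrees, Mendelian checks, phasing, co-segregation verdicts |
| `ciliaseek.domains` | protein-domain intervals, residue mapping, truncation extent |
| `ciliaseek.popgen` | Hardy–Weinberg carrier-frequency consistency test |
| `ciliaseek.synthetic` | deterministic fixture/panel/cohort generator with planted truth |
| `ciliaseek.cli` | the `ciliaseek` command-line interface |

See `docs/methods.md` for the model, parameter defaults and limitations.

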
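# qtnmap

Fine-mapping toolkit for quantitative trait loci (QTL) in half-sib
livestock designs. Given the QTL segregation statuses of a panel of
patriarch sires (from a daughter design) and their dense SNP genotypes,
`qtnmap` finds markers **concordant** with the QTL, computes the exact
probability that such concordance arises by chance, delimits the candidate
interval as the haplotype shared by all chromosomes carrying the favorable
marker allele, reconstructs gene variants from allele-specific amplicon
sequencing, and quantifies variant copy number from qPCR for association
with breeding values. A seeded synthetic-data generator makes every stage
testable end to end without external data.

It is written for geneticists fine-mapping QTL in dairy cattle and similar
designs, but nothing in the library is species-specific.

## The model in brief

A marker is fully concordant with a QTL across a sire panel when every
QTL-homozygous sire is marker-homozygous, every QTL-heterozygous sire is
marker-heterozygous, and all doubly heterozygous sires share one linkage
phase. Under the null of marker–QTL independence with marker allele
frequency *p* (*q* = 1 − *p*), the probability of the exact configuration
"all *n*<sub>hom</sub> homozygotes matched, all *n*<sub>het</sub>
heterozygotes matched, *k* of them on the designated phase" is

&nbsp;&nbsp;&nbsp;&nbsp;P = (p² + q²)<sup>n_hom</sup> · C(n_het, k) · (pq)<sup>n_het</sup>

and m·P is the expected number of markers reaching that level among m
tested. Copy number is quantified as the efficiency-corrected normalized
relative quantity NRQ ∝ E<sub>t</sub><sup>−Ct_t</sup> /
E<sub>r</sub><sup>−Ct_r</sup> against a non-CNV reference gene, rescaled
so the top sample equals 2. See `docs/methods.md` for the full account.

## Worked example

The package bundles the worked example it was built around: a 10-sire
Israeli Holstein daughter-design panel at the intergenic marker NGS-58779
on BTA7 (a fertility QTL), the sires' phased haplotypes over the 20
flanking SNPs, and the allele-specific amplicon base calls of the
duplicated *KIAA1683* gene's exon 3. Running

```
qtnmap reproduce
```

prints

```
concordance: 5/5 hom, 5/5 het, k=4 phase-correct -> 9/10 families (PHASE_PARTIAL)
chance probability (p=0.5): 0.000152588; expected over 704 markers: 0.1074
shared haplotype: 4.65-4.92 Mbp (span 270 kbp, consensus G-A-A-G-G-A, 9 carriers, 8 non-carrier chromosomes share it)
variants: 4 distinct (V3=ACTCCCA, V2=GCCATCG, V4=GCCCCCG, V1=ATCCCTG)
presence patterns: 4 (V1+V2+V3+V4:1; V1+V2+V3:5; V1+V3+V4:1; V2+V3:3)
NTC specificity bound at 4 cycles: 6.25%
```

Reading the numbers: all five QTL-homozygous sires are homozygous at the
marker and all five segregating sires are heterozygous, with four of the
five sharing the same marker–QTL phase — nine of ten families concordant.
A single independent marker reaches this configuration by chance with
probability 1.5 × 10⁻⁴, so among the 704 markers tested in the QTL
confidence interval only ~0.1 are expected by chance. The nine
chromosomes carrying the favorable "A" allele share one haplotype over
270 kbp (4.65–4.92 Mbp), the candidate interval for the causal variant;
its alleles are common, though — eight of the eleven "G" chromosomes carry
the same stretch. Deconvolving the allele-specific amplicons yields four
distinct gene variants in four distinct per-sire presence patterns, and a
≥4-cycle gap between the lowest standard and the no-template control
bounds nonspecific qPCR product below 6.25%.

The same stages are available as library calls (`qtnmap.classify_snp`,
`find_shared_region`, `collect_variants`,
`normalized_relative_quantity`, `regress_breeding_values`, …) and as CLI
subcommands `simulate`, `scan`, `haplotype`, `deconvolve`, `cnv`. A full
synthetic run:

```
qtnmap simulate --seed 7 --out run/
qtnmap scan --genotypes run/panel.tsv --phases run/phases.tsv --out run/scan.tsv
qtnmap cnv --ct run/qpcr.tsv --bv run/breeding_values.tsv \
       --target target --reference reference \
       --out-estimates run/nrq.tsv --out-regression run/assoc.tsv
```

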
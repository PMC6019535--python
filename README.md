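# ldprune

Whole-genome linkage-disequilibrium (LD) pruning of bi-allelic SNP panels.

High-density SNP arrays and whole-genome sequence data carry substantial
redundancy: many pairs of loci are in complete (r² = 1) or very high LD,
which inflates dimensionality and co-linearity in downstream analyses such
as genomic prediction. Standard tools prune LD inside a sliding window of
neighbouring loci; `ldprune` instead finds **every** pair of loci above an
r² threshold, genome-wide, while computing only a tiny fraction of the
(m² − m)/2 pairwise correlations.

## The algorithm

LD between loci *j* and *k* is the squared correlation between their phased
alleles a<sub>i,j,l</sub> ∈ {0, 1} (individual *i*, haplotype *l*),

r²(j,k) = ( Σ a<sub>i,j,l</sub> a<sub>i,k,l</sub> − Σa<sub>i,j,l</sub> Σa<sub>i,k,l</sub> / 2n )²
/ [ (Σa²<sub>i,j,l</sub> − (Σa<sub>i,j,l</sub>)²/2n)(Σa²<sub>i,k,l</sub> − (Σa<sub>i,k,l</sub>)²/2n) ],

or, without phase information, the analogous correlation between the
per-individual allele counts x<sub>i,j</sub> ∈ {0, 1, 2}. Two key facts make
global pruning tractable:

1. **Complete LD requires equal minor allele counts (MAC).** For phased 0/1
   alleles, r² = 1 forces the two minor-oriented allele vectors to be
   identical. Sorting loci by MAC and comparing vectors only inside
   equal-MAC groups — stopping at the first mismatching haplotype — finds
   all r² = 1 pairs without computing a single correlation.
2. **High LD bounds the partner's MAC.** With minor alleles coded 1, the
   cross-product term is at most the smaller MAC; for MACs c_j ≤ c_k the
   maximum achievable r² is c_j(2n − c_k) / (c_k(2n − c_j)). A precomputed
   *bound table* maps each MAC value to the largest partner MAC that can
   still exceed the threshold t, so only pairs inside that interval are
   candidates. Candidates are then screened with stored *partial sums* —
   minor-allele sums over nested subsets of the individuals (10 by default):
   if on any subset the commoner locus exceeds the rarer one by more than
   the full-data slack, r² > t is impossible and the pair is dropped. Only
   the few survivors get an exact r², of which only the cross-product is
   computed fresh. Loci at MAF exactly 0.5 are exempt from the screen
   because their minor-allele coding is ambiguous.

The two stages run sequentially; within each offending pair the "leftmost"
locus (lower MAC, earlier input position on ties) is removed. Allele-count
input reuses the phased machinery by treating double heterozygotes as if
the minor alleles shared a haplotype, and switches to the allele-count r²
only in the final exact step.

## Worked example

A five-locus panel (rows are loci, columns the four individuals' allele
counts), where locus 2 is the mirrored copy of locus 1:

```
$ printf '0 0 1 2\n2 2 1 0\n0 1 1 2\n0 1 2 1\n0 0 0 1\n' > panel.txt
$ ldprune prune --matrix panel.txt --r2 0.99 --out demo
INFO read 4 individuals x 5 loci (matrix)
INFO loci: input=5 monomorphic=0 complete_ld=1 high_ld=0 kept=4
INFO pairs: candidates=1 screened_out=0 r2_computed=1 (10.00% of all pairs, 16.67% after complete-LD pruning)
```

`snp1` is pruned as the earlier member of the complete-LD pair with `snp2`
(r² = 1 despite the opposite allele coding); `demo.prune.in` keeps
`snp2..snp5`. Of the 10 possible pairs only one candidate (the two MAF-0.5
loci `snp3`/`snp4`, r² = 0.25) ever reaches an exact r² computation.
`demo.pairs.tsv` records each removal with its partner, reason and r²:

```
locus_removed  partner  reason    r2   same_chromosome  distance
snp1           snp2     complete  1
```

Inputs can also be PLINK BED/BIM/FAM triplets (`--bed PREFIX`), phased VCF
(`--vcf FILE`, with `--mode phased` to compare haplotypes rather than
counts), or real-valued dosage matrices on [0, 2] (`--dosage-matrix`,
rounded to hard calls: ≤ 0.5 → 0, ≥ 1.5 → 2, else 1). Missing genotypes are
a hard error unless `--drop-missing-loci` is given. The cost of the
sliding-window alternative is available as
`ldprune window-cost --m M --window WS --step SS`.

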
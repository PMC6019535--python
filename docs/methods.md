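# Methods

## Model and procedure

`ldprune` removes one locus from every pair of bi-allelic loci whose
squared allele correlation exceeds a threshold t, over all pairs in the
panel rather than within a sliding window. Two measures of LD are
supported: the squared correlation between phased 0/1 alleles over the 2n
haplotypes (the Hill–Robertson r²), and the squared correlation between
per-individual allele counts 0/1/2. The count-based r² is the standard
proxy when phase is unknown; its expectation equals the phased r².

Pruning proceeds in two sequential stages over loci sorted by minor allele
count (MAC), stably, with input order breaking ties.

**Complete LD.** For phased alleles, r² = 1 is only possible when both loci
have the same MAC, and then only when the minor-oriented allele vectors are
identical. Each equal-MAC group is processed in input order against a
survivor list: a locus is compared against each survivor (directly when
both loci's minor alleles have the same stored code, against the complement
otherwise; both ways when MAC = n, where the coding is ambiguous), the scan
stopping at the first mismatching entry. On a match the earlier-appearing
locus is removed and the later one recorded as its partner, so in a clique
of g mutually identical loci the last one in the data survives — the
opposite of the keep-first habit of window-based tools, which is one reason
removal sets from different tools overlap imperfectly even at equal counts.

**High LD.** With minor alleles coded 1, the between-locus cross-product is
at most the smaller allele sum, giving a closed-form maximum r² for MACs
c_j ≤ c_k of c_j(2n − c_k) / (c_k(2n − c_j)). A bound table maps each MAC
value c to max_mac(c), the largest partner MAC for which this maximum still
exceeds t; it is built by the iterative partner-sum growth procedure (start
at c, grow while the threshold can be exceeded) and stores the last passing
value, making the candidate interval [c, max_mac(c)] tight. Candidates are
screened against stored partial sums — minor-oriented allele sums over
nested prefixes of the individuals — rejecting a pair whenever any subset
gap exceeds the full-data slack max_mac(c_j) − c_j. Survivors get an exact
r², computing only the cross-product fresh; on the first partner with
r² > t the lower-MAC locus is removed and its scan stops. Pairs involving a
MAF-0.5 locus skip the screen (coding ambiguity) but not the interval or
the exact test.

The same machinery serves allele-count input by treating counts as
pseudo-phased data (double heterozygotes assumed to carry both minor
alleles on one haplotype): MACs, the bound table and the partial sums use
the phased-equivalent sums, and only the final exact step switches to the
count-based r² with true genotype moments.

## Parameters

- `threshold` (t): r² above which a pair is pruned; default 0.99. Strict
  comparison (r² > t), evaluated as `num² > t·den` on exact integer
  numerator/denominator with a single float rounding, so borderline pairs
  are reproducible. Values below ~0.8 are supported but widen the candidate
  interval and erode the screen's benefit.
- `mode`: `phased` (haplotype input) or `counts`; default inferred from the
  input format. Phased and count modes give near-identical removal sets
  away from the threshold's immediate neighbourhood.
- `subset_count`: number of nested partial-sum subsets, default 10 (10%,
  20%, …, 100% of individuals). Subsets are *prefixes* of the individuals
  in input order — first ceil(p·n/10) individuals — chosen so results are
  single-pass computable and machine-independent; any fixed subsets would
  be equally valid.
- `workers`: the high-LD scan is partitioned over sorted positions; each
  position's decision depends only on complete-LD-surviving data, so
  results are identical for any worker count (counters merge by summation).

## Numerical choices and edge cases

- All r² arithmetic is integer until the final division; denominators are
  precomputed per locus. Orientation never rewrites stored codes: it is a
  flag, with a minor-oriented integer matrix materialized once as a pure
  optimization.
- Monomorphic loci (MAC 0) are excluded before any pairing: r² is undefined
  at zero variance. In count mode, zero-variance columns whose MAC is not 0
  (all-heterozygote columns, MAC = n) are excluded for the same reason.
- At MAF exactly 0.5 the minor allele is declared to be the coded-1 allele
  on both a column and its complement; complete-LD comparison therefore
  tests both orientations there, and the high-LD screen is skipped for such
  pairs. Flip-invariance of the oriented partial sums genuinely fails at
  this boundary, which is why the exemption exists.
- BED decoding maps 2-bit codes to counts of the .bim A2 allele; the choice
  only affects reporting, never pruning. Missing genotype codes are a hard
  error (the algorithms assume complete data); an opt-in flag drops
  affected loci with a logged count. Multi-allelic VCF records are skipped
  with a warning rather than erroring, to keep real files usable.
- No mismatch tolerance: complete LD means exact vector identity. Tools
  that allow a small fraction of discordant genotypes (to absorb genotyping
  error) will prune supersets of our complete-LD pairs.

## Synthetic data

`simgen.generate_base_panel` draws loci independently: per locus a MAF
uniform on [0.05, 0.5], then 2n independent Bernoulli alleles, redrawing
monomorphic columns up to 10 times before keeping them. There is no
recombination map, demography or selection — the pruning algorithm is
position-agnostic, so LD structure is planted explicitly instead:
`plant_duplicate` appends exact copies (r² = 1), complemented copies
(r² = 1 with opposite coding), and perturbed copies with a chosen number of
flipped haplotypes, recording the oracle-computed true r² of each planted
pair. Chromosome/position metadata is assigned round-robin across five
chromosomes purely to exercise distance reporting.

The standard fixture uses n = 100 individuals and m = 1000 loci with 20
planted pairs of each kind and 6 flipped haplotypes per perturbed copy
(3% discordance, true r² ≈ 0.85–0.94). At this panel size the largest r²
any non-identical pair can reach is 0.9604, so pairs strictly between a
0.99 threshold and 1 cannot occur; high-LD removals are exercised
separately at n = 1000, where a single discordant haplotype yields
r² > 0.99. Because loci are drawn independently, passing tests demonstrate
the algorithm's correctness and screening behaviour, not performance on
realistically block-structured genomes; background LD between unlinked
simulated loci is far below any practical threshold.

`simgen.brute_force_prune` is the testing ground truth: it computes every
pairwise r² from integer Gram matrices and applies the identical removal
rules and stage sequencing, so its removal set is comparable element for
element with the fast path. It is guarded to 5000 loci.

## Known limitations

- The MAC-equality premise of the complete-LD stage, and the MAC-interval
  bound of the high-LD stage, are theorems for *phased* alleles (verified
  exhaustively over all haplotype columns at small n in the test suite).
  For allele counts they are approximations: genotype vectors related by a
  non-identity affine map (e.g. x and x+1, or x and 2x) can have
  count-r² = 1 with different MACs and are invisible to the algorithm.
  Such vectors require every individual's genotype to satisfy the affine
  relation, which does not occur in realistic panels, but an exhaustive
  enumeration over all length-6 genotype columns does surface them; the
  corresponding soundness test in `tests/test_acceptance.py` fails on
  exactly these pairs and documents the boundary of the count-mode
  guarantee.
- Missing genotypes are unsupported by design; impute or drop loci first.
- Thresholds well below 0.8 make the candidate interval cover most of the
  panel, reverting toward all-pairs cost.
- The sliding-window cost formula (m/step)·(window² − window)/2 treats the
  window count as a real number and ignores truncated trailing windows; it
  is the conventional planning estimate, not an exact enumeration.
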
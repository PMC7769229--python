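# Methods

This note documents the models and procedures implemented in `flatpeach`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## The inversion locus model

A locus is a DNA segment carrying an invertible interval. Coordinates are
0-based and half-open everywhere; the inverted interval on the wild
haplotype H1 is `[pb, db)` (proximal and distal breakpoints). The mutant
haplotype H2 is

```
H2 = H1[0 : pb - len(del)] + revcomp(H1[pb : db]) + ins + H1[db :]
```

with the default end-joining signature `del = "ACA"`, `ins = "GA"`, so
`len(H2) = len(H1) - 1`. The deletion is modelled as the three bases
immediately upstream of `pb` on H1, and the insertion sits between the
inverted segment and the downstream flank on H2. The breakpoint figure
this mimics shows the indels "in" the breakpoints without base-exact
placement; this placement is symmetric and testable, and nothing
downstream depends on the alternative (deletion overlapping the inverted
segment) beyond a relabelling of coordinates.

Four junction references are derived per locus, each a window of
`flank` bases either side of a breakpoint (clipped, never padded, at
sequence ends, with the stored centre index shifted accordingly):
W_PB and W_DB on H1, M_PB and M_DB on H2. The proximal junctions share
their upstream flank (minus the deleted bases) — which is exactly why
read classification requires overhang *past* the breakpoint.

## Read classification and diploid genotyping

Reads are aligned to the four junctions by exact k-mer seeding
(`k = 15`) followed by ungapped extension on the seed diagonal. The
reported hit is the optimal-scoring window containing the seed, with
match +1 and mismatch `-(1/max_mismatch_frac - 1)` (penalty 9 at the
default `max_mismatch_frac = 0.1`): no extension segment whose local
mismatch fraction exceeds the threshold is ever worth including. This
crosses isolated sequencing errors but refuses low-identity tails — in
particular the sequence beyond a breakpoint that the read does not
actually carry, which a naive global-mismatch-budget extension will
happily absorb after a long clean flank (we observed exactly that failure
mode before adopting window-optimal scoring: wild reads ending just past
the mutant junction centre collected spurious mutant support).

A hit *spans* its junction when the aligned interval covers at least
`min_overhang = 15` bases on both sides of the centre at identity
`>= min_identity = 0.9`. Among spanning hits the unique one with the most
matches wins; ties across junction ids are left uninformative —
conservative, and what prevents haplotype miscalls on the shared flanks.
Mates of a pair are classified independently (the genotyping rule is
read-level).

The diploid call follows the presence/absence rule of the assay this
mirrors: allele H1 is present iff W_PB **and** W_DB each have
`>= min_reads` (default 3) spanning reads; H2 likewise via M_PB and M_DB;
both -> H1H2, one -> the corresponding homozygote, neither -> no-call.
There is no allelic-balance test: homozygote versus heterozygote is
decided purely by junction-pair presence, matching the source assay; a
balance test would be a straightforward extension.

In-silico PCR treats a primer pair as present on a template when one
primer's written sequence occurs on the forward strand and the other's
reverse complement occurs downstream of it (both orientations of the pair
are searched, which also covers the reverse-strand product), each with at
most `max_mismatches = 0` substitutions and an exact 3'-terminal 3 bases,
and the product is no longer than `max_amplicon`. The three-pair assay
(P1 wild-proximal, P2 mutant-proximal, P3 mutant-distal) maps band
patterns to genotypes; P2 and P3 must co-occur, otherwise the pattern is
inconsistent and yields a no-call.

## Breakpoint refinement from split long reads

A long read from H2 that crosses the proximal junction aligns
forward-then-reverse on H1. For each read (in both orientations) the
split index `s` maximising forward matches of `read[:s]` plus
reverse-strand matches of `read[s:]` is searched over k-mer-seeded
diagonals (`k = 13`), subject to: each part has `>= 20` matching bases at
`>= 80%` identity, and the two junction-side coordinates fall one in each
user-supplied search window. The per-read estimate `(u, v)` is the pair
of H1 coordinates where the orientation switches; the consensus is the
per-coordinate majority (ties resolved to the smaller coordinate).

Three deliberate choices:

* **Forward-then-reverse template only.** Distal-junction split reads
  decompose reverse-then-forward and would report the proximal coordinate
  as `pb` rather than `pb - 3` (the deletion is observable only from
  proximal-junction reads), bimodalising the consensus. Restricting to the
  FR template makes every informative read estimate the same pair
  `(pb - 3, db)`; both sequencing orientations of proximal reads are
  captured because the template is applied to the read and its reverse
  complement.
* **Left-alignment of tie splits.** When several splits explain a read
  equally well the lowest proximal coordinate is reported — the standard
  normalisation for structural variants.
* **Canonical planted truth.** An inversion whose junction carries k bases
  of microhomology is localisable only to a k-bp interval; all equivalent
  representations produce the identical H2 sequence, so no estimator can
  distinguish them. The synthetic generator therefore breaks proximal
  junction microhomology when planting the site (at most two
  junction-adjacent bases substituted deterministically), making the
  planted breakpoints the unique representation and exact truth
  comparison well-defined.

## Synthetic data

All generators take an explicit seed and are bit-reproducible. They
emulate: an i.i.d. random reference (default GC 0.42), diploid accessions
whose phenotype is a deterministic function of genotype (complete
dominance of flat; homozygote fruit abortion — exactly the mapping seen in
every published cross and cultivar panel of this locus, so no penetrance
parameter), F1 crosses with uniform allele transmission, paired-end reads
(uniform fragments, normal insert, i.i.d. substitution errors, constant
Phred-30 qualities since classification ignores quality), single-end long
reads (normal lengths truncated to [200, haplotype length]), binomial SNP
dosages with group-specific alternative-allele frequencies, and NB2
negative-binomial expression counts (variance `mu + alpha*mu^2`, common
dispersion `alpha`, log-normal base means scaled to the library size) with
exactly one planted gene whose FP-group mean is `2^log2FC` times its
RP-group mean.

What the generators do **not** model — and hence what passing tests do not
demonstrate about real data: indel sequencing errors (the aligner is
ungapped by design; real indel-bearing reads need a gapped mapper),
platform-specific error profiles, PCR duplicates, coverage biases,
population structure in the SNP panel, gene-specific dispersions or
length-dependent count biases in the expression model, and any genomic
context beyond the simulated locus (no off-target alignment competition).

Defaults (all config-exposed, `flatpeach.config.RunConfig`): 30-kb demo
locus with a 10-kb inversion (desk-scale stand-ins for the megabase-scale
event), 30x short-read coverage of 150-bp pairs at 0.5% error with
400+-40-bp inserts, 15x long-read coverage at mean length 6 kb and 1%
error, junction flank 300 bp, 63-SNP panel with 30+30 accessions and a
0.9-vs-0.1 planted SNP among 0.5/0.5 nulls, 500-gene expression panel
with a planted log2FC of 5 at dispersion 0.05 and library size 1e6.
The sequencing-error and coverage figures are choices (published
genotyping of this locus reports none per accession); 30x/0.5% are typical
re-sequencing values and give per-allele junction support of ~12 reads in
a heterozygote, comfortably above `min_reads = 3`.

## Statistics

* **Fisher exact (two-sided):** conditioned on both margins; the p-value
  sums hypergeometric probabilities of all tables at most as probable as
  the observed one, with a 1e-7 relative tolerance for floating-point
  ties. Tables are allele-based (2 alleles per accession) by default —
  the comparison this mirrors is of allele frequencies — with a
  genotype-based (carrier) option.
* **Benjamini–Hochberg:** the classic step-up
  `q(i) = min_{j>=i} p(j)*n/j`, capped at 1, returned in input order;
  implemented directly so it agrees exactly (not merely to rounding) with
  the two-pass textbook formulation.
* **Segregation:** Pearson chi-square goodness of fit against the
  expected ratio, df = classes - 1; invariant to ratio rescaling.
* **Co-segregation:** flat accessions must be H1H2, round H1H1, aborted
  H2H2; no-calls are listed separately and not counted as discordant.
* **DEG screen:** TPM normalisation, log2 fold change on group-mean TPM
  with pseudocount 1, Welch t on `log2(TPM+1)` with
  Welch–Satterthwaite df (zero-variance equal-mean genes get p = 1), BH
  correction, and the joint filter |log2FC| > 2 and q < 0.1. The Welch t
  is a deliberately simple stand-in for a count-model fit; with three
  replicates per group its p-values are heavy-tailed (2–4 df), so after
  multiplicity correction across hundreds of genes the *joint* filter has
  limited power even for very large planted effects — the acceptance
  script reports the measured pass rate rather than hiding it. Fold-change
  estimation and top-ranking of the planted gene by |log2FC| are the
  robust deliverables at this design size. The FDR threshold default is
  0.1 (an alternative 0.05 also circulates for such screens; the
  value is config-exposed). "Adjusted" fold change
  is read as shrinkage-free log2FC with a pseudocount.
* **qPCR:** relative expression `2^-ddCt` with
  `ddCt = (Ct_target - Ct_reference) - dCt_calibrator`.

## Numerical conventions

Junction windows clip at sequence ends; alignment tie-breaks prefer more
matches, then the forward strand, then the leftmost reference position;
refinement tie splits are left-aligned and consensus ties resolve to the
smaller coordinate; BH uses a stable sort so tied p-values share a q;
monomorphic SNPs are assigned p = 1 and flagged rather than tested;
all-zero expression samples yield all-zero TPM columns with a warning.
Derived sub-seeds are CRC-32 hashes of `"<seed>:<tag>"` reduced mod 2^31,
so every stage has an independent, reproducible stream.

## Problem sizes

The bundled experiments run at desk scale by design: genotype-recovery
uses a 12-kb locus with a 6-kb inversion (the decision rule depends on
junction coverage, not locus length), breakpoint refinement uses a 20-kb
inversion in a 30-kb locus, and the demo uses the 30-kb default locus
with nine accessions. Base-resolution breakpoint coordinates of the real
megabase-scale event are not published; all runs here
are parameterised synthetic loci with known truth.
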
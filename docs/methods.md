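# Methods

This note records the models, numerical conventions and design
choices behind `otupipe`, in the spirit of a methods supplement: what
each stage assumes, which knobs matter, and what the synthetic data
can and cannot tell you about real runs.

## Genetic distance and alignment

Distance between two reads is defined on a global affine-gap
alignment: `(mismatches + internal gap columns) / aligned columns`,
with terminal gap runs excluded from both numerator and denominator
(reads have slightly variable lengths after primer trimming, and
overhangs are not evidence of divergence). Default scoring is match
+1, mismatch −1, gap open −2 (first gap column), gap extend −1; gap
columns in opposite sequences are never adjacent (the usual X↔Y
transition ban in three-state Gotoh DP). All parameters are
`Scoring` fields.

Because co-optimal alignments can disagree on the mismatch/gap column
split, the traceback is **canonical**: at score ties the diagonal
predecessor is preferred (in the order M, X, Y), gap opening is
preferred over extension, and the final state preference is M, X, Y.
Any independent implementation of these rules reproduces the distance
exactly; the test suite carries such an implementation (a plain-dict
DP written separately) and requires agreement to 1e-9 on random
sequence pairs. The canonical traceback is not symmetric under
argument swap (the tie rules distinguish the two gap states), so
`pairwise_distance` orders its arguments lexicographically first,
making the public distance exactly symmetric. The reference-search
mode is a local (Smith–Waterman) variant of the same DP: junk read
ends score negatively and drop out of the maximal block, which is
what the end-integrity screen measures.

## Read screening

The three criteria are applied in order — primers, length, quality —
and the first failure is reported. "Intact" primers mean an exact
anchored match of the 27F sequence at the 5′ end and the reverse
complement of 519R at the 3′ end; a mismatch allowance is exposed but
defaults to 0. The length window (400–580 nt) is evaluated on the
**untrimmed** read: the expected amplicon size (~500 bp) includes the
primers, and length is listed alongside primer presence as a property
of the raw read. The quality rule is a fraction, not a count: at most
1% of bases below Phred 15, so a 500 nt read passes with exactly 5
such bases and fails with 6. Phred encoding is fixed at +33. `N`
bases carry their stated quality and are not separately filtered;
they can never produce an alignment match.

## OTU clustering

De novo clustering is greedy abundance-sorted centroid clustering:
dereplicate to unique sequences, sort by decreasing total count (ties
broken lexicographically so the result is independent of input file
order), then let each unique sequence join the first centroid within
the cutoff or found a new OTU. The 5% default follows the V1–V3
rationale (V1 is the most variable region; 3% was calibrated on
full-length sequences).

Two shortcuts keep desk-scale runs fast without changing any
decision:

* **Hamming fast path.** For equal-length sequences with Hamming
  distance *h*: a gapped alignment with *g* gap columns per side has
  score at most `L − 3g − 2`, so for `h ≤ 2` the ungapped alignment
  is provably optimal and the distance is exactly `h/L`. For larger
  *h*, a gapped optimum requires `m_g < h − (3g+2)/2` mismatches,
  which bounds its distance by `(4/3)·h/L`; therefore
  `h ≤ 0.74 · cutoff · L` proves membership without running the DP.
  Sequences with `h ≤ 2` but `h/L` above the cutoff are provably
  non-members, also without the DP.
* **k-mer lower bound.** A pair within distance *d* differs in at
  most `d·L/(1−d)` columns, and each differing column can destroy at
  most *k* of the query's distinct 8-mers; a centroid sharing fewer
  8-mers than that bound allows is provably beyond the cutoff and is
  skipped.

Both inequalities are conservative, so the clustering is identical to
the naive all-DP implementation (property-tested on fixtures).

## Artifact screens

**Bimera test.** Candidate parents must have at least twice the
query's total abundance (PCR chimeras arise late from templates that
are already abundant). A query whose best single-parent full-length
identity exceeds 95% is a sequencing variant and is vetoed globally.
Otherwise each parent pair is scanned over all breakpoints for the
split maximising the **informative-column** identity: positions
matching at least one of the two parents count; positions matching
neither are almost always the query's own sequencing errors and are
excluded (the same abstention idea as uchime's vote columns). The
query is flagged when the best split reaches 99% overall with both
segments at or above 95% and at least 20 informative columns each.
The overall pooled identity is used instead of a per-segment 99% rule
because a single segment (~150–250 informative columns) cannot absorb
even one error that happens to match the wrong parent within a 1%
tolerance; pooling restores the intended error budget. On planted
ground truth this configuration reaches ≥ 98% read-level recall with
zero false flags at the default error rate. Parents are drawn from
unflagged OTUs only, most abundant first; a hook accepts a list of
ids from an external chimera tool instead.

**End integrity.** The closest reference of equal or longer length is
found by exhaustive local alignment (best hit by alignment score, as
a database search would rank it; identity alone would let a short
spurious near-perfect block outrank a full-length match). An OTU is
discarded when more than five nucleotides are missing from either end
of its alignment span, or when no eligible reference exists.

**Singleton screen.** Single-read OTUs additionally need a full-span
match with at most 1% dissimilar nucleotides. Screens run in the
order chimera → end → singleton; each OTU is discarded at the first
screen it fails, and reads of discarded OTUs are removed entirely
before rarefaction (the alternative — keeping their reads in
per-sample totals — would silently inflate coverage).

## Taxonomy

Nearest-reference assignment: the lineage is copied from the
best-scoring hit; identity (to one decimal, percent) and the <95%
novel-taxon flag come from the same hit. Rank confidence is the
fraction of near-best hits (top 10 by score, within 3 identity points
of the best and at least 80% of its score) agreeing with the best
hit's label; ranks under 0.8 confidence are reported as
`unclassified <parent>`. The score floor exists because short
spurious local blocks on unrelated references otherwise enter the
pool and dilute every rank. An external classifier's calls can be
loaded from TSV and used in place of the built-in search.

## Diversity and ordination

Estimator conventions are the mothur `summary.single` ones:
bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))`; ACE with rare
threshold 10, the squared coefficient of variation clamped at zero,
and two documented degenerate fallbacks (no rare classes → S_obs;
all rare reads singletons → coverage zero, estimator undefined,
S_obs returned); Shannon in natural log (the study-scale values of
3.1–3.7 are only consistent with ln); Simpson reported as the
unbiased **dominance** `Σnᵢ(nᵢ−1)/(N(N−1))` (decreases with
evenness); Good's coverage `1 − F1/N` in percent. Rarefaction is a
single multivariate-hypergeometric draw at a recorded seed — not a
mean over iterations — the single recorded draw keeps the rarefied
table an actual realisable dataset; note that another lab's unseeded
single draw can never be reproduced exactly, only re-drawn.

PCoA double-centers `−D²/2` with the Gower operator and
eigendecomposes; coordinates are eigenvectors scaled by √λ for
positive eigenvalues, each axis's sign fixed so its first nonzero
loading is positive. Bray–Curtis is non-Euclidean, so negative
eigenvalues occur; they are reported but excluded from coordinates
and from the variance proportions. Correspondence analysis is the
SVD of `D_r^(−1/2)(P − rcᵀ)D_c^(−1/2)` with symmetric-map principal
coordinates; total inertia equals Pearson χ²/N to 1e-9 (tested
against a separate χ² oracle).

## Group testing

Per-feature comparisons use the Friedman test with within-block
mid-ranks and the tie-corrected χ² statistic on k−1 df (the semantics
of R's `friedman.test`), followed by the Nemenyi all-pairs post hoc:
mean-rank difference divided by `sqrt(k(k+1)/(12n))`, referred to the
studentized range with infinite df, computed by numerical quadrature
of `k ∫ φ(z)[Φ(z) − Φ(z−q)]^(k−1) dz` (cross-checked against an
independent implementation to 1e-5). Pairwise results are condensed
into a compact letter display by insert-and-absorb; groups sharing no
letter differ at α = 0.05.

The four sample sets share no subjects, so a blocked test needs an
artificial blocking; blocks are formed by replicate index (sample
rank within group, ids sorted), which requires balanced groups and is
stated here prominently rather than hidden. A Kruskal–Wallis
alternative (`method="kruskal"`) provides an unblocked global test.
At the χ² approximation's small-sample end, enumerating the complete
tie-free null at n = 4 blocks, k = 3 groups gives a worst-case
|p_χ² − p_exact| of 0.181; the tests document and use that bound.
Under null simulation (k = 4, n = 10) the type-I error at α = 0.05 is
within ±0.01 of nominal.

## The synthetic community

`default_profiles()` encodes 15 taxa in 7 families and 2 phyla with
group means chosen to reproduce the study-scale family structure:
Lactobacillaceae mass 44.8% in the phase II control vs 13.0/16.0% in
the phase III groups, Streptococcaceae 2.1% vs 32.2/25.6%, plus
Clostridiaceae, Lachnospiraceae, Prevotellaceae, Veillonellaceae and
a Peptostreptococcaceae filler so each group's means sum to 1. Three
taxa are planted as "uncharacterised species": their entry in the
taxonomy reference FASTA is a mutated copy at 88–91% identity, so the
novel-taxon flag has planted positives. Reference sequences are
synthetic random DNA (438–498 nt) flanked by the real primer sites —
guaranteeing distinct taxa are far beyond the 5% cutoff — and a real
reference FASTA can be substituted by building `TaxonProfile` objects
from it.

Between-animal variation is Dirichlet-multinomial:
`p ~ Dirichlet(c·m)`, `counts ~ Multinomial(reads, p)`. The
concentration default `c = 5` was chosen by matching the implied
between-animal SEM at n = 10 to the study-scale family-level SEMs;
the fit is flat over c ∈ [3, 6] and 5 sits at the conservative end
for the dominant families that carry the printed significance
pattern. The bimodal peptide-treatment phase II group is realised at the
**sample** level — each sample follows the II-like or III-like
profile with probability ½ — matching the ordination observation
that half of those samples cluster with each control group, rather
than averaging the profiles per sample.

Reads are the taxon's primered reference with i.i.d. substitutions
(default 0.005/base) confined to the biological insert, so primer
sites stay intact and the planted QC ground truth is exact. Planted
artifacts per sample are exact counts (`round(fraction·reads)`):
chimeras (2%) from two abundance-weighted parents of the same sample
with one breakpoint uniform in the middle 60%; interior-truncated
(<400 nt) and interior-elongated (>580 nt) reads (2% each) with
primers intact so they fail on length, not primers; and reads with
2% of bases forced below Phred 15 (4%), tripping the 1% quality rule.

What the simulator does **not** emulate: real MiSeq quality profiles
and error spectra (no indels, no quality–error correlation), paired
read structure (inputs are pre-assembled contigs), taxon-specific
amplification bias, and real 16S sequence structure (conserved/
variable region mosaic). Consequences: passing tests demonstrate the
pipeline's rules are implemented correctly and are well-calibrated
under the stated noise model, not that the pipeline is robust to
every real-world artifact; in particular the clustering shortcut
analysis assumes substitution-dominated divergence (true for Illumina
contigs), and real chimeras of closely related parents would be
harder than the synthetic ones (parents here are ~60% divergent).

## Problem sizes and determinism

The default study is 4 groups × 10 samples × 5000 reads/sample
(rarefaction to 3000), which runs end to end in a few minutes on one
CPU; the test suite uses this size for the headline-pattern checks, a
10,000-read run for filter fidelity, and smaller studies elsewhere.
`scripts/acceptance.py` uses 4 × 6 × 4000 as a comfortable single-CPU
size and reports the n used with every value. Every random draw
(community, reads, rarefaction) flows from an explicit seed; the
pipeline manifest records seeds and stage counts, and rerunning with
the same seed reproduces byte-identical tables.

## Known limitations

* Greedy centroid clustering is order-canonical but still greedy:
  borderline sequences join the first centroid within the cutoff,
  not the nearest.
* The replicate-index blocking for the Friedman test is artificial
  (the design has no true blocks); treat the per-feature p-values as
  the study's convention, and use the Kruskal–Wallis option when a
  blocked test is not wanted.
* The bimera detector considers two parents and one breakpoint;
  multi-parent chimeras fall through to the end-integrity screen.
* Taxonomy confidence is a consensus over near-best hits, not a
  bootstrap; with sparse references it reflects reference coverage
  as much as signal.
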
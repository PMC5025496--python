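# Methods

## The model

Gametophytic self-incompatibility (GSI) in tuber-bearing *Solanum* is
controlled by a single multi-allelic S-locus. The pistil determinant is
an S-RNase; a haploid pollen grain is arrested iff its S-allele matches
either of the two pistil alleles. The engine in `gsi_genetics` encodes
exactly this rule and nothing more: no segregation distortion, no pollen
competition, no unreduced gametes, no sporophytic effects. Consequences
used throughout:

* A cross is INCOMPATIBLE, SEMI_COMPATIBLE or FULLY_COMPATIBLE according
  to whether 0, 1 or 2 pollen haplotypes are accepted. Incompatibility is
  reciprocal for fully known heterozygous genotypes, and the inference
  code treats a one-directional failure as a model conflict, never
  resolving it silently.
* A semi-compatible cross yields exactly two progeny genotype classes at
  1:1; progeny never carry a rejected pollen haplotype. The 1:1 test is
  the exact two-sided binomial, p = min(1, 2·P(X ≤ min(k, n−k))),
  preferred over a χ² approximation because cohorts are small (n ≈ 30).
* Compatibility is scored on berry set alone. Seeds per berry are
  simulated (Poisson, mean 90 — the order of magnitude of real diallel
  seed counts) but deliberately never used to separate semi- from full
  compatibility: with pollen in excess the two are not distinguishable
  by seed set.
* An allele that exists but was never cloned is carried as an explicit
  Unknown marker; crosses whose pollen parent carries Unknown return
  both candidate outcomes behind an uncertainty flag rather than a
  guess. A pistil Unknown is an error: the cross cannot be classified.

## Sequence analysis

**Similarity.** Percent amino-acid similarity is
100 · identities / comparable positions under exact global alignment
(Needleman–Wunsch semantics via Biopython's PairwiseAligner; BLOSUM62,
affine gaps open 10 / extend 0.5), with pairwise deletion of gap
columns. The published similarity matrix is consumed as data — the
underlying program and its exact formula are not reconstructable — so
similarity numbers from our aligner are never compared against that
matrix's cells; only the matrix's own extremes are recomputed from it.

**Distances and trees.** Evolutionary distances are Poisson-corrected,
d = −ln(1 − p), with complete deletion of gapped columns across the
alignment (a separate switch from the pairwise deletion used for
percent similarity). Neighbour joining is implemented in-package:
Saitou–Nei Q-criterion, standard two-point branch lengths, negative
length estimates clamped to zero with the deficit recorded on the tree,
and all ties broken by the lexicographically smallest label pair so
output is deterministic. Bootstrap supports resample alignment columns
with replacement (seeded NumPy generator), rebuild each replicate
through the same distance→NJ path, and score each internal edge by the
percentage of replicates containing its leaf bipartition. Supports are
attached to bipartitions, not nodes: rerooting reverses part of the
tree, so node labels are re-derived from the bipartition table after
outgroup rooting. Trees live in dendropy containers and round-trip
through Newick with supports as internal node labels.

**Clade classification.** A candidate is classified by the majority
class of the references in the smallest bootstrap-supported
(≥ 50 % by default) clade containing it and at least one labelled
reference, after rooting on a deeply diverged T2-like outgroup when one
is supplied; "unclassified" when no such clade exists. Class III
membership is one input to the functional rubric.

**Feature annotation.** Conserved blocks C1–C5 are located by the
best-scoring window against per-region position-frequency profiles
built from a reference alignment; a region's threshold is the mean
reference self-score minus k·sd (k = 2), floored at the weakest
reference self-score so every reference recovers its own annotation.
The hypervariable regions carry, by definition, no profile signal, so
HVa/HVb are placed positionally from the conserved-block offsets. A
region that does not fit (partial 3′RACE fragments lack C1 and usually
the primer-consumed part of C2) is reported absent, never guessed, and
absence of leading regions is not a rubric failure. Conserved cysteines
are counted only at the profile-defined conserved columns; a fragment
beginning at C2 can observe at most six of the eight, and the rubric
tolerates one missing cysteine (several functional S-RNases lack the
post-C5 residue). The N-glycosylation check uses the standard sequon
N-X(≠P)-[S/T] inside C2.

**Isoelectric point.** pI is found by bisection (tolerance 1e-4 pH) on
the Henderson–Hasselbalch net charge over N-/C-termini and D, E, C, Y,
H, K, R, using a flat Bjellqvist-style pKa table recorded verbatim in
`srnase_features.BJELLQVIST_PKA`. The functional threshold is
pI > 7.5. Published pI ranges were reported from a proprietary tool
whose constants are unknown, so pI is a rubric criterion here, not a
numeric reproduction target; the test suite cross-checks our values
against Biopython's independent implementation at 0.5 pH tolerance.

## In-silico cloning

Primer annealing is positional Hamming matching over IUPAC sets — no
indels, no 3′-end weighting, max mismatches 0 by default; a
3′-anchored scoring scheme would be a config extension, not a change of
model. 3′RACE products run from a forward-site 5′ base to the last base
before the first run of ≥ 10 adenines (min_polyA = 10 distinguishes a
genuine tail from A-rich coding sequence); the oligo-dT/NotI anchor then
contributes a fixed 45 nt (18 dT + the 27-nt anchor), reported
separately from the template span. Allele-specific assays are validated
by exhaustive in-silico PCR of every assay against every panel allele
(maximum product 1500 nt bounds the convergent search); an assay that
amplifies more than one allele is rejected at validation time, before
any genotype is called. Melting-temperature modelling is out of scope.

## The synthetic generator

`synthetic_data` emulates the study conditions, not real sequences:

* A 175-residue scaffold with segments C1(10) C2(14) HVa(40) HVb(34)
  C3(11) C4(10) C5(9) plus linkers and tails. Invariant anchors: His in
  C2 and C3, eight Cys (two between C1 and C2, one just after C5), the
  NAS sequon in C2, and a C2 block whose first eight residues are
  encoded by codons matching the degenerate C2 forward primer exactly.
* Alleles resample variable (hypervariable + linker) positions at
  hv_divergence = 0.9 from a K/R-biased pool (basic_bias = 0.25, D/E
  held at 2 % each), making every allele basic by construction;
  conserved non-anchor positions jitter at 0.02. Twelve founders model
  ancient, deeply diverged lineages; four derived alleles (12 %
  variable-site divergence from a founder) supply the high end of the
  similarity band. The panel is rejection-sampled (≤ 50 attempts,
  seeded) until its similarity extremes fall in the target band
  33–95 % with the low extreme ≤ 40 and the high ≥ 85, matching the
  divergence structure real S-allele panels show. hv_divergence = 0 is
  a degenerate limit that collapses the panel to scaffold copies with
  no enforcement.
* S-like class I/II panels and the outgroup descend from scaffolds whose
  conserved non-anchor positions are fully redrawn (the classes share
  only the T2-family anchors), with acidic variable positions
  (36 % D/E), so they fail the basic-pI rubric check and form tight,
  separable clades; within-class divergence is 8 % (5 % outgroup).
* Back-translation draws synonymous codons uniformly at random; 5′ UTR
  30 nt, A-poor 3′ UTR 80 nt, poly(A) 25 nt. Nucleotide-level realism
  (codon usage, indels, recombination) is deliberately absent — the
  nucleotide layer only has to support primer sites, translation and
  the poly(A) anchor.
* The default study bundle: five accessions over six alleles with one
  shared-genotype pair, full 5×5 diallel with selfs, four
  semi-compatible cohorts of 28–30 progeny simulated through the GSI
  engine, allele-specific assays cut from the hypervariable regions and
  validated for specificity, plus a 16-allele panel and one relabelled
  amino-acid-identical duplicate so 17 labels collapse to 16.
  Regeneration from the same seed is byte-identical.

What passing synthetic tests do **not** show: robustness to alignment
error and indels, to primer–template mismatch structure in real
transcripts, to segregation distortion, or to reference panels whose
classes are not cleanly separable. Those phenomena are outside the
generator by design.

## Numerical and design notes

* All coordinates are 1-based inclusive; missing matrix cells are
  explicit NaN and excluded from extremes; an upper-triangle similarity
  matrix is mirrored on read with the diagonal filled at 100.
* Every stochastic routine takes an explicit seed; bootstrap replicates
  and simulated crosses are reproducible bit-for-bit.
* Bootstrap replicate distances that saturate (p = 1 after resampling)
  are nudged to p = 1 − 1/(2L) instead of erroring: a replicate must
  always produce a tree.
* The acceptance suite sizes are deliberate: 200 random additive and 200
  random non-additive matrices at 4–8 taxa for the NJ oracle (additive
  cases check topology and path lengths to 1e-9 against the generating
  tree; non-additive cases check the join trace against scikit-bio's
  independent NJ), 500 random pairs of length ≤ 8 (weighted toward ≤ 6,
  where exhaustive enumeration of all alignments is cheap) for the
  alignment oracle, B = 200 bootstrap replicates for the clade
  separation checks, and 200 replicate cohorts for the segregation
  p-value check. For symmetric doubled-tail binomial p-values the
  distribution is exactly uniform on its atoms, and the atom at p = 1
  has mass ≈ 0.144 at n = 30; the Kolmogorov–Smirnov sanity bound of
  0.25 is that floor plus sampling noise.
* Published-table quantities that cannot be recomputed from sequence at
  desk scale (the matrix's cell values, the exact published tree
  topologies) are consumed as data; their structural equivalents are
  exercised on synthetic panels instead.
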
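# Methods

## Scope and data model

The package analyses the *architecture* of annotated circular mitochondrial
genomes: where the 37 canonical genes (13 protein-coding genes, 22 tRNAs,
2 rRNAs) sit, what lies between them, how AT-rich each region is, and how
the gene order relates to a reference arrangement. Annotation is an input,
never inferred: there is no gene finding, no tRNA folding, and no support
for multi-interval (joined) features. Coordinates are 1-based inclusive on
the majority (J) strand; features that would span the circular origin are
rejected rather than split — curated mitogenome tables place the origin
inside the control region, so such features do not arise, and excluding
them keeps every interval a plain `[start, end]` pair. A `circular=false`
flag disables the origin-wrapping junction for partial assemblies.

## Spacer arithmetic

For consecutive features *u*, *v* (sorted by start) the signed gap is
`start(v) − end(u) − 1`; the wrap junction contributes
`(L − end(u)) + (start(v) − 1)`. Definitions and conventions:

- **IGS** = a spacer of length ≥ 1 bp that is not the control region.
  Zero-length gaps contain no nucleotides and are never counted; negative
  gaps are reported separately as overlaps and never subtracted from IGS
  totals.
- **Control region** = the spacer immediately downstream of *srRNA*,
  whether or not it wraps the origin. In *A. laevigata* this is the 74 bp
  post-*srRNA* remainder (54 bp after *srRNA* plus 20 bp before *trnV*
  across the origin); the unsequenced part of the AT-rich region is not
  modelled.
- **Adjacency under overlap**: only pairwise overlaps between consecutive
  features are supported. A feature reaching back past its immediate
  predecessor makes adjacency ambiguous and is an error. All three
  overlaps in the reference annotation (3, 1 and 8 bp) are pairwise and
  between tRNAs.
- **Threshold counting**: "spacers of at least *t* bp" uses ≥ by default
  (`threshold_mode="ge"`); with *t* = 160 this counts 14 spacers on the
  reference annotation because the *trnY–COI* spacer is exactly 160 bp,
  while strict `>` would count 13. Both modes are exposed.

A conservation identity ties everything together: on a fully annotated
circular genome, Σ gene lengths + Σ signed spacers (control region
included) = genome length. Overlapped bases are counted twice in the gene
sum and subtracted once by the negative spacer. The test suite also checks
the spacer computation against an independent per-position coverage scan
of the circle and verifies that the spacer-length multiset is invariant
under rotation of the origin.

## Composition and codon statistics

AT fraction is (A+T)/(A+C+G+T); N bases count toward region length but are
excluded from the denominator, and an all-N region has undefined (NaN) AT.
Per-gene statistics are computed on the coding strand (reverse complement
for N-strand genes) — irrelevant for A+T, which is strand-symmetric, but it
makes per-base and codon counts meaningful. Percentages are reported at one
decimal, rounded half up, via decimal arithmetic on the exact float repr to
avoid binary-representation surprises at the .x5 boundary.

Codon statistics use NCBI translation table 5 (invertebrate mitochondrial:
ATA=Met, TGA=Trp, AGA/AGG=Ser). A PCG whose length is ≡ 1 or 2 (mod 3)
carries an incomplete stop — a trailing `T` or `TA`, a prefix of `TAA`
completed by polyadenylation. The trailing bases contribute only the codon
positions they occupy in the position-wise AT pooling and are excluded from
codon counts (tracked as `incomplete_codons_dropped`). A ragged PCG whose
tail is *not* a stop prefix triggers a warning and the tail is dropped
entirely. Stop calls: the final triplet when length ≡ 0 (mod 3) and the
triplet is TAA/TAG; otherwise the trailing bases, marked incomplete.
Unusual start codons (outside ATG/ATA/ATT/ATC/GTG/TTG) are reported with a
warning rather than rejected, since they usually indicate an annotation
slip rather than unusable data.

Pooled IGS composition concatenates all positive non-control-region
spacers; a mean-of-per-spacer-percentages alternative is available
(`regions="igs-mean"`), since summary figures in the literature rarely say
which convention they used.

## Rearrangement distance

Gene orders are circular sequences of (symbol, strand) pairs; rotations are
equal, reflections are not. The event model is the single-gene move:
excise one gene and reinsert it at any junction, optionally flipping its
strand. Block operations are deliberately out of scope — every
rearrangement reported for ant mitogenomes is a single-tRNA shift, and a
local permutation such as *I-Q-M* → *M-I-Q* is exactly one move of *trnM*.

The minimal move count from order *A* to *B* is *n* minus the largest set
of genes whose circular (symbol, strand) sub-order is identical in both.
Because symbols are unique, that maximum is found by taking the best
ordinary LCS of each rotation of the query against one fixed linearization
of the reference (O(n³), negligible at n ≤ 37). The distance is symmetric
and obeys the triangle inequality; the test suite proves it equal to an
exhaustive breadth-first search over move operations on *every* signed
circular order of five and six genes (7,680 states at n = 6).

Minimal moved sets are often not unique. Ties are resolved by preferring
the set that moves the fewest non-tRNA genes (tRNA translocations are by
far the commonest mitogenome rearrangement, so an explanation that moves a
tRNA is preferred over one moving an rRNA or PCG), then the
lexicographically smallest symbol set. Candidate sets are enumerated
exhaustively when C(n, d) is small (≤ 2·10⁵) and otherwise taken from an
LCS traceback. A moved gene whose strand differs between the orders is
annotated `translocation+inversion`.

The shipped reference is the ancestral pancrustacean arrangement,
linearized at the gene following the control region (*trnI* first, *trnV*
at the *lrRNA–srRNA* junction). Orders extracted from records are anchored
the same way when *srRNA* is present; equality is rotation-invariant either
way.

## Synthetic genome generator

The generator exists to give every analysis stage a ground truth. It lays
genes onto the circle junction by junction from a spec holding: a gene
order (default: ancestral), per-gene lengths (defaults matching a real ant
mitogenome, tRNAs 70 bp), per-junction signed spacer lengths (explicit
list or a sampler; negative values allowed only between tRNA genes, and an
overlap may never consume a whole neighbour), a control-region length
placed at the wrap junction, per-region AT weights, and a stop-codon
policy. PCGs are built codon-wise: a start codon from {ATG, ATA, ATT}, an
i.i.d. body with independent AT weights per codon position (defaults
0.763/0.736/0.864), and a TAA/TAG stop or an incomplete `T`/`TA` tail — a
length not divisible by 3 implies an incomplete stop. N-strand genes are
reverse-complemented into the J strand. The `atta-like` profile copies the
bundled annotation's order, gene lengths and junction lengths, so its
realized genome reproduces the published spacer architecture (3,808 bp /
30 IGS, three overlaps, 18,729 bp) exactly, with composition statistics
concentrating near the configured weights.

What the model does *not* emulate: codon-level selection, amino-acid
composition, strand-asymmetric skews (GC/AT skew), repeats inside spacers,
sequence homology between genomes, or evolution along a phylogeny. Tests
passing on synthetic data therefore validate the *arithmetic and
bookkeeping* of the pipeline — interval logic, strand handling, codon
framing, order comparison — not any biological inference about real
sequences.

## Determinism, sizes and degenerate inputs

All randomness flows through a single integer seed per generated genome
(`numpy.random.default_rng`); identical specs yield byte-identical FASTA
and feature tables. The test suite and the acceptance script run on the
37-gene fixture, synthetic genomes of ≤ 18,729 bp, randomized circles of ≤
10 genes, and the full 6-gene order space — everything completes in
seconds on one CPU. Degenerate inputs are defined behaviour: a record with
zero features is valid (and yields a header-only table on write); a single
annotated gene on a circle has one wrap spacer of `L − length`; abutting
genes yield zero-length spacers; an empty move list is the identity; a
non-circular record computes linear spacers with a warning.

## Known limitations

- Reproduction of IGS totals for *other* published mitogenomes depends on
  their GenBank annotation conventions (rRNA end calls, control-region
  annotation, naming); the synonym table is editable for that reason, and
  exact agreement with hand-curated tables for arbitrary accessions is not
  guaranteed.
- The ≥160 bp threshold convention and the post-*srRNA* control-region
  rule are conventions of this package chosen to match curated ant
  mitogenome tables; other papers may count differently.
- The move distance treats every single-gene move as cost 1 and does not
  infer mechanisms (duplication–random-loss, recombination), nor does it
  handle gene sets that differ between query and reference (that is an
  error, not a distance).
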
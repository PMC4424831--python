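# Methods

## The model

`pepsig` treats a protein family as a union of subfamilies, each
characterised not by an alignment or an HMM but by a flat list of short
conserved peptides. A subfamily's signature is a list of at most 70
hexapeptides, each carrying a *frequency*: the fraction of the
subfamily's member proteins that contain the peptide at least once.
Classification and genome annotation then reduce to exact substring
matching: a query sequence is scored against a list by

* `n_peptides` — how many distinct list peptides it contains,
* `frequency_score` — the sum of those peptides' frequencies
  (presence, not occurrence counts), and
* `covered_aa` — the number of distinct residues covered by the union
  of all occurrences of all matched peptides.

The approach assumes subfamilies are cohesive enough that members share
tens of exact hexapeptides, and divergent enough that different
subfamilies share few. It needs no alignment, tolerates unordered or
partially rearranged domains, and works directly on translated genomic
fragments that contain only part of a gene.

## Subfamily building

Parameters (`PPRConfig`): peptide length 6; membership threshold 10
peptides per protein; list size 70 peptides per group; minimum training
protein length 51 residues; minimum group size 2; iteration cap 100.
The 6/10/70 profile is the canonical setting for carbohydrate-active
enzyme families, where it empirically maximises functional-prediction
accuracy; the other floors guard degenerate inputs (a singleton "group"
has no meaningful frequencies).

The grouping procedure is a greedy seeded iteration authored for this
package:

1. Over the still-unassigned proteins, count for every hexapeptide the
   number of proteins containing it (duplicated sequences count with
   their multiplicity). The most widespread peptide — ties broken
   lexicographically — seeds a candidate group consisting of every
   protein that contains it.
2. Alternate two steps until the member set is stable (or the iteration
   cap is reached): (a) the candidate list becomes the 70 peptides with
   the highest presence among current members (ties lexicographic);
   (b) the members become the unassigned proteins containing at least
   10 list peptides.
3. A converged group with at least `min_group_size` members is emitted
   with frequencies recomputed over its final members, and its members
   are removed from the pool. A seed that fails to grow a group is
   banned and the next-best seed tried; the procedure stops when no
   viable seed remains.

Seeding from the single top peptide, rather than from a block of the
top 70 peptides, is deliberate: when several subfamilies are equally
represented in the pool, their peptides tie in the global ranking and a
block seed would interleave unrelated subfamilies, whereas a single
seed peptide anchors the candidate group in exactly one subfamily.
Every tie-break in the package is lexicographic after the stated
criteria, so identical inputs give byte-identical outputs.

Duplicate sequences are collapsed before training and re-expanded into
the emitted member sets, so repeated submissions of one protein neither
inflate the peptide ranking nor change the result.

## Significance and genome annotation

A match between a sequence and a subfamily list is *significant* only
if all three hold (`HotpepConfig`):

* `n_peptides >= 3`,
* `frequency_score > 1.0` (strict: one perfectly conserved peptide
  alone scores exactly 1.0 and fails; either several peptides or high
  joint conservation is required), and
* `covered_aa >= 10` (three maximally overlapping hexapeptides cover
  only 8 residues and fail; three non-overlapping ones cover 18).

Fungal mode splits the genome into 2000-base fragments overlapping by
100 bases, translates each fragment in six frames, scores every frame
against every list, and keeps per fragment the single best significant
(frame × subfamily) hit — argmax on frequency score, ties by peptide
count then group id. Significant same-family hits whose fragment start
positions differ by less than 5800 bases are chained (single linkage)
into one gene call whose subfamily and score come from the
best-scoring contributing hit and whose interval spans the
contributing fragments. Strand is ignored during merging, and distance
is measured start-to-start between fragments: fragments are the unit
of assignment, and any finer within-fragment coordinate would be
invented precision.

Bacterial mode translates the whole genome in six frames, extracts
maximal stop-free runs strictly longer than 50 residues (no start
codon required), scores each ORF independently and reports every
significant ORF as its own call — no merging, since bacterial genes
lack introns and stop-to-stop runs already delimit them.

Internally all coordinates are 0-based half-open; TSV and GFF3 output
converts to 1-based inclusive. Scores are compared exactly (no
rounding before thresholding) and printed to 6 decimals.

## Cluster analysis and position profiles

Subfamily relatedness is the exact set-intersection count of two
peptide lists. For dendrograms the count S is converted to the
dissimilarity d = L − S with L the list-size cap (70 by default) — the
simplest monotone inversion bounded by the list size — and fed to Ward
agglomerative clustering; group ids are sorted so equal dissimilarities
resolve deterministically, and the tree is exported as Newick with
branch lengths equal to merge heights. Fine branching order under
other monotone transforms of S is not a stable property and should not
be over-interpreted.

A conserved peptide's position is the median over all member proteins
containing it of the 1-based start of its first occurrence — the
median, not the mean, so truncated or extended members do not drag the
position. Corner conventions, all configurable: first occurrence per
protein, lower median for even counts, bins [1, 20], [21, 40], ….
Per-subfamily profiles add one count per peptide to the bin holding its
median; the accumulated profile is the bin-wise sum over subfamilies.

## The synthetic generator

The generator emulates the structure the method assumes. Each
subfamily's motif set is the 70 overlapping hexamers of a random
75-residue conserved region — mirroring how conserved peptides tile a
conserved region in real families rather than being scattered — and
the region is planted at a subfamily-fixed offset inside otherwise
uniform-random sequence of length 200–350 residues (enzyme-domain
scale, conserved region in the N-terminal two-thirds). Motif sets are
drawn disjointly across subfamilies, with regeneration on collision, so
zero sharing is exact by construction; an optional shared core
(`cross_family_sharing`) plants a common sub-region in every
subfamily. Per-residue mutations are applied i.i.d. (replacement drawn
uniformly from the 19 other residues). Genomes reverse-translate
proteins with uniformly random synonymous codons (no codon-bias model:
matching operates on translated peptides, so bias is irrelevant to the
tested contracts), frame each gene with TAA stops, place it on a
uniform-random strand and separate genes by uniform-random intergenic
sequence, 8000–12000 bases by default — beyond the 5800-base merge
radius plus fragment geometry, so distinct planted genes yield
distinct calls. All coordinates and motif sets are recorded as
machine-checkable truth, and everything is deterministic under the
seed.

What it does not emulate: real amino-acid composition, introns, GC
content, repeat families, or gradual within-subfamily divergence.
Passing the planted-recovery tests therefore shows the machinery is
correct under the model's own assumptions, not that the thresholds are
optimal for any particular real clade.

Test and example pools are kept at desk scale — the recovery suite
uses 3 families × 4 subfamilies × 20 proteins (70 motifs, zero
mutation) and genomes of roughly 10 genes / 100 kb — sizes at which
every planted structure is still fully resolvable and the entire suite
runs in well under a minute.

## Known limitations

* When subfamilies share a sizeable motif core (around the membership
  threshold of 10 peptides or more), the greedy builder can merge them
  into one group: the shared peptides dominate the seed ranking and
  alone satisfy membership. Real divergent subfamilies share few
  peptides, but closely related ones may be reported as a single
  group.
* The 5800-base merge rule joins genuinely distinct same-family genes
  lying closer than the merge radius; this is a documented property of
  the rule, not a defect of its implementation.
* A conserved region straddling a fragment boundary is split between
  two overlapping fragments; each side usually remains significant and
  the merge step rejoins them, but a region with very few matching
  peptides may drop below the significance floor in both halves.
* The frequency score is comparable across groups only under the
  presence-fraction normalisation used here; lists produced by other
  tools with occurrence counts must be renormalised before use.
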
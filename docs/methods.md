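# Methods

## Overview

The pipeline decides, for each autosomal copy of a gene family with X/Y
gametologs, whether it is a *functional rescue* of a lost Y-linked gene.
The decision combines three per-copy functionality screens (ORF,
transcription, recency) with four comparative analyses (parental-origin
trees, synteny grouping/dating, Dollo event placement, dN/dS). This note
records the models behind each stage, the parameters that matter, and the
choices made where the design was genuinely open.

## Species tree

The packaged tree covers 13 mammals (great apes, two Old World monkeys,
two New World monkeys, mouse, rat, cattle, opossum, wallaby), is rooted,
binary and ultrametric (leaf depths equal within a relative tolerance of
1e-6), with branch lengths in millions of years. Two dates carry
analytical weight and are treated as fixed: mouse–rat at 25 My and
opossum–wallaby at 88 My — these set the dating lower bounds below. The
remaining node ages are standard TimeTree-style values and only shape the
topology. Branches are identified by the sorted leaf set below them, so
event placements are stable across runs and tree serializations.

## ORF integrity

Translation is frame 0 under the standard genetic code; codons containing
N translate as unknown and are never counted as stops, because assembly
gaps must not masquerade as pseudogenizing mutations. A stop in the final
complete codon is terminal, not premature. A candidate is *intact* when it
has no premature stop, its length is divisible by 3, and its ORF reaches
at least `orf_length_ratio_min` (default 0.95) of the sex-linked
reference's ORF; *truncated* when only the length test fails; *disrupted*
otherwise. The 0.95 cutoff operationalizes "slightly truncated is not
intact"; there is no universal biological constant here and the value is
configurable. When the reference itself is disrupted (this occurs in real
data: a wallaby X-linked ribosomal-protein gene carries an ORF-disrupting
mutation) the comparison proceeds against the reference's full frame with
a warning.

## Divergence and the recency filter

The recency screen uses the uncorrected proportion of differing sites
(p-distance) between the transposed copy and its inferred parental copy,
with gap/N columns excluded; copies with p < `recency_threshold` (default
0.02, strictly) are dismissed as too young for selection to have vetted
them. The uncorrected distance is used deliberately: at the 2% scale the
Jukes–Cantor correction is negligible and the threshold is conventionally
quoted on raw divergence. When the true parent no longer exists (the
usual case — the Y copy was lost), the comparison falls back to the
same-species copy of the inferred parent class, then to the nearest
species' copy of that class; this proxy only adds divergence, so it can
only make the filter more permissive, never dismiss an old copy.

## dN/dS (Nei–Gojobori 1986)

Counting method with equal pathway weighting:

* per-codon site fractions enumerate the 9 single-base mutations; mutations
  to stop codons are removed from the denominator position by position, so
  every codon still contributes exactly 3 sites (S + N = 3 × codons);
* differences between a codon pair are averaged over all shortest
  substitution pathways that avoid stop-codon intermediates, each pathway
  weighted equally; codon pairs whose pathways all cross a stop are skipped
  with a warning and excluded from the site totals;
* pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)·p), and ω = dN/dS.

Conventions for degenerate cases: ω is undefined when dS = 0 (no
synonymous signal) or when pS is saturated (≥ 3/4) with dN > 0; but when
there are zero nonsynonymous differences alongside synonymous ones, ω = 0
is reported even if pS is saturated — short toy pairs can have pS > 3/4
while the biology (pure synonymous change) is unambiguous. These
stop-handling choices shift third-decimal results and are therefore spelled
out; the implementation is checked to 1e-12 against an independent
exhaustive pathway-enumeration oracle. Published values computed with
ML-based tools are expected to agree to roughly 2 significant figures,
not bit-exactly.

## Alignment

Family CDS are aligned at the protein level and back-threaded onto codons,
so gap runs are codon-sized and downstream distances and dN/dS stay in
frame. Sequences are translated up to their first stop (terminal stops
stripped; disrupted copies contribute their readable prefix); the MSA is
center-star: the center sequence maximizes the summed pairwise alignment
score, every other sequence is aligned to it by global Needleman–Wunsch
(BLOSUM62, gap open −11, extend −1, via Biopython's PairwiseAligner), and
the pairwise alignments merge under once-a-gap-always-a-gap. Center-star
is exact for two sequences and adequate for the package's indel-poor,
closely related gene families; it is not a general-purpose MSA.

## Gene trees, bootstrap, origin calls

Distances are Jukes–Cantor-corrected nucleotide distances over pairwise
gap/N-free columns (saturated pairs capped at 5 substitutions/site so the
matrix stays finite). Trees are Saitou–Nei neighbor joining; ties in the
Q criterion break to the lexicographically smallest pair of cluster
representatives, and negative branch lengths are clamped to zero with the
deficit moved to the sibling branch. Bootstrap resamples *codon* columns
(respecting the threading) with replacement; the support of a bipartition
is the percent of replicate NJ trees containing it. An alignment with no
variable codon columns yields no signal: supports are flagged
uninformative (None), never reported as 100.

Origin classification roots the tree on an outgroup — the copies of the
species with the greatest mean divergence from the others (marsupials when
present), preferring its X-linked copy — and reads the sister group of the
autosomal clade: all-Y sister ⇒ Y origin, all-X ⇒ X origin, anything else
unresolved. A verdict requires bootstrap support of the uniting clade of
at least `bootstrap_support_min` (default 70; the threshold behind the
original origin claims is not published, so this is configurable).
NJ replaces a maximum-likelihood search deliberately: it is deterministic,
fast, and oracle-testable (it provably reconstructs additive metrics, which
the tests exercise), and topology-level origin calls are robust to the
substitution. The deviation is visible in the package's metadata and here.

## Expression

Reads are assigned to the homolog with the fewest mismatches over the best
ungapped alignment (both strands, all offsets), accepted only if that
minimum is ≤ `mismatch_tolerance` (default 3) *and* strictly smaller than
against every other homolog of the family; ties are ambiguous and
discarded rather than fractionally split, which would bias toward the
longer copy. Candidates are found seed-and-extend: a read with ≤ t
mismatches must contain an exact chunk of length ⌊L/(t+1)⌋ (pigeonhole),
so only seeded diagonals are scored. Assigned + ambiguous + unassigned
equals the read total per tissue, always.

Levels are reads per kb of CDS; the per-tissue autosomal:X ratio is
(cA/LA)/(cX/LX), undefined (not infinite) when the X copy has zero reads.
A copy has transcription evidence when ≥ `min_reads_expressed` (default
10) reads land on it in at least one tissue — a raw-count rule, simple and
reproducible; depth normalization against the X copy was considered and
rejected as an extra coupling between screens. Breadth is the number of
tissues reaching that threshold. Patterns: *silent* (breadth 0);
*testis-specific* (expressed in testis with the testis level ≥
`testis_fold_min` (default 5) times the best non-testis level); otherwise
*broad* (including the degenerate case of a single expressed non-testis
tissue). The threshold behind "barely detectable" transcription in the
real data is unpublished; `min_reads_expressed` is its configurable
stand-in.

## Synteny grouping and dating

Two transposed loci in different species share an origin when they share
≥ `synteny_min_shared_flanks` (default 2) flanking-gene symbols in
consistent relative order (longest-common-subsequence test over the
ordered upstream+downstream lists); an inverted-but-shared context needs
one extra shared symbol, since inversions near the insertion site do occur
without implying independent insertion. Groups are the transitive closure
of pairwise synteny — a partition, checked as such. The minimum
origination age of a group is the maximum pairwise divergence time of its
carrier species: a lower bound (the insertion predates the carriers'
split), never an estimate of the true age; singletons get 0 (no bound).

## Dollo event placement and rescue calling

Y presence/absence per family is explained under Dollo parsimony: a single
origin at the root of the family's *scope* (the species where the family
exists at all — genes of the X/Y-added region simply do not occur in
marsupials and carry no loss signal there) and irreversible losses. The
minimal loss set is exactly the set of maximal all-absent subtrees; the
implementation is verified against a brute-force minimal-cover search over
every rooted topology with ≤ 5 leaves and a seeded sample of 6-leaf
topologies, under every presence pattern (the full 6-leaf enumeration is
945 topologies; the sampled check holds the property at the same depth for
a fraction of the cost).

Gains are placed on the stem of the MRCA of each locus group's carriers.
Gains of the same family on the same branch collapse into one origination
event that retains all its locus groups — this is the granularity at which
events are counted (the two shared marsupial ribosomal-protein loci are
one event with two loci; per-locus counts remain in the report).

A gain becomes a rescue when (i) every carrier species lies in a lineage
with a loss of the same family — or, for ancient gains that may predate
the loss, a loss lineage is contained in the carriers; the temporal order
of gain and loss on the same lineage is not inferable from presence data,
so both orders are admitted and flagged `ordering_ambiguous` — and (ii) at
least one carrier copy is intact, transcribed, and passes the recency
filter. Everything else is reported as an excluded gain with its reasons
(pseudogene, too recent, no matched loss), and per-filter counts form the
pipeline's audit trail.

## Synthetic data generator

The generator emulates exactly the processes the pipeline must recover:

* a stop-free random CDS (default 300 codons, fixed ATG/TAA ends) evolves
  along the dated tree at `subs_rate` (default 0.002 attempted
  substitutions/site/My, the canonical mammalian neutral rate); attempted
  point mutations arrive as Poisson(branch × length), synonymous changes
  always fix, nonsynonymous changes fix with probability ω, stop-creating
  changes never fix. Acceptance–rejection on ω (rather than a full codon
  rate matrix) keeps the generator oracle-simple: realized dN/dS equals
  configured ω in expectation, which the recovery tests rely on;
* X and Y gametologs split `gametolog_split_my` ago (default 180 My, an
  early-in-sex-chromosome-evolution stratum) and evolve under per-class ω
  (defaults X 0.1, Y 0.15, functional autosomal copies 0.1, pseudogenes 1);
* transposition events are planted at a configurable fraction along their
  branch (default the midpoint — planting at a branch end would create a
  zero-length internal edge and make the origin call unresolvable in
  principle, which is a property of the history, not of the method);
  retro events get fresh flanking-symbol contexts inherited by all
  descendant carriers, DNA-transposition events copy their parent
  chromosome's context; `pseudogenize` fixes an in-frame stop at an
  event-chosen codon (applied at emission, so later evolution cannot
  revert it); `recent` plants the copy at 0.005 substitutions/site from
  its parent, safely inside the 2% dismissal zone;
* reads are drawn per copy and tissue at `depth` (default 50 reads/kb) ×
  a pattern multiplier (broad 1 everywhere; testis-specific 1 in testis,
  1/fold elsewhere; silent 0), read length 75, i.i.d. per-base errors at
  0.002, uniform start positions, with per-read truth origins recorded.

The standard benchmark scenario (`simulate.standard_scenario`) plants four
families mirroring the canonical rescue cases — Y-derived rodent
retrogene with rodent-stem Y loss, X-derived ape retrogene with
simian-wide loss, X-derived marsupial-stem retrogene, Y-derived
marmoset DNA transposition — with each family's autosomal ω set to the
published pairwise estimate for the case it emulates (0.0010, 0.075,
0.0132, 0.3381) and events placed early enough on their branches that
every planted copy is diverged past the recency cutoff, as every reported
real event necessarily is.

What the generator does *not* emulate: indels, rate heterogeneity across
sites and lineages, GC/isochore structure, intron sequences (only presence
flags), spliced reads, expression noise beyond Poisson-by-construction
counts, and assembly artifacts. Passing on simulated data therefore
demonstrates the pipeline's logic and its estimators' consistency under
its own model, not robustness to alignment error or real RNA-seq biases.

## Problem sizes used by the test suite

Chosen to exercise each property at convincing depth while keeping the
default suite in the minutes range: 1,000 random short codon pairs for the
NG86 oracle; all rooted topologies with ≤ 5 leaves plus 120 sampled 6-leaf
topologies × all presence patterns for Dollo; 50 random additive trees of
4–8 taxa for NJ; ω recovery at ~10 kb for ω ∈ {0.05, 0.5, 1.0}; 20 seeded
end-to-end replicates of the standard scenario (≥ 19 must match the
planted truth exactly).

## Known limitations

* The curated dataset carries presence, synteny and evidence verdicts but
  no sequences; the sequence-level stages run only on user-supplied or
  simulated data. The four published dN/dS reproduction tests require the
  original GenBank CDS under `data/external/`.
* Origin calls for events on the deepest rootward branches (e.g. a
  marsupial-stem copy when marsupials are also the only available
  outgroup) are structurally unresolved — consistent with the real
  marsupial case remaining ambiguous.
* Dollo parsimony with a presence/absence matrix cannot order gain vs loss
  on a single lineage; the report flags this rather than guessing.
* The synteny rule is a local flanking-symbol test, not whole-genome
  synteny-block detection; it presumes curated ortholog symbols.
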
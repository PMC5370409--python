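# Methods

`mitevol` implements three analysis tracks for small organellar genome
sets — discovery of highly conserved elements (HCEs), a weighted
cut-and-join rearrangement distance between chromosome structures with
distance trees and ancestral gene-order reconstruction, and protein
family clustering — together with a simulator that generates genomes
with a fully known evolutionary history so that every stage can be
scored against ground truth. This note records the models, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and the known limitations.

## Highly conserved elements

An HCE is a cluster of near-identical DNA words shared between (or
repeated within) genomes, found without reference to gene annotation;
a fully invariant cluster is the ultraconserved special case.

**Pipeline.** (1) Every exact `key_length`-mer of both strands is
indexed in canonical (lexicographically smaller) strand form; keys with
more than `max_key_repeat` occurrences are dropped, as are
low-complexity keys with fewer than three distinct bases (homopolymers
and two-letter repeats otherwise flood AT-rich sequence with spurious
seeds). Same-genome seed pairs closer than `min_word_length` are
skipped as self-overlapping tandem matches; distant same-genome repeats
are kept, so a repeated element inside one genome is found. (2) Each
seed pair is extended outward by a greedy X-drop scan (+1 per matching
column, −3 per mismatch — the standard nucleotide-search weighting, so
extension dies within a few bases in background even at 75 % A+T — with
drop threshold `max_word_cost`, trimmed back to the best-scoring
column). Per genome, extension intervals merge when they overlap by at
least `min_overlap` bases; merged word ends are then trimmed to the
region supported by at least two contributing extensions, because a
single pair's overshoot into unrelated flanking sequence has support
one while the conserved core is covered by every pair. A word is
emitted if its span reaches `min_word_length` and the span per seed
stays within `max_compaction_ratio × key_length`. (3) Words become
vertices of a graph with edges where `word_cost ≤ max_word_cost`;
within each connected component the minimum-degree vertex is peeled
(ties by genome, start, strand) until the remainder is a clique, which
is emitted as an HCE when it has at least `min_diff_words_word` members
of which at least `min_diff_words_key` share one exact key; peeled
vertices re-enter the pool. Every emitted HCE therefore satisfies the
all-pairs cost bound by construction, and HCE numbering follows
emission order, so the procedure is deterministic.

**Word cost.** Words from different genomes carry a few bases of
boundary jitter, so the cost slides one word along the other and counts
mismatches over the overlap window; the inherent length difference is
free, while refused overlap (an overlap shorter than the shorter word)
is charged at `deletion_cost` per base. With
`max_consecutive_deletions > 0` the windows are additionally aligned
with run-limited internal deletions, and a run-limited global alignment
of the whole words lets a true internal deletion cost a single gap. At
the default `max_consecutive_deletions = 0` the cost is a pure weighted
Hamming distance on the best overlap. Two consequences are worth
noting: an exact substring at full overlap costs 0 (so "zero cost"
means "identical up to boundary jitter", not literal string equality),
and the cost is evaluated for both orientations of the second word,
because near-identical words can canonicalise to opposite strands.

**Defaults** (the standard parameter set): key length 8, minimum word
length 24, maximum word cost 3.1, minimum merge overlap 20, consecutive
deletions 0, deletion cost 2.1, maximum key repeat 1000, maximum
compaction ratio 2.2, minimum words per cluster 4 with 3 sharing a key.
The member floor is read as a member-word count, not a distinct-sequence
count: conserved elements routinely contain identical member words, and
a distinct-sequence reading would reject exactly the most conserved
clusters.

**Promoter scan.** `scan_consensus` compiles an IUPAC pattern (e.g. the
plant-mitochondrial promoter core `YRTA`, or the extended
`YRTAnnAATTY`) to a regular expression with overlap-aware lookahead and
reports all 1-based match positions on the given strand.

## Chromosome structures and the rearrangement distance

A genome is abstracted as a set of linear (`L`) or circular (`C`)
chromosomes of strand-signed gene occurrences, equivalently a set of
adjacencies between gene extremities (head/tail); linear chromosomes
are paths of the extremity graph, circular ones cycles. Evolution
proceeds by weighted operations: `dcj` (cut two adjacencies or telomere
pairs, rejoin the four ends in an alternative pairing; cost 1.2, the
telomere-involving case is the "linear variant"), `sesqui` (one cut
plus one join touching three ends; 1.1), adjacency gain `a_insert`
(1.0) and loss `a_delete` (0.9) — which interconvert circular and
linear chromosomes — and gene gain `b_insert` (0.9) and loss `b_delete`
(1.0, flanks optionally healed). Deletions of adjacencies or genes
marked *special* by a caller-supplied predicate are charged 2.0 / 2.5;
by default no edge is special, since nothing in the data identifies
one — the hook exists so callers can mark edges.

**Distance.** `distance(s1, s2)` searches for a minimum-total-cost
operation sequence. A greedy beam (width 2) over strictly
mismatch-reducing operations provides a valid scenario and an upper
bound; candidates are enumerated goal-directedly (every improving
rearrangement must create a missing target adjacency), states are
ranked by accrued cost plus an admissible bound, and termination is
guaranteed because a strictly mismatch-reducing operation always
exists. When the combined gene universe has at most nine occurrences
the bound is refined by A\*: the heuristic weighs wrong adjacencies,
missing adjacencies and surplus/absent genes with coefficients from a
small linear program over the per-operation mismatch-reduction
capacities (e.g. one dcj can fix at most two wrong plus two missing
adjacencies), so it is admissible and the refinement is exact whenever
the search completes within the node budget — always the case at these
sizes. `distance_oracle` is an independent uniform-cost (Dijkstra)
search over the same operation semantics, capped by a valid scenario
cost so the capped search still returns the exact minimum; it is the
certification route for the guided search. Gene insertions are
restricted to target gene occurrences: inserting any other gene can
never be part of a minimum-cost scenario under non-negative costs,
because its later deletion undoes it at extra cost.

The returned event list replays on `s1` to exactly `s2` (up to
renumbering of paralogous occurrence indices). Paralogous copies are
matched across the two structures before graph construction by a
minimum-cost bipartite assignment on flanking context. The directed
distance is asymmetric for two reasons: gene gain and loss have
different costs, and a dcj that joins two telomere pairs has no
equal-cost reverse (a pure double-cut is not an operation). Tree
building therefore symmetrises, by the arithmetic mean by default
(minimum available as a flag).

**Exactness boundary.** On instances above nine gene occurrences the
greedy scenario is returned as-is; it is tight for short scenarios
(independent events are realised one-to-one) and an upper bound in
general. The certification against the oracle on ≤5-gene instances
covers the regime where exhaustive search is feasible; behaviour on
large instances is heuristic and documented as such.

## Trees

`neighbor_joining` is the Saitou–Nei agglomeration with deterministic
tie-breaking (smallest label pair) and negative branch lengths clamped
to zero with a warning; on additive matrices it reconstructs the
generating topology exactly, which the tests verify on random trees and
against an independent implementation. `binary_distance` turns the HCE
presence/absence matrix into row distances (Hamming by default,
matching the binary-character framing; Jaccard as an alternative).
`rf_distance` counts Robinson–Foulds bipartition differences, and
`clade_check` tests whether a named leaf group is a bipartition of the
unrooted tree (a clade under some rooting).

## Ancestral reconstruction

Given a tree (unrooted trees are midpoint-rooted by default; polytomies
are resolved deterministically, smallest labels first) and leaf
structures, internal nodes are initialised and improved by a
deterministic local search: each internal node is re-optimised against
the sum of directed distances to its tree neighbours, choosing among
its current structure, its neighbours' structures, a majority-consensus
structure (genes and adjacencies carried by more than half of the
neighbours, added greedily by support), and intermediates along optimal
pairwise scenarios between those candidates. A sweep visits every
internal node; the search stops when a full sweep yields no
improvement, so the total cost is non-increasing across sweeps. Two
starts are run — nearest descendant leaf per node, and
majority-consensus of each node's descendant leaves — and the cheaper
converged scenario is kept; both starts are deterministic, so repeated
runs give identical output. Exact Steiner/median optimality is not
attempted. Per-edge event lists come from the pairwise distance
certificates, so replaying each edge transforms the parent structure
into the child structure by construction.

On simulated scenarios with up to two events per edge the procedure
recovers roughly three quarters of the true internal structures
exactly and its total cost tracks the true scenario cost closely
(ratios near 1, sometimes below when the true event sequence was not
minimal); the recovery rate is a heuristic diagnostic, reported by the
acceptance script, with a configured floor in the test suite rather
than a hard model claim.

## Protein clustering

All-against-all Smith–Waterman (BLOSUM62, gap open 11 / extend 1 — the
classic protein-search defaults, so an external BLAST+ backend is
interchangeable) with Karlin–Altschul E-values (gapped constants
λ = 0.267, K = 0.041; database size = total residue count of the input
set). Pairs with E ≤ 0.001 become edges; edges are filtered by coverage
≥ `L` and per-vertex strongest-fraction `H`, and clusters are the
connected components — with the most relaxed settings (`L = 0`,
`H = 1`) plain connected components, which is why the additional
parameter `p` of the originating method is accepted for interface
compatibility but has no effect here. Cluster ids are canonical by
smallest member, so the partition is independent of input order.
Within-genome member pairs of a cluster (recent paralog candidates)
are reported post hoc with their pairwise difference counts;
`count_differences` counts differing columns of a unit-score global
alignment, a gap opposite a residue counting one per column. A
descriptive NJ tree on difference counts is available per family; no
model-based (ML/Bayesian) tree inference is implemented or wrapped as a
requirement — an optional subprocess hook can invoke external tools,
and no test depends on it.

## Synthetic data

The generator emulates the statistical shape of a small ciliate-like
mitochondrial genome set; defaults, chosen once as the study
conditions: 8 genomes, 20 genes on one linear chromosome (real sets
range roughly 20–100 genes per genome), 75 % A+T, protein lengths
60–120 aa, intergenic spacers 40–120 bp, 10 planted elements of
30–60 bp inserted at the root (every leaf carries a copy) and mutated
at 0.02 substitutions per base per copy, protein families at 70 %
within-family identity (per-copy substitution probability
q = 1 − √identity, so two leaf copies meet the target in expectation).
Protein seeds and the substitution kernel draw residues from natural
(Robinson–Robinson) background frequencies rather than uniformly: a
uniform background over-represents rare high-scoring residues (W, C)
and mis-calibrates the Karlin–Altschul significance statistics that
the similarity search relies on, producing spurious cross-family
links between genuinely unrelated random proteins.
Gene orders evolve along a random binary tree by the model's own
operations — counts per edge are Poisson with mean rate × branch
length, or uniform in a configured range when a test requires every
branch to carry events — with operands drawn uniformly among the legal
operations of the drawn kind; a gene gain duplicates an existing family
with probability 0.3, producing occasional recent paralogs. Everything
derives from one integer seed and serialises byte-identically: GenBank
flat files (one record per chromosome; a fixed LOCUS date keeps output
reproducible), a protein FASTA, a gene-order table and a truth JSON.

Deliberate non-realism, hence what passing tests do and do not show:
background sequence (gene bodies and intergenic spacers) is drawn
i.i.d. per leaf, so planted elements are the only conserved sequence —
real genomes share coding sequence between species, and a real run must
rely on the key-repeat, compaction and clique constraints to separate
coding conservation from intergenic elements, which the synthetic tests
do not probe. There are no codon structure, no tRNA genes, no
mutation-rate heterogeneity, no indel noise in planted elements (the
gapped word-cost branch is exercised by direct unit tests instead), and
nucleotide gene bodies are unrelated to the annotated translations.

**Problem sizes used by the verification runs** (the package's own
desk-scale choices): planted-element recovery and specificity use 10
genes / 8 leaves (~2.5–3.5 kb genomes) over 100 seeds; whole-pipeline
tree recovery uses 10 leaves, 40-gene genomes and 1–2 events per branch
over 100 seeds — with Poisson counts ~37 % of branches carry no event
and their bipartitions are unresolvable in principle, so the recovery
regime fixes at least one event per branch; oracle certification uses
structure pairs with at most 5 gene occurrences, where exhaustive
search is feasible, under the default and two randomly drawn cost
vectors; reconstruction soundness uses 6 leaves / 20 genes with 0–2
events per edge.

## Numerical choices and degenerate inputs

Floating-point cost comparisons use absolute tolerances of 1e-9/1e-12;
all tie-breaks (peeling order, NJ joins, event enumeration, polytomy
resolution) are lexicographic, so every pipeline stage is deterministic
given its inputs. Empty structures are rejected at construction; a
genome shorter than the key length contributes nothing to the HCE index
(warning); a CDS without an annotated translation is translated from
the nucleotide sequence with the record's translation table (warning);
an oracle search that exhausts its explicit cost cap reports "unknown
at or above the cap" rather than a number. Features wrapping the origin
of a circular genome are kept as a single flagged feature. Coordinates
are 1-based inclusive throughout.
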
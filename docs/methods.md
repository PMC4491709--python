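# Methods

## Ordered networks and the substructure catalog

An *ordered network* is a directed graph whose nodes carry a strict
total order, independent of the topology — in a food web, species
ranked by average adult body mass. Any pair of rank-ordered nodes is
in one of four states (no link, a downward link from the higher- to
the lower-rank node, an upward link, or both), so a triple of nodes
realises one of 4³ = 64 configurations. Ten of these leave a node
with no incident link; the remaining 54 *connected ordered
substructures* are the objects everything else counts. Ignoring the
order collapses them onto the 13 classical connected 3-node digraph
classes; each class contains between 1 and 6 ordered members (the
class size times the order of the digraph's automorphism group is
always 3! = 6, which the test suite verifies by brute force over the
six rank relabellings).

Substructures are labelled (q, s) with q the isomorphism class and s
the member. The numbering is a convention of this package — classes
sorted by link count and then by canonical edge set, members in
lexicographic order of their pair-state code — chosen because it is
deterministic across platforms and fully reconstructible from the
published table in `docs/catalog.md`. Code that cares about specific
feeding patterns should use the structural aliases instead of raw
numbers: `fan_in_up` (a predator with two smaller prey), `up_chain`
(a body-size-ordered tri-trophic chain) and `fan_out_up` (a prey
shared by two larger predators).

## Spectrum counting

The spectrum η₍q,s₎ counts, over all C(N,3) node triples, the induced
configuration of each triple (all three pair states read from the full
edge set). Counting iterates the triples with O(1) adjacency lookups,
vectorised over all triples at once; for the network sizes this
package targets (food webs, N up to a few hundred) this is fast and
has no failure modes, so no edge-anchored enumeration is implemented.
Self-loops (cannibalism) are stored on the network but never enter a
triple; the number skipped is logged. Ties in the niche variable are
broken by input order with a warning, since the order must be strict;
the order actually used is always written alongside results.

## The directed ordered random model

For every rank-ordered pair j < i an upward link appears with
probability p_up and a downward link with p_down, independently. A
substructure's appearance probability is the product of its three
pair-state probabilities, which reduces to

    P = p_up^u (1 − p_up)^(3−u) · p_down^d (1 − p_down)^(3−d),

where u and d count upward and downward link factors (a bidirectional
pair contributes to both). Substructures sharing (u, d) form a
*statistical class* with identical P regardless of their isomorphism
class. Connected substructures realise every (u, d) ∈ {0..3}² except
(0,0), (1,0) and (0,1), hence exactly 13 probability levels for
generic p_up ≠ p_down, collapsing to 5 levels (P = p^l (1−p)^(6−l),
l = u + d ∈ 2..6) in the symmetric case. Expected counts are
C(N,3)·P. When counting distinct levels, values are grouped within a
relative tolerance of 1e−12: products of the same factor multiset can
differ in the last ulp depending on evaluation order, while genuinely
different levels are separated by factors of order p.

## The niche model

The niche model generates food-web topologies from two parameters,
species richness N and connectance C = L/N² (self-loops included in
L, as is conventional). Each species draws a niche value
nᵢ ~ Uniform[0,1]; its feeding range is rᵢ = x·nᵢ with
x ~ Beta(1, β), β = 1/(2C) − 1, so E[x] = 2C and the expected diet
width is C; the range centre cᵢ is uniform on [rᵢ/2, nᵢ]. Species i
eats every j whose niche value lies within rᵢ/2 of cᵢ (boundaries
included); edges are stored prey → predator (energy flow), and ranks
ascend in niche value. The Beta(1, β) density β(1−x)^(β−1) is the
standard choice with mean 2C; note that the exponent must be β − 1
for the density to normalise. Webs are kept exactly as generated —
no rejection of isolated species, duplicate diets or connectance
drift — because the plain ensemble is the model; an optional
realized-connectance tolerance is available for users who want
filtered ensembles. Ensemble replicates run on independent RNG
substreams spawned from a single seed sequence, so ensembles are
reproducible from (seed, parameters) and safe to parallelise.

The defaults used throughout the examples and acceptance runs are the
published Alford-lake fit, N = 56 and C = 0.0692 with 1000
realizations. Under these conditions roughly 37 of the 54
substructures ever appear (the union over the ensemble; run-to-run
variation of ±2 is normal), dominated by the three two-upward-link
patterns — the same three that dominate the asymmetric random model,
because feeding runs predominantly up the body-size axis.

## Nulls and Z-scores

Two null ensembles are built in. The *reordering null* applies
independent uniform random permutations to the node ranks, keeping the
topology fixed; since reordering can only move counts between members
of the same isomorphism class, the collapsed 13-class census of every
replicate is identical to the original — any Z-signal against this
null is purely hierarchical. For networks with at most 8 nodes the
null can be enumerated exhaustively over all N! orders, which is what
the small-fixture tests compare against. The second null is any
generative ensemble (niche model, or the random model with p_up and
p_down estimated from the observed up/down link densities).

Deviations are scored per substructure as

    Z₍q,s₎ = (η_obs − η̄_null) / σ_null,

with σ_null the sample standard deviation (n − 1 denominator — the
choice is a convention and is documented rather than hidden).
Substructures absent from the observed network enter with η = 0.
Entries with σ_null = 0 are flagged as degenerate and carry no Z;
they are never reported as 0 or ±∞. No multiple-testing correction is
applied: the 54 Z-values form a significance *profile* to be read as
a whole, not 54 independent hypothesis tests — users who need
per-entry error control must correct downstream.

## What the synthetic generators do and do not emulate

The random model and the niche model are the package's data sources
for tests; neither is real data. The niche model reproduces the
contiguous-diet, body-size-ordered structure of real webs and the
empirical dominance of upward feeding motifs, but real webs have
taxonomic lumping, sampling error in both links and body masses, tied
or missing mass estimates, and omnivory in excess of the model — the
known systematic gap that significance profiling is designed to
expose in the first place. Passing tests therefore certify the
counting, the analytics and the generators against each other, not
that any particular empirical web will match a niche ensemble.

## Numerical and design choices

- Canonical forms and isomorphism grouping use exhaustive search over
  the 6 permutations of three labels — exact and platform-independent;
  no hashing heuristics.
- Pair-slot order (bottom,middle), (bottom,top), (middle,top) is fixed
  package-wide and documented once.
- A bidirectional pair contributes 2 to a substructure's link count l,
  so l spans 2..6.
- Degenerate inputs: networks with fewer than 3 nodes yield an empty
  spectrum with a warning (not an error); duplicate edges in input
  files collapse with a warning; an edge endpoint missing from the
  node table is a hard error naming the node.
- Ensemble sizes in tests are chosen so the whole suite runs in a few
  seconds: the simulation/theory comparison uses 100 realizations at
  N = 100 and the niche ensemble 1000 webs at N = 56, matching the
  scales the analyses were designed around; stochastic assertions use
  3 standard errors with the binomial sampling error as a floor for
  entries whose expected count is far below one.

## Limitations

- Only 3-node substructures; the catalog machinery would extend to
  larger motifs but counting costs grow steeply.
- No degree-preserving edge-swap null; the nulls here are rank
  reordering and the two generative models.
- No weighted, time-resolved or multi-layer variants.
- The (q, s) numbering is internally canonical but is not guaranteed
  to coincide with any particular published figure's numbering; rely
  on the aliases or the code strings in `docs/catalog.md`.
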
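# Methods

## Data model

A chimeric read ("duplex") is two aligned arms L and R on one or two
transcripts, each a 1-based closed interval. Intra-RNA duplexes of the RNA
of interest are orientation-normalized so that L starts 5′ of R; inter-RNA
duplexes keep their reported arm order and expose a reversed view instead,
so both reporting orientations stay available. All coordinates are 1-based
inclusive throughout (the convention of dot-bracket, CT and vienna files,
which dominate the downstream logic); BED exports convert to 0-based
half-open at the boundary.

The duplex TSV dialect is a minimal 7-column schema (read_id, tx_L, L_start,
L_end, tx_R, R_start, R_end, tab-separated, header optional and
auto-detected by a non-integer third field, extra columns preserved). A
pluggable reader is not needed for the analyses here; any upstream aligner
output that can be projected onto these seven columns is accepted.

## Contact matrices

Every duplex increments the full rectangle L × R of the contact matrix
(not just arm endpoints): this reproduces the block-shaped signals of
duplex contact maps and gives the domain caller dense signal. The matrix
total therefore equals Σ|L|·|R| exactly (a conservation law used as a
test), and matrix construction is additive over duplex sets. Matrices are
stored sparse (CSR) and densified on demand. Note that a duplex whose arms
overlap (possible for spurious chimeras) contributes cells on both sides of
the diagonal; the upper-triangle property holds for all disjoint-arm
duplexes.

## Clustering

For a duplex the gap g = R.start − L.end − 1 counts nucleotides strictly
between the arms (clamped at 0 for overlapping arms). Fragments of the same
in-vivo duplex in different molecules give chimeras with overlapping arms
and near-identical g, so two duplexes are linked iff their L intervals
overlap (≥ 1 nt), their R intervals overlap, and |Δg| ≤ `max_gap_diff`
(default 10 nt); the edge weight is 1/(1+|Δg|). The overlap predicate
matters: g alone is location-free and would link unrelated regions.

Communities are found by walktrap (random-walk agglomerative clustering,
walk length `steps` = 2 by default). The merge dendrogram comes from
igraph; the package then scores *every* cut level with its own weighted
Newman modularity of the full graph and keeps the best level, with ties
broken toward fewer merges, making the cut rule explicit and the whole
procedure deterministic. Isolated vertices form singleton communities.
Communities smaller than `min_cluster_size` (default 2; a single read
carries no redundant evidence) are discarded.

Trimming: per cluster and per side, per-position read coverage is computed
over member arms; the trimmed footprint is the longest contiguous run of
positions with coverage ≥ `trim_quantile` × the side's maximum (default
0.5, i.e. majority evidence). Trimming is always a contraction of the raw
min–max footprint; if the threshold empties a side (degenerate mixtures)
the modal exact interval is used and the cluster flagged.

Replicate agreement: each trimmed cluster is a rectangle in contact space;
support of cluster c against sample t is the best Jaccard index between
rectangles, and the (s, t) agreement entry is the mean support over s's
clusters. The Jaccard-on-rectangles definition is one of several possible
agreement statistics; it is exact, symmetric in the two footprints and
cheap to compute in closed form.

## Domains

To keep folding tractable the contact matrix is partitioned into domains in
the style of Hi-C topological-domain callers, at 1-nt bins (configurable;
kilobase bins make no sense at transcript scale). The mean cross-boundary
signal in a w × w diagonal window is computed at every position (windows
clipped at the ends; matrices already symmetric are used as-is, triangular
contact matrices are reflected with M + Mᵀ). Candidate boundaries are
strict local minima; each must then pass a one-sided Mann–Whitney rank-sum
test of cross-block depletion against the two flanking within-domain blocks
(α = 0.05, Benjamini–Hochberg corrected across candidates; the filter can
be disabled). Domains are the intervals between retained boundaries and
always tile [1, n]. The default window sweep is {10, 25, 50, 100} nt.

## Folding

Two engines implement one contract — fold(sequence, hard_pairs,
forbidden_positions, reactivities) → structure with every hard pair
enforced, deterministically:

* **vienna** — RNAfold MFE via the ViennaRNA bindings; hard pairs via
  enforced base-pair constraints, forbidden positions forced unpaired,
  reactivities as Deigan pseudo-energies (slope 1.8, intercept −0.6
  kcal/mol by default).
* **stub** — a Nussinov maximum-base-pair dynamic program (AU/GC/GU,
  minimum hairpin loop 3 nt), ties broken toward pairing the 5′-most base
  with its 5′-most admissible partner, dg = −(pair count). Hard pairs are
  carried by a score bonus larger than any achievable pair count, which
  guarantees their inclusion whenever they are jointly satisfiable
  (validated up front: in-bounds, loop-legal, non-conflicting, non-crossing).
  It exists as a fast, exactly-checkable engine for tests and law checks
  and is never mixed with thermodynamic energies in one ensemble.

Cluster folding: a trimmed cluster with consensus gap ≤ `short_range_gap`
(default 10 nt) folds the contiguous region [L.start, R.end]; a long-range
cluster folds left-arm + linker + right-arm, with the 10-N linker prohibited
from pairing, and pair indices mapped back to transcript coordinates. Only
cross-arm pairs (one end in each footprint) are kept; they form one atomic
constraint carrying the cluster's read support. Atomicity (the whole pair
set, not individual pairs) preserves helix integrity when constraints are
added. Constraints below `min_support` reads (default 10) stay in the
table flagged ineligible.

Ensemble: per sample the region is folded `n_structures` times (default
100). Each iteration draws eligible constraints uniformly at random without
replacement (RNG seeded by (seed, sample index, iteration), so the run is
bit-reproducible and iterations are independent); a drawn constraint is
accepted only if its nucleotide footprint is disjoint from all previously
accepted ones — mutually exclusive constraints, the signature of
alternative in-vivo topologies, thus separate into different ensemble
members — stopping at `max_constraints` acceptances or exhaustion. The
final structure of the iteration is the fold of the region with all
accepted pairs as hard constraints; since acceptance depends only on
footprints, the intermediate refolds after each acceptance cannot change
the recorded result and are elided (identical accepted sets are folded
once and cached). Acceptances (not draws) count toward `max_constraints`.

## Ensemble analysis

Structures are embedded as binary per-nucleotide paired indicators (lower
dimension than pair-incidence and identical on the degenerate cases
tested); PCA is mean-centering plus SVD, with variance fractions summing to
1 whenever total variance is nonzero. Predictions are scored against a
reference pair set with sensitivity = tp/|ref| and PPV = tp/|pred| under
exact (i, j) matching; a ±1 slip relaxation is available but off by
default. A cluster is "explained" by a reference when some reference pair
falls inside its L × R footprints (optionally extended by a slack).

## Synthetic data generator

The generator emulates the statistical structure of proximity-ligation
chimera data from one transcript: non-crossing helices laid out one per
equal transcript segment (long-range helices put their arms at the segment
ends, gap > 100 nt), a random ACGU sequence rewritten to make helix arms
reverse-complementary (GU wobble rate 0.1), and per replicate
`reads_per_helix` chimeras per helix whose arm endpoints are jittered by a
rounded, truncated Normal(0, `frag_noise_sd`) — a single interpretable
knob for random fragmentation. Background chimeras (uniform random ordered
arm pairs, 10–30 nt arms) make up `background_fraction` of the total;
optional inter-RNA chimeras target a fixed window of a second transcript.
Everything is seeded and byte-reproducible.

Reference condition (the package's default spec, used throughout the test
suite): 600-nt transcript, 4 helices of 6–12 bp (one long-range), 50
reads/helix, jitter SD 2 nt, 6.25% background, 3 replicates, seed 7. These
sizes let the whole pipeline — including 100-member ensembles per replicate
— run in seconds while keeping ~200 reads per replicate, enough for
footprint coverage profiles to be informative.

What it does *not* model: sequencing errors, ligation and coverage biases,
PCR duplication, multi-mapping ambiguity, crossing (pseudoknotted)
structures, and condition-dependent structural change. Passing recovery
tests on this generator therefore shows correctness of the algorithms
under the stated noise model, not performance on real libraries.

## Numerical and design notes

* Weighted modularity is computed incrementally during the dendrogram
  replay (merge-by-merge updates of internal weight and degree sums), so
  the max-modularity cut costs O(E) overall rather than O(V·E).
* On structureless random graphs the walktrap dendrogram need not contain
  the maximum-modularity partition at any cut level, even when that
  optimum is unique by a clear margin; oracle-equivalence tests therefore
  draw graphs from a planted-partition model, the family community
  detection is meant for.
* The Nussinov fill is JIT-compiled (numba); the traceback is plain Python.
* Degenerate inputs: empty duplex lists give empty graphs/zero matrices;
  an empty eligible-constraint set gives an ensemble of identical
  unconstrained folds (warned); clusters whose folds have no cross-arm
  pairs yield empty constraints that are flagged and excluded downstream;
  undefined sensitivity/PPV (empty reference in region / empty prediction)
  are returned as missing values with warnings, never as 0.
* Group codes from the sample table are carried as opaque labels through
  all outputs; no control subtraction is performed.
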
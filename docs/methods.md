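# Methods

## Problem setting

The package infers a target-species protein–protein interactome from a
related source species' interaction data. Two transfer routes are combined:
*interolog transfer* (an interaction is carried across species when both
partners have counterparts there) and *domain-based prediction* (domain
pairs mediating interactions are more conserved than the interactions
themselves, so domain-pair interaction probabilities learned on the source
species can score target protein pairs that have no source counterpart at
all). The target genome is assumed to descend from the source by
polyploidy followed by fractionation, so the protein correspondence is
multi-to-multi (one to three retained copies per source gene).

## Interaction compilation

MITAB exports are spoke-model representations: co-purification experiments
already appear as bait–prey binary pairs, and the same physical pair
recurs once per detection event. Records are canonicalized to unordered
pairs (lexicographically smallest accession first; self-pairs kept),
collapsed by pair with sources, publications and detection-method terms
unioned, and merged across databases with full Venn accounting (pairwise
and higher-order intersection counts for pairs, proteins and
publications). Detection-method terms are retained through deduplication —
deliberately, although only the pair identity keys the collapse — because
the training set for domain inference is the two-hybrid subset of the
compiled data, selected by method term. Method terms are stored both as
PSI-MI identifiers (`MI:0018`) and lower-cased names (`two hybrid`); the
subset-defining list is configuration, not hard-coded. Splice-variant
suffixes (`.1`, `.2`, …) are stripped to gene-level accessions by a
configurable regex.

## The bridging map

Three evidence streams produce source↔target links with per-link evidence
codes:

* `I` — ortholog clusters: within a cluster, every source member is linked
  to every target member. No inclusion-score threshold is applied.
* `P` — synteny blocks: aligned gene pairs link directly; a gene may recur
  across blocks, duplicate links merge.
* `B` — BLAST best hits at e-value ≤ 1e−6, **only** for target proteins
  not already covered by `I` ∪ `P` (BLAST is a fill-in, not a competing
  stream). Per query the smallest e-value wins; ties break by higher bit
  score, then lexicographic subject id, for determinism. An e-value of
  exactly 0 ("too small to report") is retained.

Coverage reports (covered/uncovered counts and percentages per species)
validate that covered counts never exceed the configured genome size
(41,173 protein-coding genes for the target by default — a configuration
value, since published counts for this genome differ by one between
sources).

## Domain catalogue

Domain assignments are read from per-domain tabular files and filtered at
a stringent e-value cutoff (default 1e−10). Domain multiplicity within a
protein is collapsed to a set: the factor model is defined on distinct
domain pairs, and a repeated domain adds no new candidate. Known-DDI
tables are fused into a single canonical set with per-pair provenance;
membership is binary (no confidence weighting of the origins). Clan or
family relationships between domains are ignored — pairs are
exact-accession pairs.

## The factor-graph model

Variables are candidate domain pairs; x_d = 1 means "domain pair d
interacts", with independent Bernoulli(β) priors. Function nodes are
signed training protein pairs over their candidate sets
{{a, b} : a ∈ domains(p), b ∈ domains(q)}. The two constraints — an
interacting pair needs at least one interacting candidate, a
non-interacting pair none — are softened by a single reliability
parameter ε as a *normalized* observation channel:

    f₊(x) = [1 − (1−ε) ∏ (1−x_d)] / (1+ε)
    f₋(x) = [ε + (1−ε) ∏ (1−x_d)] / (1+ε)

The unnormalized numerators are the minimal soft-OR encoding of the two
constraints; they sum to 1+ε over the two possible labels, so dividing by
(1+ε) makes {f₊, f₋} a proper conditional distribution of the observed
label given the configuration (label flipped with probability ε/(1+ε);
ε = 0 gives hard constraints). The choice matters only for parameter
fitting: per-factor constants cancel out of messages and beliefs, but
without the normalization the partition function is monotone increasing in
ε for every configuration (∂f/∂ε ≥ 0 for both factor types), and a
free-energy minimization over ε would always return the largest ε
searched. With the channel normalization the free energy acquires the
+ln(1+ε)-per-factor term that penalizes slack, and an interior optimum
becomes possible.

### Belief propagation

Sum-product messages for OR factors have closed forms. With p_j the
incoming probability that x_j = 1 and Π = ∏_{j≠i} (1−p_j):

* positive factor → variable: m(1) = 1, m(0) = 1 − (1−ε)Π
* negative factor → variable: m(1) = ε, m(0) = ε + (1−ε)Π

(normalized; the 1/(1+ε) cancels). The closed forms are verified in the
test suite against a generic configuration-sum message on random factors.
An iteration therefore costs O(edges) irrespective of factor degree.

Schedule: synchronous (flooded), messages initialized uniform, damping 0.5,
tolerance 1e−6 on the largest absolute message change, at most 500 sweeps;
beliefs are returned either way with a convergence flag. Message products
are accumulated in log space with exact handling of zeros, so ε = 0 (hard
constraints, beliefs of exactly 1) is supported. Determinism: the same
graph, parameters and schedule always produce the same state.

### Bethe free energy

F = Σ_a Σ_x b_a(x) ln(b_a(x)/f_a(x)) + Σ_i Σ_x b_i(x) ln(b_i(x)/φ_i(x))
− Σ_i deg(i) Σ_x b_i(x) ln b_i(x), with the Bernoulli prior φ_i treated as
a unary factor (so the counting number of a variable is its real-factor
degree plus one). Factor beliefs are computed exactly from incoming
messages by enumerating the 2^k configurations of each factor; factor
degree is therefore capped (default 16). Factors exceeding the cap are
pruned at graph construction to the candidates with the smallest combined
assignment e-values, with a warning — with ≈1.4 domains per protein the
typical factor degree is 1–4 and pruning is rare. At a BP fixed point on
an acyclic graph F equals −ln Z; the test suite verifies this to 1e−8
(observed ~1e−12) against exhaustive enumeration.

### Training set

Positives: the two-hybrid subset of the compiled interactions. Negatives:
random protein pairs accepted only if (i) not in the compiled set, (ii) no
candidate domain pair in the known-DDI catalogue, (iii) sharing a
cellular-component GO term, and (iv) |co-expression| < 0.4 — co-localized
pairs with no expression signature of interaction. Sampling is seeded,
with per-rule rejection tallies and an attempt budget (default 200 draws
per requested pair; shortfalls warn). The positive:negative ratio defaults
to 1:1.

### Fitting and selection

(β, ε) are fitted by grid search — β ∈ {0.1, …, 0.8} step 0.1,
ε ∈ {0.01, …, 0.10} step 0.01 — minimizing the Bethe free energy at a BP
fixed point; non-converged grid points are recorded but excluded from the
argmin. Domain pairs with belief ≥ 0.85 are selected. A *sole pair* — the
only candidate of an interacting training pair — with no negative evidence
has belief ≥ β/(β + (1−β)ε) regardless of the rest of the graph (other
positive factors can only raise it); at (0.2, 0.02) the bound is 0.926, so
every such pair clears the 0.85 cutoff. Selection reports the overlap with
the known-DDI catalogue and flags the sole-pair subset.

**Identifiability of ε.** The fitted ε tracks the fraction of training
constraints that belief propagation cannot satisfy at prior cost. A false
positive whose candidate variables are otherwise unconstrained is
*absorbable*: setting one variable to 1 costs ln(1/β) ≈ 1.6 nats, cheaper
than the ln(1/ε) ≈ 3–4 nats of a violation, so it inflates the prediction
set rather than ε. Because the negative-sampling rules are effective
(planted worlds yield ≈99.9 % clean negatives) and dropped true
interactions are simply absent from training, synthetic worlds contain
almost no unabsorbable violations and the grid search settles at the lower
grid edge of ε — the generative dropout/false-positive rate is *not*
recovered. This is a property of the estimation problem, not of the
optimizer: recovering a generative error rate of 5 % would require ~5 % of
training factors to be in irreconcilable conflict, i.e. an implausibly
contaminated negative set. Accordingly, fitted ε values near the bottom of
the grid should be read as "the training constraints are almost mutually
consistent", not as an estimate of assay error.

## Prediction assembly

* **P1/P2 (interolog transfer).** For a source interaction (a₁, a₂),
  every combination of bridged copies yields a target edge. A source
  self-interaction (a, a) yields all unordered pairs *with replacement*
  among the copies — the homomer in each copy plus cross-copy dimers,
  which is the interolog-consistent reading for duplicated genes. Source
  pairs with an unbridged endpoint are dropped and tallied; duplicate
  target edges union their provenance.
* **P3 (domain-based).** Candidate universe: annotated target pairs
  sharing ≥ 1 cellular-component GO term (exact-term sharing by default;
  a slim-level switch is configuration). A pair is admitted with ≥ 2
  interacting candidate domain pairs, or with ≥ 1 when it is already
  predicted by transfer. The "already transferred" condition is read as
  membership in P1 ∪ P2 (inclusive-or): one supporting domain pair is
  *sufficient* for a pair with independent transfer evidence, while an
  unsupported pair needs two. Self-pairs are admitted on the same terms.
  Supporting domain pairs are recorded per edge.
* **Tiers.** P-all is the union with per-edge evidence labels ⊆
  {P1, P2, P3}; Phc = edges with ≥ 2 labels, Plc = exactly 1. The
  partition Phc ∪ Plc = P-all, Phc ∩ Plc = ∅ is invariant. Only stream
  membership counts toward confidence; the amount of supporting detail
  within a stream does not add weight.
* **Coverage.** Per slim-category genome vs interactome counts and
  ratios, an unmapped bucket for proteins without annotation, the overall
  interactome/genome protein fraction, and the genome annotation fraction.

## Network structure

Self-interactions are counted, then removed; all metrics refer to the
simple graph. Conventions chosen where the standard summaries are
ambiguous: "protein clusters" are connected components with ≥ 2 nodes
(isolated proteins are reported separately, so the two numbers are not
redundant); diameter and mean shortest path are computed within components
(finite for disconnected networks, averaging over all connected ordered
pairs); transitivity is the global clustering coefficient
3·triangles/connected triples; degree centralization is Freeman's index
normalized by (N−1)(N−2); density is reported both for the simple graph
(primary) and with self-loops included in the edge count, since published
interactome tables differ in this convention.

MCL follows the standard procedure: column-stochastic adjacency with unit
self-loops, alternating expansion (matrix squaring) and inflation
(entrywise power, default 2.0, then column renormalization), pruning
entries below 1e−5, to a 1e−8 fixed point; clusters are read from
attractor rows, overlaps resolved to the lowest-indexed attractor so the
output is a true partition.

The domain projection maps a protein sub-network onto the domain pairs
supporting its edges, labelled by evidence origin (known vs inferred) and
with self-interacting domains flagged; protein edges with no supporting
domain pair are omitted and tallied.

## Synthetic worlds

The generator mirrors the model's own generative assumptions, so the
pipeline can be validated against planted truth:

| parameter | default | rationale |
| --- | --- | --- |
| n_source_proteins | 300 | large enough for ~600 interactions and ~50 planted DDIs; small enough that the full grid search runs in seconds |
| n_domains | 120 | each domain recurs in ~3.5 proteins, giving realistic candidate sharing |
| domains_per_protein_mean | 1.4 | matches typical plant proteome Pfam statistics (~1.4 domains/protein); realized as 1 + Poisson(0.4) |
| ddi_density | 0.007 | ≈50 true DDIs among the 7,260 possible domain pairs; yields an interactome density of ~1.4 % of pairs |
| epsilon_true | 0.05 | dropout probability of a true interaction from the observed map |
| false_positive_rate | 0.05 | fraction of the observed map that is spurious |
| copy_number_probs | {1: 0.40, 2: 0.35, 3: 0.25} | triplication followed by substantial fractionation (~1.85 copies/gene) |
| coexpr_interacting_mean/sd | 0.7 / 0.15 | interacting pairs mostly exceed the 0.4 screen |
| coexpr_noninteracting_bound | 0.35 | non-interacting pairs always pass rule iv |
| y2h_fraction | 0.8 | share of observed pairs labelled two-hybrid (the training subset) |
| p_ortholog / p_synteny | 0.7 / 0.5 | most links carry I and/or P evidence; ~15 % are BLAST-only fill-ins |

A protein pair truly interacts iff ≥ 1 of its candidate domain pairs is a
planted DDI (the exact noisy-OR the model assumes); GO terms are assigned
so interacting partners usually share one; co-expression is generated
directly as pairwise r values (only |r| vs the 0.4 threshold is ever
consumed, so an expression matrix would add nothing); the known-DDI
fixture is a random 50 % subset of the truth plus 10 % decoys so that
overlap reporting is exercised. Emission is round-trip faithful: parsing
the emitted MITAB reproduces the observed set exactly, and re-filtering
the emitted BLAST file at 1e−6 with the fill-in rule reproduces the
B-coded links.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: realistic sequence or domain-boundary
content; correlated assay biases (noise is i.i.d.); promiscuous-domain
degree distributions (domain usage is uniform); GO term hierarchies (flat
term sets); expression-matrix structure; lineage-specific target genes
with no source ancestor.

## Known limitations

* ε is weakly identified from consistent training data (see above); the
  fitted value is a consistency measure, not an error-rate estimate.
* On loopy graphs BP beliefs are approximate; the suite checks them to
  within 0.05 of exact marginals on ≥ 90 % of variables for small random
  loopy graphs, which is a regression guard, not a guarantee.
* Interolog transfer cannot down-weight diverged duplicate copies: every
  bridged copy inherits every interaction, which inflates the predicted
  set exactly as multi-copy transfer implies.
* The MCL implementation is dense (O(n³) per iteration) and intended for
  sub-networks of up to a few thousand nodes, not whole interactomes.
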
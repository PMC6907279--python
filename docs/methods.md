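# Methods

`hetpath` implements a network-based compound-repositioning pipeline on
heterogeneous knowledge networks (hetnets): typed nodes (compounds,
diseases, genes, anatomical entities, ...) joined by typed, dated edges
mined from literature-style subject–predicate–object triples. The
learning task is to score drug–disease pairs for treatment likelihood
using path-structure features, and — centrally — to evaluate such models
*time-resolved*: training only on knowledge available at a year Y and
testing on indications approved after Y.

## Network construction

A raw triple table (one subject–predicate–object assertion per row, each
with a supporting publication id) is cleaned by five rules, applied in
this order:

1. **Concept remapping.** Granular identifiers are merged into canonical
   concepts via a user-supplied map; duplicated triples union their
   publication sets, and triples whose subject equals their object after
   mapping are dropped (a self-referential assertion carries no path
   information). Unmapped ids pass through and are counted.
2. **Edge-type condensation.** Predicates of similar meaning are merged
   class-by-class (e.g. PREVENTS between a compound and a disease folds
   into TREATS); classes mapped to `DROP` are removed.
3. **Sparse-type removal.** Edge types carrying strictly less than a
   fraction (default 0.1%) of all edges are removed, with their edges.
   The fraction is computed after condensation; the inequality is strict,
   so a type sitting exactly at the threshold is kept.
4. **Hub removal.** The top-n (default 100) nodes by total incident edge
   count across all edge types are deleted; such nodes are typically
   vacuous general concepts. Ties at the cutoff break by lexicographic
   node id, making the pipeline deterministic.
5. **Support filtering.** Edges backed by fewer than 2 publication ids
   are removed as text-mining noise, and nodes left without edges are
   pruned.

The source prose lists these rules without an explicit order; the order
above is asserted by this package and logged in build reports. Whether
hub removal precedes the support filter is a genuine ambiguity; placing
the support filter last means hub degrees are measured on the fuller
network, which is the more conservative reading of "top nodes by degree".

Undirected edge classes (symmetric predicates between a type and itself,
e.g. compound RELATED_TO compound) are stored once under lexicographic
endpoint ordering. Self-loops are rejected at load time.

## Dating and slicing

Each edge's year is the minimum publication year over its supporting ids,
looked up in a publication-year map. Edges whose ids are all unmappable
are *undated*: they stay in the full network but are excluded from every
time slice, since an assertion that cannot be dated cannot be placed in a
past state of knowledge. A slice at year Y keeps edges dated ≤ Y, then
prunes isolated nodes and empty edge types. Slices are nested by
construction. Dating commutes with edge merging (the minimum over a
unioned publication set equals the minimum of the separate minima), so
years are always recomputed after merges, never cached across them.

Indications (drug–disease positives) are dated by the drug's first
approval year for that indication. Relative to a slice year Y, approvals
≤ Y train and approvals > Y test, with the boundary year inclusive on the
training side; a positive whose drug or disease is absent from the slice
is dropped from both sides and reported. Indications whose TREATS edge
already appears in literature before approval are *not* filtered from the
test side — that mild leakage is part of the evaluation paradigm being
modelled, and the split logic keeps it by default.

## Degree-weighted path counts

Features are metapath-based. A *metapath* is a chain of edge types from
the compound type to the disease type, e.g. `CDrtCDtDO` ("compound
related to a compound that treats the disease"). For a metapath m and a
node pair (s, t), the degree-weighted path count is

    DWPC(s, t; m, w) = Σ_paths Π_edges (d_u · d_v)^(-w)

summed over node-distinct paths conforming to m, where d_u, d_v are the
edge endpoints' degrees with respect to that edge's type and w ≥ 0 is the
damping exponent. w = 0 recovers plain path counts; larger w down-weights
paths through hubs — a compound with thousands of TREATS edges
contributes almost nothing through any individual one. The default
operating point is w = 0.4 with metapaths of length ≤ 3; length 3 keeps
the feature count in the low hundreds on a 30-edge-type schema, which is
where regularized linear models of this kind operate comfortably.

The engine computes all pairs at once by chained products of
degree-weighted sparse adjacency matrices. Matrix products count *walks*;
node-distinct semantics are restored by subtracting the walk
contributions that revisit a node. For length ≤ 3 the correction is
exact and closed-form: revisits can only pair positions of equal node
type, adjacent repeats are impossible (self-loops are rejected), and the
three possible coincidences (positions 0=2, 1=3, 0=3) are handled by
diagonal-restricted products with one inclusion–exclusion term for the
0=2 ∧ 1=3 overlap. Metapaths longer than 3 fall back to the exhaustive
oracle per pair. The oracle — a depth-first enumeration of node-distinct
paths with a path budget — is the governing definition; the matrix
engine is required (and tested) to agree with it elementwise to 1e-10.

Degree-zero nodes get weight zero rather than 0^(-w): a node without
edges of a type can carry no path through that type. Degrees are always
the current network's degrees, recomputed per slice and per perturbation.

### Traversal policy

Directed edge types may be traversed against their arrow inside a
metapath (a backward step is distinct from a forward one); this is what
makes features like `CDloAloCDtDO` — two compounds co-located in an
anatomical structure — expressible, since LOCATION_OF points from anatomy
to compound. The one exception, on by default and overridable, is that
directed edge types running straight from the source type to the target
type (the TREATS relation being predicted) are never traversed in
reverse: such reversed steps re-enter the feature set through the label
relation itself and are excluded from the drug→disease feature set.

### Feature table

Each (drug, disease) pair gets one DWPC column per enumerated metapath
plus degree-count columns: for each edge type touching the drug's or the
disease's node type, the entity's degree at that end (`degree_source_*` /
`degree_target_*`; directed same-type edge types contribute separate
in/out columns). Column order is deterministic.

## Feature transformation

Before fitting, each DWPC column x is mapped to `asinh(x / mean(x))` and
then z-scored; degree columns are asinh-mapped and z-scored. The
mean-scaling puts heavy-tailed DWPC columns on a common scale before the
variance-stabilising asinh. z-scores use the sample standard deviation
(ddof = 1). All parameters (per-column mean, location, scale) are frozen
on the training rows and reused verbatim at prediction time; all-zero or
zero-variance columns map to all-zeros and the degenerate case is
recorded. A plain z-score mode is available as a configuration switch.

## Learning and evaluation

The classifier is an ElasticNet-regularized logistic regression
(scikit-learn, saga solver). Defaults: mixing parameter α = 0.7, a
single frozen inverse regularization strength C = 0.3, damping w = 0.4.
Hyperparameters were tuned once on synthetic studies and then frozen —
held constant across every run, slice, and perturbation. The freeze is
deliberate: supplying a multi-value `c_grid` enables selection by 3-fold
cross-validated log-loss inside the training set, but a data-driven
selector can flip between perturbation conditions, and a flipped
selector contaminates ablation deltas with selection noise. A frozen
strength keeps condition-to-condition metric differences attributable to
the perturbation alone, echoing the once-chosen-then-constant discipline
the method calls for. Class imbalance is handled
by design — negatives are sampled uniformly without replacement from the
non-positive drug–disease pairs at 10:1 — with no reweighting.

Two regimes:

* **Cross-validation**: positives are partitioned by indication into k=5
  folds (repeatable with different seeds). Within each fold the holdout
  positives' TREATS edges are removed from the network *before* feature
  extraction, so the model cannot read a held-out answer off its own
  edge; features are re-extracted per fold. Negatives are partitioned
  alongside.
* **Time-split**: per network year, the model trains on past-approved
  positives plus 80% of the sampled negatives and is evaluated on
  future-approved positives plus the held-out 20%. Negative counts are
  10× the total (past and future) positives. Years with too few training
  positives are skipped; years with no future positives report metrics
  as absent, never zero.

Metrics are AUROC (midrank ties) and AUPRC (average precision). Rank
statistics report, per query drug (or disease), the average-rank position
of its true partners within the full candidate slate.

To pool models across years, each model's probabilities are z-scored over
all pairs it scored (population sd here, ddof = 0, per that module's
convention; models with zero variance are excluded). Positives are binned
by integer offset = approval year − network year in [−20, 20], and each
bin's AUROC/AUPRC is computed against a single 10:1 negative sample drawn
once globally — per-model affine rescaling cannot affect the result by
construction. A centered 5-year rolling mean (shrinking at the edges)
smooths the curve.

## Ablations

*Dropout* removes a uniformly chosen floor(rate% · n) subset of one edge
type (rates 25/50/75/100, five replicate seeds) and retrains.
*Replacement* swaps one edge type's edges for their state in another
year's slice, restricted to endpoints present in the base network — the
node set is held constant so the measured effect isolates the edge
information, not vocabulary growth. The test set and negative samples are
frozen across all conditions of a suite; deltas are reported against the
unperturbed baseline with a 95% CI of mean ± 1.96·sd/√n over replicates.
At 100% dropout the removal set is the whole type, so replicates
coincide and the CI collapses to the point estimate; judgements about
"indistinguishable from zero" therefore use partial rates, where
replicate variance exists. Hyperparameters are never re-tuned per
condition.

The base year of an ablation suite should be one where the model has
genuine future-prediction skill to lose. In the synthetic default study
the supporting paths of an indication appear within 8 years before its
approval, so at early base years most future positives are inherently
unpredictable and deleting even the most informative edge type costs
nothing measurable; the shipped experiments use the year-2000 slice,
where a solid fraction of future approvals fall inside the lead window
and the TREATS deletion effect is unambiguous.

## Synthetic studies

The generator builds a four-type network (160 compounds, 100 diseases,
60 genes, 20 anatomical entities by default) with seven edge types
mirroring the TREATS / RELATED_TO / ASSOCIATED_WITH / INTERACTS_WITH /
LOCATION_OF structure of text-mined biomedical networks. Background
edges are placed uniformly at random per type to hit target mean degrees
(TREATS 2, similarity edges 3, LOCATION_OF 6 per source node). Edge
years over 1950–2015 are drawn with weight ∝ exp(0.04·(year − 1950)), an
exponential arrival model that reproduces the accelerating growth of
real literature-derived networks: cumulative edge counts grow
superlinearly and every type's mean degree rises with the slice year.
Each edge carries 1 + Poisson(1) synthetic publication ids whose minimum
year equals the edge year; 5% of background edges are undated (their ids
are withheld from the year map) to exercise the undated-edge policy.

The gold standard plants 100 positives with approval years uniform over
1960–2015. Signal is planted at the path level: for each positive,
Poisson(3) supporting paths per planted metapath (`CDrtCDtDO` and
`CDtDOawDO`) are constructed by adding the similarity edge and the
neighbouring TREATS edge, dated within the 8 years preceding approval;
the pair's own TREATS edge is added dated at approval. Because supports
cluster shortly before approval, a past network predicts near-future
approvals better than far-future ones — the temporal gradient the
time-split evaluation is designed to expose. With effect size 0 nothing
is planted and positives are uniform random pairs.

Node-set scale matters and was chosen deliberately: planting necessarily
creates decoy pairs (the drug with its decoy disease, the neighbour drug
with the target disease) that are structurally positive-like, and in a
small candidate universe these pollute the sampled negatives enough to
cap measurable AUROC. At the default scale (16,000 candidate pairs) the
decoy fraction among sampled negatives is a few percent, comparable in
spirit to the real setting where candidate universes run to millions of
pairs.

What the generator does *not* emulate: the vocabulary, the extraction
noise spectrum, or the size of real text-mined databases; hub-degree
distributions (background degrees are roughly uniform, not heavy-tailed);
correlated redundancy between edge types. Passing tests therefore show
that the pipeline recovers signal of the planted form under realistic
temporal structure — not that any particular real-world AUROC would be
attained.

## Numerical and policy choices

* Sample sd (ddof=1) in the feature transform; population sd (ddof=0) in
  per-model probability standardization.
* Strict inequality in the sparse-type filter; floor in dropout counts;
  lexicographic tie-breaks wherever an ordering is needed.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2^31. Re-running
  any stage with the same configuration is byte-identical.
* Problem sizes in the shipped tests and in `scripts/acceptance.py`
  (default-scale studies, 3–5 seeds per experiment, 5-year slice grids
  over 1960–2010/2015) are the package's standard desk-scale study
  conditions; they keep each experiment in the seconds-to-minutes range
  while leaving the planted effects well clear of their decision
  thresholds.

## Known limitations

* The node-distinct correction is closed-form only to metapath length 3;
  longer metapaths use the per-pair oracle and are impractical on large
  networks.
* Metapath label parsing requires that an edge token be unambiguous
  between an unordered pair of node types (two opposite-direction edge
  types with the same token between the same types are rejected).
* The replacement ablation never adds donor-only nodes; effects of
  vocabulary growth are out of scope by design.
* No bootstrap confidence bands on the relative-year curve, and no
  plotting — curves export as CSV.
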
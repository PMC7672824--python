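# Methods

## Problem setting

Each protein is to be assigned a set of Gene Ontology (GO) terms with
confidence scores in [0, 1]. GO is a directed acyclic graph in three
independent namespaces (BPO, CCO, MFO); annotation obeys the true-path
rule, so a term implies all of its ancestors. `goknn` processes namespaces
independently and closes every annotation set under the ancestor relation
(following both `is_a` and `part_of` edges, the GO-consortium convention)
before any training or counting. Namespace roots are removed from closed
sets, predictions, and evaluation: predicting a root carries no
information.

## Feature representation

The gapped dipeptide *XdY* is an ordered pair of residue types separated by
exactly *d* positions, 0 ≤ *d* ≤ *l*; the feature space has
20 · (*l* + 1) · 20 dimensions (5600 at the default *l* = 13), laid out as
`index = aa(X)·(l+1)·20 + d·20 + aa(Y)` with amino acids ordered
`ACDEFGHIKLMNPQRSTVWY`.

Rather than counting patterns in the bare sequence, the count is softened
by the protein's PSSM (the n × 20 log-odds profile from iterative homology
search). The exact published form of this transform is not fully specified
by its sources, so the implementation here is an explicit reconstruction,
chosen once and documented:

* each log-odds score *s* is squashed to a per-position residue weight
  σ(s) = 1 / (1 + e^(−s)), so score 0 maps to 0.5 and the transform is
  monotone and overflow-safe;
* the raw value of *XdY* is Σᵢ σ(i, X) · σ(i + d + 1, Y) over all valid
  positions — a product-sum that reduces to the plain sequence pattern
  count when the weight rows are one-hot;
* the vector is normalized to unit sum (a per-protein term frequency).

Nonstandard residues (B, Z, X, U, O, …) keep their row — preserving gap
distances — but contribute zero weight. Proteins shorter than two residues
have no pairs and produce a zero vector with a warning. Sequences lacking a
PSSM fall back to a one-hot profile, i.e. normalized sequence pattern
counts. PSI-BLAST itself is never executed; the parameter string used to
generate compatible profiles externally is shipped as the documented
constant `PSIBLAST_PARAMS`.

## Dimensionality reduction and distance

PCA is fit on training vectors only (full SVD via scikit-learn). The
retained dimensionality is the smallest count whose cumulative
explained-variance ratio reaches the target (default 0.96); this
minimal-count rule is enforced in the module rather than delegated, so an
exact hit on the target counts as reached. Whitening (default on) rescales
each retained component to unit training variance; whitening is applied to
the retained components only. Each component's sign is fixed so its
largest-magnitude entry is positive, making serialized models reproducible
across platforms. Protein similarity everywhere downstream is Euclidean
distance between projected vectors. Upstream sequence-redundancy reduction
is honored by an optional cluster-membership table (one representative kept
per cluster); the clustering itself is out of scope.

## Neighbor selection

* **1NN** — the query inherits its nearest training protein's closed GO
  set, every term at confidence 1.00.
* **Fixed-KNN** — the k nearest training proteins (k chosen by
  cross-validation over 1–10 in the experiment grid).
* **Dynamic-KNN** — a distance threshold is *trained*: for every training
  protein, the distance to its nearest other training protein is recorded,
  and the Q1/Q2/Q3 quartile (linear interpolation between order statistics)
  of that distribution is the selection radius. All training proteins
  strictly closer than the radius vote; a query with none is left
  unpredicted, which is why dynamic mode is naturally evaluated in partial
  mode. The single-nearest-neighbor reading of "each protein's nearest
  neighbors" was adopted; it makes the threshold a pure property of the
  training set.
* **Hybrid-KNN** — dynamic first, fixed-k fallback, so coverage is 100% by
  construction.

Distance ties are broken by ascending protein id for cross-platform
determinism.

## Voting, weighting, propagation

Each selected neighbor votes for every term in its closed annotation set
with one weight: equal (1), inverse (1/d), sqrt-inverse (√(1/d)) — d
clamped below by ε = 1e−9 so exact duplicates stay finite — or FunOverlap.
FunOverlap weights a neighbor by the overlap of its CATH FunFam assignments
with the query's, after discarding assignments with E-value above 1e−5.
"Overlap proportion" is implemented as Jaccard (|∩| / |∪|); an asymmetric
variant (|∩| / |query|) is available behind a flag. A neighbor with no
retained FunFams or zero overlap is excluded from voting entirely, which is
why FunOverlap is restricted to dynamic mode (fixed modes promise k
voters). FunFam assignment itself (HMM scanning) is consumed as a file, not
performed.

Raw votes are then propagated child→parent in reverse-topological order.
Each term's propagated score merges its own direct votes with its direct
children's propagated scores: **Max** takes the maximum, **Sum** adds every
child's propagated score. On diamond-shaped regions the recursive Sum
counts a descendant once per path; a `unique_descendants` switch counts
each voted descendant once instead. The per-path recursion is the default
because it is the direct recursive reading of the merge rule; toy
ontologies that are trees make the two identical. After propagation, root
terms are dropped and scores are divided by the maximum, mapping them into
(0, 1] with the top term at exactly 1. (Dropping roots before normalizing
keeps that guarantee; the root otherwise absorbs the global maximum under
Sum.)

## Baselines

* **Naive** — every query receives the same prediction: each term scored by
  its frequency among closed training annotations.
* **BLAST** — consumes a 12-column tabular hit file; a hit's weight is
  −log₁₀ E (E clamped at 1e−180, non-positive weights discarded), a term's
  score is the best weight among hits whose subject carries it, and scores
  are max-normalized per query. The E-value→confidence mapping is a
  monotone reconstruction; only the hit table's query, subject and E-value
  columns are consulted.

## Evaluation

Protein-centric precision/recall as in the CAFA assessments. Both
prediction and truth sets are ancestor-closed (roots excluded) before
counting; a predicted ancestor inherits its best descendant's score. The
threshold grid is 0.00–1.00 in steps of 0.01 with inclusive thresholding
(score ≥ τ). Precision at τ averages over m(τ), the proteins with at least
one term at or above τ; recall averages over all benchmark proteins (full
mode) or over m(0) (partial mode). Fmax is the maximum harmonic mean over
grid points where both averages are defined. Proteins whose truth closes to
empty are excluded from the benchmark with a warning. Coverage is
|m(0)| / n_full. Five-fold splitting is a seeded shuffle with round-robin
assignment (fold sizes differ by at most one); when a redundancy cluster
table is supplied, whole clusters are placed in one fold (largest first,
into the currently smallest fold — exact size balance is then no longer
guaranteed, by necessity).

## Synthetic benchmarks

The generator emulates the *structure* a real study has: a rooted toy
ontology of configurable depth and branching (with occasional second
parents, so propagation sees true DAGs), protein clusters that share one
coherent annotation set, and PSSMs sampled around a cluster consensus
profile (score +6 at the consensus residue, −3 elsewhere) with Gaussian
noise. Defaults — 40 proteins, 5 clusters, sequences of 40–60 residues,
depth-3 branching-3 ontology, 3 terms per cluster, noise σ = 0.5 — are
small enough for exhaustive oracle checking while leaving neighbor voting
real work to do. At noise 0, cluster members are identical in feature
space, so nearest-neighbor transfer is exact and the pipeline must reach
Fmax = 1; rising noise monotonically degrades transfer. What the generator
does **not** emulate: real PSSM score statistics, the long-tailed term
frequencies and annotation depths of curated corpora, and sequence-level
homology structure — so passing tests demonstrate correctness of the
machinery, not expected accuracy on real proteomes.

## Numerical and interface choices

* Tests and the grid runner use reduced problem sizes (max gap 2, 20–40
  proteins, ≤ 50-term ontologies), keeping every oracle comparison exact
  while the full-scale defaults (l = 13, 5600 dimensions) remain the
  library defaults.
* Ontology parsing accepts the OBO 1.2 subset (id, name, namespace, is_a,
  relationship: part_of, is_obsolete); cycles, dangling parents and
  cross-namespace edges are hard errors, obsolete terms are retained but
  edgeless and excluded from roots.
* Prediction files follow the CAFA submission format, scores clamped to
  [0.01, 1.00] at two decimals.
* All randomness (synthetic generation, fold splitting) flows through
  seeded `numpy` generators; identical seeds give byte-identical artifacts.

## Known limitations

The TFPSSM transform is a documented reconstruction, not a byte-for-byte
reimplementation of its published ancestor. The dynamic threshold uses each
training protein's single nearest neighbor; alternatives (several nearest
neighbors) would shift the quartiles. Whether 1NN should union equidistant
nearest neighbors' annotation sets is resolved by the deterministic
tie-break instead. Term-centric evaluation (per-term AUC) and semantic
distance metrics are not implemented.
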
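# Methods

## The model

`kglit` treats link prediction between drugs and targets (or indications) as
binary classification on learned entity representations. Two token streams
feed one embedding method:

* **Graph walks.** From every node of the directed, edge-labeled knowledge
  graph we start `num_walks` uniform random walks of `walk_length` node
  visits, without restart; a walk that reaches a sink ends early. With edge
  labels on, a walk is emitted as `node relation node relation …`, so
  relations are vocabulary items just like entities, and a skip-gram window
  spans both. Walks only follow outgoing edges; biologically symmetric
  relations (protein–protein `interacts_with`) are materialized in both
  directions at graph-construction time so they are traversable either way.
  Ontology `subclass_of` edges point child → parent only, giving walks
  access to superclasses.
* **Normalized literature.** PubTator-annotated abstracts (offsets 0-based,
  end-exclusive, over `title + " " + abstract`) are tokenized with every
  mapped entity mention replaced by its graph IRI as a single atomic token.
  Overlapping annotations keep the longest span (ties: earliest start).
  Unmapped mentions stay ordinary lowercased words; an identifier map never
  fabricates an IRI. The sentence unit is the whole document.

Because both corpora share IRI tokens, a single skip-gram run on their
shuffled union ("jointly learned embeddings") places graph-only and
text-only entities in one space — this is what handles the zero-shot case
where an entity is absent from one modality. The alternative combination
("concatenated embeddings") trains the two corpora separately and stacks
vectors, zero-filling the block of a missing modality.

**Leakage discipline.** The relation being predicted is removed from the
graph *before* walk generation, so no corpus sentence can contain the
held-out edges; `validate_corpus` provides an exhaustive oracle that every
(node, relation, node) window of a corpus is a graph triple.

## Embedding learners

*Skip-gram with negative sampling* (in-package, numba-compiled): dimension
128, window 10, 5 negatives per positive — the configuration the prediction
results are reported with; epochs 5, `min_count` 1 (so every walked entity
receives a vector), initial learning rate 0.025 decaying linearly to 1e-4.
Contexts use the word2vec reduced-window trick and frequent tokens are
downsampled at threshold 1e-3; negatives are drawn from the unigram^0.75
distribution. Each token is finally represented by the **sum of its input
and output vectors, mean-centered over the vocabulary**: the input–output
cross terms add first-order (direct co-occurrence, ≈PMI) signal to the
second-order shared-context signal, and removing the vocabulary mean strips
the global anisotropy direction that negative sampling induces on small
corpora — without it, cosine similarities on a desk-scale corpus are
dominated by one common component and nearly uninformative, even though
classifiers can still exploit the residual dimensions. Training is a single
seeded stream, so identical inputs give identical vectors.

*TransE*: triple score d(**s**+**p**,**o**) under L1 (default) or L2;
minibatch SGD (batch 64, constant lr 0.01) on the hinge margin loss with
γ = 1, corrupting head or tail (fair coin) with a uniformly random entity,
entity vectors renormalized to unit L2 norm each epoch. The printed form of
the ranking loss omits the positive part; the implementation uses the hinge
max(0, ·), since the raw sum is unbounded below and untrainable. Corruption
is unfiltered during training (original TransE protocol); ranking evaluation
offers a filtered mode that masks other known-true objects.

## Classifiers

Features are the drug vector concatenated with the candidate vector (drug
block first; optional zero-fill for out-of-vocabulary entities under the
union entity pool). Defaults follow the published configuration:

| kind | settings |
| --- | --- |
| `ann` | one hidden layer of 2× input width, ReLU; sigmoid output; cross-entropy; RMSprop (lr 1e-3), 100 epochs, batch 128 |
| `rf` | 50 trees, Gini impurity, min 1 sample per leaf |
| `lr` | L2 penalty, C = 10 |
| `siamese` | one weight-shared dense(d)+ReLU tower per entity, absolute-difference merge, sigmoid head; RMSprop |

The ANN training schedule (epochs/batch) is not part of the published
configuration; the values above are fixed package defaults. The Siamese
encoder depth and merge are likewise open choices; the single-layer
absolute-difference form is the simplest symmetric architecture with a
confidence output. Note a structural caveat: a Siamese network scores
*similarity*, so it can only learn label functions that are symmetric in
the two encodings; logistic regression, conversely, cannot express
interactions between the two blocks at all (it weights coordinates
individually), which is why interaction-style labels favour the ANN/RF.

Negative pairs are sampled uniformly without replacement from
(drug pool × candidate pool) minus the positives, once per experiment,
*before* the 80/20 split — negatives are therefore shared consistently
across classifiers, train/test are disjoint, and classes are balanced 1:1.

## Evaluation

AUROC uses rank concordance with half credit for ties; AUPR is step-wise
precision–recall integration (ties grouped per threshold). *Per-drug
recall* is not precisely defined in the source description; the default
here is the fraction of a drug's held-out positives scoring ≥ 0.5,
macro-averaged over drugs with at least one test positive, with a top-k
alternative (`recall_at_k`) behind a flag. Candidate rankings break score
ties lexicographically by IRI so results are reproducible. Entity pools for
evaluation are set algebra over the graph and text vocabularies (`overlap`
for the head-to-head modality comparison, `union` for the coverage
experiment, with zero-filled features for single-modality entities).

## The synthetic world

The generator plants structure the method is designed to exploit, at desk
scale:

* Every entity carries a latent factor vector (dimension 8, N(0, 1/√k)
  coordinates). Each relation's edges are exactly the top-scoring pairs
  under the factor inner product, at a configured density
  (`round(density · |A|·|B|)` edges). Drug–target and drug–indication
  positives and all side relations derive from the *same* factors, so the
  residual graph (after removing the evaluation relation) still carries
  correlated signal — as real side-effect/association/PPI data does.
  Ontology terms chain to their most similar predecessor, giving HPO/GO-like
  `is_a` hierarchies that keep walks alive past otherwise-sink leaves.
* Abstracts each mention one entity pair plus Zipfian filler (lexicon of
  500 words). A pair is drawn from the planted positives with probability π
  solved so that P(co-mention | linked)/P(co-mention | unlinked) equals
  `co_mention_lift` exactly (default 100, which makes roughly half to
  two-thirds of planted positives co-mentioned at least once in 2,000
  documents — the magnitude observed in real literature corpora).
  `mention_noise` (default 0.05) blanks an annotation's identifier;
  `text_overlap_fraction` (default 0.9) controls how many entities the ID
  map covers, the remainder being graph-only zero-shot entities.
* Presets: `default` (200 drugs, 300 genes, 100 diseases, 80 phenotypes,
  40 classes, 2,000 docs — sized to run end-to-end in minutes on one CPU);
  `complementary` (30% of drugs lose all their non-evaluation graph edges
  and are recoverable only from text, while 30% of entities are absent from
  text and recoverable only from the graph — the configuration where
  combining modalities must beat either alone); `null` (no-signal control:
  positives drawn *uniformly at random* and side relations generated from
  independent factors, with `co_mention_lift` = 1). The null world avoids
  latent-factor positives deliberately: top-inner-product links concentrate
  on hub entities, and a classifier can partially memorize per-entity
  popularity from the training pairs alone, lifting AUROC well above 0.5
  with no usable features; uniform positives make train and test degrees
  independent, so chance level is actually chance.

What the synthetic world does *not* emulate: real biomedical language
(filler words carry no syntax or semantics), multi-species gene ambiguity,
annotation boundary errors, ontology semantics beyond `is_a`, and the scale
and skew of real literature. Passing end-to-end tests therefore shows the
*pipeline* recovers plantable multi-modal signal, not that any particular
real-world AUROC would be attained.

## Numerical and reproducibility choices

* All randomness flows through seeded PCG64 generators (or the seeded
  numba/TransE streams); nodes and vocabularies are iterated in sorted
  order, so every artifact is byte-reproducible for a fixed seed on a
  single thread.
* Degenerate inputs fail loudly: empty corpora, single-class training sets,
  single-entity graphs (TransE corruption impossible), one-class test sets
  (AUROC undefined), exhausted negative-sampling space.
* The null-control evaluation holds out 50% of pairs instead of the
  pipeline's standard 20%: under the null, AUROC's sampling sd at n≈380 is
  ~0.03, too wide to distinguish "chance" from "slight signal"; n≈950
  brings it to ~0.02. Training quality is irrelevant there.
* STITCH/STRING-style score columns can be thresholded at load time
  (`min_score`); the default keeps every row.
* The walk hyperparameter defaults (walk_length 10, num_walks 20) and the
  skip-gram epoch count (5) are package choices exposed in the configs and
  on the CLI.

## Known limitations

* The skip-gram trainer is single-threaded by design (determinism over
  speed); corpora of tens of millions of tokens would need a parallel
  implementation.
* TransE models only one-to-one relations well; many-to-one biomedical
  relations (a drug with many targets) are a known weakness of the
  translation assumption, and no TransH/TransR-style variant is provided.
* PubTator parsing accepts the exchange format only; running NER or entity
  normalizers on raw text is out of scope — the pipeline consumes
  pre-annotated documents.
* Benchmark loaders parse Yamanishi/DrugBank-style interaction lists, but
  the gold-standard files themselves are not redistributed.
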
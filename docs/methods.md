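# Methods

## Problem and model

`ontorel` classifies unordered pairs of entity mentions co-occurring in
one sentence into {negative, mechanism, effect, advice, int}. Two tasks
are scored: *detection* (positive vs negative) and *classification*
(detection plus the correct type). The model is a multi-channel LSTM:
each channel embeds a symbol sequence, runs an LSTM over it, and
max-pools the hidden states over time; pooled channel vectors are
concatenated, passed through a dense sigmoid layer, and a softmax
produces class probabilities.

The channels:

1. **words** — the tokens of the shortest dependency path (SDP) between
   the two entity head tokens, with every entity token on the path
   (candidate or not) replaced by a single generic mask token
   (default `"entity"`), so surface strings of entities never reach the
   model.
2. **wordnet** — one coarse WordNet hypernym class (supersense) per SDP
   token. The inventory is the 26 noun + 15 verb WordNet lexicographer
   classes (41 categories) plus a null class; the mask token and
   punctuation receive the null class, since a masked token carries no
   lexical sense.
3. **concat_ancestors** — Conc(c₁,c₂) = Anc(c₁) ⊕ Anc(c₂), the two
   entities' ontology-ancestor sequences joined end to end.
4. **common_ancestors** — CA(c₁,c₂) = Anc(c₁) ∩ Anc(c₂). Concatenation
   provides a usable representation when two concepts share almost no
   ancestry; common ancestors capture exactly the shared information.

### Ancestor sequence semantics

Ancestry is the transitive closure of the is-a edge relation of an OBO
ontology; all other relationship types (part-of, regulates, ...) are
dropped at load time and the edge set is verified acyclic. Sequences
are ordered most-general-first: ascending by `concept_depth` (length of
the *longest* is-a path from any root; multiple roots are permitted and
no virtual root is added), ties broken lexicographically by concept id,
with the concept itself appended in the final position. For common
ancestors the intersection is taken over ancestor-or-self sets, so the
two concepts themselves participate only when one subsumes the other or
they are equal; in particular CA(c,c) equals the full ancestor sequence
of c. These conventions are checked against a brute-force
transitive-closure oracle (iterated relation composition to fixpoint)
on random DAGs.

### Entity linking

Mentions are linked to concepts by case-insensitive normalised
Levenshtein similarity, `1 − editdist/max(len)`, in [0,1] (edit distance
computed with edlib). The best preferred-label match is accepted at
score ≥ 0.7 (the conventional threshold for this kind of fuzzy lexical
matching); otherwise the best synonym match is used only when it
strictly beats the label score. Ties break toward the smallest concept
id for determinism. Obsolete terms are loaded (so files parse) but are
never linkable. The normalisation by the longer string is one of
several defensible variants; it maps the 0.7 threshold onto a bounded
scale and is fixed here.

### Negative-instance filtering

DDI corpora are heavily imbalanced, so three rules exclude pairs from
training and force a negative prediction at inference: (1) both
mentions have the same text case-insensitively (a drug does not
interact with itself); (2) only punctuation and whitespace separate the
mentions (lists, enumerations, abbreviation introductions) — conjunction
words like "and" are *not* punctuation, by a literal reading of the
rule; (3) both entities' syntactic governors are on the anti-positive
list: head words that governed entity mentions at least `min_count`
times in training (default 3, a floor against noise on small corpora)
and never governed an entity of a positive pair. Both governors must be
anti-positive, reading the rule conjunctively. Filtering is a
partition — nothing is dropped silently — and auto-negatives are scored
as negative predictions (they contribute false negatives when
gold-positive).

### Pluggable parser and tagger

Dependency parsing and supersense tagging are interfaces. The bundled
implementations are deterministic: a chain parser (each token's head is
its predecessor, making the SDP the contiguous span between the
entities) and a fixed-table supersense tagger that assigns unknown
words a stable hash-derived class so every token is covered. Adapters
over an industrial parser/tagger slot in for real-corpus runs; entity
mentions align to the token containing their last character, a
head-final heuristic that is robust to tokenizer drift. Discontinuous
mentions (semicolon-separated offsets) are reduced to their first span
so path extraction stays well-defined.

## Hyperparameters

| parameter | default | notes |
|---|---|---|
| ontology embedding dim | 50 | selected from {50, 100, 150}; 50 performed best in the reference setting |
| WordNet embedding dim | 50 | standard choice for supersense channels |
| word embedding dim | from the vector file | pre-trained vectors, frozen by default to isolate the ontology contribution; trainable by flag |
| LSTM units / dense units | 100 / 100 | typical widths for DDI-scale LSTM systems; the desk-scale experiment uses 32/32 since the synthetic task is far smaller |
| dropout | 0.5 | on embeddings and pooled concatenation; not on the penultimate dense or output layers |
| optimiser | Adam, lr 0.001 | cross-entropy loss, mini-batches (default 64; 32 in the experiment) |
| early stopping | patience 3 | literal stop-on-first-rise is noise-sensitive; best-validation weights restored |
| split | 80/20 | shuffled with the run seed before splitting |
| classes | 5 | detection is derived by collapsing the four positive classes; a 2-class mode exists because detection can also be trained directly |

Ontology and WordNet embeddings are randomly initialised and trained
with the network; the concept vocabulary covers only the concepts
observed in the data (each instance's sequences already include all
ancestors), a small fraction of a full ontology. Index 0 is padding and
fixed to the zero vector; index 1 is a shared unknown symbol. Sequences
longer than the longest training sequence are truncated from the
general (left) end, preserving the most specific concepts and the
entity endpoints. Post-padding plus masked pooling makes the pooled
output exactly invariant to padding length (a tested property).

## Numerical choices

The network is implemented directly in NumPy (float64): standard LSTM
recurrence with forget-gate bias initialised to 1, uniform ±1/√fan-in
dense initialisation, inverted dropout, max-pool backward routed to
argmax positions, and Adam with the usual bias correction. All
gradients are verified against central-difference numeric
differentiation to ~1e-10 absolute error in the test suite. All
randomness (initialisation, shuffles, splits, dropout) derives from one
user-visible seed. Softmax is computed with max-subtraction; the loss
adds 1e-12 inside the log. Degenerate inputs: an empty channel sequence
(e.g. an unlinkable entity) pools to the zero vector; instances whose
entities align with no token are dropped with a logged warning; fewer
than 5 instances cannot be split and raise an error.

## Synthetic data: what it emulates, what it does not

The generator emulates the three real inputs — an OBO ontology, a DDI
XML corpus, pre-trained word vectors — as a pure function of a spec
(identical specs give byte-identical files):

* **Ontology**: a random is-a DAG (default 60 concepts, depth ≤ 4,
  branching ≤ 3) in which ~20% of non-root concepts get a second
  parent, exercising multi-parent ancestry. Labels and 0–2 synonyms are
  unique pronounceable strings of ≥ 6 characters.
* **Corpus**: 2–4 entities per sentence (default 500 sentences ≈ 1700
  candidate pairs); a *marker* concept — the depth ≥ 1 concept with the
  most descendants — defines the label: a pair is positive (type
  *effect*) iff the marker is a common ancestor of the two entity
  concepts. Sampling entities from inside the marker's subtree with
  probability √0.25 yields a realized positive fraction of 0.25 ± 0.05,
  a moderate imbalance (the real DDI corpus is harsher, 1:5.9, and
  reachable via `positive_rate`). Mention surfaces are concept labels
  or synonyms, corrupted by one character edit with probability 0.2 —
  keeping similarity ≥ 0.8, which exercises the 0.7 linking threshold
  without breaking links. Filler text comes from a label-independent
  template vocabulary. An alternative rule keyed to one entity's own
  ancestry (exercising the concatenation channel alone) is available
  via `label_rule="own_ancestor"`.
* **Vectors**: one seeded random unit vector per corpus token, in the
  textual word2vec format.

Because the label is planted in ancestry and masked away from the text,
passing the end-to-end experiment shows that the ontology channels
transmit label-bearing information through linking, sequence
construction, training and inference — and the words-only floor shows
there is no lexical leak. It does **not** show that real DDI labels are
predictable from ChEBI ancestry to any particular accuracy: real
language, real parse trees, annotation noise and the harsher class
imbalance are all outside what the generator emulates. The experiment
uses 500 train / 200 test sentences and five repetitions with distinct
ontologies and corpora; these sizes give stable medians while keeping
the whole suite fast on one CPU.

## Design decisions where the design was open

* One 5-class model with detection-by-collapse as the primary
  realization (plus an optional binary mode), keeping the two reported
  tasks consistent by construction.
* A wrong-type positive is counted as FP for the predicted type and FN
  for the gold type, micro-averaged over the four positive types — the
  SemEval Task 9.2 convention.
* Candidate pairs are unordered; SDP direction is fixed text-order
  (earlier entity first) because sequence models need a convention.
* The prediction TSV (doc, sentence, e1, e2, flag, type) feeds this
  package's own scorer, which is the authoritative evaluator here.
* Gene annotation for phenotype–gene corpora uses case-sensitive,
  word-boundary exact matching (gene symbols are case-meaningful), and
  labels positives "int" — an interaction of unspecified type — so the
  label set stays closed.

## Known limitations

* Only is-a semantics; no information-content weighting or semantic
  similarity measures over the ancestry.
* The bundled chain parser is a deterministic stand-in: its SDPs are
  simply the spans between entities. Conclusions about real syntactic
  paths require an adapted parser.
* No BioC/brat/PubTator formats and no entity recognition; entities
  are assumed annotated.
* Training is CPU-bound NumPy; it is sized for corpora of thousands of
  instances, not for large-scale pre-training.
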
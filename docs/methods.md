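# Methods

## Problem and model

Given a compound and M transporter classes with known substrate sets
𝕊₁ … 𝕊_M, the package predicts the subset of classes whose transporters
accept the compound.  Two independence assumptions shape the design:

1. **Similarity carries the signal.**  A compound is represented only by
   its *maximum* similarity to each class's known substrates — a 2·M
   vector [α₁…α_M, β₁…β_M].  Nothing else about the molecule enters the
   model, so the method inherits the usual similar-property-principle
   caveats (activity cliffs, novel scaffolds).
2. **Label structure is low-order.**  Correlations between transporter
   classes are exploited through communities of the label co-occurrence
   graph; interactions beyond co-occurrence (e.g. three-way exclusions)
   are not modelled.

### Structural features

α_i = max over members of 𝕊ᵢ of the mean Tanimoto coefficient
TC = c/(a+b−c) over the available fingerprint types.  Fingerprints are
opaque fixed-length bit-vectors; the canonical set is MACCS, FP2, FP3,
FP4 as emitted by Open Babel, supplied precomputed (the package never
reimplements the hashing schemes).  Conventions:

* two all-zero fingerprints share no substructure evidence: TC := 0,
  with a warning;
* a compound missing a requested fingerprint type is a hard error — the
  four-type average is part of the method, silent skipping would change
  its meaning;
* during training and evaluation the query is removed from its own
  classes before the max (`exclude_self=True`), otherwise membership
  leaks a trivial α = 1 for every true class.  Both behaviours exist
  because the original protocol is ambiguous on this point; the
  leakage-guarded one is the default, plain encoding is available for
  pure inference.

### Semantic features

β_i = max over members of 𝕊ᵢ of the Lin similarity between
chemical-ontology terms, 2·IC(MICA)/(IC(c₁)+IC(c₂)), with MICA the
most informative common ancestor in the is_a DAG.  Information content
is GO-style: annotation counts propagate to all ancestors,
p(c) = count(c)/count(root-of-c), IC = −log p in nats.  Choices:

* **IC corpus** — by default the training compounds' own annotations
  (recomputed per training split to avoid leakage); a user IC table
  overrides.
* **Log base** — irrelevant to Lin (the ratio cancels); the
  base-invariance is enforced to 1e−12 in tests.  The cap for terms
  unseen in the corpus is max observed IC + 1 nat, with the increment
  converted to the chosen base so the table still scales uniformly.
* **Relations** — is_a only by default.  ChEBI's three subontologies
  have disjoint roots, so cross-subontology pairs correctly score 0.
* **Unannotated compounds** — contribute 0 to the max, and an
  unannotated query gets a zero semantic block rather than being
  dropped: the structural block still informs, and feature
  dimensionality stays fixed.
* Obsolete terms are dropped at parse time; alt_id aliases resolve to
  their primary term.

### Classifier

Training: (1) build the label co-occurrence graph on the training
labels — nodes are labels, edge weight the number of compounds carrying
both (weighted by default; unweighted available); (2) detect
communities — greedy modularity maximisation (deterministic) or
asynchronous label propagation run as 5 seeded restarts keeping the
most frequent partition; isolated labels become singletons; (3) per
community, restrict the label matrix to its columns and fit one
label-powerset unit: every distinct observed restriction (including the
all-zero one — compounds negative for a whole community must be
representable) becomes one multiclass class; (4) the base learner is
pluggable behind a scikit-learn-style contract — random forest
(200 trees) is the default engine, extremely randomized trees, RBF SVM
and 1-NN adapters ship with the package.  Prediction is the union of
decoded labelsets; per-label scores for AUROC are the maximum over
communities of the summed probabilities of classes containing the
label.  RAkELd is the same machinery over a seeded random disjoint
partition with subset sizes differing by at most one.

## Label-association analytics

Pairwise association uses Bergsma's bias-corrected Cramér's V
(φ̃² = max(0, φ² − (r−1)(c−1)/(n−1)), normalised by corrected
dimensions); the plain sample V is also provided.  The correlation
matrix sets the diagonal to 1 by convention and reports 0 (with a
warning) for constant labels, keeping heatmaps finite.  Labelset
intersection tallies (UpSet-style counts) and pairwise co-membership
matrices are exported as delimited text.

## Evaluation

* **Multi-label metrics** (per-sample means): aiming |𝕃∩𝕃*|/|𝕃*|,
  coverage |𝕃∩𝕃*|/|𝕃|, accuracy |𝕃∩𝕃*|/|𝕃∪𝕃*|, absolute true
  1[𝕃=𝕃*], Hamming loss |𝕃⊝𝕃*|/M.  An empty predicted set contributes
  0 to aiming and accuracy (0/0 := 0).  The per-sample Hamming term is
  normalised by the label count M — the standard definition; a
  `hamming_raw` switch reports the raw symmetric-difference count
  instead.
* **Binary metrics** per label from confusion counts, with
  CCR = (sensitivity+specificity)/2 and zero denominators reported as 0
  with a warning; AUROC by the trapezoidal rule (equals the tied-pair
  probability P(s⁺>s⁻)+½P(=); undefined for single-class truth → NaN).
* **Iterative stratification**: greedy rarest-label-first fold
  assignment — repeatedly take the label with the fewest remaining
  samples, place each of its samples into the fold with the largest
  remaining desired count for that label (ties: larger remaining fold
  budget, then a seeded random draw), decrement the chosen fold's
  budgets for the sample's labels; label-free samples fill the largest
  remaining budgets at the end.  On single-label data this is exact
  (per-fold positives deviate from n·rⱼ by at most 1).
* **Protocols**: jackknife (leave-one-out; the held-out compound is
  excluded both from the class subsets used in feature encoding and
  from the IC corpus — a conservative anti-leakage stance) and repeated
  stratified k-fold CV (per-fold re-encoding on the training split
  only; per-label metrics averaged over folds × repeats; AUROC skipped
  with a warning for folds whose truth is single-class).

## Synthetic benchmark generator

`synthdata` emulates the statistical structure of the real
transporter-substrate benchmark so every claim is testable offline:

* **Labels** — 13 transporter names with marginal prevalences equal to
  the published class sizes over the 1,846 unique benchmark compounds
  (MDR1 ≈ 0.49 down to SO2B1 ≈ 0.02; 1.24 labels per compound on
  average) at n = 200 by default (a CI-friendly scale; the statistics,
  not the size, are what the generator reproduces).  One label pair —
  ABCG2/MDR1, the co-transport pair the field documents — carries an
  odds ratio of 10; all other labels are latently independent.
  Every compound carries at least one label.  Because conditioning on
  "≥1 label" at these imbalanced margins necessarily induces pairwise
  exclusivity (a factorial-moment argument shows no distribution with
  these margins, no empty rows and all-pairs independence exists),
  empty draws are *rescued* with a singleton label drawn from the
  unpaired labels in proportion to prevalence, and base rates are
  fixed-point-shrunk so observed marginals match their targets; the
  correlated pair is never rescued, so its observed margins and odds
  ratio are exactly the configured ones.  The residual systematic
  exclusivity among unpaired prevalent labels (corrected V up to
  ≈ 0.25) mirrors the real data, where 86% of compounds are substrates
  of exactly one transporter.
* **Fingerprints** — four types at realistic lengths (MACCS 166,
  FP2 1024, FP3 64, FP4 512) and type-specific background densities;
  each label owns a block of positions drawn at elevated density
  d + effect·(1−d) for carriers (effect 0.3 by default), so
  within-class Tanimoto exceeds between-class — the planted signal.
* **Ontology** — a random single-rooted DAG (each later term attaches
  to 1–2 earlier terms) serialised as OBO text that round-trips through
  the parser; each label owns a "home" term and compounds are annotated
  to a home term of one of their labels with probability 0.8, else to a
  random term (annotation noise 0.2, a plausible curation error rate).
* All randomness flows from a single `SynthConfig.seed` through spawned
  child generators; identical configs give identical datasets.

What the generator does **not** emulate: real chemistry (SMILES are
placeholders), fingerprint bit correlations within a molecule, the deep
and uneven topology of real ChEBI, or scaffold clustering.  Passing
tests therefore demonstrate correctness of the machinery and
recoverability of a planted signal — not prospective accuracy on real
substrates.

## Numerical choices and degenerate inputs

* 0/0 conventions: Tanimoto of two empty fingerprints → 0; empty class
  subset after self-exclusion → feature 0 with warning; empty predicted
  labelset → aiming/accuracy terms 0; association of a constant label
  → 0; corrected Cramér's V with m̃ ≤ 0 → 0.
* Community-detection ties: greedy modularity follows networkx's
  deterministic agglomeration; label propagation uses seeded restarts
  with a canonical-order tie-break, so identical seeds give identical
  partitions and models.
* Learner seeds are derived per community from the model seed
  (`seed + 1000003·(k+1) mod 2³¹−1`).
* Model archives are version-tagged; loading a foreign or
  newer-versioned file fails loudly.

## Evaluating against the external benchmark

The published benchmark (2,293 virtual / 1,846 unique substrates over
13 transporters) and a real ChEBI release are not redistributed here,
but the workflow accepts them directly:

1. export the benchmark as `compounds.csv` (`id,smiles,ontology_term`
   with curated ChEBI ids) and `labels.csv` (0/1 matrix);
2. generate fingerprints with Open Babel, e.g.
   `obabel compounds.smi -ofpt -xfFP2` per type, hex-encoded into
   `fingerprints.csv` (`compound_id,fp_type,hex_bits,n_bits`);
3. download `chebi.obo` and run
   `substrate-nlsp evaluate --protocol jackknife …`.

The report mirrors the package's CV layout (five multi-label metrics
plus the per-label table).  Agreement with previously published numbers
should be *reported*, not asserted: it depends on the ChEBI release,
the fingerprint software version and the unstated self-exclusion and
corpus conventions of the original protocol.

## Known limitations

* Maximum-similarity features discard all but one neighbour per class;
  extremely small classes make α/β noisy.
* Communities are detected once per training run; no consensus across
  resamples.
* The label-powerset codebook cannot emit labelsets never seen in
  training (inherent to LP; the community partition mitigates but does
  not remove this).
* Jackknife with the default random forest retrains n models; use the
  CV protocol for datasets beyond a few hundred compounds.
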
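# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Ontologies and closures

Ontologies are consumed as OBO flat files; only the `id`, `name`,
`synonym` and `is_a` tags are read. Synonyms of every scope
(EXACT/BROAD/NARROW/RELATED) enter the matching lexicon, since narrower or
related synonyms are exactly the strings authors use in abstracts.
Obsolete classes and non-`is_a` relationships are ignored. Closures are
computed over the asserted `is_a` DAG only: the package expects
pre-reasoned ontology files (integrated cross-species phenotype ontologies
already materialize their inferred subsumptions), and performs no
description-logic reasoning itself. Multiple phenotype ontologies are
merged by identifier into one DAG with one root per input; no
cross-ontology axioms are invented.

Two closures drive everything: the subclass closure defines the matching
lexicon *Terms(C)* (labels and synonyms of a class and all its
descendants), and the superclass closure *Cl(X)* extends annotation sets
with all ancestors so that profiles annotated at different levels of
detail remain comparable.

## Text matching and counting

Documents are title + abstract. Normalization tokenizes on alphanumeric
runs, lower-cases, and removes a fixed 33-word English stop list (the
classic Lucene/Snowball list, frozen in `diseasome.corpus.STOP_WORDS`).
No stemming is applied — a standard analyzer does not stem, and stemming
pseudo-medical vocabulary creates more false matches than it recovers.
A class matches a document when any term phrase occurs contiguously in
the normalized title or abstract; phrases may not span the title/abstract
junction. All counts are counts of distinct documents, never mentions.
The corpus is first restricted to documents that match at least one term
of any ontology, and *n*<sub>tot</sub> is the size of this filtered corpus.
Pairs that never co-occur are omitted from the association table rather
than scored: every collocation score is undefined at *n*<sub>DP</sub> = 0.

## Collocation scores

The four measures (NPMI, T-score, Z-score, LMI) use the standard forms
from the collocation-measures literature, with natural logarithms
throughout; NPMI is base-invariant and the LMI scale is thereby fixed to
nats. All four are zero at exact independence and share the sign of
*n*<sub>DP</sub>*n*<sub>tot</sub> − *n*<sub>D</sub>*n*<sub>P</sub>. NPMI is
clamped to [−1, 1] to absorb float roundoff at the perfect-co-occurrence
endpoint. NPMI is the primary ranking score; ties are broken by phenotype
identifier ascending so profiles are reproducible regardless of input
order.

## Rank cutoff

A disease's profile is its top-*n* phenotypes by NPMI. Using a rank
rather than a score threshold gives every retained disease the same
profile size, which matters because simGIC is sensitive to profile
cardinality. The exclusion rule is implemented as "fewer than *n*
strictly positive-NPMI associations → excluded entirely", i.e. ranks are
0-based and the association at rank *n*−1 must be positive; zero NPMI
counts as non-positive. Profiles at smaller *n* are therefore always
subsets of profiles at larger *n* for diseases surviving both.

`select_optimal_cutoff` evaluates each candidate *n* by building profiles,
computing simGIC against model profiles (IC over the union of disease and
model profiles), pooling all (model, disease) pairs into one ROC against
the known positives, and taking the argmax (ties prefer the smaller *n*).
Candidates where no positive pair is retrievable are reported with an
undefined AUC and skipped. At toy scale the candidate list should not
extend far beyond the expected profile size: the exclusion rule shrinks
the surviving-disease set with *n*, and once only a handful of diseases
remain the pooled AUC is computed over a pool too small and too selected
to be comparable with smaller cutoffs. The bundled analyses therefore
evaluate candidates 1..15 (three times the planted signature size); the
pipeline default for full-scale corpora is 1..50.

## Information content and simGIC

IC(x) = −ln p(x), where p(x) is the fraction of entities in the annotation
corpus whose superclass-closed profile contains x. The annotation corpus
is exactly the profile collection passed to `information_content` — by
convention the diseases and models under analysis together — and is a
pipeline-level configuration rather than a hidden global. Classes
annotated to every entity (any shared root) get IC 0 and carry no signal;
classes never annotated are absent from the map and contribute 0 to both
simGIC sums, which is equivalent to excluding them (−ln 0 is undefined).
simGIC returns 0 when the union IC sum is 0, and 1 for identical closures
containing at least one informative class.

## Evaluation

ROC AUC is computed in Mann–Whitney form (average ranks; ties count ½),
which equals the trapezoidal area under the tied ROC curve. All scored
pairs not listed as positives are treated as negatives; since the positive
lists are never exhaustive in practice, reported AUCs are lower bounds.
The standard-error estimate is σ = √(AUC(1−AUC)/min(m, n)) with m
positives and n negatives — a conservative simplification of the binormal
variance — and AUC ± 2σ serves as an approximate 95% interval.
Per-query retrieval evaluations (category coherence, self-retrieval,
model retrieval) pool all query–target pairs into a single micro-averaged
ROC; queries never score themselves, and queries without positives are
skipped rather than diluting the pool. Disease self-retrieval is phrased
as pair scoring with (d, d) as the positive pair, so the identity pair is
retained there by construction.

## Network construction

The edge threshold is the value at the `top_fraction` quantile of **all**
N² matrix entries — including the diagonal self-similarities and both
symmetric copies of each off-diagonal value. The full-square convention
matters only for the threshold's position; edges themselves are undirected
and deduplicated. Entries exactly equal to the threshold are kept, so the
retained fraction can slightly exceed `top_fraction` under ties.
Self-loops are removed after thresholding, then degree-0 nodes (removal
cannot cascade: dropping an isolated node changes no other degree). At
the default 0.5% the quantile only clears the unit diagonal when
N > 1/0.005 = 200; smaller analyses (including the synthetic reference
bundle) must raise `top_fraction` accordingly, and the acceptance run uses
10% at N ≈ 25.

## FLAME clustering

FLAME is implemented from its published description: distance
1 − similarity; k nearest neighbors (default k = 10, capped at N − 1);
density = 1 / mean distance to neighbors; cluster-supporting objects are
local density maxima over their neighborhood, outliers are local minima
below a density threshold (default: mean density − 2 standard deviations);
memberships of all remaining objects are iteratively replaced by weighted
averages of their neighbors' memberships until the largest change falls
below 10⁻⁶ or 500 sweeps. Neighbor weights are proportional to
(farthest-neighbor distance − distance), falling back to uniform when a
neighborhood is equidistant. Every ordering — neighbor selection under
distance ties, density ties in CSO election — is broken by object
identifier ascending, making the algorithm a pure function of the matrix.
The algorithm is treated as parameter-free in the sense that these
defaults are fixed and documented, not exposed as tuned knobs.

Purity takes the majority category of a cluster as the category contained
in the most members' category sets (ties by category name) and reports
the containment fraction; the average is the unweighted arithmetic mean
over clusters, so multi-category diseases count for whichever category
wins. For the Rand index a hard partition is required; diseases with
multiple top-level categories are excluded by default
(`categories_to_partition(..., multi_label="exclude")`), with
first-category projection available as an alternative.

## Synthetic data: what it emulates, and what it does not

The generator emulates, at desk scale, the structure of the real inputs:

- **Ontologies** — rooted DAGs with unique two-word pseudo-word labels and
  optional synonyms; disease and phenotype lexicons carry distinct marker
  letters so no label collides across ontologies. Real label ambiguity
  (shared strings between disease and phenotype vocabularies) is
  deliberately out of scope.
- **Corpus** — each signal document co-mentions a disease and one of its
  planted signature phenotypes; with probability 0.5 it also mentions one
  of the disease's two ring-neighbor "confusion partners", emulating
  comorbidity and differential-diagnosis co-mentions. Noise documents
  mention random diseases and phenotypes independently. One guaranteed
  document per planted pair is emitted first so every planted association
  is attested. Signatures mimic disease families: each disease shares one
  *cardinal* phenotype with each ring neighbor, mentioned 3× more often
  than its three distinctive phenotypes. This structure is what gives the
  cutoff-selection curve its realistic shape — too-short profiles keep
  only the ambiguous cardinal phenotypes, too-long profiles absorb partner
  signatures.
- **Annotations** — positive model profiles copy a disease's signature
  with each class replaced at `corruption_rate` by a random phenotype;
  negative models are random sets. 80% of the 60 models are positives,
  cycled over the diseases. Replacements are drawn outside the signature,
  so the corruption rate exactly controls the realized overlap with the
  truth; at full corruption positive models are therefore disjoint from
  their signature and retrieve slightly below chance (≈ 0.44 rather than
  0.5), which is the expected behavior of this calibration-control design.

Reference conditions (the generator defaults): 20 diseases, signature
size 5, 140 phenotype classes, 2,000 documents, 60 model profiles,
corruption 0.2, all drawn from keyed sub-streams of one seed so that,
e.g., enlarging the corpus does not perturb the annotations.

Passing tests on these bundles shows that the pipeline's machinery is
correct and that its selection and retrieval behavior responds to planted
signal as designed. It does not show performance on real literature:
real abstracts have negation, abbreviation, morphological variation and
label ambiguity that the generator intentionally omits, and real
ontologies are far deeper and more unbalanced. Cutoff recovery is exact
to ±1 on most seeds but the AUC-vs-n curve is flat enough near its peak
that individual seeds can place the argmax 2–3 ranks beyond the planted
size.

## Numerical and degenerate-input conventions

- Natural logarithms everywhere (scores and IC).
- NPMI clamped to [−1, 1]; scores undefined at n<sub>DP</sub> = 0
  (error), NPMI undefined when a pair co-occurs in every document (error).
- Empty filtered corpus is an error; empty term sets are warnings at the
  caller's discretion.
- simGIC 0/0 → 0; ROC with zero positives or zero negatives → error.
- The FLAME membership iteration is a convex combination, so membership
  vectors remain distributions at every step.
- All tie-breaks (NPMI ranks, KNN selection, CSO election, purity
  majorities) are by identifier or name ascending.

## Known limitations

- Phrase matching is exact on normalized tokens; no stemming, spelling
  variation, abbreviation expansion, or negation handling.
- Sentence-level co-occurrence is not modeled; the counting unit is the
  document.
- The IC corpus conflates diseases and models by design (matching the
  analysis definition); alternative IC corpora must be passed explicitly.
- The σ estimator ignores score correlation between pairs sharing a
  disease or model; intervals are approximate.
- FLAME is O(N²) in memory and the membership iteration is pure Python;
  the implementation targets matrices up to a few thousand objects, not
  millions.
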
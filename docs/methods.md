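# Methods

## The model

The toolkit treats a multi-herb medicine as a four-layer tree: the
formula (layer 1) is a set of crude drugs (layer 2), each crude drug a
set of constituent compounds (layer 3), and each compound maps to
target proteins (layer 4). Layer 4 is populated from two sources: a
curated compound–protein interactome, and similarity-based predictions
(TESS). Identifiers are opaque strings throughout; nothing is resolved
against external services, so the whole pipeline runs offline and
deterministically.

### Compound representation and similarity

Compounds are sparse nonnegative frequency vectors over substructure
features. The canonical similarity is the generalized Jaccard
(Ruzicka) coefficient J(x, y) = Σ min(xᵢ, yᵢ) / Σ max(xᵢ, yᵢ), which
reduces to the set Jaccard index on binary vectors, is symmetric,
bounded in [0, 1], equal to 1 exactly for proportional support-equal
count patterns (and for identical vectors), and invariant to scaling
both vectors by the same positive constant. Two empty vectors compare
as 0 with a warning rather than NaN: this keeps every ranking total.

The feature scheme is deliberately pluggable. Any sparse counted
substructure vocabulary can be supplied as a precomputed fingerprint
table (`compound_id, feature_id, count`); scores are
descriptor-dependent, the pipeline is not. For SMILES input a default
featurizer produces unhashed Morgan count fingerprints (radius 2),
which are deterministic and counted, matching the contract the rest of
the pipeline assumes. 3D and docking-based descriptors are out of
scope.

### Interactome filtering

A curated interaction record is retained iff it is explicitly flagged
active or its affinity is strictly below 30 μM (30 000 nM; 1 μM =
1000 nM). Records with neither affinity nor flag are dropped and
counted in a log message. Duplicate (compound, protein) pairs are
collapsed keeping the record with the lowest affinity — the strongest
evidence, and the conservative choice for a strict upper-bound filter;
an active flag breaks ties. The threshold is a parameter
(`threshold_nM`, default 30 000) so other activity conventions can be
studied.

### TESS scoring

For each interactome protein k with known ligand set L_k, the query's
prediction score is max over c ∈ L_k of J(q, c), with the argmax
recorded as the best reference ligand (ties broken by smallest
compound ID, making output deterministic). No score cutoff is imposed
by default (`min_score = 0`, full ranking exposed, `top_n` optional):
the method's natural output is a ranked list, and any cutoff is a
presentation choice. The matrix path vectorizes the per-query
computation over CSR-stacked reference fingerprints using
Σ max = Σx + Σy − Σ min over the shared support; a scalar double loop
over proteins × ligands serves as the independent oracle in tests.

### Aggregation to crude drugs and formulas

Entity-level predictions are the union over constituent compounds;
per protein the retained score is the maximum across contributing
compounds. Max is the default because it preserves the single best
piece of evidence and matches the max-over-ligands convention of the
scorer itself; `mean` and `count` are exposed as alternatives, and the
full (compound, score) contribution list is kept on every aggregated
row so any other aggregation is recomputable from the output.

### Enrichment

For query target set G_comp, namespace term G_path, background
universe of size l, k = |G_path|, r = |G_comp| and z = |G_comp ∩
G_path|, the p-value is the hypergeometric tail P(X ≥ z). For l ≤
2000 the sum is evaluated in exact big-integer arithmetic (one final
float division, hence correctly rounded and free of cancellation); for
larger universes scipy's log-space survival function takes over. The
enrichment ratio is z / k. q-values are Benjamini–Hochberg within each
namespace (the standard reading of "FDR-corrected").

Term sets are intersected with the background universe before testing
— the hypergeometric model requires G_path ⊆ universe — and the
reported k is the restricted size; terms left empty are excluded and
logged. The default background is the protein set of the filtered
interactome (union the query's own targets); an explicit universe file
can be supplied instead. Whether the ratio denominator should count a
term's proteins inside or outside the background is a genuine
convention choice; the restricted k is used because it is the quantity
the test itself sees, and both are recomputable since z, k, r are all
reported.

### Indication prediction

Each target protein of the query (known and predicted together) is
looked up in the disease → therapeutic-target map. A link scores 1
when the protein is a known target of the query and the TESS score
otherwise; diseases are ranked by maximum link score with ties broken
by disease ID. Max is chosen for consistency with the scorer, and the
complete link table is emitted so sum- or count-based disease scores
can be derived losslessly. Prediction is compound-level; a
medicine-level roll-up is available through the aggregation module but
should be treated as exploratory. Proteins absent from the disease map
contribute nothing, by construction.

## The synthetic-data generator

The generator emulates the features of real chemogenomic data that the
method's validity rests on, and only those:

* **Ligand families.** Each family owns a disjoint block of core
  features with a fixed count profile; a member expresses each core
  feature with probability `family_feature_overlap` (default 0.8) and
  adds `n_noise_features` (default 6) private noise features. Chemical
  similarity is therefore informative of family membership.
* **Family-coherent targets.** Each protein is assigned a family and
  draws `interactions_per_protein` (default 8) ligands, 85% from its
  family. A held-out ligand's family mates thus point back to its true
  targets — the property leave-one-out evaluation measures.
* **Affinities straddling the filter.** Log-uniform over
  [1 nM, 1 mM], so both sides of the 30 μM boundary are always
  populated; a small fraction of records carry only an active flag.
* **Medicines.** Each crude drug samples its compounds from one
  family (a herb's chemistry is coherent); formulas combine three
  crude drugs, so a formula's known-target set is structured the way
  the enrichment stage assumes.
* **Planted enrichment.** Per namespace, one randomly positioned term
  receives `planted_term_effect · |G_comp|` members of the designated
  query formula's known-target set (default effect 0.8); all other
  terms, and the disease map, are uniform draws.

Defaults — 150 proteins, 400 compounds, 600 features, 12 families, 4
formulas of 3 crude drugs × 5 compounds, 25 terms per namespace with
sizes uniform on [5, 40], 25 diseases — are sized like a small curated
chemogenomic study: large enough that the formula target set (r ≈
15–30 proteins) gives the hypergeometric test a reasonably fine null
support, small enough that the full benchmark suite runs in seconds.
The generator uses only integer draws and elementwise float transforms
of numpy's PCG64 streams (separate streams per stage), so identical
seed and config give byte-identical files on any platform.

What it does **not** emulate: real descriptor statistics (true
substructure counts are heavy-tailed and correlated), assay noise and
database inconsistencies, promiscuous ligands, correlated pathway
membership, or realistic disease–target sparsity. Passing tests
therefore demonstrate that the algorithms are implemented correctly
and recover structure that is present; they say nothing about
predictive accuracy on any particular real interactome or descriptor
set.

## Numerical and statistical choices

* **Exact tail probabilities.** The hypergeometric tail is exact
  integer arithmetic up to l = 2000 and is certified against an
  exhaustive subset-enumeration oracle for every (l, k, r, z) with
  l ≤ 12, and against scipy's survival function at larger sizes.
* **Discreteness and null calibration.** The tail p-value of a
  discrete statistic is *super-uniform* under the null — P(p ≤ t) ≤ t,
  with atoms — not Uniform(0, 1). A two-sided KS test of the raw
  p-values against the uniform therefore rejects even an exact
  implementation whenever the atoms are coarse. The calibration
  checks consequently test two properties: (i) the randomized
  transform p_rand = P(X > z) + U · P(X = z), which is exactly
  Uniform(0, 1) for a valid test, passes a two-sided KS check; and
  (ii) the raw p-values never exceed the uniform CDF beyond the
  one-sided KS bound (validity). Together these are strictly stronger
  evidence of correctness than a raw-p KS check, without being
  confounded by discreteness.
* **Determinism.** Every ordering is lexicographic with explicit
  tie-breaks (score desc, then protein/term/disease ID asc); floats
  are written with a fixed `%.10g` format; config echoes carry no
  timestamps. Repeated runs are byte-identical, which the test suite
  asserts end to end through the CLI.
* **Degenerate inputs.** Empty compound sets union to the empty set;
  empty query target sets yield empty (header-only) reports with a
  warning and exit code 0; empty-support fingerprints rank with
  similarity 0 after a warning. Genuine integrity problems (dangling
  IDs, missing fingerprints, malformed lines) raise typed errors that
  the CLI maps to exit code 3 (usage errors are 2).

## Benchmark problem sizes

The acceptance studies run at the generator defaults: leave-one-out
over 25 held-out compounds per study across 10 study replicates
(chance-level median rank 75); planted-term recovery and null
calibration over 100 replicates each. The whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Scores are only as good as the fingerprints; the bundled Morgan
  featurizer is a stand-in interface, and users with a preferred
  counted-substructure scheme should supply precomputed vectors.
* Max-aggregation makes an entity look as good as its best compound;
  for formulas with many inert constituents the `count`/`mean` views
  give a complementary picture.
* Enrichment treats targets as a set: protein activity, pathway
  topology and expression context are ignored, so broad formulas
  enrich many terms — specificity requires orthogonal data.
* The indication stage can only rediscover diseases already present in
  the disease–target map, and a predicted target whose similarity is
  1 (an exact fingerprint duplicate of a known ligand) is scored like
  a known one even though `via_known` stays false.
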
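# tesspred

Ligand-based target prediction and mode-of-action analysis for
multi-component medicines (herbal formulas, crude drugs, and their
constituent compounds).

Traditional multi-herb formulas act through many constituent compounds
hitting many proteins at once. This package implements the complete
computational workflow for studying that polypharmacology offline:

1. **Target prediction by similarity search (TESS).** A query compound
   with sparse substructure-count fingerprint *q* is scored against
   every protein *k* of a curated compound–protein interactome with
   known ligand set *L\_k*:

   *score(q, k) = max\_{c ∈ L\_k} J(q, c)*,  where
   *J(x, y) = Σᵢ min(xᵢ, yᵢ) / Σᵢ max(xᵢ, yᵢ)*

   is the generalized Jaccard (Ruzicka) similarity on frequency
   vectors (the set Jaccard index on 0/1 vectors). The similarity of
   the nearest known ligand is used directly as the prediction score;
   known ligands score 1 by self-similarity. The interactome is first
   filtered to records flagged active or with binding affinity
   strictly below 30 μM.

2. **Hierarchical aggregation.** Per-compound predictions are grouped
   up a four-layer hierarchy — formula → crude drug → constituent
   compound → target protein — retaining, per protein, the best score
   across contributing compounds with full provenance.

3. **Functional enrichment.** A query entity's target set *G\_comp* is
   tested against four annotation namespaces (pathway, brite, process,
   function). With background size *l*, term size *k = |G\_path|*,
   *r = |G\_comp|* and intersection *z*, the hypergeometric tail

   *p = Σ\_{i=z}^{min(k,r)} C(k, i) C(l−k, r−i) / C(l, r)*

   is computed exactly, the enrichment ratio is *z / k*, and p-values
   are corrected per namespace by Benjamini–Hochberg.

4. **Indication prediction by target matching.** Each (known or
   predicted) target is looked up in a disease → therapeutic-target
   map; a compound–disease link scores 1 via a known target and the
   TESS score via a predicted one, and diseases are ranked by their
   best link.

A seeded synthetic-data generator produces full input bundles with the
statistical structure the method assumes (ligand families, planted
enriched terms, a disease map), so every stage is testable with no
external databases. All inputs and outputs are plain TSV/GMT/JSON.

## Worked example

```bash
tesspred simulate --seed 7 --out bundle
# wrote bundle for query formula F001 (17 known targets) to bundle

tesspred predict-targets --query C00007 \
    --interactome bundle/interactome.tsv \
    --fingerprints bundle/fingerprints.tsv --top-n 5 --out preds.tsv
head -6 preds.tsv
# compound_id  protein_id  score         is_known  best_reference
# C00007       P0026       1             1         C00007
# C00007       P0062       1             1         C00007
# C00007       P0066       1             1         C00007
# C00007       P0133       0.6285714286  0         C00384
# C00007       P0004       0.6164383562  0         C00231
```

Compound C00007 is a known ligand of three proteins (score 1,
`is_known=1`) and is newly linked to P0133 because its nearest known
ligand there, C00384, has Ruzicka similarity 0.63. Matching these
targets against the disease map and enriching the formula's target set:

```bash
tesspred predict-indications --targets preds.tsv \
    --disease-map bundle/diseases.tsv --out ind
head -3 ind/indications.tsv
# disease_id  disease_name  best_score  n_links
# DIS005      disease 5     1           1
# DIS008      disease 8     1           2

tesspred enrich --query F001 \
    --formulas bundle/formulas.tsv --crude-drugs bundle/crude_drugs.tsv \
    --interactome bundle/interactome.tsv \
    --gmt pathway=bundle/pathway.gmt --out enr
head -2 enr/enrichment_pathway.tsv
# term_id   term_name        enrichment_ratio  p_value         q_value         z   k   r
# PWY0019   pathway term 19  0.4               5.505148647e-08 1.376287162e-06 14  35  17
```

The top pathway term covers 14 of the formula's 17 known targets
(enrichment ratio 14/35 = 0.4, p ≈ 5.5 × 10⁻⁸) — it is exactly the
term the generator planted (`bundle/truth.json`). Diseases DIS005 and
DIS008 rank first with score 1 because they share a *known* target
with the query compound.

Other subcommands: `similarity` (pairwise compound similarities),
`aggregate` (compound → crude drug/formula grouping), `hierarchy`
(JSON export of the four-layer tree). The same functionality is
available as a library (`import tesspred`).

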
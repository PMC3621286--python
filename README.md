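# wildmeat

Species authentication for game-meat market surveys from mitochondrial
barcodes (cytochrome *b* and COI), built for the food-forensics question
*"is the species in this product the species on the label?"*

Commercial game products — biltong, droë wors (dried sausage), carpaccio,
mince — are sold under labels like kudu, springbok or gemsbok, but the label
is often wrong. Given a curated, aligned reference set of candidate species
and sequenced market samples, `wildmeat` assigns a species to every
sequenced dissection by three independent lines of evidence and scores each
sample's label against the DNA:

1. **Similarity** — percent identity against every reference over shared
   unambiguous sites (a desk-scale BLAST-style best hit, flagged *perfect*
   at 100% and *strong* above 97%);
2. **Phylogeny** — the query must fall in a monophyletic cluster with its
   candidate species, with bootstrap support, on a neighbor-joining or
   maximum-likelihood tree under the Kimura 2-parameter (K80) model with
   nearest-neighbor-interchange search;
3. **Diagnostic characters** — species-specific residue states (single
   columns or conjunctions) learned from the references; an IUPAC ambiguity
   at a diagnostic site yields the forensic *non-excluded* outcome rather
   than an exclusion.

A call is *validated* only when all three tracks concur. Samples are scored
*correct* when every dissection and marker matches the label species and
*false* otherwise; two species across the dissections of a sausage flag a
mixture. Verdicts aggregate into per-product-type and per-label
substitution tables.

The reference set itself is screened for a usable **barcoding gap**: the
maximum within-species K2P distance

$$d = -\tfrac12\ln(1 - 2P - Q) - \tfrac14\ln(1 - 2Q)$$

(*P*, *Q* the transition and transversion proportions) is compared per
species with the net between-groups distance to its sister species,
$d_{net} = \bar d_{AB} - (\bar d_A + \bar d_B)/2$, with bootstrap standard
errors from column resampling, against the published screening thresholds
(within < 1.5, between > 2.5 on the ×100 scale, the 3% rule and the
10-fold rule).

A forward simulator generates reference databases and mislabeled markets
under the same K80 process — with within-species phylogeographic clusters,
358-bp cytb-like and 650-bp COI-like fragments, configurable substitution
and mixture rates, and IUPAC ambiguity injection — so the entire pipeline is
testable without any sequence download.

## Worked example

```python
from wildmeat import PipelineConfig, run_pipeline
from wildmeat.synthetic_data import SimConfig, simulate_market, simulate_reference_db

cfg = SimConfig(n_species=5, n_samples=40, p_sub=0.5, p_mix=0.5, seed=23)
db, species_tree, pops = simulate_reference_db(cfg)
samples, sequences, truth = simulate_market(cfg, db, pops, seed=23)

result = run_pipeline(db, samples, sequences,
                      PipelineConfig(tree_mode="shared", bootstrap_B=50))
t = result.table_by_product
print(t.table[["product_type", "N", "n_false", "pct"]])
print(f"overall {t.overall_pct}%")
```

prints

```
    product_type   N  n_false     pct
0        biltong  22       12   54.55
1      carpaccio   1        1  100.00
2    dry_sausage  11        7   63.64
3  fresh_sausage   1        1  100.00
4    mince_fresh   2        1   50.00
5         smoked   3        1   33.33
overall 57.5%
```

— 23 of 40 simulated samples carry a species other than their label (the
generator drew substitutions at rate 0.5 plus sausage mixtures), and the
pipeline's 23 false verdicts recover exactly the generator's truth table on
this seed. Each row is one product type with its sample count, false-label
count and substitution percentage.

The same pipeline runs from the shell on FASTA + manifest inputs:

```sh
authenticate simulate --out demo --n-species 4 --n-samples 12 --seed 3
authenticate run --refs cytb=demo/refs_cytb.fasta --refs COI=demo/refs_COI.fasta \
    --queries demo/queries_cytb.fasta --queries demo/queries_COI.fasta \
    --manifest demo/manifest.tsv --out demo/out
```

producing `assignments.tsv`, `verdicts.tsv`, `table1.tsv` (by product),
`table2.tsv` (by label), `gap_report.tsv` and `trees/*.nwk`.

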
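# adrmine

Statistically validated **protein target ↔ adverse drug reaction (ADR)**
association mining.

Unexpected adverse reactions are a leading cause of attrition in drug
development, and most resources linking drugs to ADRs are drug-centric.
If drug X causes ADR Y and binds protein Z, the naive inference "Z causes
Y" is wrong in general: drugs bind sets of pharmacologically similar
proteins (members of the same family), so every family member would
inherit every ADR of every shared drug.  `adrmine` implements the
association pipeline that controls this confounding: it curates drug–ADR
evidence, filters drug–target evidence, collapses protein redundancy and
family promiscuity, and only then tests each (protein, ADR) pair for
enrichment across the shared drug universe.

## The statistic

For each protein *t* and preferred term *a*, over the universe of *N*
unified drugs with evidence on both sides, the 2×2 contingency counts are

|              | has ADR *a* | no ADR *a* |
|--------------|-------------|------------|
| binds *t*    | *n₁₁*       | *n₁₀*      |
| doesn't bind | *n₀₁*       | *n₀₀*      |

and the one-sided Fisher exact p-value is the hypergeometric upper tail
P(X ≥ n₁₁) given the margins, computed in log space.  P-values are
corrected to Storey q-values (π̂₀ by a cubic smoother on the λ grid
0.05…0.95; Benjamini–Hochberg fallback for small test counts) within each
evidence set — *self-reporting* (spontaneous-report style) and *curated*
(label/literature style) evidence are never pooled.  An association is
accepted at q ≤ 0.05.

Upstream of the test:

- **Spontaneous-report curation** — drug-name normalization against a
  synonym table, demographic-key deduplication, and a per-drug
  multinomial likelihood-ratio disproportionality screen
  (llr = n·ln(n/E) + (n₋−n)·ln((n₋−n)/(n₋−E)), one-sided, judged against
  a Monte-Carlo null of the per-drug maximum); only signals present in
  **both** self-reporting sources survive.
- **ADR filtering** — preferred terms under unspecific system organ
  classes (Investigations, Product issues, …) and listed psychiatric
  high-level terms are removed.
- **Drug unification** — by full InChIKey, else by standard name gated on
  2D Tanimoto ≥ 0.7 (2048-bit Morgan fingerprints, radius 2); drugs with
  fewer than 10 ADRs are discarded.
- **Target filtering** — potency IC50/EC50 ≤ 100 nM or interaction
  confidence ≥ 0.8; drug-metabolism proteins (GO:0042737, GO:0017144)
  removed; greedy identity clustering collapses redundancy at 90% and
  forms families at 70%; a drug binding > 10 members of one family keeps
  only the centroid; non-main family members are kept only when sharing
  ≥ 50% of the main target's drugs.

Because the real source databases are licensed or versioned, the package
ships a first-class synthetic generator (`adrmine.synthetic`) that
emulates all six evidence sources with planted causal (target, ADR)
links and exact per-stage bookkeeping, so the whole pipeline is testable
offline.

## Worked example

Generate the default synthetic ecosystem (300 drugs, 60 targets in 12
families, 120 preferred terms, 20 000 + 10 000 spontaneous reports, 15
planted causal links) and run the pipeline:

```bash
adrmine generate --out fixture
adrmine run --input-dir fixture --out results --evidence-set both --seed 42
adrmine query results/associations_curated.tsv --by uniprot --term T00A
```

The run manifest records every stage (input, output, removed counts),
e.g. for the curated branch:

```
target_main_prune             800 -> 466
curated_soc_filter          11325 -> 8074
curated_pairs_to_unified     8074 -> 7699
curated_sparse_drug_filter   7699 -> 7409
curated_association          7409 -> 543
```

and `associations_curated.tsv` is sorted by q-value, most significant
first:

```
uniprot_id  gene_name  pt_code  pt_name                       p_value      q_value      significant
T00A        GN00A      P0107    skin reaction 75              1.47793e-13  8.02515e-11  1
T06A        GN06A      P0060    vascular reaction 28          4.21729e-12  1.14499e-09  1
T00A        GN00A      P0098    gastrointestinal reaction 66  6.72755e-12  1.21769e-09  1
```

All three rows are planted causal links recovered at q ≪ 0.05; columns
a–d carry the contingency cells and `supporting_drugs` the drugs in cell
a.  On this ecosystem the pipeline recovers 15/15 planted links in both
evidence sets with a realized false-discovery proportion ≤ 0.07.

## Layout

- `src/adrmine/datamodel.py` — domain types and strict-keyed config
- `src/adrmine/ingest.py` — TSV/FASTA interchange readers and writers
- `src/adrmine/pharmacovigilance.py` — curation + LRT screen
- `src/adrmine/adr_filter.py` — SOC-based term exclusion
- `src/adrmine/drug_unify.py` — InChIKey/name/Tanimoto unification
- `src/adrmine/target_filter.py` — potency, GO, clustering, family rules
- `src/adrmine/association.py` — contingency tables, Fisher, q-values
- `src/adrmine/synthetic.py` — ground-truthed synthetic ecosystem
- `src/adrmine/pipeline.py`, `cli.py` — workflow wiring and CLI
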
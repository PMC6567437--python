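# metexpand

Extend genome-scale metabolic models with reactions arising from
**enzyme promiscuity** ("underground metabolism"), validated against
metabolomics data.

Most enzymes catalyse transformations beyond their annotated primary
reaction, but genome-scale models such as *E. coli* iML1515 record only
the annotated ones. `metexpand` closes part of that gap for
metabolic-engineering and systems-biology users: it learns local
biotransformation rules from the reactions an organism already encodes,
applies them to the organism's own metabolites to enumerate putative
promiscuous products, keeps the products that a metabolomics database
says actually occur in the organism, and curates each surviving
prediction into an atom-balanced, evidence-classified reaction that can
be added to the model.

## Method

**1. Rule extraction (RDM decomposition).** For each model reaction with
a KEGG reaction id, the main reactant–product pair (the non-cofactor
pair sharing the largest common substructure) is atom-mapped and its
structural change decomposed into

* **R** — the reaction-centre atom, present on both sides,
* **D** — the difference region: first-shell atoms removed, added or
  rebonded at R,
* **M** — the matched region: first-shell atoms preserved at R,

with all atoms labelled by a radius-1 KEGG-style atom-type scheme
(`metexpand/data/atom_types.tsv`). Each single-centre pair becomes a
lookup-table **operator**: key = (R, M, D) in the substrate, value =
(R, D) in the product, plus an explicit local graph edit. Reversible
reactions contribute both directions; multi-centre pairs (e.g.
transketolase-like chemistry) are skipped.

**2. Derivatization and metabolome matching.** Operators are applied at
every matching site of every metabolite in the high-concentration
substrate pool (strictly above 1 µM by default). Predicted products are
compared with a metabolomics table (ECMDB-style) whose record identities
are first reconciled by **majority vote** over the primary ids retrieved
through each cross-reference (InChIKey, KEGG, CAS, ChEBI, BioCyc) plus
the declared id; records without a strict majority are excluded.

**3. Curation and classification.** Verified predictions pass discard
filters (infeasible, cofactor substrate, multi-centre), are completed
into stoichiometric reactions by copying the template reaction's
cofactor couple (e.g. NADPH/NADP⁺, ATP/ADP), checked for per-element
balance, and classified by a decision tree:

| Category | Evidence |
|----------|----------|
| C1 | same transformation already in the model under a **different enzyme** (parallel route) |
| C2 | absent from the model but documented for the organism (KEGG/EcoCyc) |
| C3 | documented only in other organisms |
| C4 | not catalogued anywhere |

## Worked example

The package bundles a curated benchmark of 23 promiscuous-reaction
predictions for *E. coli* iML1515, each with its cofactor couple,
formula table and database-membership evidence. Classifying it:

```bash
metexpand classify --benchmark --outdir out/
```

prints

```
{"C1": 4, "C2": 10, "C3": 5, "C4": 4}
```

— four parallel routes (e.g. cytosine + PRPP ⇌ CMP + diphosphate via
orotate phosphoribosyltransferase, EC 2.4.2.10, parallel to the model's
EC 3.2.2.10 route), ten reactions known for *E. coli* but missing from
iML1515, five known only in other organisms, and four uncatalogued. All
23 completed equations pass the heavy-atom balance check
(`balanced_reactions: 23` in `out/summary.json`).

The full pipeline can be exercised end-to-end on a synthetic universe
with planted promiscuous products:

```bash
metexpand make-fixture --seed 7 --outdir fix/
metexpand run --model fix/model.json --structures fix/structures.tsv \
  --concentrations fix/concentrations.tsv --metabolome fix/metabolome.tsv \
  --xrefs fix/xrefs.tsv --known fix/known_compounds.tsv \
  --reference fix/reference_index.json --cofactors fix/cofactor_ids.txt \
  --outdir out/
```

which reports (seed 7):

```
"operators_entries": 30,   30 directed rules from 15 reversible reactions
"derivatives": 397,        putative products over the 28-metabolite pool
"matched": 45,             confirmed by the synthetic metabolome
"kept": 45,                all pass the discard filters
"categories": {"C1": 7, "C2": 14, "C3": 10, "C4": 14},
"balanced_reactions": 45   every recommended reaction balances
```

Every planted promiscuous product is recovered with its intended
category (this is asserted by the test suite across seeds), and the
counts obey the stage conservation law
`derivatives = matched + unmatched`, `kept = ΣC1..C4`.

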
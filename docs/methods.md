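# Methods

This note documents the models, conventions and numerical choices behind
`metexpand`, and what the test suite does and does not demonstrate.

## Chemical representation

Molecules are constitutional graphs with implicit hydrogens and explicit
bond orders (single/double/triple/aromatic). Stereochemistry is ignored
everywhere — identity keys, matching and rule application — because the
biotransformation rules operate on constitution and first-shell bonding
only; d/l pairs therefore collapse to one key, which is the desired
behaviour for rule transfer and database matching. Kekulé input is
normalised to aromatic bond orders on parse, explicit hydrogens are
collapsed, and RDKit's sanitiser is the single authority for valence
validity and hydrogen counts. The canonical identity key is canonical
SMILES of the (stereo-free) graph, so it is invariant under atom
reordering; this is property-tested with 100 random renumberings per
panel molecule.

## Atom typing

Atoms carry a radius-1 environment code: a pure function of element,
formal charge (suffix `+`/`-`), aromatic flag, implicit hydrogen count
and the multiset of (bond order, neighbour element) pairs. The ~45-code
vocabulary lives in `src/metexpand/data/atom_types.tsv` and is
deliberately coarse — it must separate environments that react
differently (carbonyl vs carbinol carbon, phosphate vs phosphine
phosphorus, hydroxyl vs ether vs carboxylate oxygen) while staying a
strictly local function, so that a modification beyond the first shell
never retypes an atom (tested). Fidelity to any external atom-type table
is a non-goal; rule keys only need consistent, discriminating labels.

## Atom mapping

The reactant–product mapping maximises mapped atoms and localises the
change. Candidate mappings are seeded from two maximum-common-
substructure searches (RDKit FMCS): one comparing elements, one
comparing atom types (encoded as isotopes). Exact bond-order comparison
is used so aromatic never matches aliphatic. Each seed is extended
greedily over unmapped neighbours that agree on element and connecting
bond order, and candidates are ranked by: most mapped atoms, fewest
connected change components, most atom-type-exact pairs, lexicographic
pairing. The second criterion matters: a single maximum common subgraph
can embed a near-symmetric backbone in a flipped orientation that
scatters one chemical change into two spurious reaction centres; ranking
by change-component count selects the chemically parsimonious mapping.
Ties are broken deterministically via RDKit canonical atom ranks, so
mapping — and everything downstream — is reproducible for a given input.

## RDM decomposition and operators

The mapped change is grouped into connected components (lost atoms,
gained atoms, rebonded pairs). For each component the reaction centre R
is the mapped atom that (a) can anchor the entire edit in its first
shell and (b) has the most preserved neighbours (ties by canonical
rank). A component that cannot be anchored at a single atom — e.g. a
bond formed between two previously distant mapped atoms — is not
representable as a first-shell rule and is skipped with a logged reason.
A pair with more than one component is multi-centre and generates no
operator, mirroring the scope restriction to single-centre promiscuity;
multi-centre chemistry (transketolase-like) is explicit future work.

An operator stores the (R, M, D) key, the (R, D′) value, and an explicit
graph edit: bond-order changes on selected neighbours, deletable
fragments (matched by anchored subgraph isomorphism and required to be
severable — no bonds escaping the match except to R), and attachable
fragments. Application rebuilds hydrogens from default valences and
rejects valence-violating products. The defining invariant, tested
exhaustively over generated universes (≥150 operators), is the round
trip: every operator applied to its originating substrate at the
originating site regenerates the originating product's canonical key.

Main-pair selection uses a configurable cofactor list
(`data/cofactors.tsv`: nicotinamide and flavin couples, adenosine
phosphates, CoA, THF, phosphate/diphosphate, water, proton, CO2, O2,
ammonia); the non-cofactor substrate/product pair with the largest
mapped substructure is the main pair, one per reaction. Reactions are
treated as reversible unless their flux bounds say otherwise, and a
reversible reaction contributes operators in both directions. Exact
duplicate operators from different reactions are merged with
multi-provenance; the pre-merge entry count is also reported, since the
per-reaction entry count is what a lookup-table census naturally counts.

## Substrate pool and matching

The substrate pool is the structure-bearing metabolites with
concentration **strictly above** the threshold (default 1 µM — the
working assumption is that high-concentration metabolites are the most
likely to meet promiscuous enzymes at catalytically relevant rates);
metabolites absent from the table form the remainder pool, available via
a flag. Application is single-step: derivatives are never re-fed as
substrates. Products regenerating a provenance reaction's own pair are
flagged self-transformations and excluded from new-prediction reports.

Metabolomics records are reconciled before matching: each resolvable
cross-reference (InChIKey, KEGG, CAS, ChEBI, BioCyc) retrieves a primary
id from an offline lookup table, the declared primary id casts one vote,
and a **strict majority** (> half of cast votes) decides; ties and empty
vote sets leave the record unresolved and excluded. Strict majority is
the conservative reading of a majority vote — a tie is a genuine
ambiguity, not a coin flip. The implementation is checked against an
exhaustive brute-force vote counter over all splits of up to five votes.
Matching then compares derivative known-compound ids with reconciled
primary ids, with canonical-structure-key equality as a fallback when
the record carries a structure.

## Curation and the decision tree

Discard filters run in a fixed order — infeasible, cofactor substrate,
multi-centre — so reason codes are stable; the chemical-feasibility
judgment is an input flag (default feasible) because human review is out
of scope but its position in the pipeline must be preserved.

Cofactor completion copies the template (native) reaction's
co-substrates and co-products — everything except the native main pair —
onto the candidate pair, oriented by operator direction. Balance is
per-element, product side minus substrate side; a reaction is balanced
iff every **heavy-atom** delta is zero. Hydrogen and charge deltas are
reported separately because protonation conventions differ across
sources; an opt-in tolerance may absorb a consistent H/charge residual
with protons (logged), but the heavy-atom criterion never relaxes.

The decision tree tests, in order:

1. **Transformation in the model?** The unordered (substrate key,
   product key) pair is looked up in the model reaction set. Same
   enzyme → discard (already present); different enzyme → **C1**.
   The root deliberately tests the *transformation*, not the product
   metabolite: a product can be a long-standing model metabolite while
   the route to it is still missing (guanine → GMP is the canonical
   case in the bundled benchmark), and such routes are curation gaps
   (C2), not parallel routes.
2. **Curator-asserted parallel route?** A candidate may carry a
   documented parallel route by a different enzyme that is not a model
   reaction (the benchmark's bicarbonate → carboxyphosphate entry,
   parallel to the carbamoyl-phosphate-synthase partial reaction). If
   present and the enzyme differs → **C1**.
3. Pair documented for the organism (KEGG/EcoCyc emulation) → **C2**.
4. Pair documented in other organisms → **C3**.
5. Otherwise → **C4**.

Enzyme identity compares gene sets and falls back to EC numbers when
either side lacks gene annotations. Reference lookups are
direction-agnostic, consistent with default reversibility. New-to-model
metabolites are the distinct C2–C4 products absent from the model
metabolite set; the count is computed, never asserted (for the bundled
benchmark it is 18 — the benchmark encodes only GMP among C2–C4
products as already in the model, the one case the source evidence
pins down).

Summary counts are per candidate — one (substrate, product, enzyme
attribution) each — so one transformation attributed to several enzymes
counts once per attribution; this matches how the benchmark itself
counts its 23 entries (the bicarbonate → carboxyphosphate pair appears
under both C1 and C2 with different evidence).

## Synthetic universes

The generator builds molecules from a scaffold grammar — carbon chains
of length 3–6 (up to 8 after mutation) decorated with hydroxyl, amino,
keto, carboxyl and terminal-phosphate groups — so that every native
reaction is a single-centre edit from four archetypes: alcohol
oxidation (toy NAD couple), terminal phosphorylation (toy ATP couple),
terminal decarboxylation (CO2) and reductive amination (NH3/water/NAD
couple). All archetype couples are heavy-atom- and hydrogen-exact, so
every curated toy reaction balances by construction.

Defaults are 14 base scaffolds, 10 native reversible reactions, and a
promiscuity rate of 2 planted products per native reaction (20 planted)
in an equal C1–C4 mix — enough reactions for ≥50 operators over five
seeds and enough planted products for per-category counts of five,
while a full five-seed end-to-end run stays under a few seconds.

Planting constructs, for a chosen native reaction, a novel substrate
whose radius-2 decoration window around the reaction site equals the
native substrate's (mutations — chain extension, far-position
decoration — only beyond radius 2). Because operator keys see at most
radius-2 information (R's type is radius 1; M/D neighbour types reach
radius 2), the extracted operator is guaranteed to apply at the planted
site, making 100% recall a well-defined target: any miss is a pipeline
defect. The generator also validates unambiguity by grammar-level
enumeration of every archetype application over every model metabolite:
a planted product reachable from any unintended substrate is rejected
and resampled, so planted labels are consistent with the generated
reference index. C1 is realised by adding a parallel native reaction
with a different gene; C2/C3 by inserting the pair into the
organism/other-organism reference sets. All randomness flows through one
`random.Random(seed)`; two generations under one seed are byte-identical
when serialised.

What the toy universes do **not** emulate: ring chemistry and
aromaticity changes, multi-centre transformations, stereochemistry,
realistic cofactor structures, measurement noise or ambiguous metabolite
identities beyond the planted inconsistent-vote records. Passing the
planted-recovery test therefore demonstrates the pipeline's internal
correctness (rule extraction, site matching, editing, matching,
classification), not predictive accuracy on real chemistry; the
transcribed 23-reaction benchmark covers the curation logic on real
reactions, and real-model runs depend on the quality of the supplied
structures and reference tables.

## Numerical and degenerate-input choices

* FMCS timeout 20 s per pair, substructure matches capped (200 per
  side, 40×40 seed combinations) — far above what desk-scale molecules
  need, bounded for pathological inputs.
* No common substructure at all degrades to a single best-element atom
  pair; no common atom yields an empty mapping and no pattern.
* Identical substrate/product pairs produce no operator; reactions
  without a KEGG id, without a structured non-cofactor pair, or with
  multi-centre main pairs are skipped with logged, machine-readable
  reasons.
* Operator application that disconnects the molecule keeps the
  reaction-centre component (the detached part is a leaving group).
* All reports are sorted (category, EC, substrate, product) and contain
  no timestamps, so repeat runs are byte-identical; this is asserted in
  the acceptance suite.

## Known limitations

* Single reaction centre only; operators never span two centres.
* Radius-1 keys generalise aggressively: one rule can fire on many
  sites, so specificity relies on the metabolome-matching step, as in
  the underlying workflow.
* The offline cross-reference table stands in for live compound-database
  queries; its coverage bounds what reconciliation can resolve.
* Cofactor completion copies the template couple verbatim; it cannot
  invent a couple for an enzyme whose template is unavailable (such
  reactions are emitted uncompleted and flagged).
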
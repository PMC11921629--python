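# Methods

## Scope and model

`xenomet` implements rule-based metabolite prediction: biochemical
reactions from genome-scale metabolic models (GEMs) are generalized into
graded reaction patterns and applied forward to query molecules. The model
assumes single-step biotransformations — no pathway cascades, no transport
or stereochemical conversion (which do not change atom connectivity and
therefore cannot be expressed as connectivity-rewriting rules), and no
quantitative rates. Predictions are hypotheses ranked by a structural
confidence score, not kinetic statements.

## Molecular conventions

All molecules are stored as stereo-free, Kekulé, canonical SMILES with
implicit hydrogens; identity means equality of canonical (aromatic) SMILES
keys. Sanitization keeps the largest organic fragment (ties: prefer a
carbon-containing fragment, then the smallest canonical SMILES), replaces
dummy/R-group atoms with carbon, removes stereochemistry, and neutralizes
charges through the RDKit standardizer's uncharger, which leaves
charge-separated groups (nitro, N-oxide) and permanently charged centers
(quaternary ammonium) intact; a retained net charge is flagged, not an
error. Kekulization failure rejects the molecule with a reason rather than
silently keeping aromatic flags. "Atom counts" always mean heavy atoms;
formulas include hydrogens.

Structure deduplication uses these canonical keys directly: any injective
canonical key gives the same equivalence classes, so no separate string
encoding is needed.

## Reaction intake and filtering

The TSV schema is the reference format; model JSON and SBML (via cobrapy,
with metabolite SMILES in notes) map onto the same records. Classification
is structural where possible: transport (subsuming passive diffusion) is
identical canonical-key multisets on both sides with differing compartment
tags; stereo-only is identical multisets in the same compartments from
differing raw structures; exchange is an empty side or boundary flag;
biomass is recognized by its id/subsystem designation because biomass
pseudo-metabolites carry no structures.

Balance is checked per element as Σ(stoichiometry × count). Two modes:

* `slack` (default): hydrogen and net-charge deltas are ignored when all
  heavier elements balance. GEM exports routinely omit protons; tying the
  tolerance to an explicit proton stoichiometry would discard exactly the
  records that omit it, so the simpler rule is used.
* `strict`: every element must balance exactly. The packaged fixtures pass
  strict mode, including hydrogen accounting via explicit reductants
  (formate-driven nitro and azo reduction).

Reversible reactions are expanded into two directed copies before rule
generation because rules are directional.

## Atom mapping

Input atom maps are the recommended path and are validated: unique indices
per side, every substrate heavy atom mapped, elements agreeing across each
map pair. Reactions of ≥ 1200 heavy atoms are skipped with a reason.
Unmapped reactions fall back to a greedy maximum-common-substructure
assignment (element comparison, any-bond comparison, fragments paired by
descending match size with canonical-SMILES tie-breaks). This fallback is
deliberately simple and deterministic; it is adequate for small molecules
with distinctive fragments but weaker than learned mappers on symmetric or
repetitive structures, which is why pre-mapped input is preferred.

## SRR decomposition and reaction centers

A single-reactant reaction (SRR) pairs one distinct substrate (stoichiometric
copies collapse) with every product inheriting ≥ 1 of its atoms; the main
product maximizes inherited-atom count, with ties broken by heavy-atom
count then canonical key. A substrate whose atoms reach no product is a
mapping defect and an error.

An atom belongs to the reaction center iff its formal charge, aromaticity,
ring membership, hydrogen count, or bonded-neighbor multiset (neighbors
identified by map index, bonds by order; non-substrate atoms pooled as
"external") differs between substrate and product context. An empty center
(identity transformation) is an error.

## Rule generation

Context grows in bond-radius shells around the center — shells give a
canonical nesting, and the realized atom count is recorded per rule for
downstream granularity analysis. When a shell would overshoot the 40-atom
cap, it is filled partially in canonical-rank order so the largest rule
holds exactly min(40, all) atoms. Query-side atoms are serialized with
element, aromatic/aliphatic, ring/not-ring, degree, and formal-charge
primitives; degree counts all heavy neighbors in the full substrate, so
ring bonds cut at the context boundary survive as degree constraints.
Transform-side atoms are written with explicit hydrogen counts and explicit
charges (including `+0`) because the pattern engine otherwise inherits both
from the matched query atom — the charge default would, for example, leak
nitro-group charges into reduction products. Atoms contributed by
cosubstrates appear as unmapped template atoms; excluded substrate atoms
are carried over unchanged by the engine at application time.

Every rule is applied back to its own source substrate at generation time;
a rule that fails to reproduce its source main product is dropped and
logged. Duplicate rules (same pattern, substrate, and product) are stored
once with merged annotations — this also merges chemically identical
half-reactions shared between different reactions (e.g. the formate → CO₂
side of two different reductions), which is intended. Rule databases are
sorted before writing, so repeated runs are byte-identical.

## Prediction and scoring

Each distinct embedding of a rule's query side yields one application;
symmetric sites therefore give distinct products, and outcomes collapse
only when both the main-product key and the matched-atom set coincide.
Invalid products (valence violations after the transform) are dropped with
a log entry. Confidence is the sum of three components in [0, 1]:
query↔source-substrate Tanimoto, prediction↔source-product Tanimoto (both
over 2048-bit path fingerprints, 1–7 bond paths, binary), and atom
efficiency = matched atoms / query heavy atoms. The published wording of
atom efficiency varies; the matched-over-total-query-atoms form is
implemented because it is the one consistent with a [0, 1] component and a
maximum total of 3. Defaults: reporting cutoff 0.6, high-confidence
threshold 1.2 (≥ 40% per component).

Bond-less molecules (water, methane) enumerate no paths; their path
fingerprint is seeded with one atom-derived bit so that identical such
molecules compare at unit similarity instead of the degenerate 0/0 case.
Fingerprints of two genuinely empty bitsets compare at 0.0.

Metabolic accessibility normalizes per-atom match counts by the number of
successful rule applications, giving frequencies in [0, 1] over the
canonical query structure; no matches yield an empty profile rather than a
zero-filled one. Secondary products are reported but never scored. A
separate reducer keeps the best prediction per (query, reaction) pair for
"top hit" summaries.

## Downstream analysis

* Descriptors: molecular weight, Wildman–Crippen logP, TPSA, H-bond
  donors, acceptors (N+O count — the classic rule-of-five reading),
  rotatable bonds. Rule-of-five comparisons are inclusive (≤).
* BOILED-Egg: point-in-ellipse tests in the (TPSA, logP) plane using the
  published best-fit ellipses of the cited permeation model (white/
  absorption: center (71.051, 2.292), axes 142.081 × 8.740; yolk/brain:
  center (38.117, 3.177), axes 82.061 × 5.557; small rotations).
* Structural alerts: the published PAINS and Brenk catalogs as shipped in
  RDKit's filter-catalog module.
* Isotope patterns: per-element isotope distributions convolved exactly,
  aggregated at nominal-mass resolution with abundance-weighted mean
  masses, truncated at 1e-6 relative abundance, renormalized to 1.
  Supported elements: C, H, N, O, P, S, F, Cl, Br, I.
* Benchmark statistics: Q1/Q3 by linear interpolation between order
  statistics (configurable to Tukey hinges; the conventions differ only on
  small arrays), upper whisker Q3 + 1.5·IQR, exceedances counted strictly
  above. Exact-match evaluation compares canonical keys, optionally also
  requiring reaction-id agreement.
* Chemical-space projection: standard PCA of the binary Morgan (radius-2,
  2048-bit) fingerprint matrix; an all-identical input is flagged
  degenerate instead of returning noise.
* Similarity networks: all-pairs Tanimoto on Morgan fingerprints, edges
  kept at weight ≥ cutoff (≥, not >), self-pairs excluded by construction,
  isolated nodes kept. The same topology constructor accepts any symmetric
  similarity matrix. External annotation services are represented by a
  pluggable interface whose default returns nothing, keeping runs offline.

## Fixture set and what it shows

The fixture generator emulates, at toy scale, the content of curated
reconstructions: five balanced, hand atom-mapped biotransformations typical
of gut-microbial xenobiotic chemistry (tyrosine decarboxylation,
formate-driven nitrobenzene reduction, aspirin hydrolysis, guaiacol
O-demethylation, formate-driven azobenzene reduction), each with enzyme/EC/
biosystem/organism annotations; three deliberately invalid records; and a
query panel (levodopa, 4-nitrotoluene, phenyl acetate) whose reference
metabolites (dopamine, p-toluidine, phenol) are each reachable by exactly
one fixture reaction's chemistry. The chemistry is fixed; the seed affects
only optional decoy queries.

Passing tests on these fixtures demonstrate the machinery — filtering,
mapping, decomposition, serialization, application, scoring — is correct
and deterministic. They do not demonstrate recall on real reconstructions:
real GEM exports bring incomplete annotations, missing cofactors, and much
larger molecules, and mapping quality then depends on the supplied atom
maps. Problem sizes throughout (a handful of reactions, tens of rules,
three queries) are the package's chosen test scale; the pipeline itself is
linear in rules × queries.

## Known limitations

* The MCS fallback mapper can misassign atoms in symmetric molecules;
  supply atom maps for production use.
* Rules cannot represent transformations that leave connectivity unchanged
  (transport, racemization) and do not model multi-step metabolism.
* Aromaticity changes across a reaction (e.g. ring-opening dearomatization)
  rely on the pattern engine's resanitization and may reject exotic cases;
  such rules are dropped at the round-trip gate rather than kept wrong.
* The slack balance mode intentionally ignores all hydrogen imbalance; use
  strict mode when proton bookkeeping matters.
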
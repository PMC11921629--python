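# xenomet

Reaction-rule extraction from genome-scale metabolic models (GEMs) and
confidence-scored metabolite prediction for human and gut-microbial
biotransformations.

## The problem

The gut microbiome metabolizes dietary compounds and xenobiotics through
thousands of enzymatic reactions, but most of the resulting metabolites are
unknown. Genome-scale metabolic reconstructions encode these reactions with
enzyme, pathway, and organism annotations, yet they describe only the
substrates already curated into them. `xenomet` generalizes such reactions
into *chemically specific reaction rules* (CSRRs) — trimmed, graded reaction
patterns that can be applied to new query molecules (e.g. orally
administered drugs) to predict their metabolites, together with the enzyme
and organism context inherited from the source models.

It is aimed at researchers in cheminformatics, drug metabolism, and
microbiome science who want an auditable, fully offline pipeline from a
reaction table to scored metabolite predictions.

## Method

1. **Filtering.** Reactions read from a TSV table, a model-JSON export, or
   SBML are classified; transport, exchange, passive diffusion, biomass,
   stereo-only, unbalanced, and incomplete records are excluded with an
   audit trail. Elemental balance is checked per element, with an optional
   proton/charge slack for GEM exports that omit H⁺.
2. **Atom mapping.** Reactions below 1200 heavy atoms are accepted with
   validated input atom maps (recommended) or mapped by a deterministic
   greedy maximum-common-substructure fallback.
3. **SRR decomposition.** Each mapped reaction is split into single-reactant
   reactions: one per distinct substrate, pairing it with every product that
   inherits at least one of its atoms. The product inheriting the most atoms
   is the *main product*; the rest are secondary (cofactors, CO₂, water).
4. **Rule generation.** The reaction center — atoms whose bonds, charge,
   aromatic/ring state, or hydrogen count change — is expanded in
   bond-radius shells, emitting one reaction-SMARTS rule per context size
   until min(40, all) substrate atoms are included. Query atoms carry
   element, aromaticity, ring, degree, and charge constraints. Every rule is
   verified to reproduce its own source product (round trip) before it
   enters the database.
5. **Prediction and scoring.** Each rule whose query side embeds in a query
   molecule executes its transform. A prediction's confidence is

   *score* = T(q, s) + T(p̂, p) + |matched| / |q|  ∈ [0, 3]

   where T is the Tanimoto coefficient over 2048-bit path fingerprints
   (1–7 bond paths), q/s are the query and source substrate, p̂/p the
   predicted and source main product, and the last term is the atom
   efficiency (fraction of query heavy atoms covered by the match).
   Predictions below the reporting cutoff (default 0.6) are dropped;
   scores ≥ 1.2 — at least 40% on each component — are high-confidence.

Downstream modules provide per-atom metabolic accessibility, descriptor
profiles and rule-of-five checks, BOILED-Egg absorption/brain-penetration
classification, PAINS/Brenk structural alerts, isotopic envelopes,
exact-match benchmarking with Tukey-whisker statistics, PCA projection of
fingerprint space, and Tanimoto similarity networks (GraphML/SIF export).

## Worked example

The package ships a deterministic toy fixture generator (five hand-mapped
biotransformations — decarboxylation, nitro reduction, ester hydrolysis,
O-demethylation, azo reduction — plus three deliberately invalid records):

```sh
xenomet make-fixtures --seed 7 --out fx
xenomet generate-rules --reactions fx/reactions.tsv --out rules --balance-mode strict
xenomet predict --rules rules/rules.tsv --queries fx/queries.smi --out preds
xenomet benchmark --predictions preds/predictions.tsv \
                  --reference fx/reference_metabolites.tsv --out bench
```

prints

```
wrote fx/reactions.tsv, fx/queries.smi, fx/reference_metabolites.tsv
retained 5/8 reactions; wrote 33 rules to rules/rules.tsv
10 predictions for 3 queries at cutoff 0.6
exact-match fraction 1.000 (3/3)
```

The three invalid records (a transport, an unbalanced reaction, a pure
stereochemical conversion) are excluded and logged in `rules/audit.jsonl`;
the five valid reactions yield 33 graded rules. Applying them to the query
panel recovers all three reference metabolites. The top row of
`preds/predictions.tsv`:

```
query_id  rule_id               reaction_id  predicted_smiles      confidence_score
levodopa  RXN_DECARB__s0__n009  RXN_DECARB   NCCC1=CC=C(O)C(O)=C1  2.094192
```

i.e. levodopa is decarboxylated to dopamine by the tyrosine-decarboxylase
rule at confidence 2.09 (substrate similarity + product similarity + atom
efficiency), well above the 1.2 high-confidence threshold. Per-query
per-atom match frequencies land in `preds/accessibility.json`.

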
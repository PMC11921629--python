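"""Apply a rule database to query molecules and score the predictions.

Each successful substructure embedding of a rule's query side yields one
application: the transform is executed, products are sanitized, and the
prediction is scored with the three-component confidence score

* substrate similarity — Tanimoto between path fingerprints of the query
  and the rule's source substrate,
* product similarity — same, between the predicted and the source main
  product,
* atom efficiency — fraction of the query's heavy atoms covered by the
  matched substructure.

The total is their sum, bounded by 3 (reached exactly when a rule is
applied back to its own source substrate with full-molecule context). The
packaged high-confidence threshold is 1.2, i.e. a minimum of 40% on each
component; the default reporting cutoff is 0.6.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_core import (
    MoleculeRecord,
    SanitizationError,
    fingerprint,
    mol_from_record,
    sanitize_molecule,
    tanimoto,
)
from .rule_generation import ReactionRule, apply_rule_to_mol

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceScore",
    "Prediction",
    "AccessibilityProfile",
    "DEFAULT_CUTOFF",
    "HIGH_CONFIDENCE_THRESHOLD",
    "apply_rule",
    "score_prediction",
    "predict_metabolites",
    "best_per_pair",
    "accessibility_profile",
    "write_predictions_tsv",
    "write_accessibility_json",
]

DEFAULT_CUTOFF = 0.6
HIGH_CONFIDENCE_THRESHOLD = 1.2


@dataclass(frozen=True)
class ConfidenceScore:
    substrate_similarity: float
    product_similarity: float
    atom_efficiency: float

    @property
    def total(self) -> float:
        return self.substrate_similarity + self.product_similarity + self.atom_efficiency


@dataclass(frozen=True)
class Prediction:
    query_id: str
    rule_id: str
    reaction_id: str
    main_product: MoleculeRecord
    secondary_products: tuple[MoleculeRecord, ...]
    matched_atoms: frozenset[int]
    score: ConfidenceScore
    biosystem: str = "both"
    enzyme_name: str = ""
    ec_numbers: tuple[str, ...] = ()
    subsystem: str = ""
    organism_refs: tuple[str, ...] = ()


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-atom frequency with which query atoms fall inside matched rule
    substructures; empty when there are no successful matches."""

    frequencies: dict[int, float] = field(default_factory=dict)
    n_matches: int = 0


@dataclass(frozen=True)
class RuleApplication:
    main_product: MoleculeRecord
    secondary_products: tuple[MoleculeRecord, ...]
    matched_atoms: frozenset[int]


def apply_rule(query: MoleculeRecord, rule: ReactionRule) -> list[RuleApplication]:
    """All distinct outcomes of one rule against one query.

    Chemically invalid products (valence violations after the transform)
    are discarded with a log entry; duplicate outcomes — same main-product
    key and matched-atom set — are collapsed. A non-matching query yields
    an empty list, not an error.
    """
    mol = mol_from_record(query)
    try:
        raw = apply_rule_to_mol(rule.smarts, mol)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pattern engine failure for rule {rule.rule_id}: {exc}") from exc
    seen: set[tuple[str, frozenset[int]]] = set()
    out: list[RuleApplication] = []
    for prods, matched in raw:
        main = _sanitize_product(prods[0])
        if main is None:
            logger.info("rule %s on %s: invalid main product dropped", rule.rule_id,
                        query.identifier or query.key)
            continue
        key = (main.key, matched)
        if key in seen:
            continue
        seen.add(key)
        secondary = []
        for p in prods[1:]:
            rec = _sanitize_product(p)
            if rec is None:
                logger.info("rule %s on %s: invalid secondary product dropped",
                            rule.rule_id, query.identifier or query.key)
                continue
            secondary.append(rec)
        out.append(RuleApplication(main, tuple(secondary), matched))
    return out


def _sanitize_product(mol: Chem.Mol) -> MoleculeRecord | None:
    try:
        Chem.SanitizeMol(mol)
        return sanitize_molecule(Chem.MolToSmiles(mol))
    except (SanitizationError, Exception):  # noqa: BLE001 - rdkit raises bare exceptions
        return None


def score_prediction(
    query: MoleculeRecord,
    rule: ReactionRule,
    main_product: MoleculeRecord,
    matched_atoms: frozenset[int],
) -> ConfidenceScore:
    """Three-component confidence score for a successful application."""
    q_fp = fingerprint(query, "path")
    s_fp = fingerprint(sanitize_molecule(rule.substrate_smiles), "path")
    p_fp = fingerprint(main_product, "path")
    ref_fp = fingerprint(sanitize_molecule(rule.product_smiles), "path")
    return ConfidenceScore(
        substrate_similarity=tanimoto(q_fp, s_fp),
        product_similarity=tanimoto(p_fp, ref_fp),
        atom_efficiency=len(matched_atoms) / query.heavy_atom_count,
    )


def predict_metabolites(
    query: MoleculeRecord,
    rules: list[ReactionRule],
    cutoff: float = DEFAULT_CUTOFF,
    biosystem: str | None = None,
) -> list[Prediction]:
    """Apply every rule (optionally restricted to one biosystem) to a query.

    Predictions scoring below ``cutoff`` are dropped; the result is sorted
    by descending total confidence, then rule id, with at most one row per
    (query, rule, main-product key).
    """
    if not rules:
        raise ValueError("empty rule database")
    predictions: list[Prediction] = []
    for rule in rules:
        if biosystem and rule.biosystem not in (biosystem, "both"):
            continue
        best_by_product: dict[str, Prediction] = {}
        for app in apply_rule(query, rule):
            score = score_prediction(query, rule, app.main_product, app.matched_atoms)
            if score.total < cutoff:
                continue
            pred = Prediction(
                query_id=query.identifier or query.key,
                rule_id=rule.rule_id,
                reaction_id=rule.reaction_id,
                main_product=app.main_product,
                secondary_products=app.secondary_products,
                matched_atoms=app.matched_atoms,
                score=score,
                biosystem=rule.biosystem,
                enzyme_name=rule.enzyme_name,
                ec_numbers=rule.ec_numbers,
                subsystem=rule.subsystem,
                organism_refs=rule.organism_refs,
            )
            prev = best_by_product.get(app.main_product.key)
            if prev is None or pred.score.total > prev.score.total:
                best_by_product[app.main_product.key] = pred
        predictions.extend(best_by_product.values())
    predictions.sort(key=lambda p: (-p.score.total, p.rule_id, p.main_product.key))
    return predictions


def best_per_pair(predictions: list[Prediction]) -> list[Prediction]:
    """Keep the highest-confidence prediction per (query, reaction) pair.

    Post-processing reducer for "top best" summaries where several rule
    granularities of one reaction hit the same query.
    """
    best: dict[tuple[str, str], Prediction] = {}
    for p in predictions:
        k = (p.query_id, p.reaction_id)
        if k not in best or p.score.total > best[k].score.total:
            best[k] = p
    return sorted(best.values(), key=lambda p: (-p.score.total, p.rule_id))


def accessibility_profile(
    query: MoleculeRecord, predictions: list[Prediction]
) -> AccessibilityProfile:
    """Metabolic accessibility: per-atom match frequency across predictions.

    Frequencies are counts of membership in matched substructures divided
    by the number of successful rule matches; atom indices refer to the
    canonical query structure. Empty predictions give an empty profile.
    """
    qid = query.identifier or query.key
    preds = [p for p in predictions if p.query_id == qid]
    if any(p.query_id != qid for p in predictions):
        raise ValueError("accessibility profile requires predictions for a single query")
    if not preds:
        return AccessibilityProfile()
    counts: dict[int, int] = {i: 0 for i in range(query.heavy_atom_count)}
    for p in preds:
        for idx in p.matched_atoms:
            counts[idx] += 1
    n = len(preds)
    return AccessibilityProfile(
        frequencies={i: c / n for i, c in counts.items()},
        n_matches=n,
    )


PREDICTIONS_TSV_COLUMNS = [
    "query_id", "rule_id", "reaction_id", "predicted_smiles", "secondary_smiles",
    "substrate_similarity", "product_similarity", "atom_efficiency",
    "confidence_score", "biosystem", "enzyme_name", "ec_numbers", "subsystem",
    "organism_refs",
]


def write_predictions_tsv(predictions: list[Prediction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTIONS_TSV_COLUMNS) + "\n")
        for p in predictions:
            fh.write("\t".join([
                p.query_id, p.rule_id, p.reaction_id, p.main_product.structure,
                ";".join(s.structure for s in p.secondary_products),
                f"{p.score.substrate_similarity:.6f}",
                f"{p.score.product_similarity:.6f}",
                f"{p.score.atom_efficiency:.6f}",
                f"{p.score.total:.6f}",
                p.biosystem, p.enzyme_name, ";".join(p.ec_numbers), p.subsystem,
                ";".join(p.organism_refs),
            ]) + "\n")


def write_accessibility_json(
    profiles: dict[str, AccessibilityProfile], path: str
) -> None:
    """Accessibility as JSON; atom indices are 0-based over the canonical
    query structure, as stated in the embedded header."""
    payload = {
        "_header": "atom indices are 0-based positions in the canonical query structure",
        "profiles": {
            qid: {"n_matches": prof.n_matches,
                  "frequencies": {str(i): f for i, f in sorted(prof.frequencies.items())}}
            for qid, prof in sorted(profiles.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
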
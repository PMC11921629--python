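"""Graded reaction-rule (CSRR) extraction from atom-mapped biotransformations.

The pipeline implemented here:

1. ``map_atoms`` — validate atom maps supplied with the reaction (the
   recommended path) or fall back to a deterministic greedy
   maximum-common-substructure assignment. Reactions with 1200 or more
   heavy atoms are skipped.
2. ``decompose_to_srrs`` — split a mapped reaction into single-reactant
   reactions (SRRs): one per distinct substrate, each pairing that
   substrate with every product that inherits at least one of its atoms.
   The product inheriting the most substrate atoms is the main product.
3. ``identify_reaction_center`` — substrate atoms whose bonding partners,
   bond orders, charge, aromaticity/ring state, or hydrogen count change.
4. ``generate_csrrs`` — grow bond-radius shells around the center and emit
   one serialized reaction-SMARTS rule per distinct included-atom set,
   until the rule covers min(40, all) substrate heavy atoms. Query-side
   atoms carry element, aromaticity, ring-membership, degree, and charge
   constraints; the transform side is written with explicit hydrogen
   counts so applying a rule is fully deterministic.

Every emitted rule is verified to reproduce its own source main product
when applied to its source substrate; rules failing this round trip are
dropped and logged, never kept silently.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdChemReactions, rdFMCS

from .chem_core import MoleculeRecord, canonical_key, sanitize_molecule
from .gem_io import Participant, ReactionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MappedReaction",
    "SRR",
    "SRRProduct",
    "ReactionRule",
    "MappingError",
    "ReactionSkipped",
    "map_atoms",
    "decompose_to_srrs",
    "identify_reaction_center",
    "generate_csrrs",
    "generate_rules_for_reaction",
    "apply_rule_to_mol",
    "write_rule_db",
    "read_rule_db",
]

ATOM_BUDGET = 1200  # heavy atoms; larger reactions are skipped, not mapped
MAX_RULE_ATOMS = 40

RULE_DB_VERSION = "xenomet-rules-v1"
RULE_DB_COLUMNS = [
    "rule_id", "reaction_id", "smarts", "num_atoms", "substrate_smiles",
    "product_smiles", "biosystem", "enzyme_name", "ec_numbers", "subsystem",
    "organism_refs",
]


class MappingError(ValueError):
    """Inconsistent or incomplete atom maps."""


class ReactionSkipped(Exception):
    """Reaction excluded from rule generation, with a reason."""

    def __init__(self, reaction_id: str, reason: str):
        self.reaction_id = reaction_id
        self.reason = reason
        super().__init__(f"{reaction_id}: {reason}")


@dataclass
class MappedReaction:
    base: ReactionRecord
    substrate_mols: list[Chem.Mol]
    product_mols: list[Chem.Mol]
    mapper_source: str  # "input" | "fallback_mcs"


@dataclass
class SRRProduct:
    mol: Chem.Mol
    record: MoleculeRecord
    inherited_atoms: int


@dataclass
class SRR:
    reaction_id: str
    substrate_mol: Chem.Mol
    substrate_record: MoleculeRecord
    products: list[SRRProduct]
    main_product_index: int
    base: ReactionRecord
    substrate_index: int = 0

    @property
    def main_product(self) -> SRRProduct:
        return self.products[self.main_product_index]


@dataclass(frozen=True)
class ReactionRule:
    """A chemically specific reaction rule at one atom-context size."""

    rule_id: str
    reaction_id: str
    smarts: str
    num_atoms: int
    substrate_smiles: str
    product_smiles: str
    biosystem: str = "both"
    enzyme_name: str = ""
    ec_numbers: tuple[str, ...] = ()
    subsystem: str = ""
    organism_refs: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# atom mapping


def _sanitize_mapped(mol: Chem.Mol) -> Chem.Mol:
    """Apply the record-level sanitization while keeping atom map numbers."""
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(6)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def _parse_side(parts: tuple[Participant, ...], reaction_id: str) -> list[Chem.Mol]:
    mols = []
    for p in parts:
        mol = Chem.MolFromSmiles(p.raw)
        if mol is None:
            raise ReactionSkipped(reaction_id, f"unparseable participant {p.raw!r}")
        mols.append(_sanitize_mapped(mol))
    return mols


def _maps_of(mol: Chem.Mol) -> dict[int, int]:
    """map number -> atom index for mapped heavy atoms."""
    return {a.GetAtomMapNum(): a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum()}


def _validate_maps(subs: list[Chem.Mol], prods: list[Chem.Mol], reaction_id: str) -> None:
    for side_name, side in (("substrate", subs), ("product", prods)):
        seen: set[int] = set()
        for mol in side:
            for m in _maps_of(mol):
                if m in seen:
                    raise MappingError(f"{reaction_id}: duplicate {side_name}-side map index {m}")
                seen.add(m)
    sub_maps = {m: (mol, idx) for mol in subs for m, idx in _maps_of(mol).items()}
    prod_maps = {m: (mol, idx) for mol in prods for m, idx in _maps_of(mol).items()}
    for mol in subs:
        for atom in mol.GetAtoms():
            if not atom.GetAtomMapNum():
                raise MappingError(
                    f"{reaction_id}: substrate atom {atom.GetSymbol()}{atom.GetIdx()} is unmapped")
            m = atom.GetAtomMapNum()
            if m not in prod_maps:
                raise MappingError(f"{reaction_id}: substrate map {m} missing on product side")
            pmol, pidx = prod_maps[m]
            if pmol.GetAtomWithIdx(pidx).GetAtomicNum() != atom.GetAtomicNum():
                raise MappingError(f"{reaction_id}: map {m} pairs different elements")
    for m in prod_maps:
        if m not in sub_maps:
            raise MappingError(f"{reaction_id}: product map {m} missing on substrate side")


def _fallback_mcs_map(subs: list[Chem.Mol], prods: list[Chem.Mol], reaction_id: str) -> None:
    """Greedy MCS-based atom assignment, in place.

    Pairs substrate/product fragments by descending common-substructure
    size with deterministic tie-breaking by canonical SMILES. Weaker than a
    learned mapper: intended for toy inputs and audits, with pre-mapped
    input as the recommended path.
    """
    next_map = itertools.count(1)
    params_order = rdFMCS.MCSParameters()

    def unassigned(mol: Chem.Mol) -> list[int]:
        return [a.GetIdx() for a in mol.GetAtoms() if not a.GetAtomMapNum()]

    progress = True
    while progress:
        progress = False
        candidates = []
        for si, smol in enumerate(subs):
            if not unassigned(smol):
                continue
            for pi, pmol in enumerate(prods):
                if not unassigned(pmol):
                    continue
                res = rdFMCS.FindMCS(
                    [smol, pmol],
                    atomCompare=rdFMCS.AtomCompare.CompareElements,
                    bondCompare=rdFMCS.BondCompare.CompareAny,
                    timeout=5,
                )
                if res.numAtoms == 0:
                    continue
                candidates.append((res.numAtoms, -si, -pi, res.smartsString, si, pi))
        if not candidates:
            break
        candidates.sort(reverse=True)
        _, _, _, smarts, si, pi = candidates[0]
        patt = Chem.MolFromSmarts(smarts)
        smol, pmol = subs[si], prods[pi]
        smatches = [m for m in smol.GetSubstructMatches(patt, uniquify=False)
                    if all(not smol.GetAtomWithIdx(i).GetAtomMapNum() for i in m)]
        pmatches = [m for m in pmol.GetSubstructMatches(patt, uniquify=False)
                    if all(not pmol.GetAtomWithIdx(i).GetAtomMapNum() for i in m)]
        if not smatches or not pmatches:
            break
        for s_idx, p_idx in zip(smatches[0], pmatches[0]):
            m = next(next_map)
            smol.GetAtomWithIdx(s_idx).SetAtomMapNum(m)
            pmol.GetAtomWithIdx(p_idx).SetAtomMapNum(m)
        progress = True

    leftover = [a.GetSymbol() for mol in subs for a in mol.GetAtoms() if not a.GetAtomMapNum()]
    if leftover:
        raise MappingError(
            f"{reaction_id}: fallback mapper could not place substrate atoms {leftover}")
    del params_order


def map_atoms(rec: ReactionRecord, atom_budget: int = ATOM_BUDGET) -> MappedReaction:
    """Validate input atom maps or compute a fallback assignment.

    Raises :class:`ReactionSkipped` for reactions at or above the heavy-atom
    budget and :class:`MappingError` for inconsistent maps.
    """
    subs = _parse_side(rec.substrates, rec.reaction_id)
    prods = _parse_side(rec.products, rec.reaction_id)
    total = sum(m.GetNumHeavyAtoms() for m in subs + prods)
    if total >= atom_budget:
        raise ReactionSkipped(rec.reaction_id, "atom budget")

    any_maps = any(_maps_of(m) for m in subs + prods)
    if any_maps:
        _validate_maps(subs, prods, rec.reaction_id)
        source = "input"
    else:
        _fallback_mcs_map(subs, prods, rec.reaction_id)
        _validate_maps(subs, prods, rec.reaction_id)
        source = "fallback_mcs"
    return MappedReaction(base=rec, substrate_mols=subs, product_mols=prods,
                          mapper_source=source)


# --------------------------------------------------------------------------
# SRR decomposition


def _unmapped_record(mol: Chem.Mol) -> MoleculeRecord:
    clean = Chem.Mol(mol)
    for a in clean.GetAtoms():
        a.SetAtomMapNum(0)
    return sanitize_molecule(Chem.MolToSmiles(clean))


def decompose_to_srrs(mr: MappedReaction) -> list[SRR]:
    """One SRR per distinct substrate (stoichiometric copies collapse).

    Per product, the number of atoms whose map index originates in the
    substrate is recorded; the product with the largest inherited-atom count
    is the main product (ties: heavy-atom count, then canonical key).
    """
    srrs: list[SRR] = []
    seen_keys: set[str] = set()
    prod_records = [_unmapped_record(p) for p in mr.product_mols]
    for si, smol in enumerate(mr.substrate_mols):
        srec = _unmapped_record(smol)
        if srec.key in seen_keys:
            continue
        seen_keys.add(srec.key)
        sub_maps = set(_maps_of(smol))
        products: list[SRRProduct] = []
        for pmol, prec in zip(mr.product_mols, prod_records):
            inherited = sum(1 for a in pmol.GetAtoms() if a.GetAtomMapNum() in sub_maps)
            if inherited > 0:
                products.append(SRRProduct(mol=pmol, record=prec, inherited_atoms=inherited))
        if not products:
            raise MappingError(
                f"{mr.base.reaction_id}: substrate {srec.key} maps to no product atoms")
        main = max(
            range(len(products)),
            key=lambda i: (products[i].inherited_atoms,
                           products[i].record.heavy_atom_count,
                           products[i].record.key),
        )
        srrs.append(SRR(
            reaction_id=mr.base.reaction_id,
            substrate_mol=smol,
            substrate_record=srec,
            products=products,
            main_product_index=main,
            base=mr.base,
            substrate_index=len(srrs),
        ))
    return srrs


# --------------------------------------------------------------------------
# reaction center


def _bond_order(bond: Chem.Bond) -> float:
    return bond.GetBondTypeAsDouble()


def _atom_env(mol: Chem.Mol, idx: int, own_maps: set[int]):
    """Comparable environment of one atom: state + neighbor multiset.

    Neighbors are identified by their map index when they belong to the
    substrate's map set, and by the token "ext" otherwise (atoms added by
    cosubstrates or unmapped atoms).
    """
    atom = mol.GetAtomWithIdx(idx)
    nbrs = []
    for b in atom.GetBonds():
        other = b.GetOtherAtom(atom)
        m = other.GetAtomMapNum()
        token = m if m in own_maps else "ext"
        nbrs.append((str(token), _bond_order(b)))
    return (
        atom.GetFormalCharge(),
        atom.GetIsAromatic(),
        atom.IsInRing(),
        atom.GetTotalNumHs(),
        sorted(nbrs),
    )


def identify_reaction_center(srr: SRR) -> set[int]:
    """Substrate atom indices whose chemical context changes.

    An atom is reacting iff its bonded-neighbor multiset (by map index and
    bond order), formal charge, aromatic/ring state, or hydrogen count
    differs between the substrate and product sides. An identity
    transformation (empty center) is an error.
    """
    own_maps = set(_maps_of(srr.substrate_mol))
    prod_by_map: dict[int, tuple[Chem.Mol, int]] = {}
    for p in srr.products:
        for m, idx in _maps_of(p.mol).items():
            if m in own_maps:
                prod_by_map[m] = (p.mol, idx)

    center: set[int] = set()
    for atom in srr.substrate_mol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m not in prod_by_map:
            raise MappingError(
                f"{srr.reaction_id}: substrate map {m} absent from SRR products")
        pmol, pidx = prod_by_map[m]
        if _atom_env(srr.substrate_mol, atom.GetIdx(), own_maps) != _atom_env(pmol, pidx, own_maps):
            center.add(atom.GetIdx())
    if not center:
        raise MappingError(f"{srr.reaction_id}: no chemical change (identity transformation)")
    return center


# --------------------------------------------------------------------------
# CSRR serialization


_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _charge_token(charge: int) -> str:
    return f"{'+' if charge >= 0 else '-'}{abs(charge)}"


def _query_atom_symbol(atom: Chem.Atom) -> str:
    """Per-atom query: element, aromaticity, ring membership, degree, charge.

    Degree counts all heavy neighbors in the full substrate, so ring bonds
    cut at the context boundary survive as degree constraints on boundary
    atoms.
    """
    return "[#{z};{arom};{ring};D{deg};{chg}:{m}]".format(
        z=atom.GetAtomicNum(),
        arom="a" if atom.GetIsAromatic() else "A",
        ring="R" if atom.IsInRing() else "!R",
        deg=atom.GetDegree(),
        chg=_charge_token(atom.GetFormalCharge()),
        m=atom.GetAtomMapNum(),
    )


def _template_atom_symbol(atom: Chem.Atom, keep_map: bool) -> str:
    """Concrete product-side atom with explicit hydrogen count."""
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    # Hydrogen count and charge are always explicit: the pattern engine
    # otherwise inherits both from the matched reactant atom, which would
    # leak e.g. nitro-group charges into reduction products.
    token = f"{sym}H{atom.GetTotalNumHs()}{_charge_token(atom.GetFormalCharge())}"
    if keep_map and atom.GetAtomMapNum():
        token += f":{atom.GetAtomMapNum()}"
    return f"[{token}]"


def _fragment_smarts(mol: Chem.Mol, atoms: list[int], symbols: list[str]) -> str:
    bonds = [b.GetIdx() for b in mol.GetBonds()
             if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms]
    bond_symbols = [_BOND_SYMBOL.get(b.GetBondType(), "~") for b in mol.GetBonds()]
    smarts = Chem.MolFragmentToSmiles(
        mol, atomsToUse=atoms, bondsToUse=bonds,
        atomSymbols=symbols, bondSymbols=bond_symbols, canonical=True,
    )
    return f"({smarts})" if "." in smarts else smarts


def _product_piece_smarts(pmol: Chem.Mol, included_maps: set[int], own_maps: set[int]) -> str:
    """Transform-side template for one product.

    Kept atoms: those mapped to included substrate atoms (they keep their
    map) and atoms the transform introduces (cosubstrate-derived or
    unmapped, written without a map). Atoms mapped to excluded substrate
    atoms are left out; the pattern engine carries them over unchanged.
    """
    keep: list[int] = []
    symbols = []
    for atom in pmol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m in included_maps:
            keep.append(atom.GetIdx())
            symbols.append(_template_atom_symbol(atom, keep_map=True))
        elif m not in own_maps:
            keep.append(atom.GetIdx())
            symbols.append(_template_atom_symbol(atom, keep_map=False))
        else:
            symbols.append("")
    if not keep:
        return ""
    return _fragment_smarts(pmol, keep, symbols)


def _rule_smarts(srr: SRR, included: set[int]) -> str:
    smol = srr.substrate_mol
    symbols = [_query_atom_symbol(a) for a in smol.GetAtoms()]
    query = _fragment_smarts(smol, sorted(included), symbols)

    own_maps = set(_maps_of(smol))
    included_maps = {smol.GetAtomWithIdx(i).GetAtomMapNum() for i in included}
    pieces = [_product_piece_smarts(srr.main_product.mol, included_maps, own_maps)]
    secondaries = sorted(
        (p for i, p in enumerate(srr.products) if i != srr.main_product_index),
        key=lambda p: p.record.key,
    )
    for p in secondaries:
        piece = _product_piece_smarts(p.mol, included_maps, own_maps)
        if piece:
            pieces.append(piece)
    return query + ">>" + ".".join(pieces)


def _shell_sets(srr: SRR, center: set[int], max_atoms: int) -> list[set[int]]:
    """Nested included-atom sets: center plus growing bond-radius shells.

    When the next shell would overshoot the atom cap, the shell is filled
    partially in canonical-rank order so the largest rule holds exactly
    min(max_atoms, all substrate atoms).
    """
    mol = srr.substrate_mol
    n = mol.GetNumHeavyAtoms()
    cap = min(max_atoms, n)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    sets: list[set[int]] = []
    current = set(center)
    if len(current) > cap:
        ordered = sorted(current, key=lambda i: ranks[i])
        current = set(ordered[:cap])
    sets.append(set(current))
    while len(current) < cap:
        frontier = set()
        for idx in current:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in current:
                    frontier.add(nbr.GetIdx())
        if not frontier:
            break
        room = cap - len(current)
        if len(frontier) > room:
            frontier = set(sorted(frontier, key=lambda i: ranks[i])[:room])
        current |= frontier
        sets.append(set(current))
    return sets


def apply_rule_to_mol(smarts: str, mol: Chem.Mol) -> list[tuple[list[Chem.Mol], frozenset[int]]]:
    """Run a rule's reaction SMARTS against a molecule.

    Returns one entry per substructure embedding: the product molecules in
    template order (main product first) and the set of reactant atom
    indices matched by the query side. Products are returned unsanitized.
    """
    rxn = _reaction_from_smarts(smarts)
    results = []
    for prod_set in rxn.RunReactants((mol,)):
        matched: set[int] = set()
        for pmol in prod_set:
            for atom in pmol.GetAtoms():
                if atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx"):
                    matched.add(atom.GetIntProp("react_atom_idx"))
        results.append((list(prod_set), frozenset(matched)))
    return results


_RXN_CACHE: dict[str, rdChemReactions.ChemicalReaction] = {}


def _reaction_from_smarts(smarts: str) -> rdChemReactions.ChemicalReaction:
    rxn = _RXN_CACHE.get(smarts)
    if rxn is None:
        rxn = rdChemReactions.ReactionFromSmarts(smarts)
        if rxn is None:
            raise ValueError(f"invalid reaction SMARTS: {smarts}")
        rxn.Initialize()
        _RXN_CACHE[smarts] = rxn
    return rxn


def _round_trips(rule: ReactionRule) -> bool:
    """A rule must reproduce its own main product from its own substrate."""
    mol = Chem.MolFromSmiles(rule.substrate_smiles)
    target = canonical_key(rule.product_smiles)
    try:
        for prods, _ in apply_rule_to_mol(rule.smarts, mol):
            main = prods[0]
            try:
                Chem.SanitizeMol(main)
                if sanitize_molecule(Chem.MolToSmiles(main)).key == target:
                    return True
            except Exception:  # noqa: BLE001 - invalid embedding, try the next
                continue
    except Exception:  # noqa: BLE001 - pattern engine failure
        return False
    return False


def generate_csrrs(srr: SRR, max_atoms: int = MAX_RULE_ATOMS) -> list[ReactionRule]:
    """Emit the graded rule series for one SRR, smallest context first."""
    center = identify_reaction_center(srr)
    base = srr.base
    rules: list[ReactionRule] = []
    seen_sizes: set[int] = set()
    for included in _shell_sets(srr, center, max_atoms):
        if len(included) in seen_sizes:
            continue
        seen_sizes.add(len(included))
        smarts = _rule_smarts(srr, included)
        rule = ReactionRule(
            rule_id=f"{base.reaction_id}__s{srr.substrate_index}__n{len(included):03d}",
            reaction_id=base.reaction_id,
            smarts=smarts,
            num_atoms=len(included),
            substrate_smiles=srr.substrate_record.structure,
            product_smiles=srr.main_product.record.structure,
            biosystem=base.biosystem,
            enzyme_name=base.enzyme_name,
            ec_numbers=base.ec_numbers,
            subsystem=base.subsystem,
            organism_refs=base.organism_refs,
        )
        if _round_trips(rule):
            rules.append(rule)
        else:
            logger.warning("rule %s failed round-trip validation; dropped", rule.rule_id)
    return rules


def generate_rules_for_reaction(
    rec: ReactionRecord,
    max_atoms: int = MAX_RULE_ATOMS,
    atom_budget: int = ATOM_BUDGET,
) -> list[ReactionRule]:
    """Map, decompose, and emit rules for one retained biotransformation."""
    mapped = map_atoms(rec, atom_budget=atom_budget)
    rules: list[ReactionRule] = []
    for srr in decompose_to_srrs(mapped):
        rules.extend(generate_csrrs(srr, max_atoms=max_atoms))
    return rules


# --------------------------------------------------------------------------
# rule database I/O


def _merge_rules(rules: list[ReactionRule]) -> list[ReactionRule]:
    """Collapse duplicates (same pattern and source pair), merging annotations.

    Input is sorted first so the surviving representative (and hence the
    serialized database) is independent of generation order.
    """
    rules = sorted(rules, key=lambda r: (r.reaction_id, r.num_atoms, r.rule_id))
    merged: dict[tuple[str, str, str], ReactionRule] = {}
    for r in rules:
        k = (r.smarts, r.substrate_smiles, r.product_smiles)
        if k not in merged:
            merged[k] = r
        else:
            prev = merged[k]
            merged[k] = ReactionRule(
                rule_id=prev.rule_id,
                reaction_id=prev.reaction_id,
                smarts=prev.smarts,
                num_atoms=prev.num_atoms,
                substrate_smiles=prev.substrate_smiles,
                product_smiles=prev.product_smiles,
                biosystem=prev.biosystem if prev.biosystem == r.biosystem else "both",
                enzyme_name=prev.enzyme_name or r.enzyme_name,
                ec_numbers=tuple(dict.fromkeys(prev.ec_numbers + r.ec_numbers)),
                subsystem=prev.subsystem or r.subsystem,
                organism_refs=tuple(dict.fromkeys(prev.organism_refs + r.organism_refs)),
            )
    return sorted(merged.values(), key=lambda r: (r.reaction_id, r.num_atoms, r.rule_id))


def write_rule_db(rules: list[ReactionRule], path: str) -> None:
    """Serialize rules to TSV (default) or JSON (``.json`` extension).

    Output ordering is stable by (reaction_id, num_atoms) so repeated runs
    produce byte-identical databases.
    """
    rules = _merge_rules(list(rules))
    if str(path).endswith(".json"):
        payload = {
            "version": RULE_DB_VERSION,
            "rules": [
                {**{c: getattr(r, c) for c in RULE_DB_COLUMNS if c not in ("ec_numbers", "organism_refs")},
                 "ec_numbers": list(r.ec_numbers), "organism_refs": list(r.organism_refs)}
                for r in rules
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        fh.write(f"# {RULE_DB_VERSION}\n")
        fh.write("\t".join(RULE_DB_COLUMNS) + "\n")
        for r in rules:
            row = [
                r.rule_id, r.reaction_id, r.smarts, str(r.num_atoms),
                r.substrate_smiles, r.product_smiles, r.biosystem, r.enzyme_name,
                ";".join(r.ec_numbers), r.subsystem, ";".join(r.organism_refs),
            ]
            fh.write("\t".join(row) + "\n")


def read_rule_db(path: str) -> list[ReactionRule]:
    """Read a rule database written by :func:`write_rule_db`."""
    if str(path).endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != RULE_DB_VERSION:
            raise ValueError(f"{path}: unsupported rule database version {payload.get('version')!r}")
        return [
            ReactionRule(
                rule_id=d["rule_id"], reaction_id=d["reaction_id"], smarts=d["smarts"],
                num_atoms=int(d["num_atoms"]), substrate_smiles=d["substrate_smiles"],
                product_smiles=d["product_smiles"], biosystem=d["biosystem"],
                enzyme_name=d["enzyme_name"], ec_numbers=tuple(d["ec_numbers"]),
                subsystem=d["subsystem"], organism_refs=tuple(d["organism_refs"]),
            )
            for d in payload["rules"]
        ]
    rules = []
    with open(path) as fh:
        version_line = fh.readline().strip()
        if version_line != f"# {RULE_DB_VERSION}":
            raise ValueError(f"{path}: missing or mismatched version header {version_line!r}")
        header = fh.readline().rstrip("\n").split("\t")
        if header != RULE_DB_COLUMNS:
            raise ValueError(f"{path}: unexpected columns {header}")
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(RULE_DB_COLUMNS):
                raise ValueError(f"{path}:{lineno}: corrupted row (rule_id={f[0] if f else '?'})")
            rules.append(ReactionRule(
                rule_id=f[0], reaction_id=f[1], smarts=f[2], num_atoms=int(f[3]),
                substrate_smiles=f[4], product_smiles=f[5], biosystem=f[6],
                enzyme_name=f[7], ec_numbers=tuple(x for x in f[8].split(";") if x),
                subsystem=f[9], organism_refs=tuple(x for x in f[10].split(";") if x),
            ))
    return rules
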
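"""Molecule sanitization, canonical keys, fingerprints, and Tanimoto similarity.

Every other module builds on the conventions fixed here:

* molecules are stored as stereo-free, Kekulé, canonical SMILES with
  implicit hydrogens;
* "atom counts" always mean heavy atoms;
* identity between molecules means equality of :func:`canonical_key`.

Sanitization mirrors the preparation applied to metabolites extracted from
genome-scale reconstructions and to query drugs: salt stripping, dummy-atom
(R-group) replacement with carbon, stereochemistry removal, and charge
neutralization wherever a valence-legal neutral form exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "Fingerprint",
    "SanitizationError",
    "sanitize_molecule",
    "canonical_key",
    "mol_from_record",
    "fingerprint",
    "tanimoto",
]

FP_NBITS = 2048
PATH_MIN, PATH_MAX = 1, 7
MORGAN_RADIUS = 2


class SanitizationError(ValueError):
    """Raised when an input structure cannot be turned into a valid record."""

    def __init__(self, raw: str, reason: str):
        self.raw = raw
        self.reason = reason
        super().__init__(f"cannot sanitize {raw!r}: {reason}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A sanitized small molecule.

    Attributes
    ----------
    identifier:
        Caller-supplied name; empty string when anonymous.
    structure:
        Canonical Kekulé SMILES, stereo-free, largest organic fragment only.
    key:
        Canonical (aromatic) SMILES used for identity comparisons.
    formula:
        Element -> count map including hydrogens.
    heavy_atom_count:
        Number of non-hydrogen atoms.
    has_permanent_charge:
        True when a formal charge could not be legally neutralized
        (e.g. quaternary ammonium); the charge is retained, not an error.
    """

    identifier: str
    structure: str
    key: str
    formula: dict[str, int] = field(compare=False)
    heavy_atom_count: int
    has_permanent_charge: bool = False
    sanitized: bool = True


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Salt strip: keep the fragment with most heavy atoms.

    Ties prefer a carbon-containing fragment, then the lexicographically
    smallest canonical SMILES, so the choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def sort_key(f: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        return (-f.GetNumAtoms(), not has_c, Chem.MolToSmiles(f))

    return sorted(frags, key=sort_key)[0]


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Neutralize formal charges wherever a valence-legal neutral form exists.

    Uses the standardizer's uncharger, which protonates/deprotonates
    chargeable centers but leaves charge-separated groups (nitro,
    N-oxides) and permanently charged centers (quaternary ammonium)
    intact. Returns the molecule and a flag set when a net formal charge
    had to be retained.
    """
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = rdMolStandardize.Uncharger().uncharge(mol)
    permanent = Chem.GetFormalCharge(mol) != 0
    return mol, permanent


def sanitize_molecule(raw: str, identifier: str = "") -> MoleculeRecord:
    """Parse and sanitize a SMILES string into a :class:`MoleculeRecord`.

    The operation is idempotent: feeding the resulting ``structure`` back in
    returns an equal record.

    Raises
    ------
    SanitizationError
        For unparseable input, structures that lose every atom, or aromatic
        systems that cannot be written in Kekulé form.
    """
    mol = Chem.MolFromSmiles(raw, sanitize=False)
    if mol is None:
        raise SanitizationError(raw, "unparseable SMILES")

    # R-groups / wildcard atoms become carbon before valence perception.
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(6)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        atom.SetAtomMapNum(0)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - rdkit raises bare exceptions
        raise SanitizationError(raw, f"valence/aromaticity perception failed: {exc}")

    mol = _largest_organic_fragment(mol)
    if mol.GetNumAtoms() == 0:
        raise SanitizationError(raw, "no heavy atoms after salt stripping")
    Chem.RemoveStereochemistry(mol)
    mol, permanent = _neutralize(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001
        raise SanitizationError(raw, f"sanitization after neutralization failed: {exc}")

    key = Chem.MolToSmiles(mol)
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
        structure = Chem.MolToSmiles(kek, kekuleSmiles=True)
    except Exception as exc:  # noqa: BLE001
        raise SanitizationError(raw, f"kekulization failed: {exc}")

    formula: dict[str, int] = {}
    for atom in mol.GetAtoms():
        formula[atom.GetSymbol()] = formula.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            formula["H"] = formula.get("H", 0) + h

    return MoleculeRecord(
        identifier=identifier,
        structure=structure,
        key=key,
        formula=formula,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        has_permanent_charge=permanent,
    )


def canonical_key(mol: MoleculeRecord | str) -> str:
    """Injective key over molecular graphs: equal keys iff equal sanitized graphs."""
    if isinstance(mol, MoleculeRecord):
        return mol.key
    return sanitize_molecule(mol).key


def mol_from_record(rec: MoleculeRecord) -> Chem.Mol:
    """Re-parse the stored structure into an RDKit molecule."""
    mol = Chem.MolFromSmiles(rec.structure)
    if mol is None:  # pragma: no cover - structure is produced by rdkit itself
        raise SanitizationError(rec.structure, "stored structure failed to re-parse")
    return mol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint (2048 bits).

    ``path`` enumerates linear bond paths of 1-7 bonds (the kind used by the
    confidence score); ``circular`` is the Morgan/ECFP4 kind (radius 2, used
    for similarity networks and chemical-space projection).
    """

    bits: tuple[int, ...]  # sorted indices of set bits
    kind: str
    nbits: int = FP_NBITS

    def popcount(self) -> int:
        return len(self.bits)


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=FP_NBITS
)
_PATH_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(
    minPath=PATH_MIN, maxPath=PATH_MAX, fpSize=FP_NBITS
)


def fingerprint(mol: MoleculeRecord | Chem.Mol, kind: str = "path") -> Fingerprint:
    """Compute a 2048-bit binary fingerprint of the requested kind."""
    if kind not in ("path", "circular"):
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    m = mol_from_record(mol) if isinstance(mol, MoleculeRecord) else mol
    gen = _PATH_GEN if kind == "path" else _MORGAN_GEN
    bv = gen.GetFingerprint(m)
    bits = set(bv.GetOnBits())
    if not bits:
        # Bond-less molecules (water, methane, single ions) enumerate no
        # paths; seed one atom-derived bit so identical such molecules
        # still compare at unit similarity.
        bits = {(a.GetAtomicNum() * 97 + 13) % FP_NBITS for a in m.GetAtoms()}
    return Fingerprint(bits=tuple(sorted(bits)), kind=kind)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a&b| / |a|b| over two same-kind fingerprints.

    Two empty bitsets are defined as 0.0 similarity.
    """
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ValueError(f"fingerprint kinds differ: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}")
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union
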
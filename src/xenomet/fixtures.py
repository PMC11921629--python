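"""Deterministic toy reaction sets, queries, and reference metabolites.

The fixture chemistry mirrors transformations typical of gut-microbial
xenobiotic metabolism at toy scale: aromatic amino-acid decarboxylation,
formate-driven nitro and azo reduction, ester hydrolysis, and
O-demethylation. Every valid reaction is hand atom-mapped and elementally
balanced including hydrogens, so it passes balance checking in strict
mode; three deliberately invalid records (a transport, an unbalanced
reaction, and a pure stereochemical conversion) exercise the filter.

Fixtures are generated by code, never checked in, so schema changes cannot
silently desynchronize. Seeded randomness affects only the optional decoy
queries; the core chemistry is fixed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .chem_core import MoleculeRecord, sanitize_molecule
from .gem_io import TSV_COLUMNS, ReactionRecord, read_reaction_table

__all__ = ["FixtureSet", "make_fixture_set", "write_fixture_files", "N_VALID_REACTIONS", "N_INVALID_RECORDS"]

N_VALID_REACTIONS = 5
N_INVALID_RECORDS = 3

# Hand-written atom-mapped reaction rows (TSV schema of gem_io).
# Heavy-atom maps are unique per side and conserve every substrate atom.
_ROWS: list[dict[str, str]] = [
    {
        "reaction_id": "RXN_DECARB",
        "reaction_smiles": (
            "[NH2:1][CH:2]([CH2:3][c:4]1[cH:5][cH:6][c:7]([OH:8])[cH:9][cH:10]1)"
            "[C:11](=[O:12])[OH:13]"
            ">>[NH2:1][CH2:2][CH2:3][c:4]1[cH:5][cH:6][c:7]([OH:8])[cH:9][cH:10]1"
            ".[O:12]=[C:11]=[O:13]"
        ),
        "direction": "forward",
        "subsystem": "Tyrosine metabolism",
        "biosystem": "both",
        "enzyme_name": "tyrosine decarboxylase",
        "ec_numbers": "4.1.1.25",
        "organism_refs": "FIX_ORG_EFAECALIS;FIX_ORG_HUMAN",
        "xrefs": "kegg:R00736",
    },
    {
        "reaction_id": "RXN_NITRO",
        "reaction_smiles": (
            "[c:1]1([N+:7](=[O:8])[O-:9])[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ".[CH:20](=[O:21])[OH:22].[CH:23](=[O:24])[OH:25].[CH:26](=[O:27])[OH:28]"
            ">>[c:1]1([NH2:7])[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ".[OH2:8].[OH2:9]"
            ".[O:21]=[C:20]=[O:22].[O:24]=[C:23]=[O:25].[O:27]=[C:26]=[O:28]"
        ),
        "direction": "forward",
        "subsystem": "Nitroaromatic degradation",
        "biosystem": "microbe",
        "enzyme_name": "periplasmic nitroreductase",
        "ec_numbers": "1.7.1.16",
        "organism_refs": "FIX_ORG_ECOLI;FIX_ORG_SENTERICA",
        "xrefs": "seed:rxn90001",
    },
    {
        "reaction_id": "RXN_ESTER",
        "reaction_smiles": (
            "[CH3:1][C:2](=[O:3])[O:4][c:5]1[cH:6][cH:7][cH:8][cH:9][c:10]1"
            "[C:11](=[O:12])[OH:13].[OH2:14]"
            ">>[OH:4][c:5]1[cH:6][cH:7][cH:8][cH:9][c:10]1[C:11](=[O:12])[OH:13]"
            ".[CH3:1][C:2](=[O:3])[OH:14]"
        ),
        "direction": "forward",
        "subsystem": "Aminobenzoate degradation",
        "biosystem": "microbe",
        "enzyme_name": "digallate acylhydrolase",
        "ec_numbers": "3.1.1.-",
        "organism_refs": "FIX_ORG_BCEREUS",
        "xrefs": "metacyc:ESTERASE-RXN",
    },
    {
        "reaction_id": "RXN_ODEMETH",
        "reaction_smiles": (
            "[OH:1][c:2]1[cH:3][cH:4][cH:5][cH:6][c:7]1[O:8][CH3:9].[OH2:10]"
            ">>[OH:1][c:2]1[cH:3][cH:4][cH:5][cH:6][c:7]1[OH:8].[CH3:9][OH:10]"
        ),
        "direction": "forward",
        "subsystem": "Methoxyphenol degradation",
        "biosystem": "microbe",
        "enzyme_name": "guaiacol O-demethylase",
        "ec_numbers": "1.14.99.15",
        "organism_refs": "FIX_ORG_ACETOBACTERIUM",
        "xrefs": "kegg:R05100",
    },
    {
        "reaction_id": "RXN_AZO",
        "reaction_smiles": (
            "[c:1]1([N:7]=[N:8][c:9]2([cH:10][cH:11][cH:12][cH:13][cH:14]2))"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ".[CH:20](=[O:21])[OH:22].[CH:23](=[O:24])[OH:25]"
            ">>[c:1]1([NH2:7])[cH:2][cH:3][cH:4][cH:5][cH:6]1"
            ".[NH2:8][c:9]1[cH:10][cH:11][cH:12][cH:13][cH:14]1"
            ".[O:21]=[C:20]=[O:22].[O:24]=[C:23]=[O:25]"
        ),
        "direction": "forward",
        "subsystem": "Azo dye degradation",
        "biosystem": "microbe",
        "enzyme_name": "azoreductase",
        "ec_numbers": "1.7.1.17",
        "organism_refs": "FIX_ORG_CPERFRINGENS",
        "xrefs": "seed:rxn90002",
    },
    # --- deliberately invalid records ---
    {
        "reaction_id": "BAD_TRANSPORT",
        "reaction_smiles": "OCC1OC(O)C(O)C(O)C1O[e]>>OCC1OC(O)C(O)C(O)C1O[c]",
        "direction": "forward",
        "subsystem": "Transport, extracellular",
        "biosystem": "microbe",
        "enzyme_name": "glucose permease",
        "ec_numbers": "",
        "organism_refs": "",
        "xrefs": "",
    },
    {
        "reaction_id": "BAD_UNBALANCED",
        "reaction_smiles": "OCC1OC(O)C(O)C(O)C1O>>CC(O)C(=O)O",
        "direction": "forward",
        "subsystem": "Glycolysis",
        "biosystem": "microbe",
        "enzyme_name": "",
        "ec_numbers": "",
        "organism_refs": "",
        "xrefs": "",
    },
    {
        "reaction_id": "BAD_STEREO",
        "reaction_smiles": "C[C@H](N)C(=O)O>>C[C@@H](N)C(=O)O",
        "direction": "forward",
        "subsystem": "Alanine metabolism",
        "biosystem": "microbe",
        "enzyme_name": "alanine racemase",
        "ec_numbers": "5.1.1.1",
        "organism_refs": "",
        "xrefs": "",
    },
]

_QUERIES: list[tuple[str, str]] = [
    ("levodopa", "NC(Cc1ccc(O)c(O)c1)C(=O)O"),
    ("nitrotoluene", "Cc1ccc([N+](=O)[O-])cc1"),
    ("phenyl_acetate", "CC(=O)Oc1ccccc1"),
]

# query_id -> (expected product SMILES, reaction that produces it)
_REFERENCE: dict[str, tuple[str, str]] = {
    "levodopa": ("NCCc1ccc(O)c(O)c1", "RXN_DECARB"),          # dopamine
    "nitrotoluene": ("Cc1ccc(N)cc1", "RXN_NITRO"),            # p-toluidine
    "phenyl_acetate": ("Oc1ccccc1", "RXN_ESTER"),             # phenol
}

_DECOY_POOL = [
    "c1ccncc1", "C1CCOC1", "CC(C)CO", "c1ccc2[nH]ccc2c1", "CCOC(=O)C",
    "CC(=O)Nc1ccc(O)cc1", "OCC(O)CO", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
]


@dataclass(frozen=True)
class FixtureSet:
    reactions: tuple[ReactionRecord, ...]
    queries: tuple[MoleculeRecord, ...]
    reference_metabolites: dict[str, tuple[str, str]] = field(compare=False)
    seed: int = 0

    def reaction_tsv_rows(self) -> list[dict[str, str]]:
        return [dict(r) for r in _ROWS]


def make_fixture_set(seed: int = 0, n_decoys: int = 0) -> FixtureSet:
    """Build the fixture set: 5 valid biotransformations, 3 invalid records,
    3 annotated queries with known products, and optional decoy queries.

    Equal seeds give byte-identical serialized output.
    """
    rng = random.Random(seed)
    queries = [sanitize_molecule(smi, identifier=qid) for qid, smi in _QUERIES]
    pool = list(_DECOY_POOL)
    rng.shuffle(pool)
    for i, smi in enumerate(pool[:n_decoys]):
        queries.append(sanitize_molecule(smi, identifier=f"decoy_{i}"))
    reference = {
        qid: (sanitize_molecule(smi).key, rxn_id)
        for qid, (smi, rxn_id) in _REFERENCE.items()
    }
    # Parse reactions through the real TSV route so the fixture exercises it.
    import io as _io
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        _write_reaction_tsv(fh)
        tsv_path = fh.name
    try:
        reactions = tuple(read_reaction_table(tsv_path, format="tsv"))
    finally:
        Path(tsv_path).unlink(missing_ok=True)
    del _io
    return FixtureSet(
        reactions=reactions,
        queries=tuple(queries),
        reference_metabolites=reference,
        seed=seed,
    )


def _write_reaction_tsv(fh) -> None:
    fh.write("\t".join(TSV_COLUMNS) + "\n")
    for row in _ROWS:
        fh.write("\t".join(row.get(c, "") for c in TSV_COLUMNS) + "\n")


def write_fixture_files(fs: FixtureSet, outdir: str | Path) -> dict[str, Path]:
    """Emit the reaction TSV, query SMILES file, and reference-metabolite TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": outdir / "reactions.tsv",
        "queries": outdir / "queries.smi",
        "reference": outdir / "reference_metabolites.tsv",
    }
    with open(paths["reactions"], "w") as fh:
        _write_reaction_tsv(fh)
    with open(paths["queries"], "w") as fh:
        for q in fs.queries:
            fh.write(f"{q.structure}\t{q.identifier}\n")
    with open(paths["reference"], "w") as fh:
        fh.write("query_id\tproduct_smiles\treaction_id\n")
        for qid, (key, rxn_id) in sorted(fs.reference_metabolites.items()):
            fh.write(f"{qid}\t{key}\t{rxn_id}\n")
    return paths
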
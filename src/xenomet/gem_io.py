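"""Reading, classifying, and filtering reactions from genome-scale-model exports.

Only genuine biotransformations — reactions that change atom connectivity —
are useful for rule extraction, so transport, exchange, passive diffusion,
biomass assembly, and pure stereochemical conversions are classified and
excluded, as are elementally unbalanced or incomplete records.

Three input routes are supported: a tab-separated reaction table (the
reference schema of this package), a model-JSON export mirroring the usual
id/metabolites/stoichiometry layout, and SBML via cobrapy (metabolite SMILES
read from the SBML notes).
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace

from .chem_core import MoleculeRecord, SanitizationError, sanitize_molecule

__all__ = [
    "Participant",
    "ReactionRecord",
    "ReactionClass",
    "BalanceResult",
    "AuditEntry",
    "read_reaction_table",
    "classify_reaction",
    "check_balance",
    "filter_reactions",
    "expand_reversible",
]

TSV_COLUMNS = [
    "reaction_id",
    "reaction_smiles",
    "direction",
    "subsystem",
    "biosystem",
    "enzyme_name",
    "ec_numbers",
    "organism_refs",
    "xrefs",
]

_COMPARTMENT_RE = re.compile(r"\[([A-Za-z][A-Za-z0-9_]*)\]$")


@dataclass(frozen=True)
class Participant:
    """One substrate or product slot of a reaction."""

    raw: str  # SMILES as given, atom maps preserved
    stoichiometry: float = 1.0
    compartment: str = ""
    record: MoleculeRecord | None = None
    error: str = ""


class ReactionClass(enum.Enum):
    BIOTRANSFORMATION = "biotransformation"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    PASSIVE_DIFFUSION = "passive_diffusion"
    BIOMASS = "biomass"
    STEREO_ONLY = "stereo_only"
    UNBALANCED = "unbalanced"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    substrates: tuple[Participant, ...]
    products: tuple[Participant, ...]
    direction: str = "forward"  # forward | reversible
    subsystem: str = ""
    biosystem: str = "both"  # human | microbe | both
    enzyme_name: str = ""
    ec_numbers: tuple[str, ...] = ()
    organism_refs: tuple[str, ...] = ()
    xrefs: dict[str, str] = field(default_factory=dict, compare=False)
    is_boundary: bool = False

    def participants(self) -> tuple[Participant, ...]:
        return self.substrates + self.products


@dataclass(frozen=True)
class BalanceResult:
    balanced: bool
    deltas: dict[str, float]  # element -> (products - substrates); "charge" entry included
    mode: str


@dataclass(frozen=True)
class AuditEntry:
    reaction_id: str
    reaction_class: ReactionClass
    detail: str = ""


class ReactionTableError(ValueError):
    """Malformed reaction file; carries the offending record locus."""


def _parse_participant(token: str) -> Participant:
    token = token.strip()
    stoich = 1.0
    parts = token.split(None, 1)
    if len(parts) == 2:
        try:
            stoich = float(parts[0])
            token = parts[1].strip()
        except ValueError:
            pass
    compartment = ""
    m = _COMPARTMENT_RE.search(token)
    if m:
        compartment = m.group(1)
        token = token[: m.start()]
    if not token:
        return Participant(raw="", stoichiometry=stoich, compartment=compartment,
                           error="empty structure")
    try:
        rec = sanitize_molecule(token)
        return Participant(raw=token, stoichiometry=stoich, compartment=compartment,
                           record=rec)
    except SanitizationError as exc:
        return Participant(raw=token, stoichiometry=stoich, compartment=compartment,
                           error=exc.reason)


def _parse_reaction_smiles(rxn: str) -> tuple[tuple[Participant, ...], tuple[Participant, ...]]:
    if ">>" not in rxn:
        raise ReactionTableError(f"reaction SMILES lacks '>>': {rxn!r}")
    left, right = rxn.split(">>", 1)

    def side(s: str) -> tuple[Participant, ...]:
        toks = [t for t in s.split(".") if t.strip()]
        return tuple(_parse_participant(t) for t in toks)

    return side(left), side(right)


def _split_list(text: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in text.split(";") if t.strip())


def _row_to_record(row: dict[str, str], locus: str) -> ReactionRecord:
    try:
        subs, prods = _parse_reaction_smiles(row["reaction_smiles"])
    except ReactionTableError as exc:
        raise ReactionTableError(f"{locus}: {exc}") from exc
    xrefs: dict[str, str] = {}
    for item in _split_list(row.get("xrefs", "")):
        if ":" in item:
            k, v = item.split(":", 1)
            xrefs[k.strip()] = v.strip()
    return ReactionRecord(
        reaction_id=row["reaction_id"],
        substrates=subs,
        products=prods,
        direction=row.get("direction", "forward") or "forward",
        subsystem=row.get("subsystem", ""),
        biosystem=row.get("biosystem", "both") or "both",
        enzyme_name=row.get("enzyme_name", ""),
        ec_numbers=_split_list(row.get("ec_numbers", "")),
        organism_refs=_split_list(row.get("organism_refs", "")),
        xrefs=xrefs,
    )


def _read_tsv(path: str) -> list[ReactionRecord]:
    records = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if "reaction_id" not in header or "reaction_smiles" not in header:
            raise ReactionTableError(f"{path}:1: header must contain reaction_id and reaction_smiles")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            row = dict(zip(header, fields))
            records.append(_row_to_record(row, f"{path}:{lineno}"))
    return records


def _read_model_json(path: str) -> list[ReactionRecord]:
    with open(path) as fh:
        model = json.load(fh)
    mets = {m["id"]: m for m in model.get("metabolites", [])}
    records = []
    for rx in model.get("reactions", []):
        subs, prods = [], []
        for mid, stoich in rx.get("metabolites", {}).items():
            if mid not in mets:
                raise ReactionTableError(f"{path}: reaction {rx.get('id')} references unknown metabolite {mid}")
            m = mets[mid]
            part = _parse_participant(m.get("smiles", ""))
            part = replace(part, stoichiometry=abs(float(stoich)),
                           compartment=m.get("compartment", part.compartment))
            (subs if stoich < 0 else prods).append(part)
        xref = rx.get("xrefs", {})
        records.append(ReactionRecord(
            reaction_id=rx["id"],
            substrates=tuple(subs),
            products=tuple(prods),
            direction=rx.get("direction", "forward"),
            subsystem=rx.get("subsystem", ""),
            biosystem=rx.get("biosystem", "both"),
            enzyme_name=rx.get("enzyme_name", ""),
            ec_numbers=tuple(rx.get("ec_numbers", [])),
            organism_refs=tuple(rx.get("organism_refs", [])),
            xrefs=dict(xref),
            is_boundary=bool(rx.get("boundary", False)),
        ))
    return records


def _read_sbml(path: str) -> list[ReactionRecord]:
    # cobrapy handles the SBML parsing; structures must sit in metabolite
    # notes under "smiles" (metabolites without one are classed incomplete).
    import cobra.io

    model = cobra.io.read_sbml_model(path)
    records = []
    for rx in model.reactions:
        subs, prods = [], []
        for met, stoich in rx.metabolites.items():
            smiles = met.notes.get("smiles", "") if met.notes else ""
            part = _parse_participant(smiles)
            part = replace(part, stoichiometry=abs(float(stoich)),
                           compartment=met.compartment or "")
            (subs if stoich < 0 else prods).append(part)
        records.append(ReactionRecord(
            reaction_id=rx.id,
            substrates=tuple(subs),
            products=tuple(prods),
            direction="reversible" if rx.reversibility else "forward",
            subsystem=rx.subsystem or "",
            is_boundary=rx.boundary,
        ))
    return records


def read_reaction_table(path: str, format: str = "tsv") -> list[ReactionRecord]:
    """Read reactions from ``tsv``, ``model_json``, or ``sbml`` input.

    Every row yields a record; rows with unparseable structures are kept and
    later classed ``incomplete`` rather than silently dropped.
    """
    readers = {"tsv": _read_tsv, "model_json": _read_model_json, "sbml": _read_sbml}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path)


def _key_multiset(parts: tuple[Participant, ...]) -> dict[tuple[str, str], float] | None:
    """Canonical-key multiset of one side, or None if any structure is missing."""
    out: dict[tuple[str, str], float] = {}
    for p in parts:
        if p.record is None:
            return None
        k = (p.record.key, "")
        out[k] = out.get(k, 0.0) + p.stoichiometry
    return out


_BIOMASS_RE = re.compile(r"biomass", re.IGNORECASE)


def check_balance(rec: ReactionRecord, mode: str = "slack") -> BalanceResult:
    """Elemental balance check: per-element stoichiometric sums must agree.

    ``slack`` mode tolerates hydrogen and net-charge imbalance (GEM exports
    routinely omit protons); ``strict`` requires every element to balance.
    Missing structures make the reaction incomplete, not unbalanced.
    """
    if mode not in ("slack", "strict"):
        raise ValueError(f"unknown balance mode {mode!r}")
    deltas: dict[str, float] = {}
    for sign, parts in ((-1, rec.substrates), (1, rec.products)):
        for p in parts:
            if p.record is None:
                raise ValueError(f"{rec.reaction_id}: participant {p.raw!r} has no structure")
            for elem, n in p.record.formula.items():
                deltas[elem] = deltas.get(elem, 0.0) + sign * n * p.stoichiometry
    deltas = {k: round(v, 9) for k, v in deltas.items()}
    checked = {k: v for k, v in deltas.items() if not (mode == "slack" and k in ("H", "charge"))}
    balanced = all(abs(v) < 1e-6 for v in checked.values())
    return BalanceResult(balanced=balanced, deltas={k: v for k, v in deltas.items() if v != 0},
                         mode=mode)


def classify_reaction(rec: ReactionRecord, balance_mode: str = "slack") -> ReactionClass:
    """Assign exactly one :class:`ReactionClass` to a parsed record.

    Transport (which subsumes passive diffusion) is detected structurally:
    identical canonical-key multisets on both sides with differing
    compartment tags. Biomass is detected by its subsystem/id designation
    because biomass pseudo-metabolites carry no structures.
    """
    if rec.is_boundary or not rec.substrates or not rec.products:
        return ReactionClass.EXCHANGE
    if _BIOMASS_RE.search(rec.reaction_id) or _BIOMASS_RE.search(rec.subsystem):
        return ReactionClass.BIOMASS
    if any(p.record is None for p in rec.participants()):
        return ReactionClass.INCOMPLETE

    sub_keys, prod_keys = _key_multiset(rec.substrates), _key_multiset(rec.products)
    if sub_keys == prod_keys:
        sub_comp = sorted(p.compartment for p in rec.substrates)
        prod_comp = sorted(p.compartment for p in rec.products)
        if sub_comp != prod_comp:
            return ReactionClass.TRANSPORT
        return ReactionClass.STEREO_ONLY
    if not check_balance(rec, mode=balance_mode).balanced:
        return ReactionClass.UNBALANCED
    return ReactionClass.BIOTRANSFORMATION


def filter_reactions(
    records: list[ReactionRecord], balance_mode: str = "slack"
) -> tuple[list[ReactionRecord], list[AuditEntry]]:
    """Partition records into retained biotransformations and an audit log.

    Every input record lands in exactly one of the two outputs; nothing is
    dropped silently. Running the filter on its own retained output is a
    fixed point.
    """
    retained: list[ReactionRecord] = []
    audit: list[AuditEntry] = []
    for rec in records:
        cls = classify_reaction(rec, balance_mode=balance_mode)
        if cls is ReactionClass.BIOTRANSFORMATION:
            retained.append(rec)
        else:
            detail = ""
            if cls is ReactionClass.UNBALANCED:
                detail = str(check_balance(rec, mode=balance_mode).deltas)
            elif cls is ReactionClass.INCOMPLETE:
                detail = "; ".join(
                    f"{p.raw!r}: {p.error}" for p in rec.participants() if p.record is None
                )
            audit.append(AuditEntry(rec.reaction_id, cls, detail))
    return retained, audit


def expand_reversible(records: list[ReactionRecord]) -> list[ReactionRecord]:
    """Expand reversible reactions into two directed records.

    Reaction rules are directional, so a reversible reaction contributes a
    forward and a reversed copy, sharing its id with a direction suffix.
    """
    out: list[ReactionRecord] = []
    for rec in records:
        if rec.direction != "reversible":
            out.append(rec)
            continue
        out.append(replace(rec, reaction_id=rec.reaction_id + "_fwd", direction="forward"))
        out.append(replace(rec, reaction_id=rec.reaction_id + "_rev", direction="forward",
                           substrates=rec.products, products=rec.substrates))
    return out
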
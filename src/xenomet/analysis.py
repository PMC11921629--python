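"""Physicochemical profiling, structural alerts, isotope patterns,
deduplication, benchmark statistics, and chemical-space projection.

These are the downstream computations applied to predicted metabolites:
drug-likeness (rule of five), passive-absorption classification
(BOILED-Egg ellipses in the TPSA/LogP plane), assay-interference and
toxicity alerts (PAINS/Brenk catalogs), isotopic envelopes for
mass-spectrometric follow-up, exact-structure benchmarking against
reference metabolite lists, and PCA projection of fingerprint space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chem_core import MoleculeRecord, fingerprint, mol_from_record

__all__ = [
    "DescriptorProfile",
    "BenchmarkStats",
    "ReferenceMetabolite",
    "MatchReport",
    "compute_descriptors",
    "lipinski_check",
    "boiled_egg_classify",
    "structural_alerts",
    "isotope_pattern",
    "dedupe_structures",
    "whisker_threshold",
    "evaluate_exact_matches",
    "project_chemical_space",
    "AnnotationProvider",
    "NullAnnotator",
]


@dataclass(frozen=True)
class DescriptorProfile:
    molecular_weight: float  # Da
    logp: float              # Wildman-Crippen atomic-contribution estimate
    tpsa: float              # topological polar surface area, A^2
    hbd: int
    hba: int                 # N+O count (classic rule-of-five reading)
    rotatable_bonds: int


def compute_descriptors(mol: MoleculeRecord) -> DescriptorProfile:
    m = mol_from_record(mol)
    return DescriptorProfile(
        molecular_weight=Descriptors.MolWt(m),
        logp=Crippen.MolLogP(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(m),
        hba=sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8)),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(m),
    )


def lipinski_check(profile: DescriptorProfile) -> dict[str, bool]:
    """Rule of five with inclusive boundaries; ``pass`` iff all four hold."""
    rules = {
        "molecular_weight": profile.molecular_weight <= 500.0,
        "logp": profile.logp <= 5.0,
        "hbd": profile.hbd <= 5,
        "hba": profile.hba <= 10,
    }
    rules["pass"] = all(rules.values())
    return rules


# Best-fit ellipses of the BOILED-Egg passive-permeation model in the
# (TPSA, WLOGP) plane: the white region predicts gastrointestinal
# absorption, the yolk predicts brain penetration.
# (center_x, center_y, full major axis, full minor axis, rotation in degrees)
_WHITE_ELLIPSE = (71.051, 2.292, 142.081, 8.740, -1.031325)
_YOLK_ELLIPSE = (38.117, 3.177, 82.061, 5.557, -0.171887)


def _in_ellipse(x: float, y: float, ellipse: tuple[float, float, float, float, float]) -> bool:
    x0, y0, major, minor, rot_deg = ellipse
    th = math.radians(rot_deg)
    dx, dy = x - x0, y - y0
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / (major / 2)) ** 2 + (v / (minor / 2)) ** 2 <= 1.0


def boiled_egg_classify(profile: DescriptorProfile) -> dict[str, bool]:
    """Point-in-ellipse classification of a descriptor profile.

    Pure function of (tpsa, logp); the yolk lies inside the white region,
    so brain penetration implies predicted absorption in the model's
    geometry.
    """
    return {
        "gastrointestinal_absorption": _in_ellipse(profile.tpsa, profile.logp, _WHITE_ELLIPSE),
        "brain_penetration": _in_ellipse(profile.tpsa, profile.logp, _YOLK_ELLIPSE),
    }


_CATALOGS: dict[str, FilterCatalog] = {}


def _catalog(name: str) -> FilterCatalog:
    if name not in _CATALOGS:
        params = FilterCatalogParams()
        if name == "pains":
            params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        elif name == "brenk":
            params.AddCatalog(FilterCatalogParams.FilterCatalogs.BRENK)
        else:
            raise ValueError(f"unknown alert catalog {name!r}; expected 'pains' or 'brenk'")
        _CATALOGS[name] = FilterCatalog(params)
    return _CATALOGS[name]


def structural_alerts(mol: MoleculeRecord, catalog: str) -> list[str]:
    """Names of matched alert substructures from the published catalogs."""
    m = mol_from_record(mol)
    return sorted(e.GetDescription() for e in _catalog(catalog).GetMatches(m))


# Isotope masses (Da) and natural abundances for the supported elements.
_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "P": [(30.97376151, 1.0)],
    "S": [(31.97207069, 0.9499), (32.97145850, 0.0075), (33.96786683, 0.0425),
          (35.96708088, 0.0001)],
    "F": [(18.99840320, 1.0)],
    "Cl": [(34.96885271, 0.7576), (36.96590260, 0.2424)],
    "Br": [(78.9183376, 0.5069), (80.9162910, 0.4931)],
    "I": [(126.904468, 1.0)],
}

_TRUNCATION = 1e-6  # relative abundance below which peaks are discarded


def isotope_pattern(formula: dict[str, int] | str) -> list[tuple[float, float]]:
    """Isotopic envelope of an elemental formula at nominal-mass resolution.

    Per-element isotope distributions are convolved, peaks are aggregated
    into nominal-mass bins (abundance-weighted mean mass per bin), low
    peaks are truncated at 1e-6 relative abundance, and probabilities are
    renormalized to sum to 1.
    """
    if isinstance(formula, str):
        formula = _parse_formula(formula)
    # Distribution over nominal-mass offsets from the monoisotopic peak.
    # Per offset we track (probability, probability-weighted total mass) so
    # each aggregated peak reports its abundance-weighted mean mass.
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for elem, count in formula.items():
        if elem not in _ISOTOPES:
            raise ValueError(f"unsupported element {elem!r} in formula")
        isos = _ISOTOPES[elem]
        base_nominal = round(isos[0][0])
        single = [(round(m) - base_nominal, p, m) for m, p in isos]
        for _ in range(count):
            new: dict[int, tuple[float, float]] = {}
            for off, (p, moment) in dist.items():
                for doff, ip, imass in single:
                    prob = p * ip
                    if prob < _TRUNCATION * 1e-3:
                        continue
                    prev_p, prev_m = new.get(off + doff, (0.0, 0.0))
                    new[off + doff] = (prev_p + prob, prev_m + moment * ip + prob * imass)
            dist = new
    total = sum(p for p, _ in dist.values())
    peaks = [(moment / p, p) for off, (p, moment) in sorted(dist.items())
             if p / total >= _TRUNCATION]
    norm = sum(p for _, p in peaks)
    return [(m, p / norm) for m, p in peaks]


def _parse_formula(text: str) -> dict[str, int]:
    import re

    out: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if not sym:
            continue
        out[sym] = out.get(sym, 0) + (int(num) if num else 1)
    return out


def dedupe_structures(mols: list[MoleculeRecord]) -> list[tuple[MoleculeRecord, int]]:
    """One representative per canonical key, first-seen identifier retained,
    with the multiplicity of each structure. Multiplicities sum to the
    input size."""
    seen: dict[str, int] = {}
    reps: list[MoleculeRecord] = []
    counts: list[int] = []
    for m in mols:
        if m.key in seen:
            counts[seen[m.key]] += 1
        else:
            seen[m.key] = len(reps)
            reps.append(m)
            counts.append(1)
    return list(zip(reps, counts))


@dataclass(frozen=True)
class BenchmarkStats:
    q1: float
    q3: float
    iqr: float
    upper_whisker: float  # q3 + 1.5 * iqr
    n_total: int
    n_above: int          # scores strictly above the whisker


def whisker_threshold(scores, convention: str = "linear") -> BenchmarkStats:
    """Tukey upper-whisker statistics of a score distribution.

    ``linear`` interpolates between order statistics (the common quantile
    default); ``tukey`` uses Tukey hinges (medians of the lower/upper
    halves). Requires at least 4 finite scores.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 4 or not np.all(np.isfinite(arr)):
        raise ValueError("whisker_threshold requires >= 4 finite scores")
    if convention == "linear":
        q1, q3 = np.quantile(arr, [0.25, 0.75])
    elif convention == "tukey":
        s = np.sort(arr)
        half = (s.size + 1) // 2
        q1, q3 = np.median(s[:half]), np.median(s[-half:])
    else:
        raise ValueError(f"unknown quantile convention {convention!r}")
    iqr = q3 - q1
    whisker = q3 + 1.5 * iqr
    return BenchmarkStats(
        q1=float(q1), q3=float(q3), iqr=float(iqr), upper_whisker=float(whisker),
        n_total=int(arr.size), n_above=int(np.sum(arr > whisker)),
    )


@dataclass(frozen=True)
class ReferenceMetabolite:
    query_id: str
    product_key: str        # canonical key of the expected metabolite
    reaction_id: str = ""   # optional; required to agree in strict mode


@dataclass(frozen=True)
class MatchReport:
    n_matched: int
    n_reference: int
    fraction: float
    matched_ids: tuple[str, ...]


def evaluate_exact_matches(predictions, reference: list[ReferenceMetabolite],
                           strict: bool = False) -> MatchReport:
    """Exact-match benchmark: a reference metabolite counts as recovered iff
    some prediction for its query has an equal canonical key (and, in
    strict mode, the same reaction id when the reference carries one)."""
    if not reference:
        raise ValueError("empty reference set")
    by_query: dict[str, set[tuple[str, str]]] = {}
    for p in predictions:
        by_query.setdefault(p.query_id, set()).add((p.main_product.key, p.reaction_id))
    matched = []
    for ref in reference:
        hits = by_query.get(ref.query_id, set())
        ok = any(
            key == ref.product_key and (not strict or not ref.reaction_id or rid == ref.reaction_id)
            for key, rid in hits
        )
        if ok:
            matched.append(ref.query_id)
    return MatchReport(
        n_matched=len(matched),
        n_reference=len(reference),
        fraction=len(matched) / len(reference),
        matched_ids=tuple(matched),
    )


def project_chemical_space(mols: list[MoleculeRecord]) -> tuple[np.ndarray, np.ndarray, bool]:
    """First two principal components of the Morgan-fingerprint matrix.

    Returns (coordinates [n, 2], explained-variance fractions [2],
    degenerate flag). The projection is degenerate when every fingerprint
    is identical (zero variance); coordinates are then all zero.
    """
    from sklearn.decomposition import PCA

    if len(mols) < 3:
        raise ValueError("projection requires >= 3 molecules")
    mat = np.zeros((len(mols), 2048), dtype=float)
    for i, m in enumerate(mols):
        fp = fingerprint(m, "circular")
        mat[i, list(fp.bits)] = 1.0
    if np.allclose(mat, mat[0]):
        return np.zeros((len(mols), 2)), np.zeros(2), True
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(mat)
    return coords, pca.explained_variance_ratio_.copy(), False


class AnnotationProvider:
    """Pluggable interface for external chemical-class/record annotation.

    Online services are out of scope; the default implementation returns
    no annotations so pipelines run fully offline.
    """

    def annotate(self, mol: MoleculeRecord) -> dict[str, str]:  # pragma: no cover - interface
        raise NotImplementedError


class NullAnnotator(AnnotationProvider):
    def annotate(self, mol: MoleculeRecord) -> dict[str, str]:
        return {}
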
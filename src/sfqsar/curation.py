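"""Chemical and endpoint curation for slope-factor QSAR datasets.

Raw toxicity tables pair a structure (SMILES) with a route-specific
carcinogenicity potency: an oral slope factor (OSF, (mg/kg-day)^-1) or an
inhalation unit risk (IUR, (ug/m3)^-1).  This module standardizes the
structures (neutralize, strip counterions, reject inorganics / metal
complexes / unresolvable mixtures), converts IUR to an inhalation slope
factor on the same dose scale as OSF, log-transforms endpoints for
modelling, deduplicates by canonical structure, and assembles the binary
carcinogen / non-carcinogen classification labels (a compound with a
defined slope factor is carcinogenic; one without is treated as
non-carcinogenic).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements permitted in an "organic" structure.  Anything else (metals,
#: metalloids outside this list) causes rejection as metal_or_complex.
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


class Route(str, Enum):
    ORAL = "oral"
    INHALATION = "inhalation"


class Units(str, Enum):
    PER_MG_KG_DAY = "per_mg_kg_day"
    PER_UG_M3 = "per_ug_m3"


class RejectionReason(str, Enum):
    INORGANIC = "inorganic"
    METAL_OR_COMPLEX = "metal_or_complex"
    MIXTURE = "mixture_or_salt_unresolvable"
    PARSE_FAILURE = "parse_failure"
    DUPLICATE_CONFLICT = "duplicate_conflict"


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical: identifier, canonical structure, route and endpoint.

    ``raw_value`` is ``None`` for compounds with no reported potency;
    such records are candidate non-carcinogens for classification and are
    excluded from regression.  When present it must be strictly positive.
    """

    identifier: str
    smiles: str
    route: Route
    raw_value: float | None = None
    raw_units: Units | None = None
    label: int | None = None  # binary class; set by build_classification_dataset

    def __post_init__(self) -> None:
        if self.raw_value is not None and not self.raw_value > 0:
            raise ValueError(
                f"{self.identifier}: raw_value must be > 0 when present, "
                f"got {self.raw_value!r}"
            )


@dataclass
class CuratedDataset:
    """Deduplicated records plus a log of rejected entries."""

    records: list[CompoundRecord]
    rejected: list[tuple[str, RejectionReason]] = field(default_factory=list)
    endpoint_scale: str = "raw_sf"  # raw_sf | log10_sf | binary

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if r.label is not None:
                counts[r.label] = counts.get(r.label, 0) + 1
        return counts


@dataclass(frozen=True)
class ExposureConstants:
    """Defaults for the adult exposure scenario used to convert IUR to ISF."""

    bw: float = 70.0  # body weight, kg
    ir: float = 20.0  # inhalation rate, m3/day
    cf: float = 1000.0  # unit conversion, ug/mg

    def __post_init__(self) -> None:
        if min(self.bw, self.ir, self.cf) <= 0:
            raise ValueError("exposure constants must be strictly positive")


class StructureRejection(Exception):
    def __init__(self, reason: RejectionReason):
        self.reason = reason
        super().__init__(reason.value)


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str:
    """Return a canonical, neutralized, counterion-free SMILES.

    Fragments with fewer than two heavy atoms (counterions, waters of
    hydration) are stripped when the input has several fragments.  The
    surviving parent must be a single organic fragment built only from
    :data:`ALLOWED_ELEMENTS` and must contain carbon.

    Raises :class:`StructureRejection` with the applicable reason
    otherwise (``parse_failure``, ``mixture_or_salt_unresolvable``,
    ``metal_or_complex``, ``inorganic``).
    """
    if not smiles or not smiles.strip():
        raise StructureRejection(RejectionReason.PARSE_FAILURE)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureRejection(RejectionReason.PARSE_FAILURE)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        parent = frags[0]
    else:
        # counterion stripping: drop single-heavy-atom fragments
        candidates = [f for f in frags if f.GetNumHeavyAtoms() >= 2]
        if len(candidates) == 0:
            # nothing organic-sized left, e.g. [Na+].[Cl-]
            raise StructureRejection(_elemental_reason(mol))
        if len(candidates) > 1:
            # distinct multi-atom components: a true mixture (identical
            # copies of one parent, e.g. a 2:1 salt, are collapsed)
            uniq = {Chem.MolToSmiles(c) for c in candidates}
            if len(uniq) > 1:
                raise StructureRejection(RejectionReason.MIXTURE)
        parent = candidates[0]

    for atom in parent.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise StructureRejection(RejectionReason.METAL_OR_COMPLEX)
    if not any(a.GetSymbol() == "C" for a in parent.GetAtoms()):
        raise StructureRejection(RejectionReason.INORGANIC)

    parent = _UNCHARGER.uncharge(parent)
    Chem.SanitizeMol(parent)
    return Chem.MolToSmiles(parent)


def _elemental_reason(mol: Chem.Mol) -> RejectionReason:
    """Classify an all-small-fragment input: carbon-free simple salts are
    inorganic; anything carrying carbon alongside a disallowed element is
    a metal species."""
    if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
        return RejectionReason.INORGANIC
    return RejectionReason.METAL_OR_COMPLEX


def convert_iur_to_isf(
    iur: float, constants: ExposureConstants = ExposureConstants()
) -> float:
    """Convert an inhalation unit risk ((ug/m3)^-1) to an inhalation slope
    factor ((mg/kg-day)^-1): ISF = IUR * BW * CF / IR."""
    if iur < 0:
        raise ValueError("IUR must be nonnegative")
    return iur * constants.bw * constants.cf / constants.ir


def cancer_risk(cdi: float, sf: float) -> float:
    """Incremental lifetime cancer risk = chronic daily intake x slope factor."""
    if cdi < 0 or sf < 0:
        raise ValueError("CDI and SF must be nonnegative")
    return cdi * sf


def log_transform_endpoint(sf: float) -> float:
    """log10 of a slope factor; the modelling scale for regression."""
    if sf <= 0:
        raise ValueError("slope factor must be strictly positive for log transform")
    return math.log10(sf)


def deduplicate(records: Sequence[CompoundRecord]) -> CuratedDataset:
    """Collapse records sharing a canonical structure.

    Copies with identical endpoint values merge into one record (the first
    identifier wins); copies with conflicting values are all removed and
    logged once per identifier as ``duplicate_conflict`` — incongruent
    source data is rejected rather than averaged.
    """
    by_structure: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.smiles not in by_structure:
            order.append(r.smiles)
        by_structure.setdefault(r.smiles, []).append(r)

    kept: list[CompoundRecord] = []
    rejected: list[tuple[str, RejectionReason]] = []
    for smi in order:
        group = by_structure[smi]
        values = {g.raw_value for g in group}
        if len(values) == 1:
            kept.append(group[0])
        else:
            rejected.extend(
                (g.identifier, RejectionReason.DUPLICATE_CONFLICT) for g in group
            )
    return CuratedDataset(records=kept, rejected=rejected)


def build_classification_dataset(
    records: Sequence[CompoundRecord], route: Route
) -> CuratedDataset:
    """Label records for the carcinogen / non-carcinogen classifier.

    A record of the requested route with a defined endpoint is positive
    (label 1); one without is negative (label 0).
    """
    labeled = [
        replace(r, label=int(r.raw_value is not None))
        for r in records
        if r.route == route
    ]
    return CuratedDataset(records=labeled, endpoint_scale="binary")


def balance_classes(dataset: CuratedDataset, seed: int) -> CuratedDataset:
    """Randomly undersample the majority class to the minority size."""
    pos = [r for r in dataset.records if r.label == 1]
    neg = [r for r in dataset.records if r.label == 0]
    if not pos or not neg:
        raise ValueError("balance_classes requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        idx = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in sorted(idx)]
    elif len(neg) > len(pos):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(idx)]
    merged = {r.identifier: r for r in pos + neg}
    records = [r for r in dataset.records if r.identifier in merged]
    return CuratedDataset(
        records=records,
        rejected=list(dataset.rejected),
        endpoint_scale=dataset.endpoint_scale,
    )


def curate(
    raw: Iterable[dict], constants: ExposureConstants = ExposureConstants()
) -> CuratedDataset:
    """Full curation of raw rows (``id, smiles, route, value, units``).

    Standardizes every structure, converts IUR values to ISF so both routes
    share the (mg/kg-day)^-1 scale, then deduplicates.
    """
    records: list[CompoundRecord] = []
    rejected: list[tuple[str, RejectionReason]] = []
    for row in raw:
        ident = str(row["id"])
        try:
            smi = standardize_structure(row["smiles"])
        except StructureRejection as exc:
            rejected.append((ident, exc.reason))
            continue
        value = row.get("value")
        units = row.get("units")
        if value in (None, ""):
            value, units = None, None
        else:
            value = float(value)
            units = Units(units)
            if units == Units.PER_UG_M3:
                value = convert_iur_to_isf(value, constants)
                units = Units.PER_MG_KG_DAY
        records.append(
            CompoundRecord(
                identifier=ident,
                smiles=smi,
                route=Route(row["route"]),
                raw_value=value,
                raw_units=units,
            )
        )
    dataset = deduplicate(records)
    dataset.rejected = rejected + dataset.rejected
    return dataset


def read_raw_csv(path) -> list[dict]:
    """Read a raw endpoint table (header ``id,smiles,route,value,units``)."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def write_curated_csv(dataset: CuratedDataset, path, rejection_path=None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "route", "value", "units", "label"])
        for r in dataset.records:
            writer.writerow(
                [
                    r.identifier,
                    r.smiles,
                    r.route.value,
                    "" if r.raw_value is None else repr(r.raw_value),
                    "" if r.raw_units is None else r.raw_units.value,
                    "" if r.label is None else r.label,
                ]
            )
    if rejection_path is not None:
        with open(rejection_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "reason"])
            for ident, reason in dataset.rejected:
                writer.writerow([ident, reason.value])
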
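"""Synthetic datasets with known structure, plus a loader for the
published curated tables.

The generators produce planted-signal descriptor matrices (regression:
y linear in a known subset of descriptors plus Gaussian noise;
classification: two Gaussian classes separated along the informative
directions) and a toy SMILES dataset of simple organics whose synthetic
potency increases with ring and chlorine counts — mirroring the
structural trends real carcinogenicity models pick up (fused rings,
halogenation).  Everything is a pure function of its spec and seed, so
every pipeline stage can be tested without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .curation import CompoundRecord, CuratedDataset, Route, Units, curate
from .descriptors import DescriptorMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    n: int
    n_descriptors: int
    n_informative: int
    effect_weights: tuple = ()
    noise_sd: float = 0.0
    class_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative exceeds n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.effect_weights and len(self.effect_weights) != self.n_informative:
            raise ValueError("effect_weights length must equal n_informative")


def _descriptor_matrix(values: np.ndarray) -> DescriptorMatrix:
    n, p = values.shape
    names = [f"d{j:03d}" for j in range(p)]
    return DescriptorMatrix(
        compound_ids=[f"c{i:04d}" for i in range(n)],
        descriptor_names=names,
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        block_tags={nm: "synthetic" for nm in names},
    )


def generate_regression_fixture(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Standard-normal descriptors; y = Σ wᵢ·xᵢ over the first
    ``n_informative`` columns plus N(0, noise_sd²)."""
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal((spec.n, spec.n_descriptors))
    w = (np.asarray(spec.effect_weights, dtype=float)
         if spec.effect_weights else np.ones(spec.n_informative))
    y = x[:, : spec.n_informative] @ w
    if spec.noise_sd > 0:
        y = y + rng.normal(0, spec.noise_sd, size=spec.n)
    return _descriptor_matrix(x), y


def generate_classification_fixture(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Two balanced Gaussian classes: class 1 is shifted by
    class_separation / √n_informative along each informative axis, so the
    between-class Mahalanobis distance equals class_separation."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.integers(0, 2, size=spec.n)
    x = rng.standard_normal((spec.n, spec.n_descriptors))
    shift = spec.class_separation / max(np.sqrt(spec.n_informative), 1.0)
    x[:, : spec.n_informative] += shift * labels[:, None]
    return _descriptor_matrix(x), labels


def _build_toy_smiles() -> list[tuple[str, str]]:
    """Simple organics spanning alkanes, chlorinated benzenes, PAH cores
    and nitrosamines, built combinatorially so the pool is large enough
    for split/train exercises after deduplication."""
    out: list[tuple[str, str]] = []
    for k in range(1, 9):  # aliphatic series
        chain = "C" * k
        out.append((f"alkane{k}", chain))
        out.append((f"alcohol{k}", chain + "O"))
        out.append((f"chloroalkane{k}", chain + "Cl"))
        out.append((f"amine{k}", chain + "N"))
    aromatics = [
        ("benzene", "c1ccccc1"),
        ("naphthalene", "c1ccc2ccccc2c1"),
        ("anthracene", "c1ccc2cc3ccccc3cc2c1"),
        ("phenanthrene", "c1ccc2ccc3ccccc3c2c1"),
        ("pyrene", "c1cc2ccc3cccc4ccc(c1)c2c34"),
    ]
    for name, smi in aromatics:
        out.append((name, smi))
        for sub, tag in (("C", "methyl"), ("Cl", "chloro"),
                         ("O", "hydroxy"), ("N", "amino"), ("CC", "ethyl")):
            out.append((f"{tag}_{name}", sub + smi))  # substituted ring
    out += [
        ("chlorobenzene", "Clc1ccccc1"),
        ("dichlorobenzene", "Clc1ccccc1Cl"),
        ("trichlorobenzene", "Clc1ccc(Cl)c(Cl)c1"),
        ("hexachlorobenzene", "Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl"),
        ("chloroform", "ClC(Cl)Cl"),
        ("carbon_tet", "ClC(Cl)(Cl)Cl"),
        ("ndma", "CN(C)N=O"), ("ndea", "CCN(CC)N=O"),
        ("styrene", "C=Cc1ccccc1"), ("vinyl_chloride", "C=CCl"),
        ("acetone", "CC(C)=O"), ("acetic_acid", "CC(=O)O"),
    ]
    return out


_TOY_SMILES = _build_toy_smiles()


def generate_toy_smiles_dataset(
    n: int, seed: int = 0, route: Route = Route.ORAL
) -> list[CompoundRecord]:
    """Sample simple organics with synthetic potencies.

    Endpoint rule: log10 SF = 0.6·(ring count) + 0.3·(chlorine count) −
    1 + N(0, 0.1), so fused-ring and polychlorinated entries get higher
    endpoints than small alkanes.  Roughly a third of compounds are
    emitted without a value (candidate non-carcinogens).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(_TOY_SMILES))
    records = []
    for i in range(n):
        idx = int(order[i % len(_TOY_SMILES)])
        name, smi = _TOY_SMILES[idx]
        mol = Chem.MolFromSmiles(smi)
        rings = mol.GetRingInfo().NumRings()
        ncl = sum(a.GetSymbol() == "Cl" for a in mol.GetAtoms())
        # endpoint is a pure function of (structure, seed): re-drawn copies
        # of one structure agree, so deduplication merges instead of
        # rejecting a value conflict
        struct_rng = np.random.default_rng(seed * 100003 + idx)
        if struct_rng.random() < 0.35:
            value = None
        else:
            log_sf = 0.6 * rings + 0.3 * ncl - 1.0 + struct_rng.normal(0, 0.1)
            value = float(10.0**log_sf)
        records.append(
            CompoundRecord(
                identifier=f"{name}_{i}",
                smiles=Chem.MolToSmiles(mol),
                route=route,
                raw_value=value,
                raw_units=Units.PER_MG_KG_DAY if value is not None else None,
            )
        )
    return records


def load_curated_table(path) -> CuratedDataset:
    """Parse a user-downloaded curated endpoint table into a dataset.

    Schema-tolerant: accepts any CSV whose header contains recognizable
    identifier, SMILES, value and (optionally) route/units columns, in
    any case or spelling variant.  Never fetched automatically.
    """
    aliases = {
        "id": {"id", "identifier", "cas", "cas_number", "casrn", "no", "name"},
        "smiles": {"smiles", "canonical_smiles", "structure"},
        "value": {"value", "sf", "osf", "isf", "iur", "slope_factor",
                  "endpoint", "experimental_value"},
        "route": {"route", "exposure_route", "exposure"},
        "units": {"units", "unit"},
    }
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty file") from None
        colmap: dict[str, int] = {}
        for want, names in aliases.items():
            for j, h in enumerate(header):
                if h.strip().lower().replace(" ", "_") in names:
                    colmap[want] = j
                    break
        if "smiles" not in colmap or "value" not in colmap:
            raise ValueError(
                f"schema mismatch: need SMILES and value columns, got {header}"
            )
        header_lower = [h.lower() for h in header]
        default_route = ("inhalation"
                         if any("iur" in h or "isf" in h or "inhal" in h
                                for h in header_lower) else "oral")
        default_units = ("per_ug_m3"
                         if any("iur" in h for h in header_lower)
                         else "per_mg_kg_day")
        rows = []
        for i, rec in enumerate(reader):
            if not any(field.strip() for field in rec):
                continue
            value = rec[colmap["value"]].strip()
            rows.append({
                "id": rec[colmap["id"]] if "id" in colmap else f"row{i}",
                "smiles": rec[colmap["smiles"]],
                "route": (rec[colmap["route"]].strip().lower()
                          if "route" in colmap and rec[colmap["route"]].strip()
                          else default_route),
                "value": value or None,
                "units": (rec[colmap["units"]].strip()
                          if "units" in colmap and rec[colmap["units"]].strip()
                          else default_units) if value else None,
            })
    return curate(rows)
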
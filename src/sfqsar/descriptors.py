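"""2D molecular descriptors and the pruning pipeline.

Descriptors are computed with the open RDKit 2D descriptor set (~210
descriptors), each tagged with a block label so downstream steps can
restrict to the constitutional and ring blocks.  Pruning removes, in
order: descriptors with missing values, constant descriptors,
semi-constant descriptors (one value dominating more than a configurable
fraction of compounds), and for every pair with |Pearson r| above the
threshold the descriptor later in name-sorted order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RD

# Block tags.  RDKit has no block taxonomy, so names are mapped here:
# atom/bond/element counts and weights are "constitutional"; ring counts
# are "ring"; the rest are tagged by family.  The split procedure needs
# the constitutional and ring blocks to be identifiable.
_CONSTITUTIONAL = {
    "MolWt", "ExactMolWt", "HeavyAtomMolWt", "HeavyAtomCount",
    "NumValenceElectrons", "NumRadicalElectrons", "NHOHCount", "NOCount",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "FractionCSP3", "NumAromaticAtoms", "NumAtoms", "NumBonds",
}
_RING = {
    "RingCount", "NumAromaticRings", "NumSaturatedRings", "NumAliphaticRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumSpiroAtoms", "NumBridgeheadAtoms",
}


def _block_of(name: str) -> str:
    if name in _CONSTITUTIONAL:
        return "constitutional"
    if name in _RING:
        return "ring"
    if name.startswith("fr_"):
        return "fragment"
    if name.startswith(("PEOE_VSA", "SMR_VSA", "SlogP_VSA", "EState_VSA", "VSA_EState")):
        return "vsa"
    if name.startswith(("Chi", "Kappa", "BalabanJ", "BertzCT", "HallKierAlpha", "Ipc", "Phi")):
        return "topological"
    return "other"


@dataclass
class DescriptorMatrix:
    """Compounds x named numeric descriptors, with a missing-value mask."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # (n_compounds, n_descriptors), float
    missing_mask: np.ndarray  # same shape, bool; True where not computed
    block_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n != len(self.compound_ids) or p != len(self.descriptor_names):
            raise ValueError("matrix shape does not match id/name lists")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("duplicate descriptor names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def restrict(self, names: list[str]) -> "DescriptorMatrix":
        """Sub-matrix with the given descriptors, preserving given order."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            block_tags={n: self.block_tags.get(n, "other") for n in names},
        )

    def restrict_blocks(self, blocks: set[str]) -> "DescriptorMatrix":
        names = [n for n in self.descriptor_names if self.block_tags.get(n) in blocks]
        return self.restrict(names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.compound_ids,
                          columns=self.descriptor_names)
        return df.mask(pd.DataFrame(self.missing_mask, index=df.index,
                                    columns=df.columns))

    def to_csv(self, path, sidecar_path=None, removal_log=None) -> None:
        self.to_frame().to_csv(path, index_label="compound_id")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"block_tags": self.block_tags,
                     "removal_log": removal_log or {}},
                    fh, indent=2, sort_keys=True,
                )


def _extra_descriptors(mol: Chem.Mol) -> dict[str, float]:
    return {
        "NumAromaticAtoms": float(sum(a.GetIsAromatic() for a in mol.GetAtoms())),
        "NumAtoms": float(mol.GetNumHeavyAtoms()),
        "NumBonds": float(mol.GetNumBonds()),
    }


def compute_descriptors(
    structures: list[str], compound_ids: list[str] | None = None
) -> DescriptorMatrix:
    """One row of 2D descriptors per canonical structure.

    Descriptors that raise during calculation are recorded as missing, not
    zero, so the pruning step can drop them explicitly.
    """
    if not structures:
        raise ValueError("empty structure list")
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(len(structures))]
    rows: list[dict[str, float]] = []
    for smi in structures:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid structure {smi!r}; standardize first")
        try:
            vals = _RD.CalcMolDescriptors(mol, missingVal=np.nan)
        except Exception:
            vals = {name: np.nan for name, _ in _RD.descList}
        vals.update(_extra_descriptors(mol))
        rows.append(vals)
    names = sorted(rows[0])
    values = np.array([[row.get(n, np.nan) for n in names] for row in rows],
                      dtype=float)
    missing = ~np.isfinite(values)
    return DescriptorMatrix(
        compound_ids=list(compound_ids),
        descriptor_names=names,
        values=values,
        missing_mask=missing,
        block_tags={n: _block_of(n) for n in names},
    )


def prune_descriptors(
    matrix: DescriptorMatrix,
    corr_threshold: float = 0.95,
    semiconstant_frac: float = 0.95,
) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Apply the four pruning rules; return survivors and a removal log.

    Rules fire in order: missing values → constant → semi-constant (most
    frequent value in more than ``semiconstant_frac`` of compounds) →
    pairwise |Pearson r| > ``corr_threshold`` (the descriptor later in
    name-sorted order is removed).  The log maps each removed descriptor
    to the rule that removed it.
    """
    if not 0 < corr_threshold <= 1:
        raise ValueError("corr_threshold must be in (0, 1]")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    n = matrix.shape[0]
    log: dict[str, str] = {}
    survivors: list[str] = []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        if matrix.missing_mask[:, j].any():
            log[name] = "missing_values"
        elif np.all(col == col[0]):
            log[name] = "constant"
        else:
            _, counts = np.unique(col, return_counts=True)
            if counts.max() / n > semiconstant_frac:
                log[name] = "semi_constant"
            else:
                survivors.append(name)

    # correlation filter: greedy keep in name-sorted order
    ordered = sorted(survivors)
    sub = np.column_stack(
        [matrix.values[:, matrix.descriptor_names.index(nm)] for nm in ordered]
    )
    corr = np.corrcoef(sub, rowvar=False)
    kept_idx: list[int] = []
    for j in range(len(ordered)):
        if any(abs(corr[j, i]) > corr_threshold for i in kept_idx):
            log[ordered[j]] = "correlated"
        else:
            kept_idx.append(j)
    kept_names = {ordered[i] for i in kept_idx}
    final = [nm for nm in matrix.descriptor_names if nm in kept_names]
    return matrix.restrict(final), log
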
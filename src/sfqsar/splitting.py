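"""Dataset splitting: PCA-ranked venetian blinds and activity sampling.

Classification uses a venetian-blind split: compounds are ranked by their
score on the first principal component of the standardized constitutional
and ring descriptors (augmented with the class value as one column), and
every k-th ranked compound goes to the test set.

Regression uses activity sampling under two schemes.  Scheme A first
extracts 10% of the whole dataset as an external set (ES), then splits
the remainder 80/20 into training (TrS) and test (TeS).  Scheme B splits
80/20 into TrS and ES only.  In both, compounds are sorted by endpoint,
cut into equal-count bins, and subsets are drawn from every bin so each
subset spans the whole activity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .descriptors import DescriptorMatrix


class Subset(str, Enum):
    TRAIN = "TrS"
    TEST = "TeS"
    EXTERNAL = "ES"


@dataclass
class SplitAssignment:
    scheme: str  # classification_vb | regression_A | regression_B
    assignment: dict[str, Subset]
    seed: int | None = None
    fractions: dict[str, float] = field(default_factory=dict)

    def ids(self, subset: Subset) -> list[str]:
        return [cid for cid, s in self.assignment.items() if s == subset]

    def mask(self, compound_ids: list[str], subset: Subset) -> np.ndarray:
        return np.array([self.assignment[c] == subset for c in compound_ids])


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance columns; zero-variance columns are dropped."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    return (x[:, keep] - mu[keep]) / sd[keep]


def _pc1_scores(x: np.ndarray) -> np.ndarray:
    """First-principal-component scores via SVD, sign-fixed for determinism.

    Sign convention: the loading with the largest magnitude is positive.
    """
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    v1 = vt[0]
    pivot = np.argmax(np.abs(v1))
    if v1[pivot] < 0:
        v1 = -v1
    return xc @ v1


def pca_venetian_split(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    train_frac: float = 0.8,
) -> SplitAssignment:
    """Rank compounds on PC1 of (block descriptors + class value), then send
    every k-th ranked compound to the test set, k = round(1/(1-train_frac)).

    The class value enters PCA as one standardized column so the ranking
    mixes structure and class, giving both subsets the full spread of each.
    Degenerate input (no column variance) falls back to compound_id order.
    """
    labels = np.asarray(labels, dtype=float)
    n = matrix.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels not aligned to matrix rows")
    k = int(round(1.0 / (1.0 - train_frac)))
    if n < k:
        raise ValueError(f"need at least {k} compounds for train_frac={train_frac}")

    aug = np.column_stack([matrix.values, labels])
    std = _standardize_columns(aug)
    ids = np.array(matrix.compound_ids)
    if std.shape[1] == 0:
        order = np.argsort(ids, kind="stable")
    else:
        scores = _pc1_scores(std)
        # ties broken by compound id for determinism
        order = np.lexsort((ids, scores))

    assignment: dict[str, Subset] = {}
    for rank, idx in enumerate(order, start=1):
        assignment[str(ids[idx])] = (
            Subset.TEST if rank % k == 0 else Subset.TRAIN
        )
    return SplitAssignment(
        scheme="classification_vb",
        assignment=assignment,
        fractions={"TrS": train_frac, "TeS": 1 - train_frac},
    )


def _apportion(total: int, bin_sizes: list[int], rng: np.random.Generator) -> list[int]:
    """Split `total` across bins proportionally (largest remainder)."""
    sizes = np.asarray(bin_sizes, dtype=float)
    quota = total * sizes / sizes.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        # break remainder ties randomly but reproducibly
        remainders = quota - base
        order = np.lexsort((rng.random(len(sizes)), -remainders))
        base[order[:short]] += 1
    return [int(min(b, s)) for b, s in zip(base, bin_sizes)]


def activity_sampling_split(
    values: np.ndarray,
    scheme: str,
    n_bins: int = 10,
    seed: int = 0,
    compound_ids: list[str] | None = None,
) -> SplitAssignment:
    """Activity-sampled split of a continuous endpoint.

    Scheme ``A``: ES = round(0.10 n) of the whole set, then the remainder is
    split into TrS = round(0.80 m) and TeS.  Scheme ``B``: TrS = round(0.80 n)
    and ES.  Compounds are sorted by endpoint and cut into ``n_bins``
    equal-count bins; each subset's global quota is apportioned across bins
    and filled by seeded random draw within each bin, so every subset covers
    the full activity range.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not np.all(np.isfinite(values)):
        raise ValueError("endpoint values must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n:
        raise ValueError("more bins than compounds")
    if scheme not in ("A", "B"):
        raise ValueError("scheme must be 'A' or 'B'")
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(n)]

    rng = np.random.default_rng(seed)
    order = np.lexsort((np.arange(n), values))  # sort by activity, stable
    bins = np.array_split(order, n_bins)
    bin_sizes = [len(b) for b in bins]

    if scheme == "A":
        n_es = round(0.10 * n)
        m = n - n_es
        n_trs = round(0.80 * m)
        n_tes = m - n_trs
        quotas = {Subset.EXTERNAL: n_es, Subset.TEST: n_tes}
        fractions = {"ES": 0.10, "TrS": 0.72, "TeS": 0.18}
    else:
        n_es = n - round(0.80 * n)
        quotas = {Subset.EXTERNAL: n_es}
        fractions = {"TrS": 0.80, "ES": 0.20}

    per_bin = {
        subset: _apportion(q, bin_sizes, rng) for subset, q in quotas.items()
    }
    assignment: dict[str, Subset] = {}
    for b, members in enumerate(bins):
        pool = list(rng.permutation(members))
        for subset in quotas:
            take = per_bin[subset][b]
            for idx in pool[:take]:
                assignment[compound_ids[idx]] = subset
            pool = pool[take:]
        for idx in pool:
            assignment[compound_ids[idx]] = Subset.TRAIN

    # preserve input order of ids in the mapping
    assignment = {cid: assignment[cid] for cid in compound_ids}
    return SplitAssignment(
        scheme=f"regression_{scheme}",
        assignment=assignment,
        seed=seed,
        fractions=fractions,
    )
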
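"""Applicability domain: a percentile box on the first two principal
components of the model descriptors.

Training compounds are projected onto the first two PCs of their
standardized descriptor block; a prediction is inside the domain iff its
PC1 and PC2 scores both fall within the closed [5th, 95th] percentile
interval of the training scores.  Predictions outside are flagged as
less reliable and excluded from evaluation-set statistics (training-set
statistics are never AD-filtered).

An alternative per-descriptor standardization rule (outside iff any
|z| > 3) is provided as a simple approximation for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class AdDefinition:
    descriptor_names: list[str]
    mean: np.ndarray  # per-descriptor training mean
    sd: np.ndarray  # per-descriptor training sd
    loadings: np.ndarray  # (n_descriptors, 2)
    bounds: np.ndarray  # (2, 2): [[pc1_lo, pc1_hi], [pc2_lo, pc2_hi]]

    def to_dict(self) -> dict:
        return {
            "descriptor_names": self.descriptor_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "loadings": self.loadings.tolist(),
            "bounds": self.bounds.tolist(),
        }

    @classmethod
    def from_dict(cls, o: dict) -> "AdDefinition":
        return cls(
            descriptor_names=list(o["descriptor_names"]),
            mean=np.array(o["mean"]),
            sd=np.array(o["sd"]),
            loadings=np.array(o["loadings"]),
            bounds=np.array(o["bounds"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _scores(ad: AdDefinition, values: np.ndarray) -> np.ndarray:
    z = (np.atleast_2d(values) - ad.mean) / ad.sd
    return z @ ad.loadings


def fit_ad(
    values: np.ndarray,
    descriptor_names: list[str],
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> AdDefinition:
    """PCA on standardized training descriptors; keep two components and
    the closed [5th, 95th] percentile interval of each score.

    Percentiles use linear interpolation between order statistics.
    PC signs are fixed (largest-magnitude loading positive) so refitting
    identical data yields an identical definition.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    if n < p + 1:
        raise ValueError("need more training compounds than descriptors")
    if n < 20:
        raise ValueError("percentile bounds need at least 20 training compounds")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    loadings = vt[:2].T.copy()
    for k in range(2):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
    scores = z @ loadings
    bounds = np.stack(
        [np.percentile(scores[:, k], [lower_pct, upper_pct]) for k in range(2)]
    )
    return AdDefinition(
        descriptor_names=list(descriptor_names),
        mean=mean, sd=sd, loadings=loadings, bounds=bounds,
    )


def in_ad(ad: AdDefinition, row: np.ndarray) -> bool:
    """True iff both PC scores fall inside their closed percentile interval."""
    s = _scores(ad, row)[0]
    return bool(
        ad.bounds[0, 0] <= s[0] <= ad.bounds[0, 1]
        and ad.bounds[1, 0] <= s[1] <= ad.bounds[1, 1]
    )


def ad_mask(ad: AdDefinition, values: np.ndarray) -> np.ndarray:
    s = _scores(ad, values)
    return (
        (ad.bounds[0, 0] <= s[:, 0]) & (s[:, 0] <= ad.bounds[0, 1])
        & (ad.bounds[1, 0] <= s[:, 1]) & (s[:, 1] <= ad.bounds[1, 1])
    )


def coverage(ad: AdDefinition, values: np.ndarray) -> float:
    """Fraction of compounds inside the applicability domain."""
    values = np.atleast_2d(values)
    if len(values) == 0:
        raise ValueError("empty matrix")
    return float(ad_mask(ad, values).mean())


def zscore_outside(
    train_values: np.ndarray, values: np.ndarray, z_max: float = 3.0
) -> np.ndarray:
    """Alternative standardization-style rule: outside iff any |z| > z_max.

    A deliberately simple approximation of consensus standardization
    approaches; provided for comparison with the percentile-box domain.
    """
    x = np.asarray(train_values, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = np.abs((np.atleast_2d(values) - mean) / sd)
    return (z > z_max).any(axis=1)
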
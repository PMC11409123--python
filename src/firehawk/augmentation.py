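"""SMOTE class balancing on flattened feature vectors.

Synthetic minority samples are built by interpolating between a randomly
chosen minority sample and one of its k nearest same-class neighbors.
Real rows are never modified; synthetic rows are appended and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    pass


@dataclass
class LabeledVectorSet:
    """Aligned matrix of flattened samples, binary labels, and origin flags."""

    vectors: np.ndarray  # (M, p)
    labels: np.ndarray  # (M,) integers
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]  # (M,) bool

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != self.labels.shape[0]:
            raise ConfigurationError("vectors and labels must be aligned (M x p and M)")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.labels.shape[0], dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)
            if self.synthetic.shape != self.labels.shape:
                raise ConfigurationError("synthetic flags must align with labels")

    @property
    def size(self) -> int:
        return self.labels.shape[0]


def nearest_neighbors(dataset: LabeledVectorSet, index: int, k: int) -> np.ndarray:
    """Indices of the k nearest same-class neighbors of ``index`` (self excluded).

    Distance ties are broken in favor of the lower row index.
    """
    label = dataset.labels[index]
    candidates = np.flatnonzero(dataset.labels == label)
    candidates = candidates[candidates != index]
    if k >= candidates.size + 1:
        raise ConfigurationError(
            f"k={k} must be smaller than the class size ({candidates.size + 1})"
        )
    diffs = dataset.vectors[candidates] - dataset.vectors[index]
    dists = np.linalg.norm(diffs, axis=1)
    # stable sort on distance; candidates are in ascending index order, so
    # ties resolve to the lower index
    order = np.argsort(dists, kind="stable")[:k]
    return candidates[order]


def synthesize_sample(
    sample: np.ndarray,
    neighbor: np.ndarray,
    rng: np.random.Generator,
    per_component: bool = False,
) -> np.ndarray:
    """Interpolate ``sample + lam * (neighbor - sample)``.

    One interpolation factor per synthetic sample by default; with
    ``per_component=True`` an independent factor is drawn per feature.
    """
    sample = np.asarray(sample, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if sample.shape != neighbor.shape:
        raise ConfigurationError("sample and neighbor must have equal length")
    lam = rng.random(sample.shape) if per_component else rng.random()
    return sample + lam * (neighbor - sample)


def smote_balance(
    dataset: LabeledVectorSet,
    k: int,
    rng: np.random.Generator,
    per_component: bool = False,
) -> LabeledVectorSet:
    """Append synthetic minority rows until the two class counts are equal."""
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if classes.size != 2:
        raise ConfigurationError("SMOTE balancing requires exactly two classes")
    if np.any(counts <= k):
        raise ConfigurationError("each class must have more than k members")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return LabeledVectorSet(dataset.vectors.copy(), dataset.labels.copy(), dataset.synthetic.copy())

    minority_rows = np.flatnonzero(dataset.labels == minority)
    new_rows = []
    for _ in range(deficit):
        idx = int(rng.choice(minority_rows))
        neigh_idx = int(rng.choice(nearest_neighbors(dataset, idx, k)))
        new_rows.append(
            synthesize_sample(dataset.vectors[idx], dataset.vectors[neigh_idx], rng, per_component)
        )

    vectors = np.vstack([dataset.vectors, np.array(new_rows)])
    labels = np.concatenate([dataset.labels, np.full(deficit, minority, dtype=int)])
    synthetic = np.concatenate([dataset.synthetic, np.ones(deficit, dtype=bool)])
    return LabeledVectorSet(vectors, labels, synthetic)
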
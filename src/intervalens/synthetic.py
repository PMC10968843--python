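"""Seeded generator of microarray-like multi-class datasets.

Bulk gene-expression matrices have three traits that matter for testing a
classifier at desk scale: very many features relative to samples, blocks of
co-regulated (hence correlated) genes, and substantial measurement noise.
The generator emulates all three with the simplest model that exhibits
them: Gaussian noise, correlated feature blocks driven by a shared latent
factor, and class-conditional mean shifts on disjoint informative-feature
subsets so that every class is separable in principle.

Class sizes follow a target probability vector exactly, via
largest-remainder rounding, which matters for the small imbalanced classes
typical of clinical microarray cohorts (e.g. a 3-class cohort of 210
samples split (0.51, 0.41, 0.08) yields counts (107, 86, 17)).

Desk-scale defaults are 200 samples x 2000 features; full microarray scale
(tens of thousands of features) is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

#: 4-class imbalanced distribution typical of the clinical cohorts emulated.
DEFAULT_CLASS_PROBS: tuple[float, ...] = (0.45, 0.28, 0.14, 0.13)


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_samples, n_features : int
        Matrix shape; defaults emulate a small cohort profiled on a
        down-sampled array (200 x 2000).
    class_probs : tuple of float
        Target class proportions (must sum to 1; at least 2 classes).
        Realised counts use largest-remainder rounding.
    n_informative : int
        Number of label-carrying features, split into disjoint per-class
        subsets that receive the mean shift.
    effect_size : float
        Class-mean shift on informative features, in noise-SD units.
    block_size : int
        Width of correlated feature blocks (co-regulated gene modules).
    block_rho : float
        Target within-block correlation in [0, 1), induced by a shared
        latent factor per block.
    noise_sd : float
        Standard deviation of the per-feature noise.
    seed : int
        Seed; the output is fully determined by the spec including it.
    """

    n_samples: int = 200
    n_features: int = 2000
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    n_informative: int = 200
    effect_size: float = 1.0
    block_size: int = 20
    block_rho: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.class_probs)
        object.__setattr__(self, "class_probs", probs)
        errors = []
        if self.n_samples < 2:
            errors.append(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_features < 1:
            errors.append(f"n_features must be >= 1, got {self.n_features}")
        if len(probs) < 2:
            errors.append(f"need >= 2 classes, got {len(probs)}")
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            errors.append(f"class_probs must be non-negative and sum to 1, got {probs}")
        if not (0 <= self.n_informative <= self.n_features):
            errors.append(
                f"n_informative must lie in [0, n_features], got {self.n_informative}"
            )
        if self.effect_size < 0:
            errors.append(f"effect_size must be >= 0, got {self.effect_size}")
        if self.block_size < 1:
            errors.append(f"block_size must be >= 1, got {self.block_size}")
        if not (0 <= self.block_rho < 1):
            errors.append(f"block_rho must lie in [0, 1), got {self.block_rho}")
        if self.noise_sd <= 0:
            errors.append(f"noise_sd must be > 0, got {self.noise_sd}")
        if errors:
            raise ValueError("invalid DatasetSpec: " + "; ".join(errors))

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)

    def to_dict(self) -> dict:
        return asdict(self)


def class_counts(n_samples: int, class_probs: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of ``n_samples`` to classes.

    Floors of ``n * p`` are topped up, one sample at a time, in order of
    decreasing fractional remainder (ties to the lower class index).
    """
    probs = np.asarray(class_probs, dtype=float)
    raw = n_samples * probs
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n_samples - counts.sum()
    # stable sort on -remainder keeps ties in index order
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def generate(spec: DatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``(X, y)`` for a spec; bit-identical for identical specs.

    Returns a float matrix of shape ``(n_samples, n_features)`` and an
    integer label vector with classes ``0 .. n_classes-1``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = class_counts(spec.n_samples, spec.class_probs)
    y = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(y)

    n, p = spec.n_samples, spec.n_features
    noise = rng.standard_normal((n, p))
    n_blocks = -(-p // spec.block_size)
    factors = rng.standard_normal((n, n_blocks))
    block_of = np.minimum(np.arange(p) // spec.block_size, n_blocks - 1)
    # x = sqrt(rho) * block factor + sqrt(1-rho) * idiosyncratic noise
    # gives unit variance and within-block correlation exactly rho.
    rho = spec.block_rho
    X = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * noise
    X *= spec.noise_sd

    if spec.n_informative > 0 and spec.effect_size > 0:
        per_class = spec.n_informative // spec.n_classes
        shift = spec.effect_size * spec.noise_sd
        for c in range(spec.n_classes):
            cols = np.arange(c * per_class, (c + 1) * per_class)
            X[np.ix_(y == c, cols)] += shift
    return X, y


def to_frame(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Samples-in-rows DataFrame with gene-style columns and a ``label`` column."""
    df = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
    df["label"] = y
    return df
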
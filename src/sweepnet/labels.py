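"""Discretization of the selection coefficient and label distributions.

The selection coefficient S (in 2*Ne units) is a continuous parameter, but
it can be estimated by multiclass classification: its range is divided into
K linearly spaced classes and the network's softmax output over those
classes is read as a posterior distribution.  The "true" target
distribution for a training example can be a one-hot (categorical) vector,
a Gaussian centred on the true class, or a randomly perturbed categorical —
the soft variants penalize predictions increasingly with their distance
from the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinningScheme",
    "assign_class",
    "categorical_label",
    "gaussian_label",
    "perturb_label",
    "shuffle_split",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BinningScheme:
    """K linearly spaced classes covering [minimum, maximum] inclusively.

    Class midpoints include both bounds, so for the default range 0..400
    with K=11 the midpoints are 0, 40, ..., 400 and S=0 (neutrality) is its
    own class.
    """

    minimum: float = 0.0
    maximum: float = 400.0
    n_classes: int = 11

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.maximum > self.minimum:
            raise ValueError("maximum must exceed minimum")

    @property
    def midpoints(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.n_classes)

    @property
    def spacing(self) -> float:
        return (self.maximum - self.minimum) / (self.n_classes - 1)


def assign_class(value: float, scheme: BinningScheme) -> int:
    """Class index of the midpoint nearest ``value`` (ties -> lower index)."""
    if not scheme.minimum <= value <= scheme.maximum:
        raise ValueError(
            f"value {value} outside [{scheme.minimum}, {scheme.maximum}]"
        )
    # argmin returns the first (lower) index on exact ties
    return int(np.argmin(np.abs(scheme.midpoints - value)))


def _check_distribution(p: np.ndarray, tol: float = _SUM_TOL) -> np.ndarray:
    """Validate a probability vector; renormalize away round-off <= tol.

    Label constructors use the default tight tolerance; posterior readers
    pass a looser one because float32 softmax rows carry ~1e-7 round-off.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("label distribution must be 1-D")
    if np.any(p < 0):
        raise ValueError("label distribution entries must be >= 0")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError("label distribution must sum to 1")
    return p / p.sum()


def categorical_label(class_index: int, n_classes: int) -> np.ndarray:
    """One-hot (Dirac delta) distribution over ``n_classes`` classes."""
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} out of range [0, {n_classes})")
    p = np.zeros(n_classes)
    p[class_index] = 1.0
    return p


def gaussian_label(class_index: int, n_classes: int, sd: float) -> np.ndarray:
    """Gaussian-shaped distribution centred on the true class.

    Weights exp(-(k - class_index)^2 / (2 sd^2)) are evaluated at the
    integer class indices and renormalized, so boundary classes keep unit
    total mass over the truncated support.  ``sd`` is in class-index units.
    """
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} out of range [0, {n_classes})")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    k = np.arange(n_classes, dtype=float)
    w = np.exp(-((k - class_index) ** 2) / (2.0 * sd * sd))
    return w / w.sum()


def perturb_label(
    class_index: int,
    n_classes: int,
    max_step: int = 1,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Randomly shift a class index by up to ``max_step`` in either direction.

    The shift is uniform over the *valid* subset of
    {-max_step, ..., +max_step} — offsets leaving [0, n_classes) are
    excluded from the draw rather than clamped, so boundary classes do not
    accumulate extra mass.
    """
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} out of range [0, {n_classes})")
    if max_step < 0:
        raise ValueError("max_step must be >= 0")
    if max_step == 0:
        return class_index
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    candidates = [
        class_index + d
        for d in range(-max_step, max_step + 1)
        if 0 <= class_index + d < n_classes
    ]
    return int(candidates[rng.integers(len(candidates))])


@dataclass
class SplitIndices:
    """Index partition of a dataset, reconstructible from the seed."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int | None = None


def shuffle_split(
    n: int,
    test_fraction: float,
    validation_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> SplitIndices:
    """Shuffle ``n`` indices and split into train/validation/test.

    The test set takes ``test_fraction`` of the whole; the validation set
    takes ``validation_fraction`` of what remains after the test split.
    For n=1000 with 10%/10% this yields 100 test, 90 validation and 810
    training examples.  Deterministic for a fixed seed; the three index
    arrays are a set-partition of range(n).
    """
    if not 0 <= test_fraction < 1 or not 0 <= validation_fraction < 1:
        raise ValueError("fractions must be in [0, 1)")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    n_val = int(round(validation_fraction * (n - n_test)))
    test = perm[:n_test]
    validation = perm[n_test : n_test + n_val]
    train = perm[n_test + n_val :]
    if train.size == 0:
        raise ValueError("training split is empty")
    if test_fraction > 0 and test.size == 0:
        raise ValueError("test split is empty")
    if validation_fraction > 0 and validation.size == 0:
        raise ValueError("validation split is empty")
    return SplitIndices(train=train, validation=validation, test=test, seed=seed)


def label_proportions(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class fraction of examples, for reporting split balance."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.zeros(n_classes)
    return np.bincount(labels, minlength=n_classes) / labels.size
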
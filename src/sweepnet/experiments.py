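"""Canned end-to-end experiments on synthetic fixtures.

These drive the full pipeline — fixture generation, image processing,
training, evaluation — for the detection (sweep vs neutral) and
quantification (multi-intensity) designs, at desk scale.  They are used by
the test suite and the reproduction script, and are convenient entry points
for exploring how sorting and sweep strength affect accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ImageConfig, build_image_batch
from .labels import shuffle_split
from .network import SweepCNN, evaluate
from .simdata import generate_fixtures


@dataclass
class ExperimentResult:
    accuracy: float
    confusion: np.ndarray
    model: SweepCNN
    n_train: int
    n_test: int


def detection_experiment(
    intensities: list[float],
    n_per_class: int = 1000,
    n_haplotypes: int = 64,
    target_sites: int = 96,
    core_width: float | None = None,
    sorting: str = "rows_and_columns",
    image_size: int = 64,
    conv_filters: tuple[int, ...] = (32, 32, 32),
    kernel_size: int = 3,
    dense_units: int | None = None,
    n_epochs: int = 2,
    learning_rate: float = 1e-3,
    test_fraction: float = 0.1,
    seed: int = 0,
    alignments_by_class: list | None = None,
) -> ExperimentResult:
    """Train a CNN to distinguish the given sweep intensities.

    One class per entry of ``intensities`` (class 0 should be the neutral
    intensity 0.0).  Returns held-out accuracy and confusion matrix.
    ``alignments_by_class`` allows reusing pre-generated fixtures across
    experiments that differ only in image processing.

    Unless overridden, the sweep footprint covers the whole window
    (``core_width=1``): a strong sweep in the recent past leaves sampled
    carrier haplotypes identical over a region of this size, and the
    sweep intensity is the frequency the swept haplotype has reached.
    """
    if core_width is None:
        core_width = 1.0
    if alignments_by_class is None:
        alignments_by_class = [
            generate_fixtures(
                n_per_class, n_haplotypes, target_sites, s, core_width,
                rng_seed=seed * 1000 + ci,
            )
            for ci, s in enumerate(intensities)
        ]
    alignments, labels = [], []
    for ci, alns in enumerate(alignments_by_class):
        alignments += alns
        labels += [ci] * len(alns)

    config = ImageConfig(
        maf_threshold=0.01,
        sorting=sorting,
        target_height=image_size,
        target_width=image_size,
    )
    batch = build_image_batch(alignments, labels, config)

    split = shuffle_split(len(batch), test_fraction, 0.0, rng=seed)
    train, test = batch.subset(split.train), batch.subset(split.test)

    model = SweepCNN(
        conv_filters=conv_filters,
        kernel_size=kernel_size,
        dense_units=dense_units,
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        random_state=seed,
    )
    model.fit(train.pixels, train.labels)
    result = evaluate(model, test.pixels, test.labels)
    return ExperimentResult(
        accuracy=result["accuracy"],
        confusion=result["confusion"],
        model=model,
        n_train=len(train),
        n_test=len(test),
    )
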
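"""Haplotype alignments to fixed-size binary images.

The image representation stacks haplotypes as rows and segregating sites as
columns.  Processing follows a fixed order — polarize, minor-allele-
frequency filter, sort, resize — so that a batch is fully reproducible from
its configuration.  Sorting rows (and optionally columns) by the frequency
of occurrence of identical patterns turns the arbitrary row order of
sampled haplotypes into an abstract, permutation-invariant layout in which
the extended common haplotype of a selective sweep becomes a contiguous
block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import h5py
import numpy as np

from .simdata import HaplotypeAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ImageConfig",
    "ImageBatch",
    "polarize_major_minor",
    "filter_maf",
    "sort_by_frequency",
    "resize_image",
    "build_image_batch",
    "ImagePipeline",
    "save_batch",
    "load_batch",
]


@dataclass(frozen=True)
class ImageConfig:
    """Settings controlling alignment-to-image conversion.

    polarization
        ``"major-minor"`` recodes each column so the commoner allele is 0
        and the rarer is 1 (for data with unknown ancestral state);
        ``"derived-as-is"`` leaves alleles untouched.
    maf_threshold
        Columns with minor-allele frequency strictly below this are dropped.
    sorting
        ``"none"``, ``"rows"``, ``"columns"`` or ``"rows_and_columns"``.
    sort_criterion
        ``"pattern"`` sorts by multiplicity of identical row/column
        patterns; ``"allele"`` sorts rows by their count of 1-alleles and
        columns by allele frequency.
    target_height, target_width
        Output image size in pixels.
    resize_policy
        ``"fixed"`` uses target_width as given; ``"mean-of-training-set"``
        replaces it with the rounded mean column count after filtering.
    interpolation
        ``"nearest"`` (preserves binary values) or ``"bilinear"``.
    """

    polarization: str = "major-minor"
    maf_threshold: float = 0.01
    sorting: str = "rows_and_columns"
    sort_criterion: str = "pattern"
    target_height: int = 128
    target_width: int = 128
    resize_policy: str = "fixed"
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if self.polarization not in ("major-minor", "derived-as-is"):
            raise ValueError(f"unknown polarization {self.polarization!r}")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")
        if self.sorting not in ("none", "rows", "columns", "rows_and_columns"):
            raise ValueError(f"unknown sorting {self.sorting!r}")
        if self.sort_criterion not in ("pattern", "allele"):
            raise ValueError(f"unknown sort_criterion {self.sort_criterion!r}")
        if self.target_height < 1 or self.target_width < 1:
            raise ValueError("target dimensions must be >= 1")
        if self.resize_policy not in ("fixed", "mean-of-training-set"):
            raise ValueError(f"unknown resize_policy {self.resize_policy!r}")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class ImageBatch:
    """A stack of equal-size images with labels and provenance."""

    pixels: np.ndarray  # (N, H, W) float32 in [0, 1]
    labels: np.ndarray  # (N,) int
    config: ImageConfig | None = None
    source: list = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (N, H, W)")
        if self.pixels.shape[0] != self.labels.shape[0]:
            raise ValueError("pixels and labels must have equal length")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def subset(self, idx: np.ndarray) -> "ImageBatch":
        src = [self.source[i] for i in idx] if self.source else []
        return ImageBatch(self.pixels[idx], self.labels[idx], self.config, src)


def polarize_major_minor(aln: HaplotypeAlignment) -> HaplotypeAlignment:
    """Recode each column so the major allele is 0 and the minor allele 1.

    Columns where the allele coded 1 is carried by more than half the
    haplotypes are flipped.  Exact 50/50 ties are left unflipped, which
    makes the operation deterministic and idempotent.
    """
    m = aln.matrix
    n = aln.n_haplotypes
    counts = m.sum(axis=0)
    flip = counts > n / 2
    out = np.where(flip[None, :], 1 - m, m).astype(np.int8)
    return HaplotypeAlignment(out, aln.positions.copy(), dict(aln.provenance))


def filter_maf(aln: HaplotypeAlignment, threshold: float) -> HaplotypeAlignment:
    """Drop columns with minor-allele frequency strictly below ``threshold``.

    A frequency exactly at the threshold is retained.  Column order is
    preserved; positions travel with their columns.
    """
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    if threshold == 0.0 or aln.n_sites == 0:
        return HaplotypeAlignment(
            aln.matrix.copy(), aln.positions.copy(), dict(aln.provenance)
        )
    n = aln.n_haplotypes
    counts = aln.matrix.sum(axis=0)
    maf = np.minimum(counts, n - counts) / n
    keep = maf >= threshold
    return HaplotypeAlignment(
        aln.matrix[:, keep], aln.positions[keep], dict(aln.provenance)
    )


def _group_sort_indices(patterns: np.ndarray) -> np.ndarray:
    """Indices that sort rows of ``patterns`` by pattern multiplicity.

    Identical patterns are grouped; groups are ordered by decreasing
    multiplicity, with ties broken lexicographically descending on the
    pattern so the ordering is a pure function of the multiset of patterns.
    """
    n, w = patterns.shape
    uniq, inverse, counts = np.unique(
        patterns, axis=0, return_inverse=True, return_counts=True
    )
    # np.lexsort: last key is primary. Primary: -count; then pattern entries
    # descending, first entry most significant.
    keys = [-uniq[:, j] for j in range(w - 1, -1, -1)] + [-counts]
    group_order = np.lexsort(keys)
    rank = np.empty(len(uniq), dtype=np.intp)
    rank[group_order] = np.arange(len(uniq))
    # stable sort of original indices by their group's rank keeps within-group
    # original order (irrelevant for identical patterns)
    return np.argsort(rank[inverse], kind="stable")


def _allele_sort_indices(patterns: np.ndarray) -> np.ndarray:
    """Indices sorting rows by their count of 1s, descending; ties broken
    lexicographically descending."""
    w = patterns.shape[1]
    keys = [-patterns[:, j] for j in range(w - 1, -1, -1)]
    keys.append(-patterns.sum(axis=1))
    return np.lexsort(keys)


def sort_by_frequency(
    aln: HaplotypeAlignment, axis: str = "rows", criterion: str = "pattern"
) -> HaplotypeAlignment:
    """Sort rows and/or columns by frequency of occurrence.

    ``axis`` is ``"rows"``, ``"columns"`` or ``"both"`` (rows first, then
    columns).  With ``criterion="pattern"`` identical row (column) patterns
    are grouped and groups are placed top-to-bottom (left-to-right) in
    non-increasing multiplicity order; ``criterion="allele"`` sorts by the
    count of 1-alleles instead.  Content is only permuted, never altered;
    positions are permuted with their columns.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows|columns|both, got {axis!r}")
    sorter = _group_sort_indices if criterion == "pattern" else _allele_sort_indices
    m = aln.matrix
    pos = aln.positions
    if aln.n_sites == 0:
        return HaplotypeAlignment(m.copy(), pos.copy(), dict(aln.provenance))
    if axis in ("rows", "both"):
        m = m[sorter(m), :]
    if axis in ("columns", "both"):
        ci = sorter(m.T)
        m = m[:, ci]
        pos = pos[ci]
    return HaplotypeAlignment(m.copy(), pos.copy(), dict(aln.provenance))


def resize_image(
    m: np.ndarray,
    target_height: int,
    target_width: int,
    interpolation: str = "nearest",
) -> np.ndarray:
    """Resize a 2-D matrix to exactly (target_height, target_width).

    Nearest-neighbour sampling maps output pixel centres onto the source
    grid (index = floor((i + 0.5) * src / dst)), preserving binary values
    and returning the input unchanged when the target equals the native
    size.  Bilinear interpolation (scikit-image) is available for
    non-binary use.
    """
    m = np.asarray(m, dtype=np.float32)
    if m.ndim != 2 or m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError(
            "cannot resize an empty matrix; drop replicates with no "
            "columns left after filtering"
        )
    if target_height < 1 or target_width < 1:
        raise ValueError("target dimensions must be >= 1")
    h, w = m.shape
    if (h, w) == (target_height, target_width):
        return m.copy()
    if interpolation == "nearest":
        ri = np.floor((np.arange(target_height) + 0.5) * h / target_height).astype(int)
        ci = np.floor((np.arange(target_width) + 0.5) * w / target_width).astype(int)
        return m[np.minimum(ri, h - 1)][:, np.minimum(ci, w - 1)]
    if interpolation == "bilinear":
        from skimage.transform import resize as _sk_resize

        out = _sk_resize(
            m, (target_height, target_width), order=1, anti_aliasing=False,
            preserve_range=True, mode="edge",
        )
        return np.clip(out, 0.0, 1.0).astype(np.float32)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _process_one(aln: HaplotypeAlignment, config: ImageConfig, width: int) -> np.ndarray | None:
    a = aln
    if config.polarization == "major-minor":
        a = polarize_major_minor(a)
    a = filter_maf(a, config.maf_threshold)
    if a.n_sites == 0:
        return None
    if config.sorting != "none":
        axis = {"rows": "rows", "columns": "columns", "rows_and_columns": "both"}[
            config.sorting
        ]
        a = sort_by_frequency(a, axis=axis, criterion=config.sort_criterion)
    return resize_image(
        a.matrix, config.target_height, width, interpolation=config.interpolation
    )


def build_image_batch(
    alignments: list[HaplotypeAlignment],
    labels: np.ndarray | list[int],
    config: ImageConfig,
) -> ImageBatch:
    """Convert alignments into a fixed-size image batch.

    Each alignment goes through polarize -> MAF filter -> sort -> resize,
    in that order.  Under ``resize_policy="mean-of-training-set"`` the
    target width is the rounded mean column count across inputs after
    filtering.  Replicates emptied by the filter are dropped with a logged
    warning and counted in ``n_dropped``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(alignments) != len(labels):
        raise ValueError("alignments and labels must have equal length")

    width = config.target_width
    if config.resize_policy == "mean-of-training-set":
        ncols = []
        for aln in alignments:
            a = polarize_major_minor(aln) if config.polarization == "major-minor" else aln
            a = filter_maf(a, config.maf_threshold)
            if a.n_sites > 0:
                ncols.append(a.n_sites)
        if not ncols:
            raise ValueError("all replicates emptied by filtering")
        width = max(1, int(round(float(np.mean(ncols)))))
        config = replace(config, target_width=width)

    images, kept_labels, source = [], [], []
    dropped = 0
    for aln, lab in zip(alignments, labels):
        img = _process_one(aln, config, width)
        if img is None:
            dropped += 1
            continue
        images.append(img)
        kept_labels.append(lab)
        source.append(dict(aln.provenance))
    if dropped:
        logger.warning("dropped %d replicate(s) emptied by the MAF filter", dropped)
    if not images:
        raise ValueError("no replicates left after filtering")
    return ImageBatch(
        np.stack(images), np.array(kept_labels), config, source, n_dropped=dropped
    )


class ImagePipeline:
    """Scikit-learn-style transformer from alignments to image arrays.

    ``fit`` resolves data-dependent settings (the mean-width resize
    policy); ``transform`` returns a ``(N, H, W)`` float32 array.  Use
    :func:`build_image_batch` when labels and provenance are needed.
    """

    def __init__(self, config: ImageConfig | None = None, **overrides):
        base = config or ImageConfig()
        self.config = replace(base, **overrides) if overrides else base

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "ImagePipeline":
        if "config" in params:
            self.config = params.pop("config")
        if params:
            self.config = replace(self.config, **params)
        return self

    def fit(self, X: list[HaplotypeAlignment], y=None) -> "ImagePipeline":
        cfg = self.config
        if cfg.resize_policy == "mean-of-training-set":
            batch = build_image_batch(X, np.zeros(len(X), dtype=int), cfg)
            self.resolved_config_ = batch.config
        else:
            self.resolved_config_ = cfg
        return self

    def transform(self, X: list[HaplotypeAlignment]) -> np.ndarray:
        if not hasattr(self, "resolved_config_"):
            self.fit(X)
        cfg = self.resolved_config_
        batch = build_image_batch(X, np.zeros(len(X), dtype=int), cfg)
        if batch.n_dropped:
            raise ValueError(
                f"{batch.n_dropped} replicate(s) emptied by filtering; "
                "use build_image_batch to drop them explicitly"
            )
        return batch.pixels

    def fit_transform(self, X: list[HaplotypeAlignment], y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def save_batch(batch: ImageBatch, path: str, seed: int | None = None) -> None:
    """Persist an ImageBatch to HDF5 (pixels, labels, config attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=batch.pixels, dtype="float32")
        f.create_dataset("labels", data=batch.labels)
        if batch.config is not None:
            f.attrs["config"] = json.dumps(asdict(batch.config))
        f.attrs["n_dropped"] = batch.n_dropped
        if seed is not None:
            f.attrs["seed"] = seed


def load_batch(path: str) -> ImageBatch:
    """Load an ImageBatch saved by :func:`save_batch`, bit-exactly."""
    with h5py.File(path, "r") as f:
        pixels = f["pixels"][...]
        labels = f["labels"][...]
        config = None
        if "config" in f.attrs:
            config = ImageConfig(**json.loads(f.attrs["config"]))
        n_dropped = int(f.attrs.get("n_dropped", 0))
    return ImageBatch(pixels, labels, config, n_dropped=n_dropped)
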
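"""Polarization, MAF filtering, frequency sorting and resizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from sweepnet import (
    HaplotypeAlignment,
    ImageConfig,
    ImagePipeline,
    build_image_batch,
    filter_maf,
    generate_fixtures,
    load_batch,
    polarize_major_minor,
    resize_image,
    save_batch,
    sort_by_frequency,
)


def aln_from(matrix, positions=None):
    matrix = np.asarray(matrix)
    if positions is None:
        positions = np.linspace(0.1, 0.9, matrix.shape[1])
    return HaplotypeAlignment(matrix, positions)


binary_matrices = arrays(
    np.int8,
    st.tuples(st.integers(4, 12), st.integers(1, 8)),
    elements=st.integers(0, 1),
).filter(
    lambda m: np.all((m.sum(axis=0) > 0) & (m.sum(axis=0) < m.shape[0]))
)


class TestPolarize:
    def test_majority_column_flipped(self):
        out = polarize_major_minor(aln_from([[1], [1], [1], [0]]))
        assert np.array_equal(out.matrix.ravel(), [0, 0, 0, 1])

    def test_tie_left_unflipped(self):
        out = polarize_major_minor(aln_from([[0], [0], [1], [1]]))
        assert np.array_equal(out.matrix.ravel(), [0, 0, 1, 1])

    def test_one_counts_bounded_by_half(self, random_alignments):
        for aln in random_alignments:
            out = polarize_major_minor(aln)
            assert out.matrix.sum(axis=0).max() <= aln.n_haplotypes // 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(binary_matrices)
    def test_idempotent(self, m):
        a = aln_from(m)
        once = polarize_major_minor(a)
        twice = polarize_major_minor(once)
        assert np.array_equal(once.matrix, twice.matrix)


class TestFilterMaf:
    def test_singleton_removed_doubleton_kept_at_paper_cutoff(self):
        # n=128: singleton freq 1/128 ~ 0.0078 < 0.01, doubleton 0.0156 >= 0.01
        m = np.zeros((128, 2), dtype=np.int8)
        m[0, 0] = 1  # singleton
        m[:2, 1] = 1  # doubleton
        out = filter_maf(aln_from(m), 0.01)
        assert out.n_sites == 1
        assert out.matrix.sum() == 2

    def test_threshold_zero_is_identity(self, tiny_alignment):
        out = filter_maf(tiny_alignment, 0.0)
        assert np.array_equal(out.matrix, tiny_alignment.matrix)

    def test_idempotent(self, random_alignments):
        for aln in random_alignments:
            once = filter_maf(aln, 0.2)
            twice = filter_maf(once, 0.2)
            assert np.array_equal(once.matrix, twice.matrix)

    def test_retained_columns_meet_threshold(self, random_alignments):
        t = 0.25
        for aln in random_alignments:
            out = filter_maf(aln, t)
            if out.n_sites:
                n = out.n_haplotypes
                counts = out.matrix.sum(axis=0)
                maf = np.minimum(counts, n - counts) / n
                assert np.all(maf >= t)

    def test_positions_travel_with_columns(self):
        m = np.zeros((10, 3), dtype=np.int8)
        m[0, 0] = 1  # maf 0.1
        m[:5, 1] = 1  # maf 0.5
        m[:4, 2] = 1  # maf 0.4
        out = filter_maf(aln_from(m, np.array([0.1, 0.2, 0.3])), 0.3)
        assert np.allclose(out.positions, [0.2, 0.3])

    def test_threshold_at_half_rejected(self, tiny_alignment):
        with pytest.raises(ValueError):
            filter_maf(tiny_alignment, 0.5)


class TestSortByFrequency:
    def test_duplicate_rows_grouped_first(self):
        a = aln_from([[0, 1], [0, 1], [1, 0], [0, 0]])
        out = sort_by_frequency(a, "rows")
        expected = np.array([[0, 1], [0, 1], [1, 0], [0, 0]])
        assert np.array_equal(out.matrix, expected)

    def test_tie_broken_lexicographically_descending(self):
        a = aln_from([[0, 0], [1, 0]])
        out = sort_by_frequency(a, "rows")
        assert np.array_equal(out.matrix, [[1, 0], [0, 0]])

    def test_all_rows_identical_unchanged(self):
        m = np.tile([0, 1, 1], (5, 1))
        out = sort_by_frequency(aln_from(m), "rows")
        assert np.array_equal(out.matrix, m)

    def test_idempotent_per_axis(self, random_alignments):
        # row and column sorts are pure functions with deterministic
        # tie-breaks, hence idempotent; their composition ("both") is not,
        # because re-sorting rows after a column permutation changes
        # lexicographic tie-breaks
        for aln in random_alignments:
            for axis in ("rows", "columns"):
                once = sort_by_frequency(aln, axis)
                twice = sort_by_frequency(once, axis)
                assert np.array_equal(once.matrix, twice.matrix)

    def test_both_axes_deterministic_and_conserving(self, random_alignments):
        for aln in random_alignments:
            a = sort_by_frequency(aln, "both")
            b = sort_by_frequency(aln, "both")
            assert np.array_equal(a.matrix, b.matrix)
            # composition: rows first, then columns
            manual = sort_by_frequency(sort_by_frequency(aln, "rows"), "columns")
            assert np.array_equal(a.matrix, manual.matrix)
            # content is only permuted: row/column sums conserved as multisets
            assert sorted(a.matrix.sum(1)) == sorted(aln.matrix.sum(1))
            assert sorted(a.matrix.sum(0)) == sorted(aln.matrix.sum(0))

    def test_row_multiset_conserved(self, random_alignments):
        for aln in random_alignments:
            out = sort_by_frequency(aln, "rows")
            orig = sorted(map(tuple, aln.matrix))
            srtd = sorted(map(tuple, out.matrix))
            assert orig == srtd

    def test_positions_permuted_with_columns(self):
        a = aln_from([[1, 0], [1, 0], [0, 1]], np.array([0.2, 0.8]))
        out = sort_by_frequency(a, "columns")
        # column patterns (1,1,0) and (0,0,1) each occur once; tie broken
        # lexicographically descending puts (1,1,0) first — already there
        assert np.allclose(out.positions, [0.2, 0.8])
        both = sort_by_frequency(a, "both")
        assert sorted(both.positions.tolist()) == [0.2, 0.8]

    def test_row_sort_stable_under_column_shuffle(self, rng):
        """Row-pattern multiplicities are invariant under column permutation,
        so the multiplicity sequence of the sorted rows must match."""
        alns = generate_fixtures(5, 12, 10, 0.5, 0.4, rng_seed=5)
        for aln in alns:
            sorted_a = sort_by_frequency(aln, "rows")
            perm = rng.permutation(aln.n_sites)
            shuffled = HaplotypeAlignment(
                aln.matrix[:, perm], np.sort(aln.positions[perm])
            )
            sorted_b = sort_by_frequency(shuffled, "rows")

            def multiplicities(m):
                _, counts = np.unique(m, axis=0, return_counts=True)
                return sorted(counts.tolist(), reverse=True)

            assert multiplicities(sorted_a.matrix) == multiplicities(sorted_b.matrix)

    def test_allele_criterion_orders_by_row_sums(self):
        a = aln_from([[0, 0, 1], [1, 1, 1], [1, 0, 0]])
        out = sort_by_frequency(a, "rows", criterion="allele")
        sums = out.matrix.sum(axis=1)
        assert np.all(np.diff(sums) <= 0)


class TestResize:
    def test_identity_at_native_resolution(self, rng):
        m = rng.integers(0, 2, (16, 16)).astype(np.float32)
        assert np.array_equal(resize_image(m, 16, 16), m)

    def test_constants_preserved(self):
        for interp in ("nearest", "bilinear"):
            out = resize_image(np.ones((7, 5)), 12, 9, interpolation=interp)
            assert np.allclose(out, 1.0)
            assert out.shape == (12, 9)

    def test_checkerboard_downsample_matches_index_map_oracle(self):
        m = np.indices((4, 4)).sum(axis=0) % 2  # 4x4 checkerboard
        out = resize_image(m.astype(np.float32), 2, 2)
        # oracle: output pixel (i, j) samples source floor((i+0.5)*4/2)
        idx = np.floor((np.arange(2) + 0.5) * 4 / 2).astype(int)
        expected = m[np.ix_(idx, idx)]
        assert np.array_equal(out, expected)

    def test_binary_preserved_by_nearest(self, rng):
        m = rng.integers(0, 2, (33, 17)).astype(np.float32)
        out = resize_image(m, 20, 20)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resize_image(np.zeros((5, 0)), 8, 8)


class TestBuildImageBatch:
    def test_batch_dimensions(self):
        alns = generate_fixtures(10, 16, 24, 0.8, 0.3, rng_seed=0)
        cfg = ImageConfig(target_height=32, target_width=32, maf_threshold=0.0)
        batch = build_image_batch(alns, [1] * 10, cfg)
        assert batch.pixels.shape == (10, 32, 32)
        assert batch.pixels.min() >= 0 and batch.pixels.max() <= 1

    def test_dropped_count_matches_brute_force(self):
        alns = generate_fixtures(40, 10, 6, rng_seed=3)
        t = 0.35
        cfg = ImageConfig(
            maf_threshold=t, target_height=10, target_width=6, sorting="none"
        )
        # independent recount of replicates emptied by the filter
        expected_dropped = 0
        for aln in alns:
            counts = aln.matrix.sum(axis=0)
            maf = np.minimum(counts, 10 - counts) / 10
            if not np.any(maf >= t):
                expected_dropped += 1
        batch = build_image_batch(alns, [0] * 40, cfg)
        assert batch.n_dropped == expected_dropped
        assert len(batch) == 40 - expected_dropped

    def test_filter_before_sort_order_pinned(self):
        """Filtering then sorting differs from sorting then filtering: a
        rare column can change the sort order of rows before it is removed."""
        m = np.array(
            [
                [1, 1, 0],
                [1, 0, 0],
                [1, 0, 0],
                [0, 0, 1],
                [0, 0, 1],
                [0, 0, 1],
                [0, 0, 0],
                [0, 0, 0],
                [0, 0, 0],
                [0, 0, 0],
            ]
        )
        aln = aln_from(m)
        t = 0.15  # drops only the singleton middle column (maf 0.1)
        correct = sort_by_frequency(filter_maf(aln, t), "rows")
        swapped = filter_maf(sort_by_frequency(aln, "rows"), t)
        assert not np.array_equal(correct.matrix, swapped.matrix)
        cfg = ImageConfig(
            polarization="derived-as-is", maf_threshold=t, sorting="rows",
            target_height=10, target_width=2,
        )
        batch = build_image_batch([aln], [0], cfg)
        assert np.array_equal(batch.pixels[0], correct.matrix.astype(np.float32))

    def test_mean_width_resize_policy(self):
        alns = generate_fixtures(20, 12, 15, rng_seed=8)
        cfg = ImageConfig(
            maf_threshold=0.0, resize_policy="mean-of-training-set",
            target_height=12, target_width=999,
        )
        batch = build_image_batch(alns, [0] * 20, cfg)
        assert batch.pixels.shape[2] == 15  # no filtering -> mean width is 15

    def test_mismatched_lengths_rejected(self):
        alns = generate_fixtures(3, 8, 6, rng_seed=0)
        with pytest.raises(ValueError):
            build_image_batch(alns, [0, 1], ImageConfig())


class TestImagePipeline:
    def test_sklearn_params_round_trip(self):
        pipe = ImagePipeline(sorting="rows", maf_threshold=0.02)
        params = pipe.get_params()
        clone = ImagePipeline(**params)
        assert clone.config == pipe.config
        pipe.set_params(sorting="none")
        assert pipe.config.sorting == "none"

    def test_fit_transform_shapes(self):
        alns = generate_fixtures(6, 12, 20, 0.6, 0.3, rng_seed=2)
        X = ImagePipeline(
            target_height=16, target_width=16, maf_threshold=0.0
        ).fit_transform(alns)
        assert X.shape == (6, 16, 16)


class TestHdf5Persistence:
    def test_round_trip_bit_exact(self, tmp_path):
        alns = generate_fixtures(8, 10, 12, 0.5, 0.4, rng_seed=4)
        cfg = ImageConfig(target_height=10, target_width=12, maf_threshold=0.0)
        batch = build_image_batch(alns, [0, 1] * 4, cfg)
        path = tmp_path / "batch.h5"
        save_batch(batch, str(path), seed=4)
        loaded = load_batch(str(path))
        assert np.array_equal(loaded.pixels, batch.pixels)
        assert np.array_equal(loaded.labels, batch.labels)
        assert loaded.config == batch.config
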
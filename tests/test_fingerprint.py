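import numpy as np
import pytest
from hypothesis import given, strategies as st

from genofp import (
    FingerprintMeta,
    ParameterMismatchError,
    RawFingerprint,
    VariantRecord,
    VariantTable,
    binarize,
    binarize_from_raw,
    compute_raw,
    merge_raw,
    normalize,
)
from genofp.keys import PAIR_KEYS

from _oracles import naive_raw, random_records


def _row(key):
    return PAIR_KEYS.index(key)


class TestComputeRaw:
    def test_hand_traced_example(self):
        recs = [
            VariantRecord("1", 100, "G", "A"),
            VariantRecord("1", 150, "T", "C"),
            VariantRecord("1", 152, "A", "C"),
        ]
        fp = compute_raw(recs, L=20, C=20)
        # GA..TC at distance 49 -> raw column 49 mod 20 = 9
        assert fp.raw[_row("GATC"), 9] == 1
        # TC..AC at distance 1 < C -> close column 1
        assert fp.close[_row("TCAC"), 1] == 1
        assert fp.meta.n_snvs == 3
        assert fp.meta.n_pairs_raw == 1 and fp.meta.n_pairs_close == 1
        assert fp.raw.sum() == 1 and fp.close.sum() == 1

    def test_close_cutoff_zero_sends_every_pair_to_raw(self):
        recs = [
            VariantRecord("1", 100, "G", "A"),
            VariantRecord("1", 150, "T", "C"),
            VariantRecord("1", 152, "A", "C"),
        ]
        fp = compute_raw(recs, L=20, C=0)
        assert fp.close.shape == (144, 0)
        assert fp.raw.sum() == 2
        assert fp.raw[_row("TCAC"), 1] == 1

    def test_single_snv_and_cross_chromosome_yield_no_pairs(self):
        one = compute_raw([VariantRecord("1", 100, "G", "A")])
        assert one.meta.n_pairs_raw == 0 and one.meta.n_pairs_close == 0
        two = compute_raw(
            [VariantRecord("1", 100, "G", "A"), VariantRecord("2", 100, "T", "C")]
        )
        assert two.meta.n_pairs_raw == 0 and two.meta.n_pairs_close == 0
        assert two.meta.n_snvs == 2

    def test_empty_stream_is_a_valid_zero_fingerprint(self):
        fp = compute_raw([])
        assert fp.meta.n_snvs == 0
        assert fp.raw.sum() == 0 and fp.close.sum() == 0

    def test_adjacent_positions_have_distance_zero(self):
        recs = [VariantRecord("1", 100, "G", "A"), VariantRecord("1", 101, "T", "C")]
        fp = compute_raw(recs, C=20)
        assert fp.close[_row("GATC"), 0] == 1
        fp0 = compute_raw(recs, C=0)
        assert fp0.raw[_row("GATC"), 0] == 1

    def test_rejects_l_below_two(self):
        with pytest.raises(ValueError):
            compute_raw([], L=1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_naive_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng, int(rng.integers(50, 500)), max_gap=90)
        fp = compute_raw(records, L=20, C=20)
        raw, close = naive_raw(records, L=20, C=20)
        np.testing.assert_array_equal(fp.raw, raw)
        np.testing.assert_array_equal(fp.close, close)

    @given(st.integers(0, 1000))
    def test_pair_conservation(self, seed):
        """raw + close pair totals = sum over chromosomes of (n_c - 1)."""
        rng = np.random.default_rng(seed)
        records = random_records(rng, int(rng.integers(0, 120)))
        fp = compute_raw(records, L=5, C=7)
        per_chrom = {}
        for r in records:
            per_chrom[r.chrom] = per_chrom.get(r.chrom, 0) + 1
        expected = sum(max(0, n - 1) for n in per_chrom.values())
        assert fp.meta.n_pairs_raw + fp.meta.n_pairs_close == expected
        assert fp.raw.sum() + fp.close.sum() == expected


class TestMerge:
    def test_chromosome_partition_merge_is_bit_identical(self, small_genome):
        table = small_genome.variant_table()
        whole = compute_raw(table)
        parts = []
        for label, pos, kidx in table.per_chrom():
            sub = VariantTable([label], np.array([0, len(pos)]), pos, kidx)
            parts.append(compute_raw(sub))
        merged = merge_raw(parts)
        np.testing.assert_array_equal(merged.raw, whole.raw)
        np.testing.assert_array_equal(merged.close, whole.close)
        assert merged.meta.n_snvs == whole.meta.n_snvs
        assert merged.meta.n_pairs_raw == whole.meta.n_pairs_raw

    def test_singleton_and_zero_merge_identities(self):
        rng = np.random.default_rng(8)
        fp = compute_raw(random_records(rng, 100))
        zero = compute_raw([])
        np.testing.assert_array_equal(merge_raw([fp]).raw, fp.raw)
        merged = merge_raw([fp, zero])
        np.testing.assert_array_equal(merged.raw, fp.raw)
        np.testing.assert_array_equal(merged.close, fp.close)

    def test_parameter_mismatch_is_an_error(self):
        a = compute_raw([], L=20)
        b = compute_raw([], L=120)
        with pytest.raises(ParameterMismatchError):
            merge_raw([a, b])
        c = compute_raw([], L=20, C=5)
        with pytest.raises(ParameterMismatchError):
            merge_raw([a, c])


def _two_pass_zscore_reference(matrix):
    """Plain-python two-pass z-scoring: columns over rows, then rows."""
    m = [list(map(float, row)) for row in matrix]
    nrow, ncol = len(m), len(m[0])
    for c in range(ncol):
        col = [m[r][c] for r in range(nrow)]
        mean = sum(col) / nrow
        sd = (sum((v - mean) ** 2 for v in col) / nrow) ** 0.5
        for r in range(nrow):
            m[r][c] = (m[r][c] - mean) / sd if sd > 0 else 0.0
    for r in range(nrow):
        row = m[r]
        mean = sum(row) / ncol
        sd = (sum((v - mean) ** 2 for v in row) / ncol) ** 0.5
        m[r] = [(v - mean) / sd if sd > 0 else 0.0 for v in row]
    return np.array(m)


class TestNormalize:
    def test_matches_independent_two_pass_oracle_on_small_matrix(self):
        rng = np.random.default_rng(17)
        raw = rng.integers(0, 9, size=(144, 2))
        fp = RawFingerprint(FingerprintMeta("raw", L=2, C=0), raw, np.zeros((144, 0), np.int64))
        nf = normalize(fp)
        np.testing.assert_allclose(nf.values, _two_pass_zscore_reference(raw), atol=1e-12)

    def test_rows_are_standardized(self, small_genome):
        nf = normalize(compute_raw(small_genome.variant_table()))
        np.testing.assert_allclose(nf.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(nf.values.std(axis=1), 1, atol=1e-9)

    def test_affine_invariance(self, small_genome):
        fp = compute_raw(small_genome.variant_table())
        transformed = RawFingerprint(fp.meta, 3 * fp.raw + 7, fp.close)
        np.testing.assert_allclose(
            normalize(transformed).values, normalize(fp).values, atol=1e-9
        )

    def test_constant_matrix_normalizes_to_zero(self):
        fp = RawFingerprint(
            FingerprintMeta("raw", L=4, C=0),
            np.full((144, 4), 5, dtype=np.int64),
            np.zeros((144, 0), np.int64),
        )
        assert (normalize(fp).values == 0).all()

    def test_requires_raw_kind(self, small_genome):
        nf = normalize(compute_raw(small_genome.variant_table()))
        with pytest.raises(ValueError, match="raw"):
            normalize(nf)


class TestBinarize:
    def test_bit_rule_on_constructed_counts(self):
        raw = np.zeros((144, 2), dtype=np.int64)
        raw[0] = [3, 5]  # odd-distance tally larger -> 1
        raw[1] = [5, 3]  # even larger -> 0
        raw[2] = [4, 4]  # tie -> 0
        fp = RawFingerprint(FingerprintMeta("raw", L=2, C=0), raw, np.zeros((144, 0), np.int64))
        bits = binarize_from_raw(fp).bits
        assert bits[0] == 1 and bits[1] == 0 and bits[2] == 0
        assert bits[3:].sum() == 0  # empty rows tie at zero

    def test_empty_genome_gives_all_zero_bits(self):
        assert binarize([]).bits.sum() == 0

    def test_is_a_function_of_the_l2_raw_fingerprint(self, small_genome):
        table = small_genome.variant_table()
        direct = binarize(table, C=20)
        via_raw = binarize_from_raw(compute_raw(table, L=2, C=20))
        np.testing.assert_array_equal(direct.bits, via_raw.bits)
        assert len(direct.bits) == 144

    def test_binarize_from_raw_requires_l2(self, small_genome):
        fp = compute_raw(small_genome.variant_table(), L=20)
        with pytest.raises(ValueError, match="L=2"):
            binarize_from_raw(fp)
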
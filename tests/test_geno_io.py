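"""Genotype I/O, MAF filtering, uniform thinning and adjacent-marker LD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phantomgs import (
    MarkerMatrix,
    adjacent_ld,
    filter_maf,
    read_genotypes,
    thin_uniform,
)
from phantomgs.geno_io import write_matrix, write_vcf

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def _vcf(tmp_path, records):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return path


class TestVCFReader:
    def test_homozygous_calls_encode_directly(self, tmp_path):
        path = _vcf(tmp_path, [
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1",
            "1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0",
        ])
        g = read_genotypes(path)
        assert g.values.shape == (3, 2)
        assert set(np.unique(g.values)) <= {0, 1}
        assert list(g.accession_ids) == ["A", "B", "C"]
        np.testing.assert_array_equal(g.pos, [100, 200])

    def test_major_alt_column_is_flipped_to_minor(self, tmp_path):
        # ALT frequency 2/3: the indicator must mark the REF (minor) allele
        path = _vcf(tmp_path, ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t1/1"])
        g = read_genotypes(path)
        np.testing.assert_array_equal(g.values[:, 0], [1, 0, 0])
        assert g.maf[0] == pytest.approx(1 / 3)

    def test_heterozygous_call_is_an_error_naming_the_record(self, tmp_path):
        path = _vcf(tmp_path, ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"])
        with pytest.raises(ValueError, match="heterozygous.*B.*1:100"):
            read_genotypes(path)

    def test_missing_genotype_is_an_error(self, tmp_path):
        path = _vcf(tmp_path, ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1"])
        with pytest.raises(ValueError, match="missing"):
            read_genotypes(path)

    def test_multiallelic_site_is_an_error(self, tmp_path):
        path = _vcf(tmp_path, ["1\t100\t.\tA\tT,C\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2"])
        with pytest.raises(ValueError, match="biallelic"):
            read_genotypes(path)

    def test_unsorted_positions_are_an_error(self, tmp_path):
        path = _vcf(tmp_path, [
            "1\t200\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1",
            "1\t100\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0",
        ])
        with pytest.raises(ValueError, match="increasing"):
            read_genotypes(path)


class TestRoundTrips:
    def test_matrix_format_round_trip_is_exact(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_matrix(tiny_matrix, path)
        back = read_genotypes(path, format="matrix")
        np.testing.assert_array_equal(back.values, tiny_matrix.values)
        assert list(back.accession_ids) == list(tiny_matrix.accession_ids)
        np.testing.assert_array_equal(back.pos, tiny_matrix.pos)
        assert list(back.chrom) == list(tiny_matrix.chrom)

    def test_vcf_written_panel_reads_back_identically(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.vcf"
        write_vcf(tiny_matrix, path)
        back = read_genotypes(path)
        np.testing.assert_array_equal(back.values, tiny_matrix.values)
        np.testing.assert_array_equal(back.pos, tiny_matrix.pos)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(n=st.integers(2, 12), p=st.integers(2, 15), seed=st.integers(0, 10_000))
    def test_random_panels_round_trip_through_tsv(self, tmp_path_factory, n, p, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(n, p)).astype(np.int8)
        flip = values.mean(axis=0) > 0.5
        values[:, flip] = 1 - values[:, flip]
        pos = np.sort(rng.choice(10_000, size=p, replace=False)) + 1
        g = MarkerMatrix(values, np.array([f"a{i}" for i in range(n)]),
                         np.full(p, "1"), pos)
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_matrix(g, path)
        back = read_genotypes(path, format="matrix")
        np.testing.assert_array_equal(back.values, g.values)
        np.testing.assert_array_equal(back.pos, g.pos)


class TestMarkerMatrixInvariants:
    def test_heterozygote_coding_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            MarkerMatrix(np.array([[2, 0], [0, 1]]), np.array(["a", "b"]),
                         np.array(["1", "1"]), np.array([1, 2]))

    def test_major_oriented_column_rejected(self):
        with pytest.raises(ValueError, match="minor"):
            MarkerMatrix(np.array([[1, 0], [1, 1], [1, 0]]), np.array(list("abc")),
                         np.array(["1", "1"]), np.array([1, 2]))

    def test_maf_equals_indicator_frequency(self, tiny_matrix):
        np.testing.assert_allclose(tiny_matrix.maf, tiny_matrix.values.mean(axis=0))


class TestFilterMaf:
    def test_threshold_keeps_exactly_the_markers_at_or_above(self):
        values = np.zeros((200, 3), dtype=np.int8)
        values[:1, 0] = 1     # maf 0.005
        values[:4, 1] = 1     # maf 0.02
        values[:100, 2] = 1   # maf 0.5
        g = MarkerMatrix(values, np.array([f"a{i}" for i in range(200)]),
                         np.full(3, "1"), np.array([10, 20, 30]))
        kept = filter_maf(g, 0.01)
        assert kept.n_markers == 2
        np.testing.assert_array_equal(kept.pos, [20, 30])

    def test_zero_threshold_is_identity(self, mosaic):
        assert filter_maf(mosaic, 0.0) is mosaic

    def test_all_markers_removed_is_an_error(self):
        values = np.zeros((8, 2), dtype=np.int8)
        values[0] = 1  # both columns at maf 0.125
        g = MarkerMatrix(values, np.array([f"a{i}" for i in range(8)]),
                         np.full(2, "1"), np.array([1, 2]))
        with pytest.raises(ValueError, match="empty"):
            filter_maf(g, 0.3)

    def test_threshold_out_of_range_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError):
            filter_maf(tiny_matrix, 0.5)


class TestThinUniform:
    def _single_chrom(self, positions):
        p = len(positions)
        values = np.zeros((3, p), dtype=np.int8)
        values[0] = 1 - (np.arange(p) % 2)
        values[1] = np.arange(p) % 2
        return MarkerMatrix(values, np.array(["a", "b", "c"]),
                            np.full(p, "1"), np.asarray(positions))

    def test_regular_grid_selects_evenly_spaced_markers(self):
        g = self._single_chrom(np.arange(1, 101))
        panel = thin_uniform(g, 10)
        assert len(panel) == 10
        gaps = np.diff(panel.pos)
        assert gaps.min() >= 9 and gaps.max() <= 11

    def test_target_at_least_p_returns_all_markers(self, mosaic):
        panel = thin_uniform(mosaic, mosaic.n_markers + 5)
        assert len(panel) == mosaic.n_markers

    def test_thinning_is_idempotent(self, mosaic):
        panel = thin_uniform(mosaic, 120)
        again = thin_uniform(panel.to_matrix(), len(panel))
        np.testing.assert_array_equal(again.pos, panel.pos)

    def test_matches_brute_force_nearest_marker_search(self):
        rng = np.random.default_rng(3)
        positions = np.sort(rng.choice(100_000, size=400, replace=False)) + 1
        g = self._single_chrom(positions)
        target = 37
        panel = thin_uniform(g, target)
        # independent brute-force oracle over the same grid definition
        lo, hi = positions[0], positions[-1]
        span = hi - lo + 1
        expected = set()
        for j in range(target):
            x = lo + (j + 0.5) * span / target
            dist = np.abs(positions - x)
            expected.add(positions[int(np.argmin(dist))])  # first min = lower pos
        assert set(panel.pos.tolist()) == expected

    def test_chromosomes_allotted_proportionally_to_length(self):
        values = np.zeros((3, 40), dtype=np.int8)
        values[0] = 1 - (np.arange(40) % 2)
        values[1] = np.arange(40) % 2
        chrom = np.array(["1"] * 20 + ["2"] * 20)
        pos = np.concatenate([np.linspace(1, 9000, 20), np.linspace(1, 900, 20)]).astype(int)
        g = MarkerMatrix(values, np.array(["a", "b", "c"]), chrom, pos)
        panel = thin_uniform(g, 10)
        n1 = (panel.chrom == "1").sum()
        assert n1 == 9  # ~10:1 physical span ratio


class TestAdjacentLD:
    def test_duplicated_columns_give_perfect_ld(self):
        rng = np.random.default_rng(0)
        col = (rng.random(60) < 0.4).astype(np.int8)
        values = np.column_stack([col] * 4)
        g = MarkerMatrix(values, np.array([f"a{i}" for i in range(60)]),
                         np.full(4, "1"), np.array([1, 2, 3, 4]))
        prof = adjacent_ld(thin_uniform(g, 4))
        np.testing.assert_allclose(prof.r_values, 1.0)
        assert prof.quantiles[0.9] == pytest.approx(1.0)
        assert prof.quantiles[0.5] == pytest.approx(1.0)

    def test_cross_chromosome_pairs_do_not_contribute(self, tiny_matrix):
        prof = adjacent_ld(thin_uniform(tiny_matrix, 5))
        # 3 markers on chrom 1 and 2 on chrom 2: 2 + 1 within-chrom pairs
        assert prof.n_pairs == 3

    def test_zero_variance_column_is_an_error(self):
        values = np.array([[1, 0], [0, 0], [0, 0]], dtype=np.int8)
        g = MarkerMatrix(values, np.array(["a", "b", "c"]),
                         np.full(2, "1"), np.array([1, 2]))
        with pytest.raises(ValueError, match="zero-variance"):
            adjacent_ld(thin_uniform(g, 2))

    def test_quantiles_ordered_on_absolute_r(self, mosaic):
        prof = adjacent_ld(thin_uniform(mosaic, 200))
        assert prof.quantiles[0.9] >= prof.quantiles[0.7] >= prof.quantiles[0.5]

    def test_independent_markers_match_monte_carlo_null(self):
        rng = np.random.default_rng(42)
        n, p = 400, 300
        values = (rng.random((n, p)) < 0.3).astype(np.int8)
        flip = values.mean(axis=0) > 0.5
        values[:, flip] = 1 - values[:, flip]
        g = MarkerMatrix(values, np.array([f"a{i}" for i in range(n)]),
                         np.full(p, "1"), np.arange(1, p + 1))
        prof = adjacent_ld(thin_uniform(g, p))
        # oracle: null |r| quantile from freshly drawn independent binary pairs
        null_rs = []
        for _ in range(3000):
            a = (rng.random(n) < 0.3).astype(float)
            b = (rng.random(n) < 0.3).astype(float)
            null_rs.append(abs(np.corrcoef(a, b)[0, 1]))
        null_q90 = np.quantile(null_rs, 0.9)
        assert prof.quantiles[0.9] == pytest.approx(null_q90, abs=0.02)

    def test_mean_abs_r_nondecreasing_in_density(self, mosaic):
        means = [
            np.abs(adjacent_ld(thin_uniform(mosaic, d)).r_values).mean()
            for d in (50, 300, 1500)
        ]
        assert means[0] <= means[1] <= means[2]
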
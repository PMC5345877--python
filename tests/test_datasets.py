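import itertools

import numpy as np
import pytest

from motifgate import datasets as ds
from motifgate.sequences import dinucleotide_count_vector, write_fasta


@pytest.fixture
def narrowpeak_file(tmp_path):
    path = tmp_path / "exp.narrowPeak"
    path.write_text(
        "chr1\t100\t400\t.\t0\t.\t5.0\t-1\t-1\t150\n"
        "chr1\t500\t700\t.\t0\t.\t9.0\t-1\t-1\t-1\n"
        "chr2\t10\t110\t.\t0\t.\t5.0\t-1\t-1\t50\n"
    )
    return path


class TestLoadPeaks:
    def test_narrowpeak_fields(self, narrowpeak_file):
        peaks = ds.load_peaks(narrowpeak_file)
        p = peaks[0]
        assert (p.chrom, p.start, p.end, p.summit_offset, p.score) == \
            ("chr1", 100, 400, 150, 5.0)

    def test_negative_summit_falls_back_to_midpoint(self, narrowpeak_file):
        p = ds.load_peaks(narrowpeak_file)[1]
        assert p.summit_offset == 100  # (700-500)//2

    def test_bed6_midpoint(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t0\t301\tname\t7\t+\n")
        p = ds.load_peaks(path)[0]
        assert p.summit_offset == 150
        assert p.score == 7.0

    def test_bed3(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t10\t20\n")
        p = ds.load_peaks(path)[0]
        assert p.score == 0.0 and p.summit_offset == 5

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert ds.load_peaks(path) == []

    def test_malformed_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\nchr1\tnot_an_int\t20\n")
        with pytest.raises(ValueError, match="line 2"):
            ds.load_peaks(path)

    def test_space_separated_accepted(self, tmp_path):
        path = tmp_path / "sp.narrowPeak"
        path.write_text("chr1 100 400 . 0 . 5.0 -1 -1 150\n")
        p = ds.load_peaks(path)[0]
        assert (p.start, p.end, p.summit_offset) == (100, 400, 150)


class TestSelectTopPeaks:
    def test_top_n_width(self):
        rng = np.random.default_rng(0)
        peaks = [ds.PeakRecord("chr1", s, s + 200, 100, float(sc))
                 for s, sc in zip(range(0, 5000, 500), rng.permutation(10))]
        regions = ds.select_top_peaks(peaks, 5, 100)
        assert len(regions) == 5
        assert all(e - s == 100 for _, s, e in regions)
        scores = {(p.start + 100): p.score for p in peaks}
        kept = [scores[(s + e) // 2] for _, s, e in regions]
        assert kept == sorted(kept, reverse=True)

    def test_centering_arithmetic(self):
        p = ds.PeakRecord("chr1", 900, 1100, 100, 1.0)  # summit at 1000
        ((_, s, e),) = ds.select_top_peaks([p], 1, 100)
        assert (s, e) == (950, 1050)

    def test_tie_break_by_coordinate(self):
        a = ds.PeakRecord("chr2", 100, 200, 50, 5.0)
        b = ds.PeakRecord("chr1", 100, 200, 50, 5.0)
        c = ds.PeakRecord("chr1", 50, 150, 50, 5.0)
        regions = ds.select_top_peaks([a, b, c], 3, 10)
        assert [r[0] for r in regions] == ["chr1", "chr1", "chr2"]
        assert regions[0][1] < regions[1][1]

    def test_short_list_allowed(self):
        p = ds.PeakRecord("chr1", 0, 10, 5, 1.0)
        assert len(ds.select_top_peaks([p], 100, 4)) == 1


class TestAlternatingSplit:
    def test_six(self):
        odd, even = ds.alternating_split([1, 2, 3, 4, 5, 6])
        assert odd == [1, 3, 5] and even == [2, 4, 6]

    def test_thousand_gives_500_each(self):
        odd, even = ds.alternating_split(list(range(1000)))
        assert len(odd) == 500 and len(even) == 500

    def test_single(self):
        odd, even = ds.alternating_split(["only"])
        assert odd == ["only"] and even == []


class TestShuffledNegatives:
    def test_pairwise_counts_matched(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 60))
                for _ in range(50)]
        pos = [ds.LabeledInstance(1, "TF1", "C1", s) for s in seqs]
        neg = ds.build_shuffled_negatives(pos, rng)
        assert len(neg) == len(pos)
        for p, n in zip(pos, neg):
            assert n.label == 0 and n.tf == p.tf and n.cell == p.cell
            assert np.array_equal(dinucleotide_count_vector(p.seq),
                                  dinucleotide_count_vector(n.seq))

    def test_homopolymer_identical(self, rng):
        pos = [ds.LabeledInstance(1, "T", "C", "A" * 30)]
        assert ds.build_shuffled_negatives(pos, rng)[0].seq == "A" * 30

    def test_deterministic(self):
        pos = [ds.LabeledInstance(1, "T", "C", "ACGTACGTAACC")]
        a = ds.build_shuffled_negatives(pos, np.random.default_rng(9))
        b = ds.build_shuffled_negatives(pos, np.random.default_rng(9))
        assert a[0].seq == b[0].seq

    def test_n_containing_positives_dropped(self, rng):
        pos = [ds.LabeledInstance(1, "T", "C", "ACGTN"),
               ds.LabeledInstance(1, "T", "C", "ACGTA")]
        assert len(ds.build_shuffled_negatives(pos, rng)) == 1


class TestUnionDhs:
    def _peak(self, chrom, summit):
        return ds.PeakRecord(chrom, summit - 50, summit + 50, 50, 1.0)

    def test_overlapping_merge(self):
        merged = ds.merge_regions([("chr1", 0, 300), ("chr1", 200, 500)])
        assert merged == [("chr1", 0, 500)]

    def test_disjoint_stay_separate(self):
        regs = [("chr1", 0, 300), ("chr1", 300, 600), ("chr2", 0, 300)]
        assert ds.merge_regions(regs) == regs

    def test_trim_to_300(self):
        out = ds.build_union_dhs([[self._peak("chr1", 1000)]])
        assert out == [("chr1", 850, 1150)]

    def test_total_bp_bounded(self, rng):
        peaks = [[self._peak("chr1", int(s))
                  for s in rng.integers(200, 100_000, 40)]
                 for _ in range(3)]
        merged = ds.build_union_dhs(peaks)
        total = sum(e - s for _, s, e in merged)
        assert total <= 300 * 120
        starts = [s for _, s, e in merged]
        assert starts == sorted(starts)
        assert all(merged[i][2] <= merged[i + 1][1] or
                   merged[i][0] != merged[i + 1][0]
                   for i in range(len(merged) - 1))


class TestDhsNegatives:
    def test_toy_pool_brute_force(self, rng):
        dhs = [("chr1", i * 1000, i * 1000 + 300) for i in range(10)]
        tf_peaks = [("chr1", 150, 250), ("chr1", 2100, 2200),
                    ("chr1", 5000, 5300), ("chr1", 9250, 9350)]

        def overlaps(a, b):
            return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

        expected_pool = [r for r in dhs
                         if not any(overlaps(r, p) for p in tf_peaks)]
        assert len(expected_pool) == 6
        out = ds.build_dhs_negatives(dhs, tf_peaks, 6, 100, rng)
        assert len(out) == 6
        for chrom, s, e in out:
            assert e - s == 100
            assert not any(overlaps((chrom, s, e), p) for p in tf_peaks)

    def test_all_covered_empty_pool(self, rng):
        dhs = [("chr1", 0, 300)]
        with pytest.warns(UserWarning, match="pool"):
            out = ds.build_dhs_negatives(dhs, [("chr1", 0, 300)], 1, 100, rng)
        assert out == []

    def test_no_tf_peaks_whole_pool(self, rng):
        dhs = [("chr1", i * 1000, i * 1000 + 300) for i in range(5)]
        out = ds.build_dhs_negatives(dhs, [], 5, 100, rng)
        assert len(out) == 5

    def test_sampling_without_replacement(self, rng):
        dhs = [("chr1", i * 1000, i * 1000 + 300) for i in range(20)]
        out = ds.build_dhs_negatives(dhs, [], 10, 100, rng)
        assert len(set(out)) == 10


def exhaustive_max_holdout(combos):
    """Oracle: largest holdout H such that every TF and cell of H remains
    covered by combos - H (brute force over all subsets)."""
    best = 0
    for r in range(len(combos), -1, -1):
        for H in itertools.combinations(combos, r):
            base = [c for c in combos if c not in H]
            tfs = {t for t, _ in base}
            cells = {c for _, c in base}
            if all(t in tfs and c in cells for t, c in H):
                return r
    return best


class TestPartitionCombinations:
    def grid(self, nt, nc):
        return [(f"T{i}", f"C{j}") for i in range(nt) for j in range(nc)]

    def test_3x3_grid_optimal(self, rng):
        combos = self.grid(3, 3)
        assert exhaustive_max_holdout(combos) == 6
        part = ds.partition_combinations(combos, [], holdout_valid_size=2,
                                         rng=rng)
        assert len(part.validset2 | part.testset3) == 6
        assert len(part.base) == 3
        assert len(part.validset2) == 2
        part.validate()

    def test_matches_exhaustive_on_random_toys(self):
        rng = np.random.default_rng(17)
        for trial in range(15):
            combos = sorted({(f"T{rng.integers(4)}", f"C{rng.integers(4)}")
                             for _ in range(rng.integers(3, 10))})
            expect = exhaustive_max_holdout(combos)
            part = ds.partition_combinations(combos, [],
                                             holdout_valid_size=0, rng=rng)
            assert len(part.validset2 | part.testset3) == expect, combos

    def test_single_combo(self, rng):
        part = ds.partition_combinations([("T", "C")], [],
                                         holdout_valid_size=0, rng=rng)
        assert part.base == {("T", "C")}
        assert not part.validset2 and not part.testset3

    def test_coverage_invariant_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            combos = sorted({(f"T{rng.integers(8)}", f"C{rng.integers(6)}")
                             for _ in range(rng.integers(2, 30))})
            part = ds.partition_combinations(combos, [],
                                             holdout_valid_size=0, rng=rng)
            part.validate()  # raises on violation

    def test_testset2_requires_replicates(self, rng):
        combos = self.grid(2, 2)
        metas = [ds.ExperimentMeta("e1", "T0", "C0", "rep1"),
                 ds.ExperimentMeta("e2", "T0", "C0", "rep2"),
                 ds.ExperimentMeta("e3", "T0", "C1", "rep1"),
                 ds.ExperimentMeta("e4", "T1", "C0", "rep1"),
                 ds.ExperimentMeta("e5", "T1", "C1", "rep1")]
        part = ds.partition_combinations(combos, metas, holdout_valid_size=0,
                                         rng=rng)
        assert part.testset2 == {c for c in part.base if c == ("T0", "C0")}

    def test_holdout_valid_size_too_large(self, rng):
        with pytest.raises(ValueError, match="holdout_valid_size"):
            ds.partition_combinations([("T", "C")], [], holdout_valid_size=5,
                                      rng=rng)

    def test_deterministic(self):
        combos = self.grid(4, 4)
        a = ds.partition_combinations(combos, [], holdout_valid_size=3,
                                      rng=np.random.default_rng(11))
        b = ds.partition_combinations(combos, [], holdout_valid_size=3,
                                      rng=np.random.default_rng(11))
        assert a.base == b.base and a.validset2 == b.validset2


class TestSplitInstances:
    def make(self, n):
        return [ds.LabeledInstance(1, "T", "C", "ACGT") for _ in range(n)]

    def test_exact_sizes(self, rng):
        split = ds.split_instances(self.make(100), (70, 10, 20), rng)
        assert (len(split.trainset), len(split.validset1),
                len(split.testset1)) == (70, 10, 20)

    def test_remainder_joins_train(self, rng):
        split = ds.split_instances(self.make(100), (50, 10, 20), rng)
        assert len(split.trainset) == 70

    def test_conservation_and_disjoint(self):
        inst = [ds.LabeledInstance(1, "T", "C", f"A{i:04d}"[:4] * 2)
                for i in range(50)]
        inst = [ds.LabeledInstance(1, "T", "C", s.seq) for s in inst]
        # give each instance a distinguishable identity
        for i, x in enumerate(inst):
            x.tf = f"T{i}"
        split = ds.split_instances(inst, (30, 10, 10),
                                   np.random.default_rng(2))
        names = [x.tf for x in
                 split.trainset + split.validset1 + split.testset1]
        assert sorted(names) == sorted(x.tf for x in inst)
        assert len(set(names)) == 50

    def test_same_seed_identical(self):
        inst = self.make(40)
        a = ds.split_instances(inst, (20, 10, 10), np.random.default_rng(7))
        b = ds.split_instances(inst, (20, 10, 10), np.random.default_rng(7))
        assert [id(x) for x in a.validset1] == [id(x) for x in b.validset1]

    def test_negative_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            ds.split_instances(self.make(10), (5, -1, 2), rng)

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError):
            ds.split_instances(self.make(10), (8, 2, 2), rng)


class TestExtractSequences:
    def test_basic_slice(self):
        genome = {"chr1": "ACGTACGT"}
        assert ds.extract_sequences([("chr1", 2, 6)], genome) == ["GTAC"]

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ds.extract_sequences([("chr1", 3, 3)], {"chr1": "ACGT"})

    def test_out_of_bounds_names_region(self):
        with pytest.raises(ValueError, match="chr1:2-10"):
            ds.extract_sequences([("chr1", 2, 10)], {"chr1": "ACGT"})

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            ds.extract_sequences([("chrX", 0, 2)], {"chr1": "ACGT"})

    def test_uppercases(self):
        assert ds.extract_sequences([("c", 0, 4)], {"c": "acgt"}) == ["ACGT"]

    def test_fasta_path_roundtrip(self, tmp_path):
        path = tmp_path / "g.fa"
        write_fasta(path, {"chr1": "AACCGGTT"})
        assert ds.extract_sequences([("chr1", 1, 5)], str(path)) == ["ACCG"]


class TestInstanceIO:
    def test_tsv_roundtrip(self, tmp_path):
        inst = [ds.LabeledInstance(1, "TF1", "C1", "ACGT"),
                ds.LabeledInstance(0, "TF2", "C2", "TTTT")]
        for name in ("x.tsv", "x.tsv.gz"):
            path = tmp_path / name
            ds.write_instances(path, inst)
            assert ds.read_instances(path) == inst

    def test_pack_and_vocab_errors(self):
        inst = [ds.LabeledInstance(1, "TF1", "C1", "ACGT")]
        packed = ds.pack_instances(inst, ("TF1",), ("C1",))
        assert packed.codes.tolist() == [[0, 1, 2, 3]]
        with pytest.raises(KeyError):
            ds.pack_instances(inst, ("OTHER",), ("C1",))

    def test_partition_json_roundtrip(self):
        part = ds.CombinationPartition(
            base={("T0", "C0"), ("T1", "C1")}, testset2={("T0", "C0")},
            validset2={("T0", "C1")}, testset3={("T1", "C0")})
        again = ds.CombinationPartition.from_json(part.to_json())
        assert again == part
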
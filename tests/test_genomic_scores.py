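import itertools

import numpy as np
import pytest

from hgsoctx.errors import ConfigError, ValidationError
from hgsoctx.genome import MB, GenomeModel
from hgsoctx.genomic_scores import (
    AlleleSegment,
    HRDResult,
    LOHClass,
    MutationRecord,
    classify_segment_loh,
    compute_hrd,
    compute_loh_count,
    compute_lst_count,
    compute_tai_count,
    compute_tmb,
    label_gene_cn,
)

TEST_GENOME = GenomeModel(
    chrom_lengths={f"chr{i}": 60 * MB for i in (1, 2, 3)},
    centromeres={f"chr{i}": (28 * MB, 32 * MB) for i in (1, 2, 3)},
)


def oracle_classify(total: int, minor: int) -> LOHClass:
    """Independent decision-table enumeration."""
    if minor > 0 and total == 2 and minor == 1:
        return LOHClass.HET
    if minor > 0 and total > 2 and 2 * minor == total:
        return LOHClass.BCNA
    if minor > 0 and total > 2 and 2 * minor != total:
        return LOHClass.ASCNA
    if minor == 0 and total <= 1:
        return LOHClass.DLOH
    if minor == 0 and total == 2:
        return LOHClass.NLOH
    if minor == 0 and total >= 3:
        return LOHClass.ALOH
    raise AssertionError(f"unclassifiable ({total}, {minor})")


def random_tiling(rng, sample="S1"):
    """Mb-aligned random tiling of the test genome with valid allele states."""
    segs = []
    for chrom, length in TEST_GENOME.chrom_lengths.items():
        n_breaks = int(rng.integers(0, 8))
        breaks = sorted(set(rng.integers(1, length // MB, size=n_breaks).tolist()))
        bounds = [0] + [b * MB for b in breaks] + [length]
        for lo, hi in zip(bounds, bounds[1:]):
            total = int(rng.integers(0, 6))
            minor = int(rng.integers(0, total // 2 + 1))
            segs.append(AlleleSegment(sample, chrom, lo, hi, total, minor))
    return segs


def oracle_loh(segs, size_mb=15):
    """Per-Mb occupancy array scanner."""
    count = 0
    for chrom, length in TEST_GENOME.chrom_lengths.items():
        n_mb = length // MB
        loh = np.zeros(n_mb, dtype=bool)
        for s in segs:
            if s.chrom == chrom and s.cn_minor == 0 and s.cn_total >= 1:
                loh[s.start // MB : s.end // MB] = True
        for flag, group in itertools.groupby(loh):
            run = len(list(group))
            if flag and run > size_mb and run < n_mb:
                count += 1
    return count


def merge_same_state(tuples):
    """(start, end, total, minor) tuples -> contiguous same-state merged."""
    out = []
    for t in tuples:
        if out and out[-1][1] == t[0] and out[-1][2:] == t[2:]:
            out[-1] = (out[-1][0], t[1], t[2], t[3])
        else:
            out.append(tuple(t))
    return out


def oracle_tai(segs):
    count = 0
    for chrom in TEST_GENOME.chrom_lengths:
        length = TEST_GENOME.length(chrom)
        cen_lo, cen_hi = TEST_GENOME.centromere(chrom)
        tuples = sorted(
            (s.start, s.end, s.cn_total, s.cn_minor)
            for s in segs
            if s.chrom == chrom
        )
        for start, end, total, minor in merge_same_state(tuples):
            ai = minor != total - minor
            touches_end = start == 0 or end == length
            spans_cen = start < cen_lo and end > cen_hi
            if ai and touches_end and not spans_cen:
                count += 1
    return count


def oracle_lst(segs, break_mb=10, smooth_mb=3):
    count = 0
    for chrom in TEST_GENOME.chrom_lengths:
        tuples = sorted(
            (s.start, s.end, s.cn_total, s.cn_minor)
            for s in segs
            if s.chrom == chrom
        )
        merged = merge_same_state(tuples)
        kept = [t for t in merged if t[1] - t[0] >= smooth_mb * MB]
        # survivors with identical states re-merge even across the removed gap
        runs = []
        for t in kept:
            if runs and runs[-1][2:] == t[2:]:
                runs[-1] = (runs[-1][0], t[1], t[2], t[3])
            else:
                runs.append(t)
        for a, b in zip(runs, runs[1:]):
            if a[1] - a[0] >= break_mb * MB and b[1] - b[0] >= break_mb * MB:
                count += 1
    return count


class TestClassification:
    def test_het(self):
        assert classify_segment_loh(AlleleSegment("S", "chr1", 0, MB, 2, 1)) == LOHClass.HET

    @pytest.mark.parametrize(
        "total,minor,expected",
        [
            (2, 0, LOHClass.NLOH),
            (1, 0, LOHClass.DLOH),
            (0, 0, LOHClass.DLOH),
            (3, 0, LOHClass.ALOH),
            (4, 2, LOHClass.BCNA),
            (5, 2, LOHClass.ASCNA),
        ],
    )
    def test_named_states(self, total, minor, expected):
        seg = AlleleSegment("S", "chr1", 0, MB, total, minor)
        assert classify_segment_loh(seg) == expected

    def test_full_enumeration_matches_oracle(self):
        """The classifier is total over every valid (total <= 8, minor <= 4)."""
        for total in range(9):
            for minor in range(min(total // 2, 4) + 1):
                seg = AlleleSegment("S", "chr1", 0, MB, total, minor)
                assert classify_segment_loh(seg) == oracle_classify(total, minor)

    def test_minor_allele_invariant_enforced(self):
        with pytest.raises(ValidationError):
            AlleleSegment("S", "chr1", 0, MB, 2, 2)


class TestScarIndices:
    def test_single_long_nloh_counts_once(self):
        segs = [
            AlleleSegment("S", "chr1", 0, 20 * MB, 2, 0),
            AlleleSegment("S", "chr1", 20 * MB, 60 * MB, 2, 1),
        ]
        assert compute_loh_count(segs, TEST_GENOME.chrom_lengths) == 1

    def test_whole_chromosome_loh_excluded(self):
        segs = [AlleleSegment("S", "chr1", 0, 60 * MB, 2, 0)]
        assert compute_loh_count(segs, TEST_GENOME.chrom_lengths) == 0

    def test_telomeric_ai_counts(self):
        segs = [
            AlleleSegment("S", "chr1", 0, 20 * MB, 3, 1),
            AlleleSegment("S", "chr1", 20 * MB, 60 * MB, 2, 1),
        ]
        assert compute_tai_count(segs, TEST_GENOME) == 1

    def test_centromere_crossing_interstitial_excluded(self):
        segs = [
            AlleleSegment("S", "chr1", 0, 10 * MB, 2, 1),
            AlleleSegment("S", "chr1", 10 * MB, 50 * MB, 3, 1),
            AlleleSegment("S", "chr1", 50 * MB, 60 * MB, 2, 1),
        ]
        assert compute_tai_count(segs, TEST_GENOME) == 0

    def test_single_segment_chromosome_no_lst(self):
        segs = [AlleleSegment("S", "chr1", 0, 60 * MB, 2, 1)]
        assert compute_lst_count(segs) == 0

    def test_adjacent_large_segments_one_lst(self):
        segs = [
            AlleleSegment("S", "chr1", 0, 20 * MB, 2, 1),
            AlleleSegment("S", "chr1", 20 * MB, 40 * MB, 3, 1),
        ]
        assert compute_lst_count(segs) == 1

    def test_random_tilings_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            segs = random_tiling(rng)
            assert compute_loh_count(segs, TEST_GENOME.chrom_lengths) == oracle_loh(segs)
            assert compute_tai_count(segs, TEST_GENOME) == oracle_tai(segs)
            assert compute_lst_count(segs) == oracle_lst(segs)

    def test_segment_beyond_chromosome_rejected(self):
        segs = [AlleleSegment("S", "chr1", 0, 61 * MB, 2, 0)]
        with pytest.raises(ValidationError):
            compute_loh_count(segs, TEST_GENOME.chrom_lengths)

    def test_hrd_sum_split_invariance(self):
        """hrd_sum is unchanged when a segment is split into identical halves."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            segs = random_tiling(rng)
            base = compute_hrd(segs, TEST_GENOME)
            idx = int(rng.integers(len(segs)))
            seg = segs[idx]
            if seg.end - seg.start < 2:
                continue
            mid = (seg.start + seg.end) // 2
            split = segs[:idx] + [
                AlleleSegment(seg.sample_id, seg.chrom, seg.start, mid, seg.cn_total, seg.cn_minor),
                AlleleSegment(seg.sample_id, seg.chrom, mid, seg.end, seg.cn_total, seg.cn_minor),
            ] + segs[idx + 1 :]
            after = compute_hrd(split, TEST_GENOME)
            assert after.hrd_sum == base.hrd_sum


class TestHRDCall:
    def test_sum_26_is_hrd(self):
        res = HRDResult("S", loh_count=10, tai_count=8, lst_count=8)
        assert res.hrd_sum == 26 and res.hrd_status == "HRD"

    def test_sum_25_is_hrr(self):
        """The call uses a strict inequality: a sum exactly at the threshold is HRR."""
        res = HRDResult("S", loh_count=10, tai_count=8, lst_count=7)
        assert res.hrd_sum == 25 and res.hrd_status == "HRR"

    def test_all_het_genome_is_hrr(self):
        segs = [
            AlleleSegment("S", chrom, 0, 60 * MB, 2, 1)
            for chrom in TEST_GENOME.chrom_lengths
        ]
        res = compute_hrd(segs, TEST_GENOME)
        assert (res.loh_count, res.tai_count, res.lst_count) == (0, 0, 0)
        assert res.hrd_status == "HRR"


class TestGeneCNLabels:
    @pytest.mark.parametrize(
        "cn,label",
        [(5, "Amp"), (0.5, "Del"), (4.0, "Neutral"), (1.0, "Neutral"), (2.0, "Neutral")],
    )
    def test_labels(self, cn, label):
        assert label_gene_cn(cn) == label

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            label_gene_cn(-1)


class TestTMB:
    def test_arithmetic(self):
        muts = [MutationRecord("S", f"g{i}", "nonsynonymous") for i in range(62)]
        assert compute_tmb(muts, 50.0) == pytest.approx(1.24)

    def test_zero_mutations(self):
        assert compute_tmb([], 30.0) == 0.0

    def test_synonymous_excluded(self, rng):
        classes = rng.choice(["nonsynonymous", "synonymous", "other"], size=100)
        muts = [MutationRecord("S", f"g{i}", c) for i, c in enumerate(classes)]
        expected = sum(1 for c in classes if c == "nonsynonymous") / 10.0
        assert compute_tmb(muts, 10.0) == pytest.approx(expected)

    def test_bad_callable_size(self):
        with pytest.raises(ConfigError):
            compute_tmb([], 0)
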
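"""ROH detection against a brute-force sub-run oracle; shared-LOH against
per-base set algebra; windowed heterozygosity against a hand tally."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohmap.autozygosity import (
    HetWindow,
    RohParams,
    detect_roh,
    merge_segments,
    shared_loh,
    window_heterozygosity,
)
from rohmap.errors import ValidationError
from rohmap.formats_io import segment_from_display
from rohmap.intervals import Segment, SegmentSet
from rohmap.variants import AnnotatedVariant, GenotypePanel


def make_panel(codes, positions=None, chrom="chr1", sample="P1"):
    codes = np.asarray(codes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, len(codes) + 1) * 1000
    markers = [(chrom, int(p), f"m{i}") for i, p in enumerate(positions)]
    return GenotypePanel(markers, [sample], codes[:, None])


def roh_oracle(codes, positions, params: RohParams):
    """Enumerate every sub-run satisfying the het/missing budgets, keep the
    maximal ones, filter by size/span, and union them per base."""
    codes = np.asarray(codes)
    positions = np.asarray(positions)
    n = len(codes)
    het = np.concatenate([[0], np.cumsum(codes == 1)])
    mis = np.concatenate([[0], np.cumsum(codes == -1)])

    def valid(i, j):  # inclusive indices
        return (
            het[j + 1] - het[i] <= params.max_het
            and mis[j + 1] - mis[i] <= params.max_missing
        )

    kept = []
    for i in range(n):
        for j in range(i, n):
            if not valid(i, j):
                continue
            # maximal iff both one-step extensions are out of bounds/invalid
            if i > 0 and valid(i - 1, j):
                continue
            if j < n - 1 and valid(i, j + 1):
                continue
            if j - i + 1 < params.min_markers:
                continue
            start, end = int(positions[i]) - 1, int(positions[j])
            if end - start < params.min_length_bp:
                continue
            kept.append((start, end))
    merged = []
    for s, e in sorted(kept):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class TestDetectRoh:
    def test_all_het_sample_has_no_runs(self):
        panel = make_panel([1] * 1000)
        assert len(detect_roh(panel, "P1", RohParams(min_markers=10))) == 0

    def test_single_interior_het_within_budget(self):
        codes = [2] * 8 + [1] + [2] * 11
        panel = make_panel(codes)
        params = RohParams(min_markers=10, min_length_bp=1, max_het=1, max_missing=0)
        segs = detect_roh(panel, "P1", params)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.n_markers == 20
        assert (seg.start, seg.end) == (999, 20_000)

    def test_zero_het_budget_splits_run(self):
        codes = [2] * 8 + [1] + [2] * 11
        panel = make_panel(codes)
        params = RohParams(min_markers=10, min_length_bp=1, max_het=0, max_missing=0)
        segs = detect_roh(panel, "P1", params)
        # the 8-marker run fails min_markers; only the 11-marker run survives
        assert [s.n_markers for s in segs] == [11]
        params_loose = RohParams(min_markers=5, min_length_bp=1, max_het=0, max_missing=0)
        assert [s.n_markers for s in detect_roh(panel, "P1", params_loose)] == [8, 11]

    def test_unknown_sample_and_empty_panel(self):
        panel = make_panel([2, 2, 2])
        with pytest.raises(KeyError):
            detect_roh(panel, "nope")
        empty = GenotypePanel([], ["P1"], np.zeros((0, 1), dtype=np.int8))
        assert len(detect_roh(empty, "P1")) == 0

    @settings(derandomize=True, deadline=None, max_examples=120)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 200),
        max_het=st.integers(0, 3),
        max_missing=st.integers(0, 3),
        min_markers=st.integers(1, 30),
    )
    def test_equals_bruteforce_oracle(self, seed, n, max_het, max_missing, min_markers):
        rng = np.random.default_rng(seed)
        codes = rng.choice([-1, 0, 1, 2], size=n, p=[0.05, 0.4, 0.2, 0.35])
        positions = np.cumsum(rng.integers(1, 5000, size=n))
        params = RohParams(min_markers, 1, max_het, max_missing)
        panel = make_panel(codes, positions)
        got = [(s.start, s.end) for s in detect_roh(panel, "P1", params)]
        assert got == roh_oracle(codes, positions, params)

    def test_recovers_planted_segments_under_error(self, noisy_dataset):
        """Every true autozygous tract >= 2 Mb is recovered with >= 90%
        reciprocal overlap at 0.5% genotyping error, after gap-tolerant
        merging repairs the error-induced fragmentation."""
        ds = noisy_dataset
        for sid, truth_set in ds.truth.autozygous_segments.items():
            detected = merge_segments(detect_roh(ds.panel, sid), 100_000)
            for seg in truth_set:
                if seg.length < 2_000_000:
                    continue
                best = max(
                    (d for d in detected if d.chrom == seg.chrom),
                    key=lambda d: min(d.end, seg.end) - max(d.start, seg.start),
                    default=None,
                )
                assert best is not None, f"{sid}: no ROH near {seg}"
                ov = min(best.end, seg.end) - max(best.start, seg.start)
                assert ov >= 0.9 * seg.length
                assert ov >= 0.9 * best.length


class TestSharedLoh:
    def test_single_affected_identity(self):
        roh = {"P1": SegmentSet([Segment("chr1", 0, 100)])}
        assert shared_loh(roh, ["P1"]) == SegmentSet([Segment("chr1", 0, 100)])

    def test_worked_example(self):
        roh = {
            "A1": SegmentSet([Segment("chr1", 0, 100), Segment("chr1", 50, 200)]),
            "A2": SegmentSet([Segment("chr1", 60, 150)]),
            "U1": SegmentSet([Segment("chr1", 120, 130)]),
        }
        got = shared_loh(roh, ["A1", "A2"], ["U1"], min_shared_bp=0)
        assert got == SegmentSet(
            [Segment("chr1", 60, 120), Segment("chr1", 130, 150)]
        )

    def test_empty_affected_rejected(self):
        with pytest.raises(ValidationError):
            shared_loh({}, [])

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(seed=st.integers(0, 100_000))
    def test_equals_perbase_algebra(self, seed):
        rng = np.random.default_rng(seed)
        L = 10_000

        def random_set():
            segs = []
            for _ in range(rng.integers(0, 8)):
                s = int(rng.integers(0, L - 1))
                e = int(min(L, s + rng.integers(1, 2000)))
                segs.append(Segment("chr1", s, e))
            return SegmentSet(segs)

        affected = [f"A{i}" for i in range(int(rng.integers(1, 4)))]
        unaffected = [f"U{i}" for i in range(int(rng.integers(0, 3)))]
        roh = {s: random_set() for s in affected + unaffected}
        min_bp = int(rng.integers(0, 500))
        got = shared_loh(roh, affected, unaffected, min_bp)

        def mask(ss):
            m = np.zeros(L, dtype=bool)
            for seg in ss:
                m[seg.start : seg.end] = True
            return m

        expect = np.ones(L, dtype=bool)
        for s in affected:
            expect &= mask(roh[s])
        for s in unaffected:
            expect &= ~mask(roh[s])
        # drop residual pieces shorter than min_bp
        exp_ivals = []
        i = 0
        while i < L:
            if expect[i]:
                j = i
                while j < L and expect[j]:
                    j += 1
                if j - i >= min_bp:
                    exp_ivals.append((i, j))
                i = j
            else:
                i += 1
        assert [(s.start, s.end) for s in got] == exp_ivals

    def test_covers_planted_variant(self, default_dataset):
        ds = default_dataset
        roh = {
            s: detect_roh(ds.panel, s)
            for s in ds.pedigree.affected_ids + ds.pedigree.unaffected_sibling_ids()
        }
        shared = shared_loh(
            roh, ds.pedigree.affected_ids, ds.pedigree.unaffected_sibling_ids()
        )
        v = ds.truth.causal_variant
        assert shared.contains(v.chrom, v.pos - 1)


class TestMergeSegments:
    def test_array_gap_fixture(self):
        # two adjacent array-derived segments separated by a 419 bp gap fuse
        # under a 1 kb tolerance into one continuous segment
        a = segment_from_display("chr6", 19_686_123, 19_803_768)
        b = segment_from_display("chr6", 19_804_188, 21_778_105)
        merged = merge_segments(SegmentSet([a, b]), max_gap_bp=1000)
        assert len(merged) == 1
        (seg,) = merged
        from rohmap.intervals import to_display

        assert to_display(seg.start, seg.end) == (19_686_123, 21_778_105)

    def test_monotone_on_table_rows(self):
        rows = [
            (71_016_157, 72_070_710), (72_320_251, 73_669_855),
            (73_671_276, 75_891_939), (77_249_400, 79_204_389),
            (79_302_419, 82_139_004), (82_147_487, 83_157_896),
            (83_541_966, 88_441_286), (88_594_159, 89_910_070),
            (89_915_484, 91_765_486), (91_766_720, 93_152_115),
            (93_251_750, 95_410_845),
        ]
        segs = SegmentSet(
            [segment_from_display("chr12", s, e) for s, e in rows]
        )
        merged = merge_segments(segs, max_gap_bp=10**6)
        assert len(merged) <= len(segs)
        assert merged.total_bp >= segs.total_bp

    def test_zero_gap_identity_on_disjoint(self):
        segs = SegmentSet([Segment("chr1", 0, 10), Segment("chr1", 20, 30)])
        assert merge_segments(segs, 0) == segs

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            merge_segments(SegmentSet(), -5)


def _variant(pos, code, chrom="chr6", sample="P1"):
    return AnnotatedVariant(
        chrom, pos, "A", "G", genotypes={sample: code}
    )


class TestWindowHeterozygosity:
    def test_pure_windows(self):
        hom = [_variant(p, 2) for p in (10, 500, 900)]
        (w,) = window_heterozygosity(hom, "P1", ("chr6", 0, 1000), 1000)
        assert (w.n_het, w.n_hom, w.avg_het) == (0, 3, 0.0)
        het = [_variant(p, 1) for p in (10, 500)]
        (w,) = window_heterozygosity(het, "P1", ("chr6", 0, 1000), 1000)
        assert w.avg_het == 1.0

    def test_empty_window_is_missing_not_zero(self):
        ws = window_heterozygosity([], "P1", ("chr6", 0, 2000), 1000)
        assert [w.avg_het for w in ws] == [None, None]

    def test_hand_tally_across_windows(self):
        # 10 variants over 3 windows of 100 bp anchored at region start 50
        spec = [
            (55, 1), (60, 2), (99, 1), (120, 0),  # hom-ref excluded
            (151, 1), (200, 2), (210, 2), (240, -1),  # missing excluded
            (260, 1), (340, 2),
        ]
        calls = [_variant(p, c) for p, c in spec]
        ws = window_heterozygosity(calls, "P1", ("chr6", 50, 350), 100)
        got = [(w.start, w.end, w.n_het, w.n_hom, w.avg_het) for w in ws]
        assert got == [
            (50, 150, 2, 1, pytest.approx(2 / 3)),
            (150, 250, 1, 2, pytest.approx(1 / 3)),
            (250, 350, 1, 1, pytest.approx(1 / 2)),
        ]
        # conservation: window het counts add up to the region total
        assert sum(w.n_het for w in ws) == sum(1 for _, c in spec if c == 1)

    def test_terminal_window_truncated(self):
        ws = window_heterozygosity([], "P1", ("chr6", 0, 250), 100)
        assert [(w.start, w.end) for w in ws] == [(0, 100), (100, 200), (200, 250)]

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            window_heterozygosity([], "P1", ("chr6", 0, 100), 0)
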
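"""Tag counting, arcsine normalization, region assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stcluster import (
    GenomeLayout,
    assemble_regions,
    bedgraph_to_counts,
    count_tags,
    normalize_track,
)
from stcluster.preprocess import BinnedTrack


class TestCountTags:
    def test_empty_stream(self, small_layout):
        counts, total = count_tags([], small_layout)
        assert total == 0 and not counts.any()

    def test_midpoint_assignment(self, small_layout):
        counts, total = count_tags([("chr1", 100, 300)], small_layout)
        assert total == 1
        assert counts[1] == 1 and counts.sum() == 1  # midpoint 200 -> bin 1

    def test_additivity(self, small_layout):
        reads = [("chr1", 600 + i, 700 + i) for i in range(10)]  # midpoints in bin 3
        counts, total = count_tags(reads, small_layout)
        assert counts[3] == 10 and total == 10

    def test_invalid_interval_raises(self, small_layout):
        with pytest.raises(ValueError, match="start >= end"):
            count_tags([("chr1", 300, 300)], small_layout)

    def test_unknown_chromosome_skipped_with_warning(self, small_layout, caplog):
        with caplog.at_level("WARNING"):
            counts, total = count_tags(
                [("chrUn", 0, 100), ("chr1", 0, 100)], small_layout
            )
        assert total == 1 and counts[0] == 1
        assert any("chrUn" in r.message for r in caplog.records)

    def test_out_of_scope_midpoint_not_counted(self):
        layout = GenomeLayout((("chr1", 9999),))  # only one complete region
        counts, total = count_tags([("chr1", 6000, 6100)], layout)
        assert total == 0 and not counts.any()

    def test_five_prime_mode_is_strand_aware(self, small_layout):
        reads = pd.DataFrame(
            [
                ("chr1", 390, 600, "r1", 0, "+"),  # 5' end 390+20 -> bin 2
                ("chr1", 390, 601, "r2", 0, "-"),  # 5' end 600-20 -> bin 2
                ("chr1", 100, 300, "r3", 0, "+"),  # 120 -> bin 0
            ]
        )
        counts, total = count_tags(reads, small_layout, mode="five_prime", shift=20)
        assert total == 3
        assert counts[2] == 2 and counts[0] == 1

    def test_five_prime_unstranded_defaults_to_plus(self, small_layout):
        counts, total = count_tags(
            [("chr1", 100, 300)], small_layout, mode="five_prime", shift=0
        )
        assert total == 1 and counts[0] == 1

    def test_dataframe_input_matches_tuples(self, small_layout):
        recs = [("chr1", 100, 300), ("chr2", 0, 50), ("chr1", 7000, 7400)]
        c1, t1 = count_tags(recs, small_layout)
        c2, t2 = count_tags(pd.DataFrame(recs), small_layout)
        assert t1 == t2 and (c1 == c2).all()


@settings(deadline=None, max_examples=30)
@given(
    st.lists(
        st.tuples(st.integers(0, 19_000), st.integers(1, 900)), max_size=50
    )
)
def test_count_conservation(intervals):
    """Total tags equals the sum over bins when nothing is skipped."""
    layout = GenomeLayout((("chr1", 20_000), ("chr2", 10_000)))
    recs = [("chr1", s, s + l) for s, l in intervals if (2 * s + l) // 2 < 20_000]
    counts, total = count_tags(recs, layout)
    assert counts.sum() == total == len(recs)


class TestNormalizeTrack:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (0, 100, 0.0),
            (100, 100, math.pi / 2),
            (25, 100, math.pi / 6),  # arcsin(sqrt(0.25)) = arcsin(0.5)
        ],
    )
    def test_arcsine_closed_form(self, count, total, expected):
        track = normalize_track(np.array([count]), total)
        assert track.values[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_library_gives_zero_track(self):
        track = normalize_track(np.array([0, 0, 0]), 0)
        assert not track.values.any()

    def test_values_bounded_by_pi_half(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=200)
        track = normalize_track(counts, int(counts.sum()))
        assert (track.values >= 0).all() and (track.values <= math.pi / 2).all()

    def test_monotone_in_count(self):
        counts = np.arange(0, 101)
        vals = normalize_track(counts, 100).values
        assert (np.diff(vals) >= 0).all()

    def test_asinh_variant(self):
        track = normalize_track(np.array([50]), 100, transform="asinh")
        assert track.values[0] == pytest.approx(np.arcsinh(0.5))


class TestAssembleRegions:
    def _tracks(self, layout, K=3, cell="c"):
        rng = np.random.default_rng(1)
        return [
            BinnedTrack(cell, f"m{k}", rng.random(layout.total_bins), 100)
            for k in range(K)
        ]

    def test_shape_and_mark_order(self, small_layout):
        tracks = self._tracks(small_layout)
        tensor = assemble_regions(tracks, small_layout)
        assert tensor.data.shape == (6, 3, 25)
        assert tensor.marks == ("m0", "m1", "m2")

    def test_region_rows_are_track_slices(self, small_layout):
        tracks = self._tracks(small_layout)
        tensor = assemble_regions(tracks, small_layout)
        B = small_layout.bins_per_region
        for k, t in enumerate(tracks):
            assert (tensor.region(1)[k] == t.values[B : 2 * B]).all()

    def test_reassembly_is_lossless(self, small_layout):
        """Concatenating each mark's rows across regions rebuilds the track."""
        tracks = self._tracks(small_layout)
        tensor = assemble_regions(tracks, small_layout)
        for k, t in enumerate(tracks):
            rebuilt = np.concatenate([tensor.region(i)[k] for i in range(tensor.n_regions)])
            assert (rebuilt == t.values).all()

    def test_mismatched_lengths_rejected(self, small_layout):
        tracks = self._tracks(small_layout)
        bad = BinnedTrack("c", "m9", np.zeros(10), 1)
        with pytest.raises(ValueError, match="bins"):
            assemble_regions(tracks + [bad], small_layout)

    def test_single_mark_rejected(self, small_layout):
        with pytest.raises(ValueError, match="K >= 2"):
            assemble_regions(self._tracks(small_layout, K=1), small_layout)


class TestBedgraph:
    def test_aligned_records_pass_through(self, small_layout):
        # one record exactly covering bin 2 of chr1
        df = pd.DataFrame([("chr1", 400, 600, 7.0)])
        counts, total = bedgraph_to_counts(df, small_layout)
        assert counts[2] == pytest.approx(7.0)
        assert total == pytest.approx(7.0)

    def test_overlap_weighted_split(self, small_layout):
        # record spans bins 0 and 1 equally -> half the value to each
        df = pd.DataFrame([("chr1", 100, 300, 4.0)])
        counts, _ = bedgraph_to_counts(df, small_layout)
        assert counts[0] == pytest.approx(2.0) and counts[1] == pytest.approx(2.0)
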
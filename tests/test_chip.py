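import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swrseq.chip import (
    CoverageTrack,
    VivosXQuant,
    call_islands,
    call_swr_dependent,
    classify_positions,
    compute_vivosx_scaling,
    count_at_nucleosomes,
    coverage_rpm,
    filter_fragments_by_length,
)
from swrseq.io import FragmentCollection, GenomicInterval
from swrseq.simulate import NucleosomeRecord


def _frags(*triples):
    return FragmentCollection(GenomicInterval(c, s, e) for c, s, e in triples)


def _nuc(i, chrom="c", start=0, cls="other"):
    return NucleosomeRecord(
        id=f"n{i}", interval=GenomicInterval(chrom, start, start + 147),
        position_class=cls,
    )


class TestLengthFilter:
    @pytest.mark.parametrize(
        "bounds,lengths,kept",
        [
            ((120, 170), [119, 120, 170, 171], [120, 170]),
            ((140, 154), [139, 147, 155], [147]),
            ((1, 10**9), [119, 147, 400], [119, 147, 400]),
        ],
    )
    def test_inclusive_bounds(self, bounds, lengths, kept):
        frags = _frags(*[("c", 0, l) for l in lengths])
        out = filter_fragments_by_length(frags, *bounds)
        assert [f.length for f in out] == kept

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            filter_fragments_by_length(_frags(), 100, 50)


class TestCoverageRpm:
    def test_single_fragment_definition(self):
        track = coverage_rpm(_frags(("c", 0, 147)), {"c": 300})
        assert (track["c"][:147] == 1e6).all()
        assert (track["c"][147:] == 0).all()
        assert track.normalization == "RPM"

    def test_duplicate_fragments_scale_invariant(self):
        one = coverage_rpm(_frags(("c", 10, 60)), {"c": 100})
        two = coverage_rpm(_frags(("c", 10, 60), ("c", 10, 60)), {"c": 100})
        np.testing.assert_allclose(one["c"], two["c"])

    def test_total_equals_1e6_times_mean_fragment_length(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 500, size=40)
        lengths = rng.integers(50, 200, size=40)
        frags = _frags(*[("c", int(s), int(s + l)) for s, l in zip(starts, lengths)])
        track = coverage_rpm(frags, {"c": 1000})
        assert track.total() == pytest.approx(1e6 * lengths.mean())

    def test_fragment_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            coverage_rpm(_frags(("c", 90, 120)), {"c": 100})

    def test_masked_bases_zeroed_and_flagged(self):
        track = coverage_rpm(
            _frags(("c", 0, 100)), {"c": 100}, mask=[GenomicInterval("c", 20, 30)]
        )
        assert track.mask_applied
        assert (track["c"][20:30] == 0).all()
        assert (track["c"][:20] == 1e6).all()


class TestVivosxScaling:
    def test_identical_strains_give_unity(self):
        q = VivosXQuant([(0.12, 0.57, 0.31)])
        assert compute_vivosx_scaling(q, q) == pytest.approx(1.0)

    def test_printed_rounded_fractions_give_0529(self):
        # rounded published fractions give 36.5/69 ~= 0.529; the in-study
        # factor 0.558 came from unrounded band intensities
        wt = VivosXQuant([(0.12, 0.57, 0.31)])
        mut = VivosXQuant([(0.025, 0.34, 0.635)])
        assert compute_vivosx_scaling(wt, mut) == pytest.approx(0.365 / 0.69, abs=1e-9)
        assert compute_vivosx_scaling(wt, mut) == pytest.approx(0.529, abs=1e-3)

    def test_zero_mutant_bound_gives_zero_factor(self):
        wt = VivosXQuant([(0.12, 0.57, 0.31)])
        mut = VivosXQuant([(0.0, 0.0, 1.0)])
        assert compute_vivosx_scaling(wt, mut) == 0.0

    def test_zero_wt_bound_rejected(self):
        wt = VivosXQuant([(0.0, 0.0, 1.0)])
        with pytest.raises(ValueError):
            compute_vivosx_scaling(wt, wt)

    def test_fraction_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            VivosXQuant([(0.5, 0.5, 0.5)])


class TestCountAtNucleosomes:
    def test_uniform_track_gives_uniform_counts(self):
        track = CoverageTrack({"c": np.full(500, 7.5)})
        nucs = [_nuc(0, start=0), _nuc(1, start=200)]
        counts = count_at_nucleosomes(track, nucs)
        assert (counts == 7.5).all()

    def test_matches_bruteforce_mean_on_random_tracks(self):
        rng = np.random.default_rng(1)
        track = CoverageTrack({"c": rng.random(1000)})
        nucs = [_nuc(i, start=s) for i, s in enumerate((0, 150, 400, 853))]
        counts = count_at_nucleosomes(track, nucs)
        for rec in nucs:
            manual = np.mean(
                [track["c"][b] for b in range(rec.dyad - 73, rec.dyad + 74)]
            )
            assert counts[rec.id] == pytest.approx(manual)

    def test_masked_nucleosome_becomes_nan(self):
        track = CoverageTrack({"c": np.ones(500)})
        nucs = [_nuc(0, start=0), _nuc(1, start=200)]
        counts = count_at_nucleosomes(track, nucs, mask=[GenomicInterval("c", 140, 150)])
        assert np.isnan(counts["n0"])
        assert counts["n1"] == 1.0


class TestCallSwrDependent:
    def _call(self, wt_pairs, mut_pairs, noise=None, threshold=10.0):
        nucs = [_nuc(i, start=200 * i) for i in range(len(wt_pairs))]
        ids = [n.id for n in nucs]
        wt = [pd.Series([p[r] for p in wt_pairs], index=ids) for r in range(2)]
        mut = [pd.Series([p[r] for p in mut_pairs], index=ids) for r in range(2)]
        if noise is None:
            noise = np.array([0.0, 1, 2, 3, 4])
        return call_swr_dependent(wt, mut, nucs, threshold=threshold, noise=noise)

    def test_equal_signals_call_nothing(self):
        t = self._call([(5, 5), (7, 7)], [(5, 5), (7, 7)])
        assert not t["swr_dependent"].any()

    def test_threshold_must_hold_in_both_replicates(self):
        t = self._call([(12, 11), (12, 9)], [(0, 0), (0, 0)])
        assert bool(t.loc["n0", "swr_dependent"]) is True
        assert bool(t.loc["n1", "swr_dependent"]) is False

    def test_calls_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        wt_pairs = rng.normal(20, 10, size=(30, 2))
        mut_pairs = rng.normal(5, 2, size=(30, 2))
        called_prev = None
        for thr in (0.0, 5.0, 10.0, 20.0, 40.0):
            t = self._call(wt_pairs, mut_pairs, threshold=thr)
            called = set(t.index[t["swr_dependent"]])
            if called_prev is not None:
                assert called <= called_prev
            called_prev = called

    def test_scaling_equivariance(self):
        # multiplying mutant counts by c and the scale factor by 1/c leaves
        # deltas, hence calls, unchanged
        rng = np.random.default_rng(3)
        wt_pairs = rng.normal(20, 10, size=(30, 2))
        mut = rng.normal(5, 2, size=(30, 2))
        c = 3.7
        t1 = self._call(wt_pairs, mut)
        t2 = self._call(wt_pairs, (mut * c) * (1 / c))
        pd.testing.assert_series_equal(t1["swr_dependent"], t2["swr_dependent"])

    def test_missing_counts_propagate_uncalled(self):
        t = self._call([(50, 50), (np.nan, 50)], [(0, 0), (0, 0)])
        assert bool(t.loc["n0", "swr_dependent"]) is True
        assert bool(t.loc["n1", "swr_dependent"]) is False

    def test_zero_variance_noise_rejected(self):
        with pytest.raises(ValueError):
            self._call([(12, 11)], [(0, 0)], noise=np.array([1.0, 1.0, 1.0]))

    def test_pvalues_match_scalar_ztest(self):
        from swrseq.stats import one_sample_ztest

        noise = np.array([0.0, 1, 2, 3, 4])
        t = self._call([(12, 11), (3, 2)], [(0, 0), (0, 0)], noise=noise)
        for nid, x in (("n0", 12.0), ("n1", 3.0)):
            ref = one_sample_ztest(x, noise)
            assert t.loc[nid, "z_1"] == pytest.approx(ref.statistic)
            assert t.loc[nid, "p_1"] == pytest.approx(ref.p_value)


class TestClassifyPositions:
    def test_reported_breakdown_arithmetic(self):
        # 10,662 called with 3,921 / 1,334 / 1,507 promoter-proximal leaves
        # 3,900 NDR-distal sites
        nucs, called = [], []
        spec = [("+1", 3921), ("+2", 1334), ("-1", 1507), ("other", 3900)]
        k = 0
        for cls, n in spec:
            for _ in range(n):
                nucs.append(_nuc(k, start=200 * k, cls=cls))
                called.append(f"n{k}")
                k += 1
        counts = classify_positions(called, nucs)
        assert counts["called"] == 10_662
        assert counts["distal"] == counts["called"] - 3921 - 1334 - 1507 == 3900

    def test_no_calls_all_zero(self):
        nucs = [_nuc(0, cls="+1")]
        counts = classify_positions([], nucs)
        assert counts == {"+1": 0, "-1": 0, "+2": 0, "distal": 0, "called": 0}

    def test_all_plus1_gives_zero_distal(self):
        nucs = [_nuc(i, start=200 * i, cls="+1") for i in range(4)]
        counts = classify_positions([n.id for n in nucs], nucs)
        assert counts["+1"] == 4 and counts["distal"] == 0


def _island_members_bruteforce(dyads, min_count, window):
    """Oracle: enumerate all O(n^2) windows; a site is a member iff some
    window of `window` bp covers it together with >= min_count sites."""
    members = set()
    n = len(dyads)
    for i in range(n):
        for j in range(i, n):
            if dyads[j] - dyads[i] <= window - 1 and j - i + 1 >= min_count:
                members.update(range(i, j + 1))
    return members


class TestCallIslands:
    def test_six_sites_within_span_form_one_island(self):
        dyads = [0, 100, 200, 300, 400, 500]
        result = call_islands({"c": dyads})
        assert len(result) == 1
        iv, members, n = result.islands[0]
        assert n == 6 and (iv.start, iv.end) == (0, 501)

    def test_five_sites_below_min_count_form_none(self):
        assert len(call_islands({"c": [0, 100, 200, 300, 400]})) == 0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            call_islands({"c": [100, 50, 200, 300, 400, 500]})

    @settings(max_examples=200, deadline=None)
    @given(
        dyads=st.lists(st.integers(0, 5000), min_size=0, max_size=50, unique=True),
        min_count=st.integers(2, 8),
        window=st.integers(100, 2000),
    )
    def test_membership_matches_bruteforce_enumeration(self, dyads, min_count, window):
        dyads = sorted(dyads)
        result = call_islands({"c": dyads}, min_count=min_count, window=window)
        got = set()
        for _, members, _ in result:
            got.update(members)
        expected = {
            f"c:{dyads[i]}"
            for i in _island_members_bruteforce(dyads, min_count, window)
        }
        assert got == expected

    def test_members_dyads_within_island_interval(self):
        rng = np.random.default_rng(4)
        dyads = sorted(int(x) for x in rng.integers(0, 20_000, size=200))
        for iv, members, n in call_islands({"c": dyads}, min_count=4, window=1000):
            assert n == len(members) >= 4
            positions = [int(m.split(":")[1]) for m in members]
            assert all(iv.start <= p < iv.end for p in positions)
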
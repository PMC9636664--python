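import numpy as np
import pytest

from tadconcord import (
    boundaries_of,
    count_tads,
    one_vs_all_boundaries,
    one_vs_all_domains,
    shared_boundaries,
    shared_domains,
    sharing_profile,
    size_stats,
)


def oracle_shared_boundaries(a, b, t):
    """Brute-force: every pair of boundary bins compared directly."""
    return sum(1 for x in a if any(abs(x - y) <= t for y in b))


def oracle_shared_domains(a, b, t):
    """Brute-force: every pair of domains compared on both ends."""
    return sum(
        1
        for da in a
        if any(
            abs(da.start_bin - db.start_bin) <= t
            and abs(da.end_bin - db.end_bin) <= t
            for db in b
        )
    )


class TestCountsAndSizes:
    def test_count_examples(self, make_tadset):
        assert count_tads(make_tadset([])) == 0
        assert count_tads(make_tadset([(0, 5), (5, 9), (12, 20)])) == 3

    def test_size_stats_examples(self, make_tadset):
        s = size_stats(make_tadset([(0, 10), (10, 30), (30, 60)]))
        assert (s.min, s.median, s.max, s.mean) == (10, 20, 30, 20)

    def test_size_stats_constant_sizes(self, make_tadset):
        s = size_stats(make_tadset([(0, 4), (4, 8), (8, 12), (12, 16)]))
        assert s.min == s.q1 == s.median == s.q3 == s.max == s.mean == 4

    def test_quartiles_linear_interpolation(self, make_tadset):
        # sizes 1,2,3,4
        s = size_stats(make_tadset([(0, 1), (1, 3), (3, 6), (6, 10)]))
        assert (s.q1, s.median, s.q3) == (1.75, 2.5, 3.25)

    def test_empty_set_rejected(self, make_tadset):
        with pytest.raises(ValueError, match="empty"):
            size_stats(make_tadset([]))


class TestSharedBoundaries:
    def test_tolerance_zero_requires_identity(self, make_tadset):
        a = boundaries_of(make_tadset([(0, 10), (10, 20)]))  # {0,10,20}
        b = boundaries_of(make_tadset([(0, 12), (12, 20)]))  # {0,12,20}
        count, matched = shared_boundaries(a, b, 0)
        assert count == 2 and matched == (0, 20)

    def test_tolerance_two_admits_nearby(self, make_tadset):
        a = boundaries_of(make_tadset([(0, 10), (10, 20)]))
        b = boundaries_of(make_tadset([(0, 12), (12, 20)]))
        assert shared_boundaries(a, b, 2)[0] == 3

    def test_self_identity(self, random_tadset):
        for seed in range(10):
            bs = boundaries_of(random_tadset(seed))
            assert shared_boundaries(bs, bs, 0)[0] == len(bs)

    def test_negative_tolerance_rejected(self, make_tadset):
        bs = boundaries_of(make_tadset([(0, 5)]))
        with pytest.raises(ValueError, match="tolerance"):
            shared_boundaries(bs, bs, -1)


class TestSharedDomains:
    def test_both_ends_must_match(self, make_tadset):
        a = make_tadset([(0, 10), (10, 20)])
        b = make_tadset([(0, 12), (12, 20)])
        assert shared_domains(a, b, 0)[0] == 0
        assert shared_domains(a, b, 2)[0] == 2

    def test_self_identity_any_tolerance(self, random_tadset):
        ts = random_tadset(3)
        for t in (0, 1, 5):
            assert shared_domains(ts, ts, t)[0] == len(ts)

    def test_binning_mismatch_rejected(self, make_tadset):
        a = make_tadset([(0, 5)])
        b = make_tadset([(0, 5)], bins=50)
        with pytest.raises(ValueError, match="binning"):
            shared_domains(a, b, 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("tolerance", [0, 1, 2, 3])
    def test_boundaries_match_brute_force(self, random_tadset, tolerance):
        for seed in range(25):
            a = boundaries_of(random_tadset(2 * seed))
            b = boundaries_of(random_tadset(2 * seed + 1))
            assert (
                shared_boundaries(a, b, tolerance)[0]
                == oracle_shared_boundaries(a.bins, b.bins, tolerance)
            )

    @pytest.mark.parametrize("tolerance", [0, 1, 2, 3])
    def test_domains_match_brute_force(self, random_tadset, tolerance):
        for seed in range(25):
            a = random_tadset(2 * seed)
            b = random_tadset(2 * seed + 1)
            assert (
                shared_domains(a, b, tolerance)[0]
                == oracle_shared_domains(a, b, tolerance)
            )


class TestMonotonicityAndBounds:
    def test_counts_non_decreasing_in_tolerance(self, random_tadset):
        for seed in range(20):
            a = random_tadset(3 * seed)
            b = random_tadset(3 * seed + 1)
            ab = [shared_boundaries(boundaries_of(a), boundaries_of(b), t)[0]
                  for t in range(5)]
            ad = [shared_domains(a, b, t)[0] for t in range(5)]
            assert ab == sorted(ab) and ad == sorted(ad)

    def test_counts_bounded_by_query_size(self, random_tadset):
        a = random_tadset(40)
        b = random_tadset(41)
        assert 0 <= shared_boundaries(boundaries_of(a), boundaries_of(b), 2)[0] \
            <= len(boundaries_of(a))
        assert 0 <= shared_domains(a, b, 2)[0] <= len(a)


class TestOneVsAll:
    def test_against_self_gives_full_counts(self, random_tadset):
        ref = random_tadset(1)
        table = one_vs_all_boundaries(ref, [ref.with_label("copy")], [0, 1, 2])
        assert (table.loc["copy"] == len(boundaries_of(ref))).all()
        dt = one_vs_all_domains(ref, [ref.with_label("copy")], [0, 1])
        assert (dt.loc["copy"] == len(ref)).all()

    def test_rows_non_decreasing_along_tolerance(self, random_tadset):
        ref = random_tadset(5)
        others = [random_tadset(6), random_tadset(7)]
        table = one_vs_all_boundaries(ref, others, [0, 1, 2, 3])
        assert (table.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_empty_others_rejected(self, random_tadset):
        with pytest.raises(ValueError):
            one_vs_all_boundaries(random_tadset(0), [], [0])


class TestSharingProfile:
    def test_identical_pair_all_mass_at_one(self, random_tadset):
        a = random_tadset(0)
        prof = sharing_profile([a, a.with_label("b")], 0, "boundaries")
        n = len(boundaries_of(a))
        assert prof.counts[1].tolist() == [n, n]
        assert prof.counts[0].sum() == 0

    def test_disjoint_boundaries_all_mass_at_zero(self, make_tadset):
        a = make_tadset([(0, 10), (20, 30)], label="a")
        b = make_tadset([(2, 14), (40, 50)], label="b")
        prof = sharing_profile([a, b], 0, "boundaries")
        assert prof.counts[0].tolist() == [4, 4]

    def test_three_sets_two_equal_one_disjoint(self, make_tadset):
        a = make_tadset([(0, 10)], label="A")
        b = make_tadset([(0, 10)], label="B")
        c = make_tadset([(40, 50)], label="C")
        prof = sharing_profile([a, b, c], 0, "domains")
        assert prof.counts.loc["A", 1] == 1 and prof.counts.loc["A", 0] == 0
        assert prof.counts.loc["C", 0] == 1

    def test_mass_conservation_and_percentages(self, random_tadset):
        sets = [random_tadset(s, label=f"d{s}") for s in range(4)]
        for mode in ("boundaries", "domains"):
            prof = sharing_profile(sets, 1, mode)
            for s in sets:
                total = (len(boundaries_of(s)) if mode == "boundaries" else len(s))
                assert prof.counts.loc[s.label].sum() == total
            np.testing.assert_allclose(
                prof.percentages.sum(axis=1), 100.0, atol=1e-9
            )

    def test_fewer_than_two_sets_rejected(self, random_tadset):
        with pytest.raises(ValueError):
            sharing_profile([random_tadset(0)], 0)
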
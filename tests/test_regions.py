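import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import occudiff as od
from occudiff.regions import RegionTestConfig, _u_statistic


def brute_force_two_sided_p(x, y):
    """Independent oracle: enumerate all group assignments, count U directly."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    obs_dev = abs(u_of(list(x), list(y)) - mu)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(xs, ys) - mu) >= obs_dev - 1e-9:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_tiny_sample(self):
        u, p = od.mann_whitney_u(np.array([1, 2]), np.array([3, 4]))
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_all_tied_gives_p_one(self):
        u, p = od.mann_whitney_u(np.full(5, 2.0), np.full(7, 2.0))
        assert p == 1.0

    def test_forty_vs_forty_separated_is_overwhelming(self):
        u, p = od.mann_whitney_u(np.full(40, 10.0), np.full(40, 1.0))
        assert u == 1600.0
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(od.GenomeValidationError):
            od.mann_whitney_u(np.array([]), np.array([1.0]))

    @given(
        x=st.lists(st.integers(0, 20), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 20), min_size=1, max_size=8),
    )
    def test_swap_symmetry(self, x, y):
        """Swapping samples maps U -> n1*n2 - U and leaves p unchanged."""
        x, y = np.array(x, dtype=float), np.array(y, dtype=float)
        u1, p1 = od.mann_whitney_u(x, y)
        u2, p2 = od.mann_whitney_u(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert p1 == pytest.approx(p2)
        assert 0.0 <= p1 <= 1.0

    def test_shift_monotonicity(self):
        """Shifting x upward (no new ties) never increases the two-sided p
        once x already dominates y."""
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 20)
        x = rng.normal(1, 1, 20)
        ps = []
        for shift in (0.0, 1.0, 2.0, 4.0):
            _, p = od.mann_whitney_u(x + shift, y)
            ps.append(p)
        assert ps == sorted(ps, reverse=True)

    def test_normal_approximation_close_to_exact_at_n6(self):
        """Tie-free n1=n2=6: approximation within 0.02 of exact enumeration."""
        rng = np.random.default_rng(1)
        exact_cfg = RegionTestConfig(max_exact_n=12)
        approx_cfg = RegionTestConfig(max_exact_n=0)
        for _ in range(50):
            pooled = rng.permutation(np.arange(12, dtype=float))
            x, y = pooled[:6], pooled[6:]
            _, p_exact = od.mann_whitney_u(x, y, exact_cfg)
            _, p_approx = od.mann_whitney_u(x, y, approx_cfg)
            assert abs(p_exact - p_approx) <= 0.02

    def test_large_sample_agrees_with_scipy(self):
        """Independent oracle: tie-corrected asymptotic p from scipy."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = np.round(rng.normal(0, 2, 40), 1)
            y = np.round(rng.normal(0.5, 2, 40), 1)
            u, p = od.mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)


def test_benjamini_hochberg_monotone_and_bounded():
    from occudiff.regions import benjamini_hochberg
    rng = np.random.default_rng(9)
    p = rng.uniform(0, 1, 30)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


class TestRegionProfile:
    def _track(self, values, length=None, step=50):
        length = length or len(values) * step
        layout = od.GenomeLayout((("c", length),))
        return od.SignalTrack(layout, step, {"c": np.asarray(values, dtype=float)})

    def test_constant_region_gives_constant_profile(self):
        track = self._track(np.full(8, 5.0))
        prof = od.region_profile(track, od.Interval("c", 0, 400), 40, "+")
        np.testing.assert_allclose(prof.values, 5.0)

    def test_minus_strand_profile_is_reversed(self):
        # genomic ramp low -> high; a - strand gene reads 3' -> 5' genomically,
        # so its 5'-first profile starts high
        track = self._track(np.arange(8, dtype=float))
        fwd = od.region_profile(track, od.Interval("c", 0, 400), 8, "+")
        rev = od.region_profile(track, od.Interval("c", 0, 400), 8, "-")
        np.testing.assert_allclose(rev.values, fwd.values[::-1])

    def test_short_region_boundaries_cover_without_gaps(self):
        track = self._track(np.full(2, 1.0), length=100)
        prof = od.region_profile(track, od.Interval("c", 0, 100), 40, "+")
        assert len(prof.values) == 40
        bounds = np.round(np.arange(41) * 100 / 40)
        assert (np.diff(bounds) > 0).all()
        assert bounds[0] == 0 and bounds[-1] == 100

    def test_region_shorter_than_bins_is_error(self):
        track = self._track(np.full(2, 1.0), length=100)
        with pytest.raises(od.GenomeValidationError):
            od.region_profile(track, od.Interval("c", 0, 30), 40, "+")


class TestRegionRatio:
    def _prof(self, values):
        return od.RegionProfile("r", np.asarray(values, dtype=float))

    def test_identical_profiles_give_one(self):
        p = self._prof([1, 2, 3])
        assert od.region_ratio(p, p) == pytest.approx(1.0)

    def test_halved_signal(self):
        assert od.region_ratio(self._prof([2, 2]), self._prof([1, 1]),
                               eps=1e-12) == pytest.approx(0.5)

    def test_zero_ctrl_guarded_by_eps(self):
        r = od.region_ratio(self._prof([0, 0]), self._prof([1, 1]), eps=1e-6)
        assert r == pytest.approx(1e6, rel=1e-2)


class TestTestRegion:
    def _profiles(self, value, n=3, n_bins=40):
        return [od.RegionProfile(f"r{i}", np.full(n_bins, float(value)))
                for i in range(n)]

    def test_strong_loss_in_all_replicates_is_consensus_down(self):
        rec = od.test_region(self._profiles(10.0), self._profiles(1.0),
                             gene_id="g", region_kind="gene_body")
        assert [r.call for r in rec.replicates] == ["down"] * 3
        assert rec.consensus == "down"

    def test_identical_profiles_are_ns(self):
        rec = od.test_region(self._profiles(5.0), self._profiles(5.0))
        assert [r.call for r in rec.replicates] == ["ns"] * 3
        assert rec.consensus == "none"

    def test_significant_p_with_small_ratio_is_ns(self):
        """Both conditions required: p < alpha but ratio 1.2 stays ns."""
        rng = np.random.default_rng(3)
        base = rng.normal(10, 0.01, 40)
        ctrl = [od.RegionProfile("c", base) for _ in range(3)]
        ko = [od.RegionProfile("k", base * 1.2) for _ in range(3)]
        rec = od.test_region(ctrl, ko)
        assert all(r.p < 0.05 for r in rec.replicates)
        assert all(abs(r.ratio - 1.2) < 0.01 for r in rec.replicates)
        assert rec.consensus == "none"

    def test_replicate_mismatch_rejected(self):
        with pytest.raises(od.GenomeValidationError):
            od.test_region(self._profiles(1.0, n=3), self._profiles(1.0, n=2))


class TestMetaprofile:
    def test_constant_track_gives_flat_profile(self, geneset):
        from conftest import constant_track
        track = constant_track(geneset.layout, 4.0)
        prof, clipped = od.metaprofile([track], geneset, flank=3000, n_points=60)
        np.testing.assert_allclose(prof, 4.0)
        assert clipped == []

    def test_step_signal_orientation(self):
        """Signal present only upstream of the TSS must appear in the first
        half of the profile for both strands."""
        layout = od.GenomeLayout((("c", 20_000),))
        for strand, tss in (("+", 10_000), ("-", 10_000)):
            data = np.zeros(400)
            if strand == "+":
                data[:200] = 1.0  # genomic left of TSS = upstream
                iv = od.Interval("c", 10_000, 14_000, strand)
            else:
                data[200:] = 1.0  # genomic right of TSS = upstream for -
                iv = od.Interval("c", 6_000, 10_000, strand)
            g = od.GeneModel("g", iv, (iv,))
            gs = od.GeneSet({"g": g}, layout)
            track = od.SignalTrack(layout, 50, {"c": data})
            prof, _ = od.metaprofile([track], gs, flank=3000, n_points=10)
            np.testing.assert_allclose(prof[:5], 1.0)
            np.testing.assert_allclose(prof[5:], 0.0)

    def test_window_past_chromosome_is_padded_and_flagged(self):
        layout = od.GenomeLayout((("c", 5_000),))
        iv = od.Interval("c", 1_000, 4_000, "+")
        gs = od.GeneSet({"g": od.GeneModel("g", iv, (iv,))}, layout)
        data = np.full(100, 2.0)
        track = od.SignalTrack(layout, 50, {"c": data})
        prof, clipped = od.metaprofile([track], gs, flank=3000, n_points=12)
        assert clipped == ["g"]
        # window [-2000, 4000): first third zero-padded
        assert prof[0] == pytest.approx(0.0)
        assert prof[-1] == pytest.approx(2.0)

    def test_empty_geneset_rejected(self, layout):
        gs = od.GeneSet({}, layout)
        with pytest.raises(od.GenomeValidationError):
            od.metaprofile([od.SignalTrack.zeros(layout)], gs)
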
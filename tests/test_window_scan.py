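import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grinscan.io_formats import GeneClusterRecord
from grinscan.window_scan import (
    DupRegion,
    IdentityProfile,
    ScanParams,
    Window,
    call_duplicated_regions,
    fragment_identity,
    max_identity_profile,
    scan_duplications,
    segment_windows,
    sliding_mean,
)

RNG = np.random.default_rng(42)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def substituted(seq, n_subs, rng=RNG):
    """Exactly n_subs isolated positions (spacing >= 3) changed to a
    different base; isolation keeps the optimal alignment gap-free."""
    arr = list(seq)
    while True:
        pos = np.sort(rng.choice(len(arr), size=n_subs, replace=False))
        if n_subs < 2 or np.all(np.diff(pos) >= 3):
            break
    for i in pos:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [(149, 0), (150, 1), (209, 2), (4350, 141)],
    )
    def test_window_count_formula(self, length, expected):
        cluster = GeneClusterRecord("c", "A" * length)
        windows = segment_windows(cluster, ScanParams())
        assert len(windows) == expected
        assert all(w.start == w.index * 30 and w.end == w.start + 150 for w in windows)
        assert all(w.end <= length for w in windows)

    def test_single_window_spans_whole_sequence(self):
        cluster = GeneClusterRecord("c", random_seq(150))
        (w,) = segment_windows(cluster, ScanParams())
        assert (w.start, w.end) == (0, 150)


class TestFragmentIdentity:
    def test_self_identity_is_100(self):
        s = random_seq(150)
        assert fragment_identity(s, s) == 100.0

    def test_substitution_only_pairs_match_hamming_oracle(self):
        # gap-free optimal alignment under the scoring => Hamming identity
        for _ in range(25):
            a = random_seq(150)
            n_subs = int(RNG.integers(0, 16))
            b = substituted(a, n_subs)
            hamming_identity = 100.0 * (150 - n_subs) / 150
            assert fragment_identity(a, b) == pytest.approx(hamming_identity)

    def test_single_insertion_gives_150_over_151(self):
        a = random_seq(150)
        b = a[:75] + "A" + a[75:]
        if b[75] == a[75]:  # ensure the insertion is not absorbable
            b = a[:75] + ("C" if a[75] != "C" else "G") + a[75:]
        assert fragment_identity(a, b) == pytest.approx(100 * 150 / 151, abs=0.01)

    def test_symmetry(self):
        for _ in range(20):
            a, b = random_seq(150), random_seq(150)
            assert fragment_identity(a, b) == pytest.approx(fragment_identity(b, a))

    def test_n_never_counts_as_match(self):
        a = "N" * 150
        assert fragment_identity(a, a) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fragment_identity("", "ACGT")


class TestMaxIdentityProfile:
    def test_exact_tandem_copy_scores_100(self):
        # every window fully inside either copy has an exact on-grid
        # counterpart; windows straddling the junction do not
        x = random_seq(1500)
        cluster = GeneClusterRecord("c", x + x)
        profile = max_identity_profile(cluster, ScanParams())
        inside = [
            i
            for i, w in enumerate(profile.windows)
            if w.end <= 1500 or w.start >= 1500
        ]
        assert np.all(profile.best_identity[inside] == 100.0)
        assert all(profile.best_partner[i] is not None for i in inside)

    def test_random_cluster_stays_below_threshold(self):
        cluster = GeneClusterRecord("c", random_seq(3000, np.random.default_rng(5)))
        profile = max_identity_profile(cluster, ScanParams(prefilter_k=None))
        assert profile.best_identity.max() < 80

    def test_single_window_has_no_partner(self):
        cluster = GeneClusterRecord("c", random_seq(150))
        profile = max_identity_profile(cluster, ScanParams())
        assert list(profile.best_identity) == [0.0]
        assert profile.best_partner == (None,)

    def test_mostly_n_window_scores_zero(self):
        x = random_seq(1500)
        cluster = GeneClusterRecord("c", "N" * 140 + x[140:1500] + x)
        profile = max_identity_profile(cluster, ScanParams())
        assert profile.best_identity[0] == 0.0

    def test_prefilter_agrees_with_exhaustive_above_threshold(self):
        x = random_seq(900, np.random.default_rng(8))
        cluster = GeneClusterRecord(
            "c", random_seq(600, np.random.default_rng(9)) + x + x
        )
        fast = max_identity_profile(cluster, ScanParams())
        full = max_identity_profile(cluster, ScanParams(prefilter_k=None))
        above = full.best_identity > 80
        assert np.allclose(fast.best_identity[above], full.best_identity[above])


def make_profile(identities, win_len=150, step=30):
    windows = tuple(
        Window(i, i * step, i * step + win_len) for i in range(len(identities))
    )
    return IdentityProfile(
        windows, np.asarray(identities, dtype=float), (None,) * len(identities)
    )


class TestCallDuplicatedRegions:
    def test_uniform_high_identity_yields_single_full_region(self):
        profile = make_profile([100.0] * 63)  # 2-kb cluster worth of windows
        (region,) = call_duplicated_regions(profile, ScanParams())
        assert (region.start, region.end) == (0, 62 * 30 + 150)
        assert region.mean_identity == 100.0

    def test_identity_below_threshold_yields_nothing(self):
        profile = make_profile([79.0] * 63)
        assert call_duplicated_regions(profile, ScanParams()) == []

    def test_planted_tandem_duplicate_recovered(self, tandem_truth):
        _, dups = scan_duplications(tandem_truth.cluster, ScanParams())
        (src, copy, _) = tandem_truth.planted_dups[0]
        union = (src[0], copy[1])
        assert len(dups) == 1
        from conftest import jaccard

        assert jaccard((dups[0].start, dups[0].end), union) >= 0.8

    def test_regions_satisfy_span_and_sliding_mean_postconditions(self, tandem_truth):
        params = ScanParams()
        profile = max_identity_profile(tandem_truth.cluster, params)
        smooth = sliding_mean(profile.best_identity, params.run)
        regions = call_duplicated_regions(profile, params)
        for region in regions:
            assert region.span >= params.min_region
            # boundary windows are always marked (regions grow from marked
            # runs; interior dips may be bridged when runs merge)
            first = region.start // params.step
            last = (region.end - params.win_len) // params.step
            assert smooth[first] > params.id_min
            assert smooth[last] > params.id_min
        # every marked window lies inside some reported region here (the
        # fixture's only marked run is far longer than min_region)
        for i, w in enumerate(profile.windows):
            if smooth[i] > params.id_min:
                assert any(r.start <= w.start and w.end <= r.end for r in regions)

    def test_regions_are_disjoint_and_sorted(self, flagship_truth):
        _, dups = scan_duplications(flagship_truth.cluster, ScanParams())
        for a, b in zip(dups, dups[1:]):
            assert a.end <= b.start

    def test_lowering_threshold_never_removes_covered_bases(self, tandem_truth):
        params_hi = ScanParams(id_min=85.0)
        params_lo = ScanParams(id_min=75.0)
        profile = max_identity_profile(tandem_truth.cluster, params_hi)

        def covered(params):
            return {
                base
                for r in call_duplicated_regions(profile, params)
                for base in range(r.start, r.end)
            }

        assert covered(params_hi) <= covered(params_lo)


class TestSlidingMean:
    def test_centered_with_truncated_edges(self):
        values = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        out = sliding_mean(values, 5)
        # center window: full 5 values; edges truncate to what exists
        assert out[2] == pytest.approx(30.0)
        assert out[0] == pytest.approx(np.mean([10, 20, 30]))
        assert out[4] == pytest.approx(np.mean([30, 40, 50]))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(min_value=150, max_value=800), st.integers(min_value=0, max_value=2**31 - 1))
def test_window_tiling_invariants(length, seed):
    cluster = GeneClusterRecord("c", random_seq(length, np.random.default_rng(seed)))
    params = ScanParams()
    windows = segment_windows(cluster, params)
    assert len(windows) == (length - 150) // 30 + 1
    for w in windows:
        assert 0 <= w.start < w.end <= length
        assert w.end - w.start == params.win_len
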
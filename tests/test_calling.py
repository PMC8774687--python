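"""Scoring, combination, segmentation and calling tests.

Includes the independent brute-force CBS oracle (plain-python exhaustive
arc search with the identical permutation stream) and the statistical
property suite: null calibration, power ordering, specificity, and
fetal-fraction monotonicity on simulated cohorts.
"""
import math

import numpy as np
import pytest

from fragcnv.binning import BinGrid, BinnedSample
from fragcnv.calling import (
    Event,
    Segment,
    ZTrack,
    call_events,
    cbs_segment,
    combine_z,
    orient_fs,
    score_sample,
    score_segment,
    segment_and_call,
    segment_track,
    within_sample_z,
)
from fragcnv.refbuild import (
    FRAGMENT_SIZE,
    READ_COUNT,
    BiasModel,
    ControlPanel,
    DatatypeReference,
    ReferenceSet,
    build_reference_set,
)
from fragcnv.simdata import simulate_sample

# frozen from an independent numerical oracle: p = norm.sf(1.5) for both
# tracks, X = -4*ln(p), combined p = chi2.sf(X, 4), z = norm.isf(p_comb)
FISHER_1_5_1_5 = 1.9015110108522792
FISHER_0_0 = -0.24448809711889075  # quirk of Fisher's method at p=0.5


# ---------------------------------------------------------------------------
# within-sample Z on a hand-built reference


def _manual_ref():
    grid = BinGrid(("chrA", "chrB"), (15_000, 15_000), 5_000)
    n = grid.n_bins
    support = np.ones(n, dtype=bool)
    model = BiasModel(FRAGMENT_SIZE, support, np.zeros(n), np.empty((0, n)))
    neighbors = np.array(
        [[3, 4, 5], [3, 4, 5], [3, 4, 5], [0, 1, 2], [0, 1, 2], [0, 1, 2]]
    )
    weights = np.tile([0.5, 0.3, 0.2], (n, 1))
    dref = DatatypeReference(model, np.arange(n), neighbors, weights)
    return grid, ReferenceSet(grid, support.copy(), 3, {FRAGMENT_SIZE: dref})


def _fs_sample(grid, means, n_frag=100):
    means = np.asarray(means, dtype=np.float64)
    counts = np.full(grid.n_bins, n_frag, dtype=np.int64)
    return BinnedSample("q", grid, counts, means * n_frag, counts.copy())


class TestWithinSampleZ:
    # neighbor values on chrB are [1, 2, 3] with weights [.5, .3, .2]:
    # mu_w = 1.7, sigma_w = sqrt(0.61)
    MU = 1.7
    SIGMA = math.sqrt(0.61)

    def test_zero_when_equal_to_weighted_mean(self):
        grid, ref = _manual_ref()
        sample = _fs_sample(grid, [self.MU, 5.0, 5.0, 1.0, 2.0, 3.0])
        z = within_sample_z(sample, ref, FRAGMENT_SIZE, min_valid_neighbors=1)
        assert z[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_sigma_gives_two(self):
        grid, ref = _manual_ref()
        x0 = self.MU + 2 * self.SIGMA
        sample = _fs_sample(grid, [x0, 5.0, 5.0, 1.0, 2.0, 3.0])
        z = within_sample_z(sample, ref, FRAGMENT_SIZE, min_valid_neighbors=1)
        assert z[0] == pytest.approx(2.0, abs=1e-10)

    def test_constant_neighbors_invalidated(self):
        grid, ref = _manual_ref()
        sample = _fs_sample(grid, [2.0, 5.0, 5.0, 4.0, 4.0, 4.0])
        z = within_sample_z(sample, ref, FRAGMENT_SIZE, min_valid_neighbors=1)
        assert np.isnan(z[0])  # sigma_w = 0

    def test_grid_mismatch_raises(self):
        grid, ref = _manual_ref()
        other = BinGrid(("chrA", "chrB"), (15_000, 15_000), 10_000)
        counts = np.full(other.n_bins, 10, dtype=np.int64)
        sample = BinnedSample("q", other, counts, counts * 1.0, counts.copy())
        with pytest.raises(ValueError, match="grid"):
            within_sample_z(sample, ref, FRAGMENT_SIZE)

    def test_boosted_bin_is_argmax(self):
        # flat panel; query with one bin's count multiplied by 1.5
        grid = BinGrid(("c1", "c2", "c3"), (50_000,) * 3, 5_000)
        rng = np.random.default_rng(42)
        controls = []
        for i in range(8):
            c = rng.poisson(1000, grid.n_bins)
            controls.append(BinnedSample(f"c{i}", grid, c, c * 170.0, c.copy()))
        ref = build_reference_set(ControlPanel(controls), K=10, n_comp=2)
        q = rng.poisson(1000, grid.n_bins)
        q[7] = int(q[7] * 1.5)
        query = BinnedSample("q", grid, q, q * 170.0, q.copy())
        z = within_sample_z(query, ref, READ_COUNT)
        assert int(np.nanargmax(np.abs(z))) == 7


class TestOrientFs:
    def test_sign_flip(self):
        np.testing.assert_allclose(orient_fs(np.array([-2.0, 0.0, 1.5])), [2.0, 0.0, -1.5])

    def test_trisomic_chromosome_pushes_positive(self, mini_params, mini_ref):
        sample = simulate_sample(mini_params, is_case=True, seed=777, ff=0.10)
        zt = score_sample(sample, mini_ref)
        grid = mini_params.grid
        on8 = grid.bin_chrom == grid.chrom_index["chr8"]
        assert np.nanmedian(zt.z_fs[on8]) > 0


class TestCombineZ:
    def test_stouffer_examples(self):
        out = combine_z(np.array([2.0, 1.3]), np.array([2.0, 0.0]), "stouffer")
        assert out[0] == pytest.approx(4 / math.sqrt(2))
        assert out[1] == pytest.approx(1.3 / math.sqrt(2))

    def test_fisher_frozen_oracle_value(self):
        out = combine_z(np.array([1.5]), np.array([1.5]), "fisher")
        assert out[0] == pytest.approx(FISHER_1_5_1_5, abs=1e-9)

    def test_fisher_null_quirk(self):
        out = combine_z(np.array([0.0]), np.array([0.0]), "fisher")
        assert out[0] == pytest.approx(FISHER_0_0, abs=1e-9)

    def test_fisher_sign_symmetry(self):
        gain = combine_z(np.array([2.5]), np.array([1.0]), "fisher")[0]
        loss = combine_z(np.array([-2.5]), np.array([-1.0]), "fisher")[0]
        assert loss == pytest.approx(-gain, abs=1e-9)
        assert gain > 0

    def test_fisher_extreme_z_stays_finite(self):
        out = combine_z(np.array([25.0]), np.array([20.0]), "fisher")
        assert np.isfinite(out[0])
        assert out[0] > 25.0

    def test_single_valid_track_falls_back(self):
        out = combine_z(np.array([np.nan, 1.7]), np.array([2.2, np.nan]))
        assert out[0] == pytest.approx(2.2)
        assert out[1] == pytest.approx(1.7)

    def test_both_invalid_stays_invalid(self):
        out = combine_z(np.array([np.nan]), np.array([np.nan]))
        assert np.isnan(out[0])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            combine_z(np.array([1.0]), np.array([1.0]), "mean")


# ---------------------------------------------------------------------------
# CBS with an independent brute-force oracle


def oracle_max_stat(x, min_bins):
    """Exhaustive arc search, re-derived with plain loops."""
    n = len(x)
    s = float(np.std(x))
    if n < 2 * min_bins or s == 0:
        return None
    total = float(np.sum(x))
    best = None
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            nin = j - i
            if nin < min_bins or n - nin < min_bins:
                continue
            m_in = float(np.sum(x[i:j])) / nin
            m_out = (total - float(np.sum(x[i:j]))) / (n - nin)
            t = abs(m_in - m_out) / (s * math.sqrt(1 / nin + 1 / (n - nin)))
            if best is None or t > best[0]:
                best = (t, i, j)
    return best


def oracle_cbs(x, alpha, n_perm, min_bins, seed, offset=0):
    """Exhaustive recursive segmentation with the same acceptance test and
    the same per-segment permutation stream as the implementation."""
    n = len(x)
    if n == 0:
        return []
    res = oracle_max_stat(x, min_bins)
    if res is None:
        return [(0, n)]
    t_obs, i, j = res
    rng = np.random.default_rng([seed, offset, n])
    count = 0
    for _ in range(n_perm):
        rp = oracle_max_stat(rng.permutation(x), min_bins)
        if rp is not None and rp[0] >= t_obs - 1e-12:
            count += 1
    if not count < alpha * (1 + n_perm) - 1:
        return [(0, n)]
    out = []
    for a, b in ((0, i), (i, j), (j, n)):
        if b <= a:
            continue
        out += [
            (a + sa, a + sb)
            for sa, sb in oracle_cbs(x[a:b], alpha, n_perm, min_bins, seed, offset + a)
        ]
    return out


class TestCbs:
    def test_constant_input_single_segment(self):
        assert cbs_segment(np.full(30, 2.5)) == [(0, 30)]

    def test_empty(self):
        assert cbs_segment(np.array([])) == []

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            cbs_segment(np.array([1.0, np.nan]))

    def test_step_signal_breakpoint(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.zeros(30), np.full(30, 5.0)]) + rng.normal(0, 0.1, 60)
        segs = cbs_segment(x, alpha=0.01, n_perm=200, seed=3)
        boundaries = sorted({b for seg in segs for b in seg})
        assert any(abs(b - 30) <= 1 for b in boundaries if 0 < b < 60)

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 80)
        x[20:45] += 4.0
        segs = cbs_segment(x, alpha=0.01, n_perm=200, seed=1)
        assert segs[0][0] == 0 and segs[-1][1] == 80
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            assert b1 == a2  # contiguous, non-overlapping

    @pytest.mark.parametrize(
        "build",
        [
            lambda rng: rng.normal(0, 1, 14),  # pure noise
            lambda rng: np.concatenate([np.zeros(8), np.full(8, 4.0)])
            + rng.normal(0, 0.3, 16),  # clear step
            lambda rng: np.concatenate(
                [np.zeros(6), np.full(7, 5.0), np.zeros(7)]
            )
            + rng.normal(0, 0.3, 20),  # arc in the middle
        ],
        ids=["noise", "step", "arc"],
    )
    def test_matches_brute_force_oracle(self, build):
        rng = np.random.default_rng(17)
        x = build(rng)
        kw = dict(alpha=0.05, n_perm=100, min_bins=2, seed=9)
        assert cbs_segment(x, **kw) == oracle_cbs(x, **kw)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50)
        x[10:30] += 3
        a = cbs_segment(x, n_perm=200, seed=4)
        b = cbs_segment(x, n_perm=200, seed=4)
        assert a == b


class TestScoreSegment:
    def _seg(self, idx):
        return Segment("chr1", 0, 1, np.asarray(idx))

    def test_single_bin(self):
        z = np.array([0.0, 3.3, 0.0])
        assert score_segment(self._seg([1]), z) == pytest.approx(3.3)

    def test_equal_bins_scale_sqrt_m(self):
        z = np.full(9, 2.0)
        assert score_segment(self._seg(range(9)), z) == pytest.approx(2.0 * 3.0)

    def test_invalid_bins_ignored(self):
        z = np.array([2.0, np.nan, 2.0])
        assert score_segment(self._seg([0, 1, 2]), z) == pytest.approx(
            4.0 / math.sqrt(2)
        )

    def test_no_valid_bins_raises(self):
        with pytest.raises(ValueError):
            score_segment(self._seg([0]), np.array([np.nan]))


class TestCallEvents:
    def _scored(self, span_mb, z):
        n = 10
        seg = Segment("chr1", 0, span_mb * 1_000_000, np.arange(n))
        zarr = np.full(n, z / math.sqrt(n))
        return seg, zarr

    @pytest.mark.parametrize(
        "span_mb,z,in_mode_i,in_mode_ii",
        [
            (12, 6.0, True, True),
            (12, -6.0, False, True),
            (5, 8.0, False, True),
            (12, 4.0, False, False),
            (0.5, 9.0, False, False),
        ],
    )
    def test_mode_criteria(self, span_mb, z, in_mode_i, in_mode_ii):
        seg, zarr = self._scored(span_mb, z)
        assert bool(call_events([seg], zarr, "I")) is in_mode_i
        assert bool(call_events([seg], zarr, "II")) is in_mode_ii

    def test_direction(self):
        seg, zarr = self._scored(12, -6.0)
        (event,) = call_events([seg], zarr, "II")
        assert event.direction == "loss"
        assert event.z_segment == pytest.approx(-6.0)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            call_events([], np.array([]), "III")


# ---------------------------------------------------------------------------
# statistical properties on simulated cohorts


class TestNullCalibration:
    def test_null_z_mean_and_sd(self, calib_setup):
        ref, queries = calib_setup
        pooled = {"rc": [], "fs": []}
        for q in queries:
            zt = score_sample(q, ref)
            pooled["rc"].append(zt.z_rc[np.isfinite(zt.z_rc)])
            pooled["fs"].append(zt.z_fs[np.isfinite(zt.z_fs)])
        for key in ("rc", "fs"):
            z = np.concatenate(pooled[key])
            assert len(z) >= 2000
            assert -0.2 < z.mean() < 0.2, f"{key} mean {z.mean():.3f}"
            assert 0.8 < z.std() < 1.25, f"{key} sd {z.std():.3f}"


class TestPowerOrdering:
    def test_combined_beats_read_count(self, mini_params, mini_cohort, mini_ref):
        _, cases, _ = mini_cohort
        assert len(cases) >= 20
        grid = mini_params.grid
        on8 = grid.bin_chrom == grid.chrom_index["chr8"]
        mean_rc, mean_comb = [], []
        for case in cases:
            zt = score_sample(case, mini_ref)
            mean_rc.append(np.nanmean(zt.z_rc[on8]))
            mean_comb.append(np.nanmean(zt.z_comb[on8]))
        assert np.mean(mean_comb) >= np.mean(mean_rc)
        assert np.mean(mean_rc) >= 0
        assert np.mean(mean_comb) >= 0


class TestSpecificity:
    def test_zero_mode_i_calls_on_negatives(self, mini_ref, null_queries):
        assert len(null_queries) >= 20
        total = 0
        for q in null_queries:
            zt = score_sample(q, mini_ref)
            _, events = segment_and_call(zt, mode="I", n_perm=200, seed=2)
            total += len(events)
        assert total == 0


class TestFetalFractionMonotonicity:
    def test_segment_z_increases_with_ff(self, mini_params, mini_ref):
        grid = mini_params.grid
        zs = []
        for ff in (0.02, 0.04, 0.08, 0.16):
            case = simulate_sample(mini_params, is_case=True, seed=4242, ff=ff)
            zt = score_sample(case, mini_ref)
            segs = segment_track(zt, "combined", n_perm=200, seed=5)
            chr8 = [s for s in segs if s.chrom == "chr8"]
            zs.append(max(score_segment(s, zt.z_comb) for s in chr8))
        assert zs == sorted(zs)
        assert zs[-1] > zs[0] + 2  # a real increase, not noise


class TestEndToEndRecovery:
    def test_planted_chromosome_called_mode_i(self, mini_params, mini_cohort, mini_ref):
        _, cases, truth = mini_cohort
        zt = score_sample(cases[0], mini_ref)
        _, events = segment_and_call(zt, mode="I", n_perm=200, seed=6)
        assert len(events) >= 1
        assert all(e.chrom == "chr8" for e in events)
        assert max(e.z_segment for e in events) >= 5.0

    def test_segment_z_grows_with_bin_count(self, mini_params, mini_cohort, mini_ref):
        # with comparable per-bin signal, z_segment scales ~ sqrt(m)
        _, cases, _ = mini_cohort
        zt = score_sample(cases[1], mini_ref)
        grid = mini_params.grid
        on8 = np.flatnonzero(grid.bin_chrom == grid.chrom_index["chr8"])
        full = Segment("chr8", 0, 1, on8)
        half = Segment("chr8", 0, 1, on8[: len(on8) // 2])
        z_full = score_segment(full, zt.z_comb)
        z_half = score_segment(half, zt.z_comb)
        assert z_full / z_half == pytest.approx(math.sqrt(2), rel=0.35)
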
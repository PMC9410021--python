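import numpy as np
import pytest

from spine_uda.dsl_loss import (
    DSLConfig,
    MaskedPrediction,
    dsl_total,
    mask_background,
    round_half_up,
    surrogate_s1_grad,
    surrogate_s2_grad,
    term_s1,
    term_s2,
    term_s3,
    term_s4,
)
from spine_uda.labels import load_reference_distances
from spine_uda.weakmask import WeakMask

# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def spine_pixel(v):
    return v >= 0.5


def oracle_s1(y, cfg):
    nrow, ncol = y.shape
    count = 0
    for s in range(1, cfg.n_shift + 1):
        for i in range(nrow):
            for j in range(ncol - s):
                a, b = y[i, j], y[i, j + s]
                if cfg.spine_only_comparisons and not (spine_pixel(a) and spine_pixel(b)):
                    continue
                diff = a - b
                viol = diff > cfg.strict_margin if cfg.strict_inequality else diff >= cfg.strict_margin
                count += bool(viol)
    return count / y.size


def oracle_s2(y, cfg):
    count = 0
    for j in range(y.shape[1]):
        col = y[:, j]
        vals = col[spine_pixel(col)] if cfg.spine_only_comparisons else col
        if len(vals) == 0:
            continue
        med = np.median(vals)
        count += int(np.sum(np.abs(vals - med) > cfg.strict_margin))
    return count / y.size


def oracle_s4(wm, y):
    if wm.n_components == 0:
        return 0.0
    total = 0
    for coords in wm.components.values():
        seen = set()
        for i, j in coords:
            v = int(np.floor(y[i, j] + 0.5))
            if v > 0:
                seen.add(v)
        total += max(len(seen) - 1, 0)
    return total / wm.n_components


def random_grid(rng):
    shape = (rng.integers(2, 21), rng.integers(6, 21))
    y = rng.integers(0, 27, size=shape).astype(float)
    y[rng.random(shape) < 0.4] = 0.0
    return y


def random_weak_mask(rng, shape):
    grid = np.zeros(shape, dtype=int)
    n = rng.integers(1, 5)
    for k in range(1, n + 1):
        r0 = rng.integers(0, shape[0])
        c0 = rng.integers(0, shape[1])
        r1 = min(shape[0], r0 + rng.integers(1, 5))
        c1 = min(shape[1], c0 + rng.integers(1, 5))
        grid[r0:r1, c0:c1] = k
    return WeakMask.from_label_grid(grid)


class TestOracleEquivalence:
    def test_s1_s2_s4_match_brute_force_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            y = random_grid(rng)
            n_shift = int(rng.integers(1, min(6, y.shape[1])))
            cfg = DSLConfig(n_shift=n_shift)
            yhat = MaskedPrediction(y, (1, 1))
            assert term_s1(yhat, cfg) == oracle_s1(y, cfg)
            assert term_s2(yhat, cfg) == oracle_s2(y, cfg)
            wm = random_weak_mask(rng, y.shape)
            assert term_s4(wm, yhat) == oracle_s4(wm, y)

    def test_s1_matches_oracle_in_literal_printed_form(self):
        """The >=-form (printed equation) variant agrees with its oracle too."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = random_grid(rng)
            cfg = DSLConfig(n_shift=3, strict_inequality=False)
            assert term_s1(MaskedPrediction(y, (1, 1)), cfg) == oracle_s1(y, cfg)


class TestWorkedValues:
    def test_s1_descending_row(self):
        yhat = MaskedPrediction(np.array([[3.0, 2.0, 1.0]]), (1, 1))
        assert term_s1(yhat, DSLConfig(n_shift=2)) == 1.0

    def test_s1_sorted_row_with_plateaus(self):
        yhat = MaskedPrediction(np.array([[1.0, 1.0, 2.0, 2.0, 3.0]]), (1, 1))
        assert term_s1(yhat, DSLConfig(n_shift=2)) == 0.0

    def test_s1_all_zero_grid(self):
        yhat = MaskedPrediction(np.zeros((4, 8)), (1, 1))
        assert term_s1(yhat, DSLConfig(n_shift=3)) == 0.0

    def test_s1_needs_enough_columns(self):
        yhat = MaskedPrediction(np.ones((2, 5)), (1, 1))
        with pytest.raises(ValueError, match="n_shift"):
            term_s1(yhat, DSLConfig(n_shift=10))

    def test_s2_single_deviant_column(self):
        yhat = MaskedPrediction(np.array([[2.0], [2.0], [3.0], [2.0]]), (1, 1))
        assert term_s2(yhat, DSLConfig()) == 0.25

    def test_s2_constant_columns(self):
        yhat = MaskedPrediction(np.tile([[4.0, 5.0, 6.0]], (5, 1)), (1, 1))
        assert term_s2(yhat, DSLConfig()) == 0.0

    def test_s3_single_pair_deviation(self, reference_distances):
        # two vertebrae whose centroid distance deviates from the table by 5 mm
        ref = reference_distances[(10, 11)]
        y = np.zeros((3, 200))
        y[1, 50] = 10.0
        y[1, 50 + int(ref) + 5] = 11.0
        val = term_s3(MaskedPrediction(y, (1, 1)), reference_distances)
        assert val == pytest.approx(5.0 / 25.0)

    def test_s3_matching_pair_and_singleton(self, reference_distances):
        ref = reference_distances[(10, 11)]
        y = np.zeros((3, 200))
        y[1, 50] = 10.0
        y[1, 50 + int(ref)] = 11.0
        assert term_s3(MaskedPrediction(y, (1, 1)), reference_distances) == 0.0
        y[1, 50 + int(ref)] = 0.0
        assert term_s3(MaskedPrediction(y, (1, 1)), reference_distances) == 0.0

    def test_s4_two_label_component(self):
        y = np.array([[3.0, 3.0, 4.0, 4.0]])
        wm = WeakMask.from_label_grid(np.ones((1, 4), dtype=int))
        assert term_s4(wm, MaskedPrediction(y, (1, 1))) == 1.0

    def test_s4_uniform_components(self):
        y = np.array([[3.0, 3.0, 0.0, 4.0, 4.0]])
        wm = WeakMask.from_label_grid(np.array([[1, 1, 0, 2, 2]]))
        assert term_s4(wm, MaskedPrediction(y, (1, 1))) == 0.0

    def test_total_with_published_constants(self, reference_distances):
        # term values (0.1, 0.2, 4, 2) -> 20*0.1 + 1*0.2 + 4/40 + 2/100 = 2.32
        cfg = DSLConfig()
        total = cfg.c1 * 0.1 + cfg.c2 * 0.2 + cfg.c3 * 4 + cfg.c4 * 2
        assert total == pytest.approx(2.32)

    def test_breakdown_total_is_weighted_sum(self, phantom_sample,
                                             reference_distances):
        from spine_uda.phantom import sagittal_projection

        proj = sagittal_projection(phantom_sample.dense.data).astype(float)
        yhat = MaskedPrediction(proj, (1, 1))
        wm = WeakMask.from_label_grid((proj > 0).astype(int) * 0)
        cfg = DSLConfig()
        b = dsl_total(yhat, wm, reference_distances, cfg)
        assert b.total == pytest.approx(
            cfg.c1 * b.s1 + cfg.c2 * b.s2 + cfg.c3 * b.s3 + cfg.c4 * b.s4
        )


class TestMaskBackground:
    def test_identity_annihilation_and_mixture(self, rng):
        raw = rng.uniform(1, 5, (4, 6))
        ones = np.ones_like(raw)
        np.testing.assert_array_equal(mask_background(raw, ones).data, raw)
        assert not mask_background(raw, np.zeros_like(raw)).data.any()
        mask = (rng.random((4, 6)) > 0.5).astype(float)
        out = mask_background(raw, mask)
        assert not out.data[mask == 0].any()
        np.testing.assert_array_equal(out.data[mask == 1], raw[mask == 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mask_background(np.ones((2, 3)), np.ones((3, 2)))


class TestInvariances:
    def test_s1_invariant_to_constant_offset(self, rng):
        y = random_grid(rng)
        cfg = DSLConfig(n_shift=4)
        base = term_s1(MaskedPrediction(y, (1, 1)), cfg)
        shifted = np.where(y >= 0.5, y + 3.0, 0.0)
        assert term_s1(MaskedPrediction(shifted, (1, 1)), cfg) == base

    def test_s3_invariant_to_spatial_translation(self, reference_distances):
        y = np.zeros((5, 200))
        y[2, 40] = 12.0
        y[2, 70] = 13.0
        a = term_s3(MaskedPrediction(y, (1, 1)), reference_distances)
        b = term_s3(MaskedPrediction(np.roll(y, 9, axis=1), (1, 1)),
                    reference_distances)
        assert a == b

    def test_all_terms_nonnegative_on_random_grids(self, rng,
                                                   reference_distances):
        for _ in range(20):
            y = random_grid(rng)
            cfg = DSLConfig(n_shift=3)
            yhat = MaskedPrediction(y, (1, 1))
            wm = random_weak_mask(rng, y.shape)
            b = dsl_total(yhat, wm, reference_distances, cfg)
            assert min(b.s1, b.s2, b.s3, b.s4) >= 0

    def test_corruption_monotonicity_of_s2(self, phantom_sample):
        """More label jitter gives a larger column-consistency penalty
        (measured on the mid-sagittal slice, where the jittered fraction is
        not masked by the maximum projection)."""
        from spine_uda.phantom import corrupt_labels

        cfg = DSLConfig()
        mid = phantom_sample.dense.shape[0] // 2

        def mean_s2(frac):
            vals = []
            for seed in range(20):
                out = corrupt_labels(phantom_sample.dense, "jitter_pixels",
                                     frac, seed=seed)
                plane = out.data[mid].astype(float)
                vals.append(term_s2(MaskedPrediction(plane, (1, 1)), cfg))
            return np.mean(vals)

        assert 0 < mean_s2(0.05) < mean_s2(0.15)


class TestSurrogateMode:
    def test_surrogate_zero_iff_exact_zero(self, rng):
        exact = DSLConfig(n_shift=4, mode="exact")
        sur = DSLConfig(n_shift=4, mode="surrogate")
        for _ in range(40):
            y = random_grid(rng)
            yhat = MaskedPrediction(y, (1, 1))
            for term in (term_s1, term_s2):
                assert (term(yhat, exact) == 0) == (term(yhat, sur) == 0)

    def test_surrogate_gradients_match_finite_differences(self, rng):
        cfg = DSLConfig(n_shift=4, mode="surrogate")
        y = rng.normal(5, 2, (6, 12))
        y[rng.random((6, 12)) < 0.3] = 0.0
        eps = 1e-6
        # probe pixels away from hinge kinks and column medians, where the
        # (sub)gradient is an ordinary derivative
        med = np.array([
            np.median(col[col >= 0.5]) if (col >= 0.5).any() else np.nan
            for col in y.T
        ])
        probes = [
            (i, j)
            for i in range(y.shape[0])
            for j in range(y.shape[1])
            if y[i, j] >= 0.5 and abs(y[i, j] - med[j]) > 0.2
        ][:6]
        assert probes
        for fn, term in ((surrogate_s1_grad, term_s1), (surrogate_s2_grad, term_s2)):
            val, grad = fn(MaskedPrediction(y, (1, 1)), cfg)
            assert val == pytest.approx(term(MaskedPrediction(y, (1, 1)), cfg))
            for i, j in probes:
                yp, ym = y.copy(), y.copy()
                yp[i, j] += eps
                ym[i, j] -= eps
                fd = (
                    term(MaskedPrediction(yp, (1, 1)), cfg)
                    - term(MaskedPrediction(ym, (1, 1)), cfg)
                ) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, abs=1e-6)

    def test_rounding_is_half_up(self):
        np.testing.assert_array_equal(
            round_half_up(np.array([0.4, 0.5, 2.4, 7.5, -0.4])),
            [0, 1, 2, 8, 0],
        )
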
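import numpy as np
import pytest

import osteotex as ot
from osteotex import features as F
from conftest import make_normalized, make_region
from _oracles import (
    cooccurrence_brute,
    glcm_stats_brute,
    rlm_stats_brute,
    runs_brute,
)


class TestHistogram:
    def test_constant_region(self):
        vals = F.histogram_features(make_normalized(np.full((6, 6), 10)))
        assert vals["hist_mean"] == 10
        assert vals["hist_variance"] == 0
        assert vals["hist_skewness"] == 0 and vals["hist_kurtosis"] == 0
        for p in ("p01", "p10", "p50", "p90", "p99"):
            assert vals[f"hist_{p}"] == 10

    def test_two_point_distribution(self):
        vals = F.histogram_features(make_normalized([[0, 0], [255, 255]], bit_depth=8))
        assert vals["hist_mean"] == pytest.approx(127.5)
        assert vals["hist_variance"] == pytest.approx(16256.25)  # population
        assert vals["hist_p50"] == pytest.approx(127.5)

    def test_spatial_order_free(self, rng):
        px = rng.integers(0, 256, (10, 10))
        a = F.histogram_features(make_normalized(px, bit_depth=8))
        b = F.histogram_features(make_normalized(np.flipud(px).copy(), bit_depth=8))
        assert a == pytest.approx(b)


class TestCooccurrence:
    def test_two_by_two_example(self):
        mat = F.cooccurrence_matrix(np.array([[0, 1], [0, 1]]), (0, 1), 2)
        np.testing.assert_allclose(mat, [[0, 0.5], [0.5, 0]])
        stats = F.glcm_features(mat)
        assert stats["contrast"] == pytest.approx(1.0)

    def test_checkerboard_distance_two(self):
        q = np.indices((6, 6)).sum(axis=0) % 2
        mat = F.cooccurrence_matrix(q, (0, 2), 2)
        assert mat[0, 1] == 0 and mat[1, 0] == 0
        assert mat[0, 0] + mat[1, 1] == pytest.approx(1.0)

    def test_diagonal_mass_zero_contrast(self):
        mat = np.diag([0.25, 0.5, 0.25])
        assert F.glcm_features(mat)["contrast"] == 0

    def test_single_cell(self):
        mat = np.zeros((4, 4))
        mat[2, 2] = 1.0
        stats = F.glcm_features(mat)
        assert stats["asm"] == 1.0 and stats["entropy"] == 0.0

    def test_sums_to_one_and_symmetric(self, rng):
        for _ in range(10):
            q = rng.integers(0, 4, (7, 5))
            for angle, offset in F.DIRECTION_OFFSETS.items():
                mat = F.cooccurrence_matrix(q, offset, 4)
                assert mat.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(mat, mat.T)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            q = rng.integers(0, 4, (rng.integers(3, 9), rng.integers(3, 9)))
            for d in (1, 2):
                for angle, (dr, dc) in F.DIRECTION_OFFSETS.items():
                    off = (dr * d, dc * d)
                    try:
                        got = F.cooccurrence_matrix(q, off, 4)
                    except F.InsufficientExtentError:
                        continue
                    np.testing.assert_allclose(
                        got, cooccurrence_brute(q, off, 4), atol=1e-12
                    )
                    got_stats = F.glcm_features(got)
                    exp_stats = glcm_stats_brute(got)
                    for k, v in exp_stats.items():
                        assert got_stats[k] == pytest.approx(v, abs=1e-10)

    def test_matches_skimage_cross_check(self, rng):
        """Independent library cross-check on the horizontal direction."""
        from skimage.feature import graycomatrix

        q = rng.integers(0, 8, (12, 12))
        ours = F.cooccurrence_matrix(q, (0, 1), 8)
        theirs = graycomatrix(q.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(ours, theirs[:, :, 0, 0], atol=1e-12)

    def test_rotation_permutes_directions(self, rng):
        q = rng.integers(0, 4, (8, 8))
        perm = {0: 90, 90: 0, 45: 135, 135: 45}
        for a, b in perm.items():
            m1 = F.cooccurrence_matrix(q, F.DIRECTION_OFFSETS[a], 4)
            m2 = F.cooccurrence_matrix(np.rot90(q).copy(), F.DIRECTION_OFFSETS[b], 4)
            np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_offset_exceeding_extent(self):
        with pytest.raises(F.InsufficientExtentError):
            F.cooccurrence_matrix(np.zeros((3, 3), dtype=int), (0, 5), 2)


class TestRunLength:
    def test_single_row_example(self):
        # runs {(0, len 2), (1, len 3)}: SRE = (1/4 + 1/9)/2 = 13/72
        region = make_normalized(np.array([[0, 0, 1, 1, 1]]) * 4094, bit_depth=12)
        stats = F.rlm_features(region, 0, levels=2)
        assert stats["sre"] == pytest.approx(13 / 72)
        assert stats["run_percentage"] == pytest.approx(2 / 5)

    def test_constant_region(self):
        region = make_normalized(np.full((4, 6), 100))
        stats = F.rlm_features(region, 0, levels=4)
        assert stats["lre"] == pytest.approx(36)  # n_cols**2, one run per row
        assert stats["run_percentage"] == pytest.approx(1 / 6)

    def test_checkerboard_all_unit_runs(self):
        q = (np.indices((6, 6)).sum(axis=0) % 2) * 4095
        stats = F.rlm_features(make_normalized(q, bit_depth=12), 0, levels=2)
        assert stats["sre"] == pytest.approx(1.0)
        assert stats["lre"] == pytest.approx(1.0)

    def test_pixel_count_conservation(self, rng):
        """Runs tile each direction's lines: run-length-weighted counts sum
        to the pixel count."""
        q = rng.integers(0, 4, (7, 9))
        for angle in (0, 45, 90, 135):
            mat = F.run_length_matrix(q, angle, 4)
            lengths = np.arange(1, mat.shape[1] + 1)
            assert (mat.sum(axis=0) * lengths).sum() == q.size

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            q = rng.integers(0, 4, (rng.integers(2, 9), rng.integers(2, 9)))
            for angle in (0, 45, 90, 135):
                region = make_normalized(q * (4096 // 4), bit_depth=12)
                got = F.rlm_features(region, angle, levels=4)
                exp = rlm_stats_brute(q, angle, 4)
                for k, v in exp.items():
                    assert got[k] == pytest.approx(v, abs=1e-10), (angle, k)


class TestGradient:
    def test_constant_region(self):
        vals = F.gradient_features(make_normalized(np.full((8, 8), 50)))
        assert vals["grad_mean"] == 0 and vals["grad_variance"] == 0
        assert vals["grad_nonzero_fraction"] == 0

    def test_step_edge_nonzero_fraction(self):
        """A vertical step edge activates exactly the two interior columns
        adjacent to the step (explicit-loop oracle)."""
        px = np.zeros((10, 10), dtype=int)
        px[:, 5:] = 100
        vals = F.gradient_features(make_normalized(px))
        # oracle: |2p(c) - p(c-1) - p(c+1)| row-invariant, nonzero at c in {4, 5}
        expected = np.zeros((8, 8))
        for r in range(1, 9):
            for c in range(1, 9):
                expected[r - 1, c - 1] = abs(
                    4 * px[r, c] - px[r, c - 1] - px[r, c + 1] - px[r - 1, c] - px[r + 1, c]
                )
        assert vals["grad_nonzero_fraction"] == pytest.approx((expected > 0).mean())
        assert vals["grad_mean"] == pytest.approx(expected.mean())

    def test_dc_invariance(self, rng):
        px = rng.integers(0, 200, (9, 9))
        a = F.gradient_features(make_normalized(px, bit_depth=12))
        b = F.gradient_features(make_normalized(px + 500, bit_depth=12))
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_too_small(self):
        with pytest.raises(F.InsufficientExtentError):
            F.gradient_features(make_normalized(np.zeros((2, 5), dtype=int)))


class TestAutoregressive:
    def test_constant_region_zero_residual(self):
        vals = F.ar_features(make_normalized(np.full((6, 6), 77)))
        assert vals["ar_sigma"] == pytest.approx(0, abs=1e-8)

    def test_parameter_recovery_left_neighbor(self):
        """A field synthesized as I(r,c) = 0.5 I(r,c-1) + ε recovers
        θ_left ≈ 0.5 and near-zero weights elsewhere."""
        rng = np.random.default_rng(3)
        n = 150
        img = np.zeros((n, n))
        eps = rng.normal(0, 30, (n, n))
        for c in range(1, n):
            img[:, c] = 0.5 * img[:, c - 1] + eps[:, c]
        vals = F.ar_features(make_normalized(np.rint(img), bit_depth=12))
        assert vals["ar_theta1"] == pytest.approx(0.5, abs=0.05)
        for k in ("ar_theta2", "ar_theta3", "ar_theta4"):
            assert abs(vals[k]) < 0.05

    def test_residuals_orthogonal_to_design(self, rng):
        """Least squares: residuals are orthogonal to every regressor."""
        px = rng.integers(0, 4096, (12, 12))
        region = make_normalized(px, bit_depth=12)
        vals = F.ar_features(region)
        p = px.astype(float)
        target = p[1:, 1:-1].ravel()
        design = np.column_stack(
            [p[1:, :-2].ravel(), p[:-1, :-2].ravel(), p[:-1, 1:-1].ravel(), p[:-1, 2:].ravel()]
        )
        theta = np.array([vals[f"ar_theta{i}"] for i in range(1, 5)])
        residuals = target - design @ theta
        np.testing.assert_allclose(design.T @ residuals, 0, atol=1e-6)


class TestHaar:
    def test_constant_region_energies(self):
        c = 9
        vals = F.haar_features(make_normalized(np.full((16, 16), c)))
        for scale in range(1, 5):
            for band in ("lh", "hl", "hh"):
                assert vals[f"haar_s{scale}_{band}"] == pytest.approx(0, abs=1e-12)
            # periodized orthogonal transform: LL gains a factor 2 per scale
            assert vals[f"haar_s{scale}_ll"] == pytest.approx((2**scale * c) ** 2)

    def test_row_stripes_period_two(self):
        px = np.zeros((16, 16), dtype=int)
        px[::2, :] = 100
        vals = F.haar_features(make_normalized(px))
        detail = {k: v for k, v in vals.items() if not k.endswith("_ll")}
        assert max(detail, key=detail.get) == "haar_s1_lh"

    def test_parseval(self, rng):
        """Subband energies weighted by subband sizes recover the total
        signal energy (orthogonal periodized transform)."""
        px = rng.integers(0, 4096, (32, 32))
        vals = F.haar_features(make_normalized(px, bit_depth=12))
        total = 0.0
        for scale in range(1, 5):
            n_coeff = (32 // 2**scale) ** 2
            for band in ("lh", "hl", "hh"):
                total += vals[f"haar_s{scale}_{band}"] * n_coeff
        total += vals["haar_s4_ll"] * (32 // 16) ** 2
        assert total == pytest.approx(float((px.astype(float) ** 2).sum()), rel=1e-10)

    def test_too_small(self):
        with pytest.raises(F.InsufficientExtentError):
            F.haar_features(make_normalized(np.zeros((8, 8), dtype=int)))


class TestGabor:
    def test_constant_region_zero_response(self):
        vals = F.gabor_features(make_normalized(np.full((32, 32), 1234), bit_depth=12))
        for v in vals.values():
            assert v == pytest.approx(0, abs=1e-9)

    def test_grating_selects_matching_filter(self):
        """A sinusoidal grating of wavelength 8 along the 0° axis peaks at
        (orientation 0°, envelope 8)."""
        g = 2000 + 1500 * np.sin(2 * np.pi * np.arange(48) / 8.0)
        px = np.rint(np.tile(g, (48, 1)))
        vals = F.gabor_features(make_normalized(px, bit_depth=12))
        assert max(vals, key=vals.get) == "gabor_a0_s8"

    def test_rotation_permutes_orientations(self, rng):
        px = rng.integers(0, 4096, (40, 40))
        a = F.gabor_features(make_normalized(px, bit_depth=12))
        b = F.gabor_features(make_normalized(np.rot90(px).copy(), bit_depth=12))
        perm = {0: 90, 90: 0, 45: 135, 135: 45}
        for ang, rotated in perm.items():
            for s in (4, 6, 8, 12, 16, 24):
                assert a[f"gabor_a{ang}_s{s}"] == pytest.approx(
                    b[f"gabor_a{rotated}_s{s}"], rel=1e-8
                )

    def test_envelope_larger_than_region(self):
        with pytest.raises(F.InsufficientExtentError):
            F.gabor_features(make_normalized(np.zeros((16, 16), dtype=int)))


class TestHog:
    def test_constant_region_all_zero(self):
        vals = F.hog_features(make_normalized(np.full((8, 8), 3)))
        assert all(v == 0 for v in vals.values())

    def test_ramp_concentrates_in_zero_bin(self):
        px = np.tile(np.arange(0, 80, 8), (10, 1))
        vals = F.hog_features(make_normalized(px))
        assert vals["hog_bin0"] == pytest.approx(1.0)
        assert sum(vals.values()) == pytest.approx(1.0)

    def test_histogram_sums_to_one(self, rng):
        px = rng.integers(0, 256, (12, 12))
        vals = F.hog_features(make_normalized(px))
        assert sum(vals.values()) == pytest.approx(1.0)


class TestExtractAll:
    def test_schema_counts(self, rng):
        region = make_region(rng.integers(0, 4096, (64, 64)), bit_depth=12)
        vec = ot.extract_all(region)
        assert len(vec) == 307
        names = list(vec)
        assert names == ot.feature_names()
        by_family = {}
        for n in names:
            by_family[F.family_of(n)] = by_family.get(F.family_of(n), 0) + 1
        assert by_family == {
            "hist": 9,
            "glcm": 220,
            "rlm": 20,
            "grad": 5,
            "ar": 5,
            "haar": 16,
            "gabor": 24,
            "hog": 8,
        }

    def test_deterministic_and_finite(self, rng):
        region = make_region(rng.integers(0, 256, (32, 32)))
        v1, v2 = ot.extract_all(region), ot.extract_all(region)
        assert v1 == v2
        assert all(np.isfinite(list(v1.values())))

    def test_constant_region_all_finite(self):
        region = make_region(np.full((32, 32), 200), bit_depth=12)
        vec = ot.extract_all(region)
        assert all(np.isfinite(list(vec.values())))

    def test_family_name_attached_to_errors(self, rng):
        region = make_region(rng.integers(0, 256, (8, 8)))
        with pytest.raises(ValueError, match=r"\[haar\]"):
            ot.extract_all(region)
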
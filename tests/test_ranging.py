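"""Range processing chain: FFT, DC removal, ABS, rank-1 SVD, localization."""

import numpy as np
import pytest
import scipy.signal

import radarid as ri
from radarid.ranging import RangeSlowTimeMatrix


def _matrix(values, stage="raw"):
    return RangeSlowTimeMatrix(np.asarray(values, dtype=complex),
                               range_resolution=0.0376, frame_rate=50.0,
                               stage=stage)


class TestRangeFFT:
    def test_constant_fast_time_goes_to_bin_zero(self, short_config):
        cube = ri.RadarCube(np.full((3, 1, 256), 2.0 + 0j),
                            ri.RadarConfig(n_frames=3), "s", "r")
        m = ri.range_fft(cube)
        assert np.allclose(m.values[0], 256 * (2.0 + 0j))
        assert np.allclose(m.values[1:], 0, atol=1e-9)

    def test_pure_exponential_bin(self):
        n = np.arange(256)
        fast = np.exp(2j * np.pi * 26 * n / 256)
        cube = ri.RadarCube(np.tile(fast, (4, 1, 1)), ri.RadarConfig(n_frames=4),
                            "s", "r")
        m = ri.range_fft(cube)
        assert (np.abs(m.values).argmax(axis=0) == 26).all()

    def test_simulator_cross_check(self, clean_cube):
        m = ri.range_fft(clean_cube)
        assert (np.abs(m.values).argmax(axis=0) == 26).all()


class TestRemoveDC:
    def test_constant_row_zeroed(self):
        out = ri.remove_dc(_matrix([[5, 5, 5, 5]]))
        assert np.allclose(out.values, 0)
        assert out.stage == "dc_removed"

    def test_two_sample_row(self):
        out = ri.remove_dc(_matrix([[1, 3]]))
        assert np.allclose(out.values, [[-1, 1]])

    def test_row_means_vanish(self, rng):
        x = rng.normal(size=(8, 100)) + 1j * rng.normal(size=(8, 100))
        out = ri.remove_dc(_matrix(x))
        assert np.abs(out.values.mean(axis=1)).max() < 1e-9 * np.abs(x).max()


class TestABS:
    def test_constant_row_tracked_exactly(self):
        out = ri.remove_static_clutter(_matrix([[3 + 1j] * 10], "dc_removed"))
        assert np.allclose(out.values, 0)

    def test_hand_recursion_two_samples(self):
        """Row [0, 1] at lambda=0.9: B = [0, 0.1], output [0, 0.9]."""
        out = ri.remove_static_clutter(_matrix([[0.0, 1.0]], "dc_removed"), lam=0.9)
        assert np.allclose(out.values, [[0.0, 0.9]])

    def test_matches_explicit_recursion(self, rng):
        """Exact agreement with a literal per-sample loop on random rows."""
        lam = 0.9
        x = rng.normal(size=(10, 30)) + 1j * rng.normal(size=(10, 30))
        out = ri.remove_static_clutter(_matrix(x, "dc_removed"), lam=lam)
        for row_in, row_out in zip(x, out.values):
            b = row_in[0]
            expect = [row_in[0] - b]
            for q in row_in[1:]:
                b = lam * b + (1 - lam) * q
                expect.append(q - b)
            assert np.allclose(row_out, expect, atol=1e-12)

    def test_sinusoid_response_matches_transfer_function(self):
        """Steady-state gain at 0.25 Hz equals |H| of the one-pole high-pass."""
        lam, fs, f0 = 0.9, 50.0, 0.25
        t = np.arange(3000) / fs
        x = np.exp(2j * np.pi * f0 * t)[None, :]
        out = ri.remove_static_clutter(_matrix(x, "dc_removed"), lam=lam)
        _, h = scipy.signal.freqz([lam, -lam], [1.0, -lam],
                                  worN=[f0], fs=fs)
        measured = np.abs(out.values[0, 1500:]).mean()
        assert measured == pytest.approx(np.abs(h[0]), rel=1e-3)

    def test_causality_prefix_property(self, rng):
        """Truncating the input truncates the output identically (causal)."""
        x = rng.normal(size=(4, 50))
        full = ri.remove_static_clutter(_matrix(x, "dc_removed"))
        part = ri.remove_static_clutter(_matrix(x[:, :20], "dc_removed"))
        assert np.allclose(full.values[:, :20], part.values, atol=1e-12)

    def test_lambda_bounds(self):
        for lam in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ri.remove_static_clutter(_matrix([[1.0, 2.0]], "dc_removed"), lam=lam)


class TestSVD:
    def test_rank1_fixed_point(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0]], dtype=complex)
        out = ri.remove_dynamic_clutter(_matrix(x, "static_removed"))
        assert np.allclose(out.values, x, atol=1e-9)

    def test_diagonal_matrix(self):
        out = ri.remove_dynamic_clutter(_matrix(np.diag([2.0, 1.0]), "static_removed"))
        assert np.allclose(out.values, [[2, 0], [0, 0]], atol=1e-12)

    def test_eckart_young_error(self, rng):
        """Frobenius error equals sqrt(sum of squared trailing singular values)."""
        for _ in range(20):
            x = rng.normal(size=(12, 25)) + 1j * rng.normal(size=(12, 25))
            out = ri.remove_dynamic_clutter(_matrix(x, "static_removed"))
            s = np.linalg.svd(x, compute_uv=False)
            err = np.linalg.norm(x - out.values, "fro")
            assert err == pytest.approx(np.sqrt((s[1:] ** 2).sum()), rel=1e-9)

    def test_output_is_numerically_rank_one(self, rng):
        x = rng.normal(size=(10, 40))
        out = ri.remove_dynamic_clutter(_matrix(x, "static_removed"))
        s = np.linalg.svd(out.values, compute_uv=False)
        assert s[1] < 1e-9 * s[0]


class TestLocateChest:
    def test_dominant_row(self):
        x = np.ones((8, 2))
        x[5] = 3.0
        # rank-1 already, so the stage tag can be advanced directly
        assert ri.locate_chest(_matrix(x, "dynamic_removed")) == 5

    def test_tie_breaks_low(self):
        x = np.zeros((4, 3))
        x[1] = x[2] = 1.0
        assert ri.locate_chest(_matrix(x, "dynamic_removed")) == 1

    def test_all_zero_flagged(self):
        with pytest.raises(ri.NoTargetError):
            ri.locate_chest(_matrix(np.zeros((4, 3)), "dynamic_removed"))

    def test_simulator_cross_check_with_clutter(self, short_config):
        """Strong static clutter (10x target power) defeats raw localization but
        not the full chain — the qualitative point of DC/ABS/SVD removal."""
        prof = ri.SubjectProfile("s", nominal_range=26 * short_config.range_resolution,
                                 breath_amplitude=2e-3)
        scene = ri.SceneConfig(dc_bias=2 + 2j,
                               static_reflectors=((50 * short_config.range_resolution,
                                                   10.0),),
                               rng_seed=7)
        cube = ri.synthesize_cube(prof, scene, short_config)
        raw = ri.range_fft(cube)
        raw_guess = int(np.abs(raw.values).sum(axis=1).argmax())
        assert raw_guess == 50          # clutter wins before cleanup
        _, chest = ri.preprocess_cube(cube)
        assert chest == 26              # chain recovers the thorax bin


class TestStageEnforcement:
    def test_pipeline_order_is_enforced(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="stage"):
            ri.remove_static_clutter(m)          # skipping DC removal
        with pytest.raises(ValueError, match="stage"):
            ri.remove_dynamic_clutter(m)
        with pytest.raises(ValueError, match="stage"):
            ri.locate_chest(m)
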
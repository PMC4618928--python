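"""Stationary wavelet transform: filters, perfect reconstruction, invariances."""

import numpy as np
import pytest

from swmar.swt import (SwtCoefficients, haar_filters, swt_decompose,
                       swt_reconstruct, wavelet_filters)


def naive_swt(x, level, wavelet="haar"):
    """Direct-indexing reference implementation of the a-trous recursion.

    Independent of the vectorized production path: explicit per-sample loops
    over the upsampled-filter convolution with circular wrap.
    """
    low, high = wavelet_filters(wavelet)
    n = len(x)
    a = np.array(x, dtype=float)
    details = []
    for j in range(1, level + 1):
        d = 2 ** (j - 1)
        new_a = np.zeros(n)
        det = np.zeros(n)
        for k in range(n):
            for l in range(len(low)):
                idx = (k + d * l) % n
                new_a[k] += low[l] * a[idx]
                det[k] += high[l] * a[idx]
        details.append(det)
        a = new_a
    return details, a


class TestHaarFilters:
    def test_orthonormal_admissible_qmf(self):
        low, high = haar_filters()
        assert np.sum(low**2) == pytest.approx(1.0)
        assert np.sum(high) == pytest.approx(0.0)
        assert np.dot(low, high) == pytest.approx(0.0)

    def test_non_orthogonal_wavelet_rejected(self):
        with pytest.raises(ValueError):
            wavelet_filters("bior1.3")


class TestDecompose:
    def test_constant_signal(self):
        c = swt_decompose(np.full(40, 3.0), level=5)
        for d in c.details:
            assert np.allclose(d, 0.0, atol=1e-12)
        assert np.allclose(c.approximation, 3.0 * 2 ** 2.5)

    def test_impulse_level1_detail(self):
        x = np.zeros(32)
        x[10] = 1.0
        c = swt_decompose(x, level=1)
        nz = np.flatnonzero(np.abs(c.details[0]) > 1e-12)
        assert len(nz) == 2
        assert np.allclose(np.abs(c.details[0][nz]), 1 / np.sqrt(2))

    def test_matches_naive_oracle(self, rng):
        x = rng.standard_normal(96)
        c = swt_decompose(x, level=5)
        details, approx = naive_swt(x, 5)
        for got, want in zip(c.details, details):
            assert np.max(np.abs(got - want)) < 1e-10
        assert np.max(np.abs(c.approximation - approx)) < 1e-10

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            swt_decompose(np.array([]), level=2)


class TestReconstruct:
    @pytest.mark.parametrize("n", [32, 96, 1000])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.standard_normal(n)
        assert np.max(np.abs(swt_reconstruct(swt_decompose(x, 5)) - x)) < 1e-9

    def test_zero_coefficients_give_zero_signal(self):
        c = swt_decompose(np.zeros(64), 3)
        assert np.allclose(swt_reconstruct(c), 0.0)

    def test_details_of_constant_are_redundant(self):
        c = swt_decompose(np.full(64, 1.25), 4)
        for d in c.details:
            d[:] = 0.0
        assert np.allclose(swt_reconstruct(c), 1.25)

    def test_inconsistent_lengths_rejected(self):
        c = swt_decompose(np.zeros(64), 3)
        c.details[1] = c.details[1][:-1]
        with pytest.raises(ValueError):
            swt_reconstruct(c)


class TestInvariances:
    def test_circular_shift_invariance(self, rng):
        x = rng.standard_normal(64)
        c0 = swt_decompose(x, 5)
        for shift in (1, 7, 32):
            cs = swt_decompose(np.roll(x, shift), 5)
            for d0, ds in zip(c0.details, cs.details):
                assert np.array_equal(np.roll(d0, shift), ds)
            assert np.array_equal(np.roll(c0.approximation, shift),
                                  cs.approximation)

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 96))
        a, b = 2.5, -1.25
        c = swt_decompose(a * x + b * y, 4)
        cx, cy = swt_decompose(x, 4), swt_decompose(y, 4)
        for dc, dx, dy in zip(c.details, cx.details, cy.details):
            assert np.allclose(dc, a * dx + b * dy, atol=1e-10)
        assert np.allclose(c.approximation,
                           a * cx.approximation + b * cy.approximation, atol=1e-10)

    def test_band_separation_of_tones(self):
        fs = 250.0
        t = np.arange(int(8 * fs)) / fs

        def detail_energies(freq):
            c = swt_decompose(np.sin(2 * np.pi * freq * t), 5)
            return np.array([np.sum(d**2) for d in c.details])

        slow = detail_energies(1.0)  # below every detail band -> coarsest levels
        assert (slow[3] + slow[4]) / slow.sum() > 0.9
        fast = detail_energies(40.0)  # ideal-band location: level 2 (31-62 Hz)
        assert np.argmax(fast) == 1
        assert fast[:3].sum() / fast.sum() > 0.75
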
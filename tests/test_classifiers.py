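"""The five SSVEP classifiers: definitions, invariances, oracle checks."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepshift import (
    ClassifierConfig,
    ReferenceSet,
    cca_coefficient,
    classify,
    delay_embed,
    fbcca_score,
    make_reference,
    msi_index,
    scores,
)
from ssvepshift.dataio import ValidationError
from oracles import cca_oracle, msi_oracle

FREQS = (60 / 10, 60 / 9, 60 / 8, 60 / 6)


@pytest.fixture(scope="module")
def refs():
    return ReferenceSet(FREQS, nh=4, fs=256.0)


class TestReference:
    def test_shape_and_first_sample(self):
        y = make_reference(6.0, 4, 256.0, 512)
        assert y.shape == (8, 512)
        assert y[0, 0] == pytest.approx(np.sin(2 * np.pi * 6 * 1 / 256))
        # rows alternate sin/cos per harmonic
        assert y[1, 0] == pytest.approx(np.cos(2 * np.pi * 6 * 1 / 256))
        assert y[2, 0] == pytest.approx(np.sin(2 * np.pi * 12 * 1 / 256))

    def test_rows_have_zero_mean_over_integer_cycles(self):
        # 6 Hz over 1 s at 256 Hz: every harmonic spans integer cycles
        y = make_reference(6.0, 4, 256.0, 256)
        np.testing.assert_allclose(y.mean(axis=1), 0.0, atol=1e-10)

    def test_rows_nearly_orthogonal(self):
        y = make_reference(10.0, 4, 256.0, 1280)
        gram = y @ y.T
        np.testing.assert_allclose(np.diag(gram), 1280 / 2, rtol=1e-6)
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * 1280

    def test_nyquist_guard(self):
        with pytest.raises(ValidationError):
            make_reference(40.0, 4, 256.0, 512)  # 160 Hz > 128 Hz


class TestCCA:
    def test_signal_in_reference_span_gives_one(self):
        y = make_reference(7.5, 4, 256.0, 640)
        assert cca_coefficient(y[:2], y) == pytest.approx(1.0, abs=1e-8)

    def test_matches_oracle_on_noise(self, rng):
        y = make_reference(10.0, 3, 256.0, 1280)
        x = rng.standard_normal((1, 1280))
        assert cca_coefficient(x, y) == pytest.approx(cca_oracle(x, y), abs=1e-8)

    def test_invariant_under_invertible_mixing(self, rng):
        y = make_reference(6.0, 3, 256.0, 512)
        x = rng.standard_normal((3, 512))
        rho = cca_coefficient(x, y)
        for _ in range(5):
            a = rng.standard_normal((3, 3))
            if abs(np.linalg.det(a)) < 1e-3:
                continue
            assert cca_coefficient(a @ x, y) == pytest.approx(rho, abs=1e-8)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            cca_coefficient(rng.standard_normal((2, 100)),
                            rng.standard_normal((4, 101)))

    def test_zero_input_gives_zero(self):
        y = make_reference(6.0, 2, 256.0, 256)
        assert cca_coefficient(np.zeros((2, 256)), y) == 0.0


class TestDelayEmbed:
    def test_circular_shift_rule(self):
        x = np.array([[1.0, 2.0, 3.0]])
        out = delay_embed(x, 1)
        np.testing.assert_array_equal(out, [[1, 2, 3], [3, 1, 2]])

    def test_tau_zero_duplicates(self):
        x = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(delay_embed(x, 0), np.vstack([x, x]))

    def test_cyclic_group_property(self, rng):
        x = rng.standard_normal((2, 16))
        once = delay_embed(x, 3)[2:]
        back = delay_embed(once, 13)[2:]
        np.testing.assert_array_equal(back, x)

    def test_tau_too_large_rejected(self):
        with pytest.raises(ValidationError):
            delay_embed(np.zeros((1, 8)), 8)


class TestMSI:
    def test_perfectly_synchronized_gives_one(self, rng):
        # X identical to the (single-row) reference: R has one non-zero
        # eigenvalue, zero entropy, S = 1
        x = rng.standard_normal((1, 128))
        assert msi_index(x, x) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_gives_small_s_decreasing_in_m(self, rng):
        y_small = make_reference(10.0, 4, 256.0, 1280)
        y_large = make_reference(10.0, 4, 256.0, 12800)
        s_small = np.mean([
            msi_index(rng.standard_normal((2, 1280)), y_small) for _ in range(10)
        ])
        s_large = np.mean([
            msi_index(rng.standard_normal((2, 12800)), y_large) for _ in range(10)
        ])
        assert s_large < s_small < 0.05

    def test_matches_oracle_small_instance(self, rng):
        y = make_reference(7.5, 2, 256.0, 64)
        x = rng.standard_normal((2, 64))
        assert msi_index(x, y) == pytest.approx(msi_oracle(x, y), abs=1e-8)

    def test_invariant_under_invertible_mixing(self, rng):
        y = make_reference(6.0, 2, 256.0, 256)
        x = rng.standard_normal((3, 256))
        s = msi_index(x, y)
        a = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        assert msi_index(a @ x, y) == pytest.approx(s, abs=1e-6)

    def test_non_finite_rejected(self):
        y = make_reference(6.0, 2, 256.0, 64)
        x = np.full((1, 64), np.nan)
        with pytest.raises(ValidationError):
            msi_index(x, y)


class TestFBCCA:
    def test_subband_weights_printed_constants(self):
        config = ClassifierConfig("FBCCA")
        assert config.subband_weight(1) == pytest.approx(1.25)
        assert config.subband_weight(2) == pytest.approx(2**-1.25 + 0.25)

    def test_single_subband_matches_cca_decisions(self, rng, refs):
        config = ClassifierConfig("FBCCA", fbcca_band_edges=((4.0, 52.0),))
        sos = scipy.signal.butter(3, (4, 52), btype="bandpass", fs=256, output="sos")
        for _ in range(20):
            x = rng.standard_normal((2, 640))
            xb = scipy.signal.sosfiltfilt(sos, x, axis=-1)
            assert classify(x, refs, config) == classify(
                xb, refs, ClassifierConfig("CCA")
            )

    def test_true_frequency_wins_with_harmonics(self, refs):
        t = np.arange(1, 1281) / 256.0
        x = (np.sin(2 * np.pi * 7.5 * t) + 0.5 * np.sin(2 * np.pi * 15 * t))[None, :]
        config = ClassifierConfig("FBCCA")
        vals = [fbcca_score(x, f, 256.0, config) for f in FREQS]
        assert int(np.argmax(vals)) == FREQS.index(7.5)


class TestClassify:
    @pytest.mark.parametrize("algorithm", ["CCA", "ECCA", "FBCCA", "MSI", "EMSI"])
    def test_noiseless_trial_classified(self, refs, algorithm):
        t = np.arange(1, 1281) / 256.0
        x = np.sin(2 * np.pi * 7.5 * t + 0.3)[None, :]
        assert classify(x, refs, ClassifierConfig(algorithm)) == FREQS.index(7.5)

    @pytest.mark.parametrize("algorithm", ["CCA", "MSI", "FBCCA"])
    def test_all_zero_trial_ties_to_lowest_index(self, refs, algorithm):
        x = np.zeros((2, 640))
        assert classify(x, refs, ClassifierConfig(algorithm)) == 0

    @pytest.mark.parametrize("base,extended", [("CCA", "ECCA"), ("MSI", "EMSI")])
    def test_tau_zero_reduces_to_base(self, rng, refs, base, extended):
        for _ in range(20):
            x = rng.standard_normal((3, 640))
            assert classify(x, refs, ClassifierConfig(base)) == classify(
                x, refs, ClassifierConfig(extended, tau=0)
            )

    @pytest.mark.parametrize("algorithm", ["CCA", "ECCA", "MSI", "EMSI"])
    def test_channel_scaling_changes_no_decision(self, rng, refs, algorithm):
        config = ClassifierConfig(algorithm)
        for _ in range(10):
            x = rng.standard_normal((3, 640))
            scaled = x.copy()
            scaled[1] *= 1000.0
            assert classify(x, refs, config) == classify(scaled, refs, config)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(1, 3),
    m=st.sampled_from([64, 128, 256]),
    algorithm=st.sampled_from(["CCA", "MSI"]),
)
def test_scores_bounded_and_normalized(seed, n, m, algorithm):
    """rho and S live in [0, 1] for arbitrary finite inputs."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, m)) * rng.uniform(0.1, 100)
    refs = ReferenceSet(FREQS, nh=2, fs=256.0)
    vals = scores(x, refs, ClassifierConfig(algorithm, nh=2))
    assert np.all(vals >= 0.0) and np.all(vals <= 1.0)


def test_msi_eigenvalue_normalization(rng):
    """Normalized eigenvalues of R sum to 1 and are non-negative."""
    # recompute the spectrum the estimator uses, via the oracle route
    y = make_reference(6.0, 2, 256.0, 128)
    x = rng.standard_normal((2, 128))
    import scipy.linalg

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    m = 128
    c11, c22, c12 = xc @ xc.T / m, yc @ yc.T / m, xc @ yc.T / m
    u1 = np.real(scipy.linalg.fractional_matrix_power(c11, -0.5))
    u2 = np.real(scipy.linalg.fractional_matrix_power(c22, -0.5))
    p = c11.shape[0] + c22.shape[0]
    r = np.block([[u1 @ c11 @ u1, u1 @ c12 @ u2], [(u1 @ c12 @ u2).T, u2 @ c22 @ u2]])
    lam = np.linalg.eigvalsh(r)
    assert lam.min() > -1e-10
    lam_n = lam / lam.sum()
    assert lam_n.sum() == pytest.approx(1.0, abs=1e-10)
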
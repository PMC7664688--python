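import numpy as np
import pandas as pd
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eegintent.channels import CHANNELS_1020
from eegintent.features import (
    FEATURE_NAMES,
    METADATA_COLUMNS,
    apply_scaler,
    approx_entropy,
    correlation_dimension,
    dwt_band_edges,
    dwt_features,
    extract_feature_table,
    feature_columns,
    fit_scaler,
    nonlinear_features,
    permutation_entropy,
    sample_entropy,
    spectral_features,
    time_features,
    Scaler,
)
from eegintent.preprocess import Epoch

# ------------------------------------------------------------- catalogue


def test_catalogue_has_65_features_with_category_counts():
    assert len(FEATURE_NAMES) == 65
    assert sum(1 for f in FEATURE_NAMES if f.startswith("dwt_")) == 24
    spectral = [f for f in FEATURE_NAMES
                if any(f.startswith(b + "_") for b in
                       ("delta", "theta", "alpha", "beta", "high_beta", "gamma", "high_gamma"))]
    assert len(spectral) == 28
    nonlinear = ("approx_entropy", "sample_entropy", "permutation_entropy",
                 "correlation_dimension")
    assert all(f in FEATURE_NAMES for f in nonlinear)
    assert 65 - 24 - 28 - len(nonlinear) == 9  # time-domain features


# ------------------------------------------------------------- time domain

def test_time_features_arithmetic():
    v = time_features(np.array([1.0, 2.0, 3.0, 4.0]))
    named = dict(zip(FEATURE_NAMES[:9], v))
    assert named["mean"] == 2.5
    assert named["median"] == 2.5
    assert named["peak_to_peak"] == 3.0
    assert named["mean_square"] == 7.5


def test_constant_input_conventions():
    v = dict(zip(FEATURE_NAMES[:9], time_features(np.full(100, 3.14))))
    assert v["peak_to_peak"] == 0.0
    assert v["hjorth_activity"] == 0.0
    assert v["hjorth_mobility"] == 0.0
    assert v["hjorth_complexity"] == 0.0
    nl = nonlinear_features(np.full(200, 1.0))
    assert np.all(nl == 0.0)


def test_hjorth_mobility_of_sampled_sinusoid_closed_form():
    """mobility(sin 2*pi*f*t) = 2 sin(pi f / fs), cross-checked numerically."""
    fs = 250.0
    for f in (5.0, 10.0, 25.0):
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        mobility = time_features(x)[7]
        closed = 2 * np.sin(np.pi * f / fs)
        brute = np.sqrt(np.diff(x).var() / x.var())
        assert mobility == pytest.approx(brute, rel=1e-12)
        assert mobility == pytest.approx(closed, rel=2e-2)


def test_hjorth_mobility_monotone_in_frequency():
    fs = 250.0
    t = np.arange(int(2 * fs)) / fs
    grid = [2.0, 5.0, 10.0, 20.0, 40.0, 60.0]
    mob = [time_features(np.sin(2 * np.pi * f * t))[7] for f in grid]
    assert all(a < b for a, b in zip(mob, mob[1:]))


# ------------------------------------------------------------- wavelet

def test_dwt_band_edges_at_250hz():
    edges = dwt_band_edges(250.0, 5)
    assert edges["D1"] == (62.5, 125.0)
    assert edges["D2"] == (31.25, 62.5)
    assert edges["A5"][0] == 0.0
    assert edges["A5"][1] == pytest.approx(3.90625)


def test_relative_energies_sum_to_one_and_conserve_energy():
    rng = np.random.default_rng(0)
    names = [f for f in FEATURE_NAMES if f.endswith("relative_energy")]
    idx = [FEATURE_NAMES.index(f) - 9 for f in names]
    for _ in range(50):
        x = rng.normal(size=500)
        v = dwt_features(x)
        rels = v[[FEATURE_NAMES.index(f) - 9 for f in names]]
        assert abs(rels.sum() - 1.0) < 1e-9


def test_dwt_energy_conservation_against_signal_energy():
    """Orthonormal decomposition: coefficient energy == signal energy to 1e-6."""
    rng = np.random.default_rng(1)
    from eegintent.features import _dwt_coeffs

    for _ in range(50):
        n = int(rng.integers(300, 700))
        x = rng.normal(size=n)
        coeffs = _dwt_coeffs(x, "db4", 5)
        total = sum((c**2).sum() for c in coeffs)
        assert abs(total - (x**2).sum()) / (x**2).sum() < 1e-6


def _circular_dwt_level(x, wavelet):
    """Independent single-level DWT oracle: circular convolution with the
    decomposition filters, rolled by half the filter length, downsampled."""
    w = pywt.Wavelet(wavelet)
    n = len(x)
    out = []
    for filt in (w.dec_lo, w.dec_hi):
        L = len(filt)
        y = np.zeros(n)
        for i in range(n):
            y[i] = sum(filt[k] * x[(i - k) % n] for k in range(L))
        out.append(np.roll(y, -(L // 2))[::2])
    return out  # [approx, detail]


def test_dwt_matches_circular_convolution_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(size=128)
    coeffs = pywt.wavedec(x, "db4", level=2, mode="periodization")  # [A2, D2, D1]
    a1, d1 = _circular_dwt_level(x, "db4")
    a2, d2 = _circular_dwt_level(a1, "db4")
    assert np.allclose(coeffs[-1], d1)
    assert np.allclose(coeffs[-2], d2)
    assert np.allclose(coeffs[0], a2)


def test_pure_50hz_sine_concentrates_in_d2():
    fs = 250.0
    t = np.arange(500) / fs
    v = dwt_features(np.sin(2 * np.pi * 50.0 * t), fs=fs)
    rel = {b: v[4 * i] for i, b in enumerate(("D1", "D2", "D3", "D4", "D5", "A5"))}
    assert max(rel, key=rel.get) == "D2"


def test_white_noise_puts_half_energy_in_d1():
    rng = np.random.default_rng(3)
    vals = [dwt_features(rng.normal(size=512))[0] for _ in range(100)]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


def test_all_zero_signal_degenerate():
    v = dwt_features(np.zeros(500))
    assert np.all(v == 0.0)


# ------------------------------------------------------------- spectral

def test_relative_powers_sum_to_one():
    rng = np.random.default_rng(4)
    rel_idx = [i for i, f in enumerate(FEATURE_NAMES[33:61]) if f.endswith("relative_power")]
    for _ in range(50):
        v = spectral_features(rng.normal(size=500))
        assert abs(v[rel_idx].sum() - 1.0) < 1e-9


def test_10hz_sine_dominates_alpha():
    fs = 250.0
    t = np.arange(500) / fs
    rng = np.random.default_rng(5)
    x = np.sin(2 * np.pi * 10.0 * t) + 1e-3 * rng.normal(size=500)
    v = dict(zip(FEATURE_NAMES[33:61], spectral_features(x, fs=fs)))
    assert v["alpha_relative_power"] > 0.9
    assert v["alpha_peak_frequency"] == pytest.approx(10.0, abs=0.5)


def test_white_noise_delta_share_is_bandwidth_fraction():
    """Flat spectrum: delta (3 Hz wide) holds ~3/49 of the 1-50 Hz total."""
    rng = np.random.default_rng(6)
    vals = [dict(zip(FEATURE_NAMES[33:61], spectral_features(rng.normal(size=500))))
            ["delta_relative_power"] for _ in range(200)]
    assert np.mean(vals) == pytest.approx(3 / 49, abs=0.01)


# ------------------------------------------------------------- nonlinear

def _sample_entropy_bruteforce(x, m=2, r_factor=0.2):
    """O(n^2) literal template counting, same degenerate conventions."""
    r = r_factor * x.std()
    n = len(x)
    B = A = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if B == 0:
        return 0.0
    return -np.log(max(A, 1) / B)


@pytest.mark.parametrize("n", [60, 120, 200])
def test_sample_entropy_matches_bruteforce(n):
    rng = np.random.default_rng(n)
    x = rng.normal(size=n)
    assert sample_entropy(x) == pytest.approx(_sample_entropy_bruteforce(x), rel=1e-12)


def test_permutation_entropy_of_iid_noise_near_one():
    rng = np.random.default_rng(7)
    vals = [permutation_entropy(rng.uniform(size=500)) for _ in range(50)]
    assert np.mean(vals) >= 0.98


def test_permutation_entropy_of_monotone_series_is_zero():
    assert permutation_entropy(np.arange(100.0)) == 0.0


def test_sine_more_regular_than_its_shuffle():
    fs = 250.0
    t = np.arange(500) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    rng = np.random.default_rng(8)
    wins = sum(
        sample_entropy(x) < sample_entropy(rng.permutation(x)) for _ in range(50)
    )
    assert wins >= 48  # >= 95% of trials


def test_correlation_dimension_of_sine_near_one():
    t = np.arange(500) / 250.0
    d = correlation_dimension(np.sin(2 * np.pi * 10.0 * t))
    assert d == pytest.approx(1.0, abs=0.3)


# ------------------------------------------------------------- table

def _epochs(n, channels=CHANNELS_1020, fs=250.0, n_samples=500, seed=0):
    rng = np.random.default_rng(seed)
    return [
        Epoch(signal=rng.normal(size=(len(channels), n_samples)), fs=fs, start=float(k),
              duration=n_samples / fs, channel_names=tuple(channels),
              subject="S01", question=k + 1, scenario_type="insider", answer="no")
        for k in range(n)
    ]


def test_single_epoch_row_has_1365_features():
    table = extract_feature_table(_epochs(1))
    assert len(feature_columns(table)) == 21 * 65 == 1365
    assert len(table) == 1
    assert table[feature_columns(table)].notna().all().all()


def test_single_channel_yields_65_columns():
    table = extract_feature_table(_epochs(1), channels=["Fz"])
    assert len(feature_columns(table)) == 65


def test_empty_epoch_list_gives_header_only():
    table = extract_feature_table([], channels=list(CHANNELS_1020))
    assert len(table) == 0
    assert len(feature_columns(table)) == 1365
    assert list(table.columns[: len(METADATA_COLUMNS)]) == list(METADATA_COLUMNS)


def test_missing_channel_raises_with_epoch_index():
    eps = _epochs(1, channels=["Fz", "Cz"])
    with pytest.raises(ValueError, match="epoch 0"):
        extract_feature_table(eps, channels=["Fz", "Pz"])


@settings(max_examples=10, deadline=None)
@given(hnp.arrays(np.float64, 500, elements=st.floats(-100, 100)))
def test_normalization_identities_hold_for_any_epoch(x):
    """Relative band powers and relative wavelet energies each sum to 1 (or 0
    for an all-constant signal) for arbitrary bounded input."""
    v_dwt = dwt_features(x)
    v_spec = spectral_features(x)
    rel_e = v_dwt[0::4].sum()
    rel_p = sum(v_spec[4 * i + 1] for i in range(7))
    assert rel_e == pytest.approx(1.0, abs=1e-9) or rel_e == 0.0
    assert rel_p == pytest.approx(1.0, abs=1e-9) or rel_p == 0.0


# ------------------------------------------------------------- scaler

def test_scaler_normalizes_training_table():
    table = extract_feature_table(_epochs(6, channels=["Fz", "Cz"]))
    scaler = fit_scaler(table)
    out = apply_scaler(scaler, table)
    X = out[feature_columns(out)].to_numpy()
    assert np.abs(X.mean(axis=0)).max() < 1e-9
    nontrivial = np.array([c not in scaler.zero_variance for c in scaler.columns])
    assert np.abs(X.var(axis=0)[nontrivial] - 1.0).max() < 1e-9


def test_scaler_does_not_leak_test_statistics():
    train = extract_feature_table(_epochs(5, channels=["Fz"], seed=1))
    test = extract_feature_table(_epochs(5, channels=["Fz"], seed=2))
    test["Fz.mean"] += 50.0
    scaler = fit_scaler(train)
    out = apply_scaler(scaler, test)
    assert abs(out["Fz.mean"].mean()) > 1.0  # train stats applied, not refit


def test_constant_column_maps_to_zero():
    train = extract_feature_table(_epochs(4, channels=["Fz"]))
    train["Fz.mean"] = 7.0
    scaler = fit_scaler(train)
    assert "Fz.mean" in scaler.zero_variance
    out = apply_scaler(scaler, train)
    assert np.all(out["Fz.mean"] == 0.0)


def test_unfitted_scaler_rejected():
    with pytest.raises(ValueError):
        apply_scaler(Scaler(), pd.DataFrame({"a": [1.0]}))
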
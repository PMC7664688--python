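"""Per-channel epoch features: 9 time-domain, 24 wavelet, 28 spectral, 4 nonlinear.

Every epoch/channel yields exactly 65 finite values.  Conventions for
degenerate (constant or all-zero) input return 0 rather than raising, with a
``degenerate`` flag carried in the feature table.

Wavelet subbands come from a 5-level Daubechies-4 decomposition in
periodization mode on the epoch zero-padded to the next multiple of
``2**levels``; the filter bank is then orthonormal, so subband energies sum
exactly to signal energy and relative energies to 1.  At 250 Hz the dyadic
bands are D1 62.5-125 Hz down to A5 0-3.9 Hz.

Spectral features use a single Hann-windowed periodogram per epoch (0.5 Hz
resolution at the 2 s default) over seven canonical bands from delta (1-4 Hz)
to high gamma (40-50 Hz); band edges are half-open [low, high) with the last
band closed at 50 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats

# ---------------------------------------------------------------- catalogue

TIME_FEATURES = (
    "mean", "mean_square", "median", "peak_to_peak", "skewness", "kurtosis",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
)
DWT_SUBBANDS = ("D1", "D2", "D3", "D4", "D5", "A5")
DWT_STATS = ("relative_energy", "shannon_entropy", "max_energy", "variance")
SPECTRAL_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "high_beta": (25.0, 30.0),
    "gamma": (30.0, 40.0),
    "high_gamma": (40.0, 50.0),
}
SPECTRAL_STATS = ("absolute_power", "relative_power", "max_power", "peak_frequency")
NONLINEAR_FEATURES = (
    "approx_entropy", "sample_entropy", "permutation_entropy", "correlation_dimension",
)

FEATURE_NAMES: tuple[str, ...] = (
    TIME_FEATURES
    + tuple(f"dwt_{b}_{s}" for b in DWT_SUBBANDS for s in DWT_STATS)
    + tuple(f"{b}_{s}" for b in SPECTRAL_BANDS for s in SPECTRAL_STATS)
    + NONLINEAR_FEATURES
)
assert len(FEATURE_NAMES) == 65

METADATA_COLUMNS = ("subject", "question", "scenario_type", "answer",
                    "start", "duration", "degenerate")


# ---------------------------------------------------------------- time domain

def _is_constant(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0.0)


def time_features(x: np.ndarray) -> np.ndarray:
    """Nine time-domain features of a single-channel epoch.

    Hjorth activity is the variance; mobility sqrt(var(dx)/var(x)); complexity
    mobility(dx)/mobility(x).  Constant input returns activity = mobility =
    complexity = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("time features need at least 3 samples")
    mean = x.mean()
    mean_square = float((x**2).mean())
    median = float(np.median(x))
    ptp = float(x.max() - x.min())
    var = float(x.var())
    if _is_constant(x):
        skew = kurt = activity = mobility = complexity = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        activity = var
        dx = np.diff(x)
        var_d = float(dx.var())
        mobility = float(np.sqrt(var_d / var))
        if var_d < 1e-300:
            complexity = 0.0
        else:
            ddx = np.diff(dx)
            mobility_d = float(np.sqrt(ddx.var() / var_d))
            complexity = mobility_d / mobility if mobility > 0 else 0.0
    return np.array([mean, mean_square, median, ptp, skew, kurt,
                     activity, mobility, complexity])


# ---------------------------------------------------------------- wavelet

def dwt_band_edges(fs: float = 250.0, levels: int = 5) -> dict[str, tuple[float, float]]:
    """Dyadic frequency bands of the detail/approximation subbands.

    At 250 Hz with 5 levels: D1 62.5-125, D2 31.25-62.5, D3 15.625-31.25,
    D4 7.8125-15.625, D5 3.90625-7.8125, A5 0-3.90625 Hz.
    """
    edges: dict[str, tuple[float, float]] = {}
    hi = fs / 2.0
    for k in range(1, levels + 1):
        edges[f"D{k}"] = (hi / 2.0, hi)
        hi /= 2.0
    edges[f"A{levels}"] = (0.0, hi)
    return edges


def _dwt_coeffs(x: np.ndarray, wavelet: str, levels: int) -> list[np.ndarray]:
    """Orthonormal decomposition of x zero-padded to a multiple of 2**levels.

    Returns [D1, D2, ..., Dlevels, A(levels)].
    """
    n = len(x)
    block = 2**levels
    padded = n if n % block == 0 else (n // block + 1) * block
    xp = np.zeros(padded)
    xp[:n] = x
    coeffs = pywt.wavedec(xp, wavelet, level=levels, mode="periodization")
    a = coeffs[0]
    details = coeffs[1:]  # [Dlevels, ..., D1]
    return list(details[::-1]) + [a]


def dwt_features(
    x: np.ndarray, fs: float = 250.0, wavelet: str = "db4", levels: int = 5
) -> np.ndarray:
    """24 wavelet features: 4 statistics per subband D1..D5, A5.

    relative_energy: subband energy over total coefficient energy;
    shannon_entropy: -sum p log p over within-subband coefficient-energy
    fractions; max_energy: largest squared coefficient; variance: variance of
    the squared coefficients.  All-zero input yields zeros (degenerate).
    """
    x = np.asarray(x, dtype=float)
    coeffs = _dwt_coeffs(x, wavelet, levels)
    energies = np.array([(c**2).sum() for c in coeffs])
    total = energies.sum()
    out = []
    for c, e in zip(coeffs, energies):
        sq = c**2
        rel = e / total if total > 0 else 0.0
        if e > 0:
            p = sq / e
            p = p[p > 0]
            ent = float(-(p * np.log(p)).sum())
        else:
            ent = 0.0
        out.extend([rel, ent, float(sq.max()), float(sq.var())])
    return np.array(out)


# ---------------------------------------------------------------- spectral

def spectral_features(x: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """28 band-power features from a Hann-windowed periodogram.

    Per band: absolute power (sum of in-band periodogram values), relative
    power (share of the total over the seven bands), max power, and the
    frequency of that maximum.
    """
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("spectral features need at least 1 s of signal")
    freqs, psd = sps.periodogram(x, fs=fs, window="hann")
    band_abs = {}
    band_max = {}
    band_peak = {}
    for name, (lo, hi) in SPECTRAL_BANDS.items():
        if name == "high_gamma":
            m = (freqs >= lo) & (freqs <= hi)
        else:
            m = (freqs >= lo) & (freqs < hi)
        p = psd[m]
        band_abs[name] = float(p.sum())
        if p.size and p.max() > 0:
            k = int(np.argmax(p))
            band_max[name] = float(p[k])
            band_peak[name] = float(freqs[m][k])
        else:
            band_max[name] = 0.0
            band_peak[name] = float(lo)
    total = sum(band_abs.values())
    out = []
    for name in SPECTRAL_BANDS:
        rel = band_abs[name] / total if total > 0 else 0.0
        out.extend([band_abs[name], rel, band_max[name], band_peak[name]])
    return np.array(out)


# ---------------------------------------------------------------- nonlinear

def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Delay-embedded vectors as rows: X[i] = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    n = len(x) - (m - 1) * tau
    if n <= 0:
        raise ValueError("series too short for the requested embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _cheb_running(x: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance matrix between all length-m templates of x.

    Built incrementally: D_m[i, j] = max_{k<m} |x[i+k] - x[j+k]|; the result
    has shape (n-m+1, n-m+1).
    """
    n = len(x)
    d = np.abs(x[:, None] - x[None, :])
    out = d[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(out, d[k : n - m + 1 + k, k : n - m + 1 + k], out=out)
    return out


def approx_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy with tolerance r = r_factor * SD(x); 0 if constant.

    Classic definition: phi(m) is the mean log fraction of templates within
    tolerance (self-matches included); ApEn = phi(m) - phi(m+1).
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    r = r_factor * x.std()

    def phi(mm: int) -> float:
        c = (_cheb_running(x, mm) <= r).mean(axis=1)
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy -log(A/B), self-matches excluded; 0 if constant.

    B counts template pairs of length m within tolerance, A of length m+1;
    both counts range over the same N-m templates.  Degenerate counts follow
    a bounded convention: B = 0 returns 0, and A = 0 is capped at 1 so the
    statistic returns its attainable maximum log(B) instead of infinity.
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    r = r_factor * x.std()
    n = len(x)
    dm = _cheb_running(x, m)[: n - m, : n - m]
    dm1 = _cheb_running(x, m + 1)
    wb = dm <= r
    wa = dm1 <= r
    np.fill_diagonal(wb, False)
    np.fill_diagonal(wa, False)
    b = float(wb.sum())
    a = float(wa.sum())
    if b == 0:
        return 0.0
    a = max(a, 1.0)
    return float(-np.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Permutation entropy of ordinal patterns, normalized to [0, 1] by log(order!)."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    emb = _embed(x, order, delay)
    ranks = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1, kind="stable")
    codes = (ranks * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(math.factorial(order)))


def _first_zero_autocorr(x: np.ndarray, max_lag: int = 10) -> int:
    xc = x - x.mean()
    denom = float((xc * xc).sum())
    if denom <= 0:
        return 1
    for lag in range(1, max_lag + 1):
        r = float((xc[:-lag] * xc[lag:]).sum()) / denom
        if r <= 0:
            return lag
    return max_lag


def correlation_dimension(
    x: np.ndarray,
    dims: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    max_vectors: int = 256,
    n_radii: int = 8,
) -> float:
    """Grassberger-Procaccia correlation-dimension estimate.

    Delay = first zero crossing of the autocorrelation (capped at 10 samples);
    for each embedding dimension the slope of log C(r) vs log r is fitted over
    radii spanning the 10th-50th percentile of pairwise Chebyshev distances,
    and the median slope across dimensions is returned.  Embedded vectors are
    subsampled to at most ``max_vectors`` for tractability.
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    tau = _first_zero_autocorr(x)
    usable = [m for m in dims if len(x) - (m - 1) * tau >= 20]
    if not usable:
        return 0.0
    # one common start-index set so distances grow incrementally with m
    n_use = len(x) - (max(usable) - 1) * tau
    idx = np.arange(n_use)
    if n_use > max_vectors:
        idx = idx[:: int(np.ceil(n_use / max_vectors))]
    iu = np.triu_indices(len(idx), k=1)
    d = np.zeros((len(idx), len(idx)))
    slopes = []
    k_done = 0
    for m in usable:
        for k in range(k_done, m):
            xi = x[idx + k * tau]
            np.maximum(d, np.abs(xi[:, None] - xi[None, :]), out=d)
        k_done = m
        dist = d[iu]
        dist = dist[dist > 0]
        if dist.size < 10:
            continue
        lo, hi = np.percentile(dist, [10, 50])
        if not hi > lo > 0:
            continue
        radii = np.exp(np.linspace(np.log(lo), np.log(hi), n_radii))
        c = np.array([(dist <= r).mean() for r in radii])
        ok = c > 0
        if ok.sum() < 2:
            continue
        slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
        slopes.append(slope)
    if not slopes:
        return 0.0
    return float(np.median(slopes))


def nonlinear_features(x: np.ndarray) -> np.ndarray:
    """ApEn, SampEn (m=2, r=0.2 SD), normalized permutation entropy (order 3),
    and the correlation-dimension estimate; zeros for constant input."""
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError("nonlinear features need at least 100 samples")
    return np.array([
        approx_entropy(x),
        sample_entropy(x),
        permutation_entropy(x),
        correlation_dimension(x),
    ])


# ---------------------------------------------------------------- table

def feature_vector(x: np.ndarray, fs: float) -> tuple[np.ndarray, bool]:
    """All 65 features for one channel of one epoch; flags degenerate input."""
    degenerate = _is_constant(np.asarray(x))
    v = np.concatenate([
        time_features(x),
        dwt_features(x, fs=fs),
        spectral_features(x, fs=fs),
        nonlinear_features(x),
    ])
    return v, degenerate


def feature_column_names(channels) -> list[str]:
    return [f"{ch}.{f}" for ch in channels for f in FEATURE_NAMES]


def extract_feature_table(epochs, channels=None) -> pd.DataFrame:
    """One row per epoch: ``channel.feature`` columns plus trial metadata.

    ``channels`` restricts extraction to a subset (default: the epochs'
    full channel set).  Deterministic column order; an empty epoch list
    yields an empty table with the full header.
    """
    if channels is None:
        channels = list(epochs[0].channel_names) if epochs else []
    cols = feature_column_names(channels)
    rows = []
    meta_rows = []
    for k, ep in enumerate(epochs):
        missing = [c for c in channels if c not in ep.channel_names]
        if missing:
            raise ValueError(f"epoch {k} lacks channel(s) {missing}")
        vec = np.empty(len(cols))
        degenerate = False
        for j, ch in enumerate(channels):
            ci = ep.channel_names.index(ch)
            v, d = feature_vector(ep.signal[ci], ep.fs)
            vec[j * 65 : (j + 1) * 65] = v
            degenerate |= d
        rows.append(vec)
        meta_rows.append({
            "subject": ep.subject,
            "question": ep.question,
            "scenario_type": ep.scenario_type,
            "answer": ep.answer,
            "start": ep.start,
            "duration": ep.duration,
            "degenerate": degenerate,
        })
    feat = pd.DataFrame(np.array(rows) if rows else np.empty((0, len(cols))), columns=cols)
    meta = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    return pd.concat([meta, feat], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature (non-metadata) columns of a feature table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


# ---------------------------------------------------------------- scaling

@dataclass
class Scaler:
    """Per-column z-normalization fitted on training rows only.

    Zero-variance training columns are flagged and map to 0 on transform.
    """

    columns: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    zero_variance: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None


def fit_scaler(train: pd.DataFrame, columns: list[str] | None = None) -> Scaler:
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty table")
    cols = columns if columns is not None else feature_columns(train)
    X = train[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    zero = [c for c, s in zip(cols, std) if s < 1e-12]
    std = np.where(std < 1e-12, 1.0, std)
    return Scaler(columns=list(cols), mean_=mean, scale_=std, zero_variance=zero)


def apply_scaler(scaler: Scaler, table: pd.DataFrame) -> pd.DataFrame:
    """Transform a table with training-fold statistics (never refits)."""
    if not scaler.fitted:
        raise ValueError("scaler has not been fitted")
    out = table.copy()
    X = out[scaler.columns].to_numpy(dtype=float)
    X = (X - scaler.mean_) / scaler.scale_
    if scaler.zero_variance:
        zi = [scaler.columns.index(c) for c in scaler.zero_variance]
        X[:, zi] = 0.0
    out[scaler.columns] = X
    return out
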
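"""EEG feature extraction: filter-bank CSP, wavelet-packet energies, nonlinear.

Three feature families are computed per 2 s window and concatenated:

* **FBCSP** (44-d at defaults): the 8-32 Hz range is split into 11
  overlapping 4 Hz bands (8-12, 10-14, ..., 28-32 Hz); per band, four
  one-vs-rest common-spatial-pattern filters (one per motor-imagery class,
  top eigencomponent each) project the signal and the log variance ratio
  ``f_i = log(var(Z_i) / sum_j var(Z_j))`` of the four components is taken.
* **WPD energies** (90-d at 15 channels): a 5-level db4 wavelet-packet
  decomposition partitions the spectrum into 32 equal leaves of 125/32 Hz;
  the six frequency-ordered leaves spanning ~7.8-31.25 Hz contribute their
  coefficient energies ``E_b = sum_n x_b(n)^2`` per channel.
* **Nonlinear** (45-d at 15 channels): sample entropy (m=2, r=0.2*std),
  spectral entropy of the normalized periodogram, and Higuchi fractal
  dimension, per channel.

The concatenated vector (179-d at defaults) is PCA-compressed (components
covering >= 95% variance) and z-scored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import eigh
from scipy.signal import periodogram
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .preproc import EpochSet, bandpass_filter


def default_filter_bank() -> list[tuple[float, float]]:
    """Eleven 4 Hz bands, 2 Hz step: 8-12, 10-14, ..., 28-32 Hz."""
    return [(8.0 + 2 * i, 12.0 + 2 * i) for i in range(11)]


# ---------------------------------------------------------------------------
# CSP

def regularized_covariance(x: np.ndarray, shrinkage: float = 0.05) -> np.ndarray:
    """Trace-normalized spatial covariance of one trial with shrinkage.

    ``C = (1-s) * XX'/tr(XX') + s * I/m`` keeps the composite covariance
    invertible when trials are short relative to the channel count.
    """
    x = np.asarray(x, dtype=float)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("zero-energy trial: covariance undefined")
    c /= tr
    m = c.shape[0]
    return (1 - shrinkage) * c + shrinkage * np.eye(m) / m


def csp_fit(C1: np.ndarray, C2: np.ndarray, k: int = 1) -> np.ndarray:
    """Spatial filters maximizing tr(W'C1W)/tr(W'(C1+C2)W) with W'(C1+C2)W=I.

    Solves the generalized eigenproblem ``C1 w = lambda (C1+C2) w``; columns
    of the returned (m, k) matrix are sorted by descending eigenvalue.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if C1.shape != C2.shape or C1.shape[0] != C1.shape[1]:
        raise ValueError("covariances must be square and same-shaped")
    comp = C1 + C2
    try:
        evals, evecs = eigh(C1, comp)
    except np.linalg.LinAlgError:
        m = comp.shape[0]
        comp = comp + 1e-8 * np.trace(comp) / m * np.eye(m)
        evals, evecs = eigh(C1, comp)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[:k]]


class _BandCSP:
    """Per-band one-vs-rest CSP bank: one top filter per class."""

    def __init__(self, n_classes: int, shrinkage: float):
        self.n_classes = n_classes
        self.shrinkage = shrinkage

    def fit(self, xb: np.ndarray, y: np.ndarray) -> "_BandCSP":
        covs = np.stack([regularized_covariance(t, self.shrinkage) for t in xb])
        class_cov = {c: covs[y == c].mean(axis=0) for c in range(self.n_classes)}
        filters = []
        for c in range(self.n_classes):
            rest = np.mean([class_cov[o] for o in range(self.n_classes) if o != c],
                           axis=0)
            filters.append(csp_fit(class_cov[c], rest, k=1)[:, 0])
        self.W_ = np.column_stack(filters)  # (m, n_classes)
        return self

    def transform(self, xb: np.ndarray) -> np.ndarray:
        z = np.einsum("mk,nmt->nkt", self.W_, xb)
        v = z.var(axis=-1)
        if np.any(v <= 0):
            raise ValueError("zero-variance projected component")
        return np.log(v / v.sum(axis=1, keepdims=True))


def fbcsp_features(x: np.ndarray, y: np.ndarray, fs: float,
                   bands: list[tuple[float, float]] | None = None,
                   shrinkage: float = 0.05,
                   models: list[_BandCSP] | None = None,
                   ) -> tuple[np.ndarray, list[_BandCSP]]:
    """Fit (if ``models`` is None) and apply the filter-bank CSP features.

    Returns the (n_windows, 4 * n_bands) feature block and the fitted
    per-band models.
    """
    bands = bands if bands is not None else default_filter_bank()
    feats, fitted = [], []
    for i, (lo, hi) in enumerate(bands):
        xb = bandpass_filter(x, fs, lo, hi, order=4)
        model = models[i] if models is not None else _BandCSP(4, shrinkage).fit(xb, y)
        fitted.append(model)
        feats.append(model.transform(xb))
    return np.concatenate(feats, axis=1), fitted


# ---------------------------------------------------------------------------
# Wavelet-packet energies

def wpd_leaf_bands(fs: float, level: int = 5) -> list[tuple[float, float]]:
    """Frequency extents of the frequency-ordered level-``level`` leaves."""
    width = fs / 2 / 2 ** level
    return [(i * width, (i + 1) * width) for i in range(2 ** level)]


def wpd_energy(window: np.ndarray, wavelet: str = "db4", level: int = 5,
               leaves: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
               all_leaves: bool = False) -> np.ndarray:
    """Per-leaf coefficient energies of a 5-level wavelet-packet decomposition.

    ``window`` is 1-D (single channel) or 2-D (channels, samples); output has
    one row per channel and one column per selected leaf (frequency order).
    Periodized boundary handling keeps the decomposition orthonormal so leaf
    energies sum to the time-domain energy.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n = window.shape[-1]
    if n < 2 ** level:
        raise ValueError("window shorter than decomposition support")
    # zero-pad to a multiple of 2^level so the periodized transform stays
    # orthonormal and leaf energies sum to the time-domain energy
    rem = (-n) % 2 ** level
    if rem:
        window = np.pad(window, ((0, 0), (0, rem)))
    sel = range(2 ** level) if all_leaves else leaves
    out = np.empty((window.shape[0], len(list(sel))))
    for ch, sig in enumerate(window):
        wp = pywt.WaveletPacket(sig, wavelet=wavelet, mode="periodization",
                                maxlevel=level)
        nodes = wp.get_level(level, order="freq")
        for j, leaf in enumerate(sel):
            out[ch, j] = float(np.sum(nodes[leaf].data ** 2))
    return out


# ---------------------------------------------------------------------------
# Nonlinear features

def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) with Chebyshev matching, self-matches excluded.

    ``B`` counts template pairs matching at length ``m`` (distance <= r),
    ``A`` at length ``m + 1``.  ``r`` defaults to ``0.2 * std(x)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    emb = sliding_window_view(x, m + 1)           # (n - m, m + 1)
    q = emb.shape[0]
    # Chebyshev distances accumulated one embedding dimension at a time
    d = np.abs(emb[:, None, 0] - emb[None, :, 0])
    for j in range(1, m):
        np.maximum(d, np.abs(emb[:, None, j] - emb[None, :, j]), out=d)
    iu = np.triu_indices(q, k=1)
    b = int(np.count_nonzero(d[iu] <= r))
    np.maximum(d, np.abs(emb[:, None, m] - emb[None, :, m]), out=d)
    a = int(np.count_nonzero(d[iu] <= r))
    if b == 0:
        warnings.warn("no length-m template matches; SampEn undefined, "
                      "returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    if a == 0:
        cap = float(np.log((n - m) * (n - m - 1)))
        warnings.warn("no length-(m+1) matches; SampEn capped", RuntimeWarning,
                      stacklevel=2)
        return cap
    return float(-np.log(a / b))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Shannon entropy (bits) of the normalized periodogram power."""
    x = np.asarray(x, dtype=float).ravel()
    if not np.any(x):
        raise ValueError("spectral entropy undefined for the zero signal")
    _, pxx = periodogram(x, fs=fs)
    total = pxx.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum")
    p = pxx / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def fractal_dimension(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension: slope of log L(k) against log(1/k).

    ``L(k)`` is the mean normalized curve length over the ``k`` decimated
    sub-series at step ``k``; a smooth line gives ~1, white noise ~2.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if n <= k_max:
        raise ValueError("series shorter than k_max")
    if np.ptp(x) == 0:
        raise ValueError("fractal dimension undefined for a constant signal")
    log_l, log_inv_k = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for s in range(k):
            idx = np.arange(s, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        log_l.append(np.log(np.mean(lengths)))
        log_inv_k.append(np.log(1.0 / k))
    slope = np.polyfit(log_inv_k, log_l, 1)[0]
    return float(slope)


def nonlinear_features(x: np.ndarray, fs: float, m: int = 2,
                       r_factor: float = 0.2, k_max: int = 8) -> np.ndarray:
    """[SampEn | SpecEn | FD] per channel for one (channels, samples) window."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nch = x.shape[0]
    out = np.empty(3 * nch)
    for c in range(nch):
        sig = x[c]
        out[c] = sample_entropy(sig, m=m, r=r_factor * float(np.std(sig)))
        out[nch + c] = spectral_entropy(sig, fs)
        out[2 * nch + c] = fractal_dimension(sig, k_max=k_max)
    return out


# ---------------------------------------------------------------------------
# Assembly

class EEGFeatureExtractor(BaseEstimator, TransformerMixin):
    """Fused FBCSP + WPD-energy + nonlinear features with PCA and z-scoring.

    Operates on band-filtered (8-32 Hz) windows shaped
    ``(n_windows, n_channels, n_samples)``.  ``fit`` learns the per-band CSP
    filters from the labelled training windows, then the PCA basis and the
    per-component standardization on the concatenated 44 + 6*ch + 3*ch block
    matrix; ``transform`` reuses that fitted state.

    Parameters
    ----------
    fs : float
        Sampling rate of the windows (Hz).
    bands : list of (lo, hi) or None
        Filter bank; None selects the default 11 bands.
    pca_variance : float or int, default=0.95
        Retained PCA variance fraction (or an explicit component count).
    """

    def __init__(self, fs: float = 250.0, bands=None, shrinkage: float = 0.05,
                 wavelet: str = "db4", wpd_level: int = 5,
                 wpd_leaves: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
                 sampen_m: int = 2, sampen_r_factor: float = 0.2,
                 fd_kmax: int = 8, pca_variance=0.95):
        self.fs = fs
        self.bands = bands
        self.shrinkage = shrinkage
        self.wavelet = wavelet
        self.wpd_level = wpd_level
        self.wpd_leaves = wpd_leaves
        self.sampen_m = sampen_m
        self.sampen_r_factor = sampen_r_factor
        self.fd_kmax = fd_kmax
        self.pca_variance = pca_variance

    def _blocks(self, x: np.ndarray, y=None, fit: bool = False) -> np.ndarray:
        bands = self.bands if self.bands is not None else default_filter_bank()
        if fit:
            f_csp, self.csp_models_ = fbcsp_features(
                x, y, self.fs, bands, self.shrinkage)
        else:
            f_csp, _ = fbcsp_features(x, None, self.fs, bands,
                                      self.shrinkage, models=self.csp_models_)
        f_wpd = np.stack([wpd_energy(w, self.wavelet, self.wpd_level,
                                     self.wpd_leaves).ravel() for w in x])
        f_nl = np.stack([nonlinear_features(w, self.fs, self.sampen_m,
                                            self.sampen_r_factor, self.fd_kmax)
                         for w in x])
        if fit:
            widths = [f_csp.shape[1], f_wpd.shape[1], f_nl.shape[1]]
            edges = np.cumsum([0] + widths)
            self.block_slices_ = {
                "fbcsp": slice(edges[0], edges[1]),
                "wpd": slice(edges[1], edges[2]),
                "nonlinear": slice(edges[2], edges[3]),
            }
        return np.concatenate([f_csp, f_wpd, f_nl], axis=1)

    @staticmethod
    def _unpack(X):
        if isinstance(X, EpochSet):
            return X.data, X.labels
        return np.asarray(X, dtype=float), None

    def fit(self, X, y=None) -> "EEGFeatureExtractor":
        x, labels = self._unpack(X)
        if y is not None:
            labels = np.asarray(y, int)
        if labels is None:
            raise ValueError("fit requires labels (CSP is supervised)")
        raw = self._blocks(x, labels, fit=True)
        self.n_raw_features_ = raw.shape[1]
        self.pca_ = PCA(n_components=self.pca_variance,
                        svd_solver="full").fit(raw)
        self.scaler_ = StandardScaler().fit(self.pca_.transform(raw))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        x, _ = self._unpack(X)
        raw = self._blocks(x)
        if raw.shape[1] != self.n_raw_features_:
            raise ValueError("feature width mismatch with fitted state")
        return self.scaler_.transform(self.pca_.transform(raw))

    def raw_blocks(self, X) -> np.ndarray:
        """Concatenated un-compressed feature matrix (training-time layout)."""
        check_is_fitted(self, "csp_models_")
        x, _ = self._unpack(X)
        return self._blocks(x)
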
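"""Morlet-wavelet spectral metrics on a base-2 logarithmic frequency grid.

A family of complex Morlet kernels is placed at frequencies
``f_k = f_min * 2**(k * sampling_oct)`` so that both the spacing between
wavelets and their spectral smoothing grow log-linearly with frequency.  The
Gaussian envelope of each kernel is chosen so the *half-power* edges of its
spectrum (|H|^2 = 1/2) sit at ``f * 2**(+-bandwidth_oct/2)``::

    sigma_f = f * (2**(b/2) - 2**(-b/2)) / (2 * sqrt(ln 2)),   sigma_t = 1/(2 pi sigma_f)

Kernels are truncated at +-5 sigma_t and normalised to unit spectral gain at
their centre frequency.  Samples within the truncation halfwidth of an epoch
edge are invalid and excluded from every downstream average; a frequency
whose halfwidth exceeds half the epoch length has no valid samples and is
flagged unusable.

From the complex coefficients four metrics are computed on a common
representation: power spectral density (units^2/Hz, via the kernel's
noise-equivalent bandwidth), the sensor covariance (real part of the average
outer product -- its diagonal is the unscaled power), the debiased squared
weighted phase-lag index (dwPLI), and the power-envelope correlation (Pearson
correlation of log-rectified coefficients).  Observations are pooled over all
valid samples of all epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal as sps


class WaveletError(ValueError):
    pass


@dataclass
class WaveletFamily:
    foi: np.ndarray                # centre frequencies, Hz
    f_min: float
    f_max: float
    bandwidth_oct: float
    sampling_oct: float
    fs: float
    kernels: list                  # per-frequency complex arrays (odd length)
    valid_halfwidth: np.ndarray    # per-frequency samples to discard per edge
    sigma_f: np.ndarray            # Hz

    @property
    def n_freqs(self) -> int:
        return len(self.foi)

    @property
    def noise_equivalent_bandwidth(self) -> np.ndarray:
        """integral of |H|^2 over Hz for a unit-peak Gaussian spectrum."""
        return self.sigma_f * np.sqrt(np.pi)


def build_wavelet_family(f_min: float = 1.0, f_max: float = 64.0,
                         bandwidth_oct: float = 0.35,
                         sampling_oct: float = 0.05,
                         fs: float = 250.0) -> WaveletFamily:
    """Build the log2-spaced Morlet family (121 wavelets at the defaults)."""
    if not (0 < f_min < f_max):
        raise WaveletError("need 0 < f_min < f_max")
    if f_max > fs / 2:
        raise WaveletError("f_max above Nyquist (aliasing)")
    if bandwidth_oct <= 0 or sampling_oct <= 0:
        raise WaveletError("bandwidth_oct and sampling_oct must be positive")
    n = int(round(np.log2(f_max / f_min) / sampling_oct)) + 1
    foi = f_min * 2.0 ** (np.arange(n) * sampling_oct)
    sigma_f = foi * (2 ** (bandwidth_oct / 2) - 2 ** (-bandwidth_oct / 2)) \
        / (2 * np.sqrt(np.log(2)))
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    kernels, halfw = [], []
    for f, st in zip(foi, sigma_t):
        h = int(np.ceil(5 * st * fs))
        t = np.arange(-h, h + 1) / fs
        env = np.exp(-t ** 2 / (2 * st ** 2))
        k = env * np.exp(2j * np.pi * f * t)
        k /= env.sum()             # unit spectral gain at the centre frequency
        kernels.append(k)
        halfw.append(h)
    return WaveletFamily(foi, f_min, f_max, bandwidth_oct, sampling_oct, fs,
                         kernels, np.asarray(halfw), sigma_f)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def convolve_frequency(signals: np.ndarray, family: WaveletFamily, fi: int):
    """Coefficients and validity for one frequency.

    Returns ``(coeffs (..., n_samples) complex, valid (n_samples,) bool)``;
    ``valid`` is all-False when the truncation halfwidth leaves no samples.
    """
    n = signals.shape[-1]
    h = int(family.valid_halfwidth[fi])
    kern = family.kernels[fi]
    coeffs = sps.fftconvolve(signals.astype(float),
                             kern[(None,) * (signals.ndim - 1)], mode="same",
                             axes=-1)
    valid = np.zeros(n, bool)
    if 2 * h < n:
        valid[h:n - h] = True
    return coeffs, valid


def convolve_epochs(signals: np.ndarray, family: WaveletFamily):
    """Full wavelet transform: ``signals`` (epochs, sensors, samples) ->
    ``(coeffs (epochs, sensors, n_freqs, samples), valid (n_freqs, samples))``.

    Materialises the whole coefficient array; for large cohorts use
    :func:`compute_spectral_tensors`, which streams frequency by frequency.
    """
    e, s, n = signals.shape
    coeffs = np.empty((e, s, family.n_freqs, n), complex)
    valid = np.zeros((family.n_freqs, n), bool)
    for fi in range(family.n_freqs):
        c, v = convolve_frequency(signals, family, fi)
        coeffs[:, :, fi, :] = c
        valid[fi] = v
    if not valid.any():
        raise WaveletError("all frequencies unusable for this epoch length")
    return coeffs, valid


def usable_frequencies(family: WaveletFamily, n_samples: int) -> np.ndarray:
    return 2 * family.valid_halfwidth < n_samples


# ---------------------------------------------------------------------------
# Metrics (single-frequency kernels operating on pooled valid samples)
# ---------------------------------------------------------------------------

def _pool(coeffs, valid):
    """(epochs, sensors, samples) complex + valid mask -> (sensors, n_obs)."""
    x = coeffs[:, :, valid]                     # (E, S, T)
    return np.moveaxis(x, 1, 0).reshape(x.shape[1], -1)


def power_from_coeffs(coeffs, valid, nebw):
    """PSD per sensor at one frequency, units^2/Hz (one-sided)."""
    if not valid.any():
        return np.full(coeffs.shape[1], np.nan)
    x = _pool(coeffs, valid)
    return 2.0 * (np.abs(x) ** 2).mean(1) / nebw


def covariance_from_coeffs(coeffs, valid):
    if valid.sum() * coeffs.shape[0] < 2:
        raise WaveletError("need >= 2 valid samples for covariance")
    x = _pool(coeffs, valid)
    c = (x @ x.conj().T).real / x.shape[1]
    return 0.5 * (c + c.T)


def dwpli_from_coeffs(coeffs, valid, chunk=512):
    """Debiased squared weighted phase-lag index.

    With ``I_t = Im(x_i(t) conj(x_j(t)))`` over the pooled valid samples:
    ``dwpli = ((sum I)^2 - sum I^2) / ((sum |I|)^2 - sum I^2)``; a zero
    denominator (e.g. identical signals) yields NaN.  The diagonal is NaN.
    """
    if valid.sum() * coeffs.shape[0] < 2:
        raise WaveletError("need >= 2 valid samples for dwPLI")
    x = _pool(coeffs, valid)
    s, t = x.shape
    sum_i = (x @ x.conj().T).imag
    sum_i2 = np.zeros((s, s))
    sum_absi = np.zeros((s, s))
    absx = np.abs(x)
    amp = absx @ absx.T                   # amplitude scale of cross-spectra
    for a in range(0, t, chunk):
        xc = x[:, a:a + chunk]
        im = (xc[:, None, :] * xc.conj()[None, :, :]).imag
        sum_i2 += (im ** 2).sum(-1)
        sum_absi += np.abs(im).sum(-1)
    num = sum_i ** 2 - sum_i2
    den = sum_absi ** 2 - sum_i2
    # zero imaginary cross-spectrum (up to rounding) -> undefined, missing
    degenerate = (den <= 0) | (sum_absi <= 1e-10 * amp)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(degenerate, np.nan, num / np.where(den > 0, den, 1.0))
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, np.nan)
    return out


def env_corr_from_coeffs(coeffs, valid):
    """Pearson correlation of log power envelopes (log |coeff| with a tiny
    floor); unit diagonal; NaN where an envelope is constant."""
    if valid.sum() * coeffs.shape[0] < 3:
        raise WaveletError("need >= 3 valid samples for envelope correlation")
    x = np.abs(_pool(coeffs, valid))
    eps = 1e-12 * max(np.median(x), 1e-300)
    env = np.log(x + eps)
    env = env - env.mean(1, keepdims=True)
    sd = env.std(1)
    cov = env @ env.T / env.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0, out=corr)


def node_strength(matrix: np.ndarray):
    """Mean of off-diagonal entries per row (missing entries excluded);
    accepts a single (S, S) matrix or a stack (..., S, S).  The per-frequency
    grand average is the mean of the returned strengths over sensors."""
    m = np.array(matrix, float, copy=True)
    s = m.shape[-1]
    ii = np.arange(s)
    m[..., ii, ii] = np.nan
    return np.nanmean(m, axis=-1)


# ---------------------------------------------------------------------------
# Per-subject driver
# ---------------------------------------------------------------------------

@dataclass
class SpectralTensors:
    """Per-subject frequency-resolved spectral metrics."""

    foi: np.ndarray
    sensor_ids: list
    psd: np.ndarray | None = None        # (S, F) units^2/Hz
    log_psd: np.ndarray | None = None    # log10(psd)
    cov: np.ndarray | None = None        # (F, S, S)
    dwpli: np.ndarray | None = None      # (F, S, S), NaN diagonal
    env_corr: np.ndarray | None = None   # (F, S, S), unit diagonal
    n_obs: np.ndarray | None = None      # (F,) pooled valid sample count


ALL_METRICS = ("power", "cov", "dwpli", "env")


def compute_spectral_tensors(signals: np.ndarray, family: WaveletFamily,
                             metrics=ALL_METRICS,
                             sensor_ids=None) -> SpectralTensors:
    """Compute the requested metrics for one subject, streaming one frequency
    at a time to bound memory."""
    e, s, n = signals.shape
    usable = usable_frequencies(family, n)
    if not usable.any():
        raise WaveletError("all frequencies unusable for this epoch length")
    nf = family.n_freqs
    out = SpectralTensors(foi=family.foi.copy(),
                          sensor_ids=(list(sensor_ids) if sensor_ids is not None
                                      else [f"MEG{i:03d}" for i in range(s)]),
                          n_obs=np.zeros(nf, int))
    if "power" in metrics:
        out.psd = np.full((s, nf), np.nan)
    if "cov" in metrics:
        out.cov = np.full((nf, s, s), np.nan)
    if "dwpli" in metrics:
        out.dwpli = np.full((nf, s, s), np.nan)
    if "env" in metrics:
        out.env_corr = np.full((nf, s, s), np.nan)
    nebw = family.noise_equivalent_bandwidth
    for fi in range(nf):
        if not usable[fi]:
            continue
        coeffs, valid = convolve_frequency(signals, family, fi)
        out.n_obs[fi] = int(valid.sum()) * e
        if "power" in metrics:
            out.psd[:, fi] = power_from_coeffs(coeffs, valid, nebw[fi])
        if "cov" in metrics:
            out.cov[fi] = covariance_from_coeffs(coeffs, valid)
        if "dwpli" in metrics:
            out.dwpli[fi] = dwpli_from_coeffs(coeffs, valid)
        if "env" in metrics:
            out.env_corr[fi] = env_corr_from_coeffs(coeffs, valid)
    if out.psd is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            out.log_psd = np.log10(out.psd)
    return out


def cohort_log_power(cohort, family):
    """Stacked log10 PSD (n_subjects, S, F) for a cohort, batching the
    convolution over subjects (power only; much faster than per-subject
    tensor computation for simulation studies)."""
    from scipy import fft as sfft

    signals = np.stack([s.signals for s in cohort])        # (n, E, S, N)
    n, e, s, nsamp = signals.shape
    usable = usable_frequencies(family, nsamp)
    if not usable.any():
        raise WaveletError("all frequencies unusable for this epoch length")
    psd = np.full((n, s, family.n_freqs), np.nan)
    nebw = family.noise_equivalent_bandwidth
    kmax = max(len(family.kernels[fi]) for fi in range(family.n_freqs)
               if usable[fi])
    fftlen = sfft.next_fast_len(nsamp + kmax - 1)
    sig_f = sfft.fft(signals, fftlen, axis=-1)             # shared forward FFT
    for fi in range(family.n_freqs):
        if not usable[fi]:
            continue
        h = int(family.valid_halfwidth[fi])
        kern_f = sfft.fft(family.kernels[fi], fftlen)
        full = sfft.ifft(sig_f * kern_f, axis=-1)
        coeffs = full[..., h:h + nsamp]                    # 'same' alignment
        pw = (np.abs(coeffs[..., h:nsamp - h]) ** 2).mean(-1).mean(1)
        psd[:, :, fi] = 2.0 * pw / nebw[fi]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log10(psd)


def cohort_spectral_tensors(cohort, family, metrics=ALL_METRICS, sensor_ids=None):
    """List of :class:`SpectralTensors`, one per subject with signals."""
    return [compute_spectral_tensors(s.signals, family, metrics, sensor_ids)
            for s in cohort if s.signals is not None]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_tensors_h5(path, tensors: dict, foi, sensor_ids):
    """``tensors``: subject_id -> SpectralTensors."""
    with h5py.File(path, "w") as fh:
        fh.attrs["foi"] = np.asarray(foi)
        fh.attrs["sensor_ids"] = [str(s) for s in sensor_ids]
        for sid, t in tensors.items():
            g = fh.create_group(sid)
            for name in ("psd", "log_psd", "cov", "dwpli", "env_corr", "n_obs"):
                arr = getattr(t, name)
                if arr is not None:
                    g.create_dataset(name, data=arr)


def read_tensors_h5(path):
    out = {}
    with h5py.File(path, "r") as fh:
        foi = fh.attrs["foi"]
        sensor_ids = [s for s in fh.attrs["sensor_ids"]]
        for sid in fh:
            g = fh[sid]
            t = SpectralTensors(foi=np.asarray(foi), sensor_ids=sensor_ids)
            for name in ("psd", "log_psd", "cov", "dwpli", "env_corr", "n_obs"):
                if name in g:
                    setattr(t, name, g[name][()])
            out[sid] = t
    return out, np.asarray(foi), sensor_ids
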
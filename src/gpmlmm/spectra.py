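"""IR and power spectra from trajectory time series.

The IR spectrum is the cosine transform of the autocorrelation of the
dipole time-derivative,

    IR(w) ~ (2 pi beta / 3 c V) * integral <mu'(0) mu'(t)> W(t) cos(w t) dt,

with a Gaussian apodization window W(t) = exp(-t^2 / 2 sigma^2)
(default sigma = 1 ps) suppressing finite-trajectory border effects.
The printed prefactor is taken to embody the harmonic quantum correction
of the underlying line-shape theory; no extra frequency-dependent factor
is applied.  Spectra are max-normalized by default; peak positions are
unaffected by either choice.

The same transform applied to the mass-weighted velocity autocorrelation,
without the thermal prefactor, yields the vibrational power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import C_CM_PER_FS, KB_KCALMOL

__all__ = [
    "Spectrum",
    "dipole_time_derivative",
    "autocorrelation",
    "ir_spectrum",
    "power_spectrum",
]


@dataclass(frozen=True)
class Spectrum:
    """Wavenumber grid (cm^-1, strictly increasing) and intensities;
    normalized intensities lie in [0, 1]."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def peak_wavenumber(self, lo: float = 0.0, hi: float | None = None) -> float:
        """Wavenumber of the highest intensity within [lo, hi]."""
        w, s = self.wavenumbers, self.intensities
        mask = w >= lo
        if hi is not None:
            mask &= w <= hi
        idx = np.flatnonzero(mask)
        return float(w[idx[np.argmax(s[idx])]])


def dipole_time_derivative(dipoles: np.ndarray, dt: float) -> np.ndarray:
    """Time derivative of an evenly spaced dipole series (a.u./fs).

    Central differences in the interior, one-sided at the ends.
    """
    mu = np.asarray(dipoles, dtype=float)
    if mu.ndim == 1:
        mu = mu[:, None]
    if mu.shape[0] < 3:
        raise ValueError("need at least 3 frames for a derivative")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = np.empty_like(mu)
    out[1:-1] = (mu[2:] - mu[:-2]) / (2.0 * dt)
    out[0] = (mu[1] - mu[0]) / dt
    out[-1] = (mu[-1] - mu[-2]) / dt
    return out


def autocorrelation(signal: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Vector autocorrelation summed over Cartesian components.

    Biased (1/N) normalization: acf[l] = (1/N) sum_t s(t).s(t+l), computed
    with a zero-padded FFT; acf[0] is the mean squared signal.
    """
    s = np.asarray(signal, dtype=float)
    if s.size == 0:
        raise ValueError("empty signal")
    if s.ndim == 1:
        s = s[:, None]
    n = s.shape[0]
    max_lag = n if max_lag is None else min(max_lag, n)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fs = np.fft.rfft(s, n=nfft, axis=0)
    acf = np.fft.irfft((fs * fs.conj()).real, n=nfft, axis=0)[:max_lag]
    return acf.sum(axis=1) / n


def _cosine_transform(
    acf: np.ndarray, dt: float, window_sigma_fs: float, pad_factor: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided cosine transform of the Gaussian-windowed, even-extended
    acf; returns (wavenumbers cm^-1, spectral density per fs)."""
    n = len(acf)
    t = np.arange(n) * dt
    w = acf * np.exp(-0.5 * (t / window_sigma_fs) ** 2)
    nfft = 1 << int(np.ceil(np.log2(max(pad_factor * n, 2))))
    ext = np.zeros(2 * nfft)
    ext[:n] = w
    ext[-(n - 1):] = w[1:][::-1]
    spec = np.fft.rfft(ext).real * dt
    freq = np.fft.rfftfreq(2 * nfft, d=dt)  # 1/fs
    return freq / C_CM_PER_FS, spec


def ir_spectrum(
    trajectory,
    temperature: float = 300.0,
    volume: float = 1.0,
    window_sigma: float = 1000.0,
    normalize: bool = True,
    pad_factor: int = 4,
) -> Spectrum:
    """IR spectrum from a trajectory's dipole series (or from any object
    with ``dipoles`` (F, 3) and ``dipole_times``/``times`` in fs).

    ``window_sigma`` is the Gaussian apodization width in fs (default
    1 ps).  ``volume`` enters only the absolute prefactor 2 pi beta/(3 c V).
    """
    mu = np.asarray(trajectory.dipoles, dtype=float)
    times = np.asarray(
        getattr(trajectory, "dipole_times", getattr(trajectory, "times", None))
    )
    if mu.shape[0] < 3:
        raise ValueError("trajectory has fewer than 3 dipole frames")
    dts = np.diff(times)
    dt = float(dts[0])
    if not np.allclose(dts, dt, rtol=1e-8, atol=1e-10):
        raise ValueError("dipole frames are not evenly spaced")
    meta = {
        "window_sigma_fs": window_sigma,
        "temperature_K": temperature,
        "volume": volume,
        "timestep_fs": dt,
    }
    if times[-1] - times[0] < 3.0 * window_sigma:
        meta["warning"] = (
            "trajectory shorter than ~3 window sigmas; line shapes are "
            "resolution-limited"
        )
    mudot = dipole_time_derivative(mu, dt)
    acf = autocorrelation(mudot)
    wn, spec = _cosine_transform(acf, dt, window_sigma, pad_factor)
    beta = 1.0 / (KB_KCALMOL * temperature)
    spec = spec * (2.0 * np.pi * beta / (3.0 * C_CM_PER_FS * volume))
    if normalize:
        peak = np.abs(spec).max()
        if peak > 0:
            spec = spec / peak
    return Spectrum(wn, spec, meta)


def power_spectrum(
    velocities: np.ndarray,
    masses: np.ndarray,
    dt: float,
    window_sigma: float = 1000.0,
    normalize: bool = True,
    pad_factor: int = 4,
) -> Spectrum:
    """Vibrational power spectrum of mass-weighted velocities.

    ``velocities``: (F, N, 3) in Angstrom/fs; the transform and window are
    identical to the IR pipeline but no thermal prefactor is applied.
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    masses = np.asarray(masses, dtype=float)
    s = (np.sqrt(masses)[None, :, None] * v).reshape(v.shape[0], -1)
    if np.allclose(s, 0.0):
        acf = np.zeros(v.shape[0])
    else:
        acf = autocorrelation(s)
    wn, spec = _cosine_transform(acf, dt, window_sigma, pad_factor)
    if normalize:
        peak = np.abs(spec).max()
        if peak > 0:
            spec = spec / peak
    return Spectrum(
        wn, spec, {"window_sigma_fs": window_sigma, "timestep_fs": dt}
    )
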
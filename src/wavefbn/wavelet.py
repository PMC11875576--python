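"""Unit-rate resampling and FFT-domain Morlet continuous wavelet transform.

The analysis convention used throughout the package: an ROI series recorded
with sampling interval ``tr`` seconds is rewritten on a unit-rate axis where
the nominal sampling interval is 1 s.  On that axis a physical component at
``f`` Hz appears at ``f * tr`` cycles/sample, so a physical band of interest
``[g0, g1]`` Hz is analysed with wavelet frequencies ``[g0 * tr, g1 * tr]``
(for TR = 3 s the canonical resting-state band 0.01-0.08 Hz becomes
0.03-0.24 Hz).  See :func:`map_physical_band` and
:func:`resample_to_unit_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AliasingError, InvalidArgumentError, TooShortSignalError
from .timeseries import MIN_TIMEPOINTS, RoiTimeSeries

__all__ = [
    "WaveletConfig",
    "WaveletDecomposition",
    "band_frequencies",
    "map_physical_band",
    "resample_to_unit_rate",
    "fcwt_decompose",
    "morlet_scale",
]


@dataclass
class WaveletConfig:
    """Parameters of the continuous wavelet analysis.

    fs is the (integer) sampling frequency after resampling -- always 1 for
    this pipeline; f0/f1 bound the analysed band in cycles/sample; fn is the
    number of analysis bands; morlet_omega0 the dimensionless centre
    frequency of the analytic Morlet mother wavelet.
    """

    fs: int = 1
    f0: float = 0.03
    f1: float = 0.24
    fn: int = 10
    spacing: str = "linear"  # or "logarithmic"
    morlet_omega0: float = 6.0

    def __post_init__(self) -> None:
        if int(self.fs) != self.fs or self.fs <= 0:
            raise InvalidArgumentError(f"fs must be a positive integer, got {self.fs}")
        self.fs = int(self.fs)
        if not (0 < self.f0 < self.f1):
            raise InvalidArgumentError(f"need 0 < f0 < f1, got f0={self.f0}, f1={self.f1}")
        if self.f1 > self.fs / 2:
            raise AliasingError(f"f1={self.f1} exceeds the Nyquist frequency {self.fs / 2}")
        if self.fn < 1:
            raise InvalidArgumentError(f"fn must be >= 1, got {self.fn}")
        if self.spacing not in ("linear", "logarithmic"):
            raise InvalidArgumentError(f"unknown spacing {self.spacing!r}")
        if self.morlet_omega0 < 5:
            raise InvalidArgumentError("morlet_omega0 must be >= 5 for practical admissibility")


@dataclass
class WaveletDecomposition:
    """Complex wavelet coefficients, shape (n ROIs, fn bands, m' time points)."""

    coeffs: np.ndarray
    band_freqs: np.ndarray
    config: WaveletConfig
    subject_id: str = ""
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_bands(self) -> int:
        return self.coeffs.shape[1]


def band_frequencies(cfg: WaveletConfig) -> np.ndarray:
    """Centre frequencies of the fn analysis bands, in cycles/sample.

    Linear spacing from f0 to f1 inclusive by default; geometric
    progression when ``spacing == "logarithmic"``.  With fn = 1 the single
    band sits at f0.
    """
    if cfg.fn == 1:
        return np.array([cfg.f0])
    if cfg.spacing == "linear":
        return np.linspace(cfg.f0, cfg.f1, cfg.fn)
    return np.geomspace(cfg.f0, cfg.f1, cfg.fn)


def map_physical_band(g0: float, g1: float, tr: float) -> tuple[float, float]:
    """Map a physical frequency band in Hz to the unit-rate analysis axis.

    Relabelling the sampling interval from ``tr`` seconds to 1 s multiplies
    every physical frequency by ``tr``: (g0, g1) Hz -> (g0*tr, g1*tr)
    cycles/sample.
    """
    if tr <= 0:
        raise InvalidArgumentError(f"tr must be positive, got {tr}")
    if not (0 < g0 < g1):
        raise InvalidArgumentError("need 0 < g0 < g1")
    return g0 * tr, g1 * tr


def resample_to_unit_rate(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Rewrite a series on the unit-rate axis, extending to round(m*tr) samples.

    The sampling interval is relabelled to 1 s, which moves a physical
    component at ``f`` Hz to ``f * tr`` cycles/sample, and the series is
    extended periodically from ``m`` to ``m' = round(m * tr)`` samples so the
    per-sample frequency content is preserved.  A linear trend is removed
    before the extension (suppressing the seam discontinuity a trend would
    cause) and the mean is restored afterwards.  With tr = 1 the output
    equals the input.
    """
    if ts.tr <= 0:
        raise InvalidArgumentError(f"tr must be positive, got {ts.tr}")
    m = ts.n_timepoints
    m_new = int(round(m * ts.tr))
    if m_new < MIN_TIMEPOINTS:
        raise TooShortSignalError(f"resampled length {m_new} < {MIN_TIMEPOINTS}")
    if m_new == m:
        return RoiTimeSeries(ts.subject_id, ts.data.copy(), 1.0, list(ts.roi_labels))

    t = np.arange(m)
    data = ts.data
    mean = data.mean(axis=0)
    # least-squares linear detrend per ROI
    tc = t - t.mean()
    slope = (tc @ (data - mean)) / (tc @ tc)
    detrended = data - mean - np.outer(tc, slope)
    idx = np.arange(m_new) % m
    out = detrended[idx] + mean
    return RoiTimeSeries(ts.subject_id, out, 1.0, list(ts.roi_labels))


def morlet_scale(freq: float, omega0: float) -> float:
    """Wavelet scale whose Fourier-space peak sits at ``freq`` cycles/sample."""
    return (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi * freq)


def _morlet_spectrum(omega: np.ndarray, scale: float, omega0: float) -> np.ndarray:
    """Spectrum of the dilated analytic Morlet wavelet on angular grid omega."""
    psi = np.zeros_like(omega)
    pos = omega > 0
    psi[pos] = (
        np.pi**-0.25
        * np.sqrt(2.0 * np.pi * scale)
        * np.exp(-0.5 * (scale * omega[pos] - omega0) ** 2)
    )
    return psi


def fcwt_decompose(ts: RoiTimeSeries, cfg: WaveletConfig | None = None) -> WaveletDecomposition:
    """Decompose each ROI signal into complex coefficients across fn bands.

    The transform is computed in the frequency domain: each coefficient row
    is the inverse FFT of the signal spectrum multiplied by the conjugated
    spectrum of the Morlet wavelet dilated to the band's centre frequency.
    The signal is reflect-padded to the next power of two before the FFT and
    the result truncated back, suppressing circular wrap-around artefacts.
    """
    cfg = cfg or WaveletConfig()
    if ts.tr != 1:
        raise InvalidArgumentError(
            f"fcwt_decompose expects a unit-rate series (tr=1), got tr={ts.tr}; "
            "call resample_to_unit_rate first"
        )
    freqs = band_frequencies(cfg)
    m, n = ts.data.shape
    nfft = 1 << int(np.ceil(np.log2(2 * m)))
    # reflect-pad: signal followed by its reversal, cycled to nfft samples
    padded = np.concatenate([ts.data, ts.data[::-1]], axis=0)
    reps = int(np.ceil(nfft / padded.shape[0]))
    padded = np.tile(padded, (reps, 1))[:nfft]
    spectrum = np.fft.fft(padded, axis=0)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0)

    coeffs = np.empty((n, cfg.fn, m), dtype=complex)
    for k, f in enumerate(freqs):
        psi = _morlet_spectrum(omega, morlet_scale(f, cfg.morlet_omega0), cfg.morlet_omega0)
        coeffs[:, k, :] = np.fft.ifft(spectrum * np.conj(psi)[:, None], axis=0)[:m].T
    return WaveletDecomposition(coeffs, freqs, cfg, ts.subject_id, list(ts.roi_labels))
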
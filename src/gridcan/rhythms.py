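"""Population-rate spectra and spike-phase coupling.

The population rate is the combined spike count in 1-ms bins.  Spectra
use the multitaper method (DPSS tapers, time-bandwidth 3, 5 tapers, 10-s
segments averaged) after smoothing the rate with a 3-ms Gaussian window
and removing the mean; power is analyzed over 1-100 Hz with the band
split delta 1-4, theta 4-12, beta 12-25, gamma 25-100 Hz.  Phase
coupling band-passes the reference rate around its in-band spectral
peak (4th-order zero-phase Butterworth), assigns each spike the analytic
phase at its time, and summarizes with the mean resultant vector length
(MRVL) and the Rayleigh test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import AnalysisError

__all__ = [
    "PopulationRate",
    "PowerSpectrum",
    "BandPower",
    "PhaseCoupling",
    "BANDS",
    "population_rate",
    "multitaper_psd",
    "band_fractions",
    "spike_phase_coupling",
    "rayleigh_p",
]

#: Closed-left / open-right frequency bands (Hz), exhaustive over 1-100.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "beta": (12.0, 25.0),
    "gamma": (25.0, 100.0),
}
FREQ_RANGE = (1.0, 100.0)


@dataclass
class PopulationRate:
    """Combined spikes per time bin for a group of populations."""

    counts: np.ndarray
    bin_ms: float
    t_start_ms: float
    populations: tuple[str, ...]

    @property
    def fs(self) -> float:
        return 1000.0 / self.bin_ms

    @property
    def duration_s(self) -> float:
        return self.counts.size * self.bin_ms / 1000.0


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray


@dataclass
class BandPower:
    fractions: dict[str, float]

    def ranked(self) -> list[str]:
        return sorted(self.fractions, key=self.fractions.get, reverse=True)

    def __getitem__(self, band: str) -> float:
        return self.fractions[band]


@dataclass
class PhaseCoupling:
    mrvl: float
    p_value: float
    n_spikes: int
    band: tuple[float, float]
    peak_freq: float


def population_rate(
    spike_times_ms: dict[str, np.ndarray],
    populations: list[str] | None = None,
    bin_ms: float = 1.0,
    t_start_ms: float = 0.0,
    t_stop_ms: float | None = None,
) -> PopulationRate:
    """Bin the combined spiking of the selected populations."""
    if populations is None:
        populations = list(spike_times_ms)
    times = [np.asarray(spike_times_ms[p], dtype=np.float64) for p in populations]
    merged = np.concatenate(times) if times else np.empty(0)
    if t_stop_ms is None:
        t_stop_ms = float(merged.max()) + bin_ms if merged.size else t_start_ms
    if t_stop_ms <= t_start_ms:
        raise AnalysisError("zero-length analysis window")
    n = int(np.ceil((t_stop_ms - t_start_ms) / bin_ms))
    sel = merged[(merged >= t_start_ms) & (merged < t_start_ms + n * bin_ms)]
    idx = ((sel - t_start_ms) / bin_ms).astype(np.int64)
    counts = np.bincount(idx, minlength=n)[:n]
    return PopulationRate(
        counts=counts, bin_ms=bin_ms, t_start_ms=t_start_ms,
        populations=tuple(populations),
    )


def _smoothed_centered(rate: PopulationRate, smooth_ms: float) -> np.ndarray:
    x = rate.counts.astype(np.float64)
    if smooth_ms > 0:
        x = ndimage.gaussian_filter1d(x, sigma=smooth_ms / rate.bin_ms)
    return x - x.mean()


def multitaper_psd(
    rate: PopulationRate,
    smooth_ms: float = 3.0,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
    segment_s: float = 10.0,
) -> PowerSpectrum:
    """Multitaper PSD of the (smoothed, demeaned) population rate.

    Series of at least ``segment_s`` are cut into non-overlapping
    segments whose taper periodograms are averaged; shorter series (but
    at least 2 s) use a single segment.
    """
    if rate.duration_s < 2.0:
        raise AnalysisError("need at least 2 s of population rate for a PSD")
    x = _smoothed_centered(rate, smooth_ms)
    fs = rate.fs
    seg_len = min(int(segment_s * fs), x.size)
    n_seg = max(1, x.size // seg_len)
    tapers = signal.windows.dpss(seg_len, time_bandwidth, Kmax=n_tapers)
    # Orthonormal tapers: periodogram normalization 1/fs per taper.
    psd = np.zeros(seg_len // 2 + 1)
    for k in range(n_seg):
        seg = x[k * seg_len : (k + 1) * seg_len]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd += np.mean(np.abs(spec) ** 2, axis=0) / fs
    psd /= n_seg
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=psd)


def band_fractions(psd: PowerSpectrum, bands: dict | None = None) -> BandPower:
    """Fraction of total 1-100 Hz power in each named band."""
    bands = bands or BANDS
    in_range = (psd.freqs >= FREQ_RANGE[0]) & (psd.freqs < FREQ_RANGE[1])
    total = psd.power[in_range].sum()
    if total <= 0:
        raise AnalysisError("no spectral power in 1-100 Hz")
    fractions = {}
    for name, (lo, hi) in bands.items():
        m = (psd.freqs >= lo) & (psd.freqs < hi)
        fractions[name] = float(psd.power[m & in_range].sum() / total)
    return BandPower(fractions=fractions)


def rayleigh_p(n: int, mrvl: float) -> float:
    """Rayleigh test for circular uniformity (Zar's approximation)."""
    Z = n * mrvl**2
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    return float(np.clip(p, 0.0, 1.0))


def spike_phase_coupling(
    spike_times_ms: np.ndarray,
    reference: PopulationRate,
    band: tuple[float, float] = BANDS["beta"],
    smooth_ms: float = 3.0,
    half_bandwidth: float = 4.0,
    min_spikes: int = 50,
) -> PhaseCoupling:
    """MRVL and Rayleigh significance of spike phases in a reference band.

    The reference rate is band-passed around its spectral peak within
    ``band`` (peak +/- ``half_bandwidth`` Hz, clipped to the band), the
    analytic phase is extracted, and each spike is assigned the phase of
    its 1-ms bin.
    """
    spikes = np.asarray(spike_times_ms, dtype=np.float64)
    t0 = reference.t_start_ms
    t1 = t0 + reference.counts.size * reference.bin_ms
    spikes = spikes[(spikes >= t0) & (spikes < t1)]
    if spikes.size < min_spikes:
        raise AnalysisError(
            f"need at least {min_spikes} spikes for phase coupling, got {spikes.size}"
        )
    psd = multitaper_psd(reference, smooth_ms=smooth_ms)
    in_band = (psd.freqs >= band[0]) & (psd.freqs < band[1])
    if not in_band.any():
        raise AnalysisError("reference PSD does not cover the requested band")
    peak_freq = float(psd.freqs[in_band][np.argmax(psd.power[in_band])])
    lo = max(band[0], peak_freq - half_bandwidth)
    hi = min(band[1], peak_freq + half_bandwidth)

    x = _smoothed_centered(reference, smooth_ms)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=reference.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    phase = np.angle(signal.hilbert(filtered))

    idx = np.minimum(((spikes - t0) / reference.bin_ms).astype(np.int64), phase.size - 1)
    phases = phase[idx]
    vec = np.exp(1j * phases).mean()
    mrvl = float(np.abs(vec))
    return PhaseCoupling(
        mrvl=mrvl,
        p_value=rayleigh_p(spikes.size, mrvl),
        n_spikes=int(spikes.size),
        band=(lo, hi),
        peak_freq=peak_freq,
    )
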
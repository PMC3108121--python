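"""Spectral tremor metrics.

The five classical accelerometric tremor parameters are computed from a
Welch power spectral density restricted to the 0.9–15 Hz band:

* **intensity** — RMS acceleration in the band, m/s²;
* **center frequency (Cf)** — power-weighted mean frequency;
* **frequency dispersion** — width of the narrowest window symmetric about
  the median frequency that contains 68% of band power (small = regular
  tremor);
* **energy distribution** — shares of band power in the 3–6.5 Hz and
  6.6–10 Hz sub-bands;
* **harmonic index (HI)** — concentration of band power within ±0.5 Hz of
  the modal (peak-density) frequency; 1.00 for a single harmonic
  oscillation, decreasing as the tremor is composed of many oscillations.

The Welch density is rescaled per axis so its full-range integral equals the
record's sample variance exactly (a normalized power distribution).  With a
tapered window the raw Welch integral underweights segment edges and can
drift several percent from the sample variance on short records; the
rescaling removes that bias from intensity and leaves every other metric
untouched, since they are ratios of spectral power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import welch

from .records import BAND, AccelRecord, UndefinedMetricError

_EPS = 1e-9


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimation settings.

    4-s Hann segments with 50% overlap give a 0.25 Hz grid on the default
    16-s records and average enough segments to stabilise Cf and dispersion.
    """

    segment_seconds: float = 4.0
    overlap: float = 0.5
    window: str = "hann"
    band: tuple[float, float] = BAND
    low_band: tuple[float, float] = (3.0, 6.5)
    high_band: tuple[float, float] = (6.5, 10.0)
    peak_halfwidth: float = 0.5

    def nperseg(self, sampling_rate: float) -> int:
        return int(round(self.segment_seconds * sampling_rate))


DEFAULT_CONFIG = SpectralConfig()


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with an analysis band attached.

    ``freqs``/``power`` cover the full 0..Nyquist grid (so Parseval checks
    can integrate the whole range); metric functions restrict themselves to
    ``band``.  Power is in (m/s²)²/Hz.
    """

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float] = BAND

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be matching 1-d arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def band_mask(self) -> np.ndarray:
        lo, hi = self.band
        return (self.freqs >= lo - _EPS) & (self.freqs <= hi + _EPS)

    @property
    def band_freqs(self) -> np.ndarray:
        return self.freqs[self.band_mask]

    @property
    def band_power(self) -> np.ndarray:
        return self.power[self.band_mask]

    def total_power(self) -> float:
        """Integral of the density over the full frequency range."""
        return float(np.sum(self.power) * self.df)

    def total_band_power(self) -> float:
        return float(np.sum(self.band_power) * self.df)


@dataclass(frozen=True)
class TremorMetrics:
    """The five spectral tremor parameters of one record."""

    intensity: float
    cf: float
    median_freq: float
    dispersion: float
    low_band_fraction: float
    high_band_fraction: float
    hi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "intensity": self.intensity,
            "cf": self.cf,
            "median_freq": self.median_freq,
            "dispersion": self.dispersion,
            "low_frac": self.low_band_fraction,
            "high_frac": self.high_band_fraction,
            "hi": self.hi,
        }


METRIC_NAMES = ("intensity", "cf", "median_freq", "dispersion", "low_frac", "high_frac", "hi")


def compute_power_spectrum(
    record: AccelRecord, config: SpectralConfig = DEFAULT_CONFIG
) -> PowerSpectrum:
    """Welch-averaged, Parseval-normalized PSD of a record.

    For two-axis records the per-axis normalized densities are averaged.
    Raises ``ValueError`` if the record is shorter than one Welch segment.
    """
    nper = config.nperseg(record.sampling_rate)
    if record.n_samples < nper:
        raise ValueError(
            f"record has {record.n_samples} samples but one Welch segment needs "
            f"{nper} ({config.segment_seconds} s at {record.sampling_rate} Hz); "
            "use a shorter segment or a longer recording"
        )
    noverlap = int(round(nper * config.overlap))
    densities = []
    freqs = None
    for k in range(record.n_axes):
        x = record.data[:, k]
        freqs, p = welch(
            x,
            fs=record.sampling_rate,
            window=config.window,
            nperseg=nper,
            noverlap=noverlap,
            detrend="constant",
            scaling="density",
        )
        raw = np.sum(p) * (freqs[1] - freqs[0])
        var = float(np.var(x))
        if raw > 0:
            p = p * (var / raw)
        densities.append(p)
    power = np.mean(densities, axis=0)
    return PowerSpectrum(freqs=freqs, power=power, band=config.band)


def _checked_band(spectrum: PowerSpectrum) -> tuple[np.ndarray, np.ndarray, float]:
    f = spectrum.band_freqs
    p = spectrum.band_power
    tot = float(np.sum(p))
    if f.size == 0 or tot <= 0 or not np.isfinite(tot):
        raise UndefinedMetricError("spectrum has no power in the analysis band")
    return f, p, tot


def tremor_intensity(spectrum: PowerSpectrum) -> float:
    """Band RMS acceleration, m/s²: sqrt of the band-integrated density."""
    return float(np.sqrt(np.sum(spectrum.band_power) * spectrum.df))


def center_frequency(spectrum: PowerSpectrum) -> float:
    """Power-weighted mean frequency over the band, Hz."""
    f, p, tot = _checked_band(spectrum)
    return float(np.sum(f * p) / tot)


def _crossing_50(f: np.ndarray, p: np.ndarray, tot: float) -> float:
    """Linear-interpolated frequency where cumulative power reaches 50%."""
    c = np.cumsum(p) / tot
    # nudge below 0.5 so a floating plateau at ~0.5 is entered, not skipped
    i = int(np.searchsorted(c, 0.5 - 1e-9))
    if i == 0:
        return float(f[0])
    i = min(i, f.size - 1)
    if c[i] <= c[i - 1]:
        return float(f[i])
    frac = (0.5 - c[i - 1]) / (c[i] - c[i - 1])
    frac = min(max(frac, 0.0), 1.0)
    return float(f[i - 1] + frac * (f[i] - f[i - 1]))


def median_frequency(spectrum: PowerSpectrum) -> float:
    """Frequency at which cumulative band power reaches 50%, Hz.

    Computed as the midpoint of the forward and backward 50% crossings of
    the interpolated cumulative sum, so that spectra whose mass splits
    evenly around a power gap (e.g. two equal lines) get the central
    frequency rather than an endpoint of the ambiguous 50% plateau.
    """
    f, p, tot = _checked_band(spectrum)
    lower = _crossing_50(f, p, tot)
    upper = -_crossing_50(-f[::-1], p[::-1], tot)
    return 0.5 * (lower + upper)


def frequency_dispersion(spectrum: PowerSpectrum) -> float:
    """Width (Hz) of the narrowest window symmetric about the median
    frequency containing at least 68% of band power.

    The window is grown symmetrically on the frequency grid: candidate
    half-widths are the distinct distances of grid points from the median.
    """
    f, p, tot = _checked_band(spectrum)
    med = median_frequency(spectrum)
    dists = np.abs(f - med)
    for w in np.sort(np.unique(dists)):
        if np.sum(p[dists <= w + _EPS]) >= 0.68 * tot:
            return float(2.0 * w)
    return float(2.0 * dists.max())  # pragma: no cover - 68% always reachable


def band_energy_fractions(
    spectrum: PowerSpectrum, config: SpectralConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """Shares of band power in the low (3–6.5 Hz) and high (6.6–10 Hz) bands."""
    f, p, tot = _checked_band(spectrum)
    lo0, lo1 = config.low_band
    hi0, hi1 = config.high_band
    low = np.sum(p[(f >= lo0 - _EPS) & (f <= lo1 + _EPS)]) / tot
    high = np.sum(p[(f > hi0 + _EPS) & (f <= hi1 + _EPS)]) / tot
    return float(low), float(high)


def harmonic_index(
    spectrum: PowerSpectrum, config: SpectralConfig = DEFAULT_CONFIG
) -> float:
    """Share of band power within ±0.5 Hz of the modal (peak-density)
    frequency.

    Equals 1.00 for a single harmonic oscillation and decreases as power
    spreads over many oscillatory components.  Ties in the modal peak are
    broken toward the lower frequency.
    """
    f, p, tot = _checked_band(spectrum)
    peak = f[int(np.argmax(p))]  # argmax returns the first (lowest-f) maximum
    win = np.abs(f - peak) <= config.peak_halfwidth + _EPS
    return float(np.sum(p[win]) / tot)


def metrics_for_record(
    record: AccelRecord, config: SpectralConfig = DEFAULT_CONFIG
) -> TremorMetrics:
    """All five tremor parameters of one record (deterministic)."""
    spectrum = compute_power_spectrum(record, config)
    low, high = band_energy_fractions(spectrum, config)
    return TremorMetrics(
        intensity=tremor_intensity(spectrum),
        cf=center_frequency(spectrum),
        median_freq=median_frequency(spectrum),
        dispersion=frequency_dispersion(spectrum),
        low_band_fraction=low,
        high_band_fraction=high,
        hi=harmonic_index(spectrum, config),
    )
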
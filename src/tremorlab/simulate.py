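"""Synthetic tremor-signal and cohort generator.

The forward model for one acceleration axis is

    a(t) = A sin(2π φ(t)) + n(t),      dφ/dt = f0 + δ(t)

where δ(t) is a slow mean-reverting (Ornstein–Uhlenbeck) instantaneous-
frequency wander with stationary SD ``freq_jitter_sd`` and timescale
``jitter_timescale`` (spectral-line broadening, hence frequency dispersion),
and n(t) is broadband Gaussian noise band-limited to the 0.9–15 Hz analysis
band.  The harmonic core carries ``harmonic_fraction`` of the band power; the
total band RMS therefore equals the implied target intensity.

Cohort simulation draws per-subject, per condition × side component
parameters from the group archetypes: intensity from a moment-matched
lognormal (the Table-derived between-subject SDs exceed the means, which no
positive truncated normal can represent), center frequency from a normal
truncated to the analysis band by resampling.  The four cells of a subject
share latent severity and frequency traits (correlation 0.8): tremor
amplitude and oscillator frequency are subject-level characteristics, while
the marginal mean/SD of every cell is preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .archetypes import ARCHETYPES, ArchetypeParams, Cell, CellTargets
from .records import BAND, CONDITIONS, SIDES, AccelRecord, SignalSpec

#: Width of the harmonic-index window (±0.5 Hz) over the 14.1 Hz band: the
#: harmonic-index share contributed by a spectrally flat component.
_FLAT_HI = 1.0 / (BAND[1] - BAND[0])

#: Ratio between the 68%-power width of the broadened harmonic line and the
#: instantaneous-frequency SD (slow-modulation, near-Gaussian line shape).
_DISPERSION_PER_JITTER_SD = 2.2

#: Within-subject correlation of the latent severity / frequency traits
#: across the four condition × side cells.
TRAIT_CORRELATION = 0.8


@dataclass(frozen=True)
class TremorComponentParams:
    """Signal-level parameters of one condition × side tremor component."""

    amplitude: float  # m/s², harmonic core
    center_freq: float  # Hz
    freq_jitter_sd: float = 0.0  # Hz
    jitter_timescale: float = 1.0  # s
    noise_floor_rms: float = 0.0  # m/s²
    harmonic_fraction: float = 1.0  # share of band power in the harmonic core

    def __post_init__(self) -> None:
        vals = (
            self.amplitude, self.center_freq, self.freq_jitter_sd,
            self.jitter_timescale, self.noise_floor_rms, self.harmonic_fraction,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("component parameters must be finite")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not BAND[0] < self.center_freq < BAND[1]:
            raise ValueError(
                f"center_freq must lie inside ({BAND[0]}, {BAND[1]}) Hz"
            )
        if self.freq_jitter_sd < 0 or self.noise_floor_rms < 0:
            raise ValueError("jitter SD and noise floor must be >= 0")
        if self.jitter_timescale <= 0:
            raise ValueError("jitter_timescale must be positive")
        if not 0.0 <= self.harmonic_fraction <= 1.0:
            raise ValueError("harmonic_fraction must lie in [0, 1]")
        if self.harmonic_fraction == 0.0 and self.amplitude > 0:
            raise ValueError("harmonic_fraction=0 requires amplitude=0")

    @property
    def implied_intensity(self) -> float:
        """Total band RMS implied by the parameters, m/s²."""
        return math.sqrt(self.harmonic_power + self.noise_power)

    @property
    def harmonic_power(self) -> float:
        return self.amplitude**2 / 2.0

    @property
    def noise_power(self) -> float:
        extra = 0.0
        if 0.0 < self.harmonic_fraction < 1.0:
            extra = self.harmonic_power * (1.0 - self.harmonic_fraction) / self.harmonic_fraction
        return self.noise_floor_rms**2 + extra


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """Gaussian noise brick-wall band-limited to BAND, scaled to exact RMS."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < BAND[0]) | (f > BAND[1])] = 0.0
    x = np.fft.irfft(spec, n)
    r = math.sqrt(float(np.mean(x**2)))
    return x * (rms / r) if r > 0 else x


def _ou_jitter(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary mean-reverting frequency wander (exact AR(1) discretisation)."""
    rho = math.exp(-dt / tau)
    e = rng.standard_normal(n)
    u = np.empty(n)
    u[0] = sd * e[0]
    u[1:] = sd * math.sqrt(1.0 - rho * rho) * e[1:]
    return lfilter([1.0], [1.0, -rho], u)


def _render_axis(
    params: TremorComponentParams, spec: SignalSpec, rng: np.random.Generator
) -> np.ndarray:
    n = spec.n_samples
    dt = 1.0 / spec.sampling_rate
    x = np.zeros(n)
    if params.amplitude > 0:
        if params.freq_jitter_sd > 0:
            inst = params.center_freq + _ou_jitter(
                rng, n, dt, params.freq_jitter_sd, params.jitter_timescale
            )
        else:
            inst = np.full(n, params.center_freq)
        phase = 2.0 * math.pi * np.cumsum(inst) * dt
        x = params.amplitude * np.sin(phase)
    noise_rms = math.sqrt(params.noise_power)
    if noise_rms > 0:
        x = x + _band_limited_noise(rng, n, spec.sampling_rate, noise_rms)
    return x


def render_signal(
    params: TremorComponentParams,
    spec: SignalSpec,
    *,
    n_axes: int = 2,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
    condition: str = "rest",
    side: str = "R",
) -> AccelRecord:
    """Render one labelled acceleration record.

    Axes are independent realisations of the same component parameters
    (the device is biaxial but per-axis statistics are pooled downstream).
    Deterministic for a fixed seed / generator state.
    """
    if spec.sampling_rate < 2.0 * BAND[1]:
        raise ValueError(
            f"sampling_rate {spec.sampling_rate} Hz is below the Nyquist "
            f"requirement for the {BAND[1]} Hz band top"
        )
    if n_axes not in (1, 2):
        raise ValueError("n_axes must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    data = np.column_stack([_render_axis(params, spec, rng) for _ in range(n_axes)])
    return AccelRecord(
        data=data,
        sampling_rate=spec.sampling_rate,
        subject_id=subject_id,
        condition=condition,
        side=side,
    )


def component_params_for_cell(
    targets: CellTargets, intensity: float, center_freq: float
) -> TremorComponentParams:
    """Map a cell's realized intensity/Cf and group-mean dispersion/HI targets
    onto signal-level component parameters.

    The HI target enters as the harmonic core's share of band power,
    hf = (HI − w/B)/(1 − w/B) with w the 1 Hz HI window and B the band width:
    a flat broadband remainder contributes w/B to the harmonic index.  The
    dispersion target sets the frequency wander SD via the 68%-width ratio.
    """
    hf = (targets.hi_mean - _FLAT_HI) / (1.0 - _FLAT_HI)
    hf = float(np.clip(hf, 0.05, 1.0))
    return TremorComponentParams(
        amplitude=intensity * math.sqrt(2.0 * hf),
        center_freq=center_freq,
        freq_jitter_sd=targets.dispersion_mean / _DISPERSION_PER_JITTER_SD,
        jitter_timescale=1.0,
        noise_floor_rms=0.0,
        harmonic_fraction=hf,
    )


# ---------------------------------------------------------------------------
# distribution draws


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _lognormal_from_z(mean: float, sd: float, z: np.ndarray | float):
    """Lognormal with exact mean/sd, driven by standard-normal deviates."""
    if sd == 0:
        return mean if np.isscalar(z) else np.full(np.shape(z), mean)
    mu, s = _lognormal_params(mean, sd)
    return np.exp(mu + s * z)


def _truncnorm_from_z(
    mean: float, sd: float, z, rng: np.random.Generator,
    lo: float = BAND[0], hi: float = BAND[1],
):
    """Normal draw truncated to (lo, hi) by resampling out-of-range values."""
    x = mean + sd * np.asarray(z, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    bad = (x <= lo) | (x >= hi)
    tries = 0
    while np.any(bad):
        x[bad] = mean + sd * rng.standard_normal(int(np.sum(bad)))
        bad = (x <= lo) | (x >= hi)
        tries += 1
        if tries > 1000:  # pragma: no cover - safeguard for degenerate bounds
            x[bad] = np.clip(x[bad], lo + 1e-6, hi - 1e-6)
            break
    return float(x[0]) if scalar else x


def _correlated_z(
    rng: np.random.Generator, n_cells: int, rho: float, size: int | None = None
) -> np.ndarray:
    """Standard-normal deviates for the cells of one (or ``size``) subjects,
    equicorrelated at ``rho`` through a shared latent trait."""
    shape = (n_cells,) if size is None else (size, n_cells)
    shared = rng.standard_normal(shape[:-1] + (1,))
    own = rng.standard_normal(shape)
    return math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own


# ---------------------------------------------------------------------------
# subjects and cohorts


@dataclass
class SubjectProfile:
    """One simulated subject: demographics, clinical signs and the realized
    tremor component parameters per condition × side."""

    subject_id: str
    group: str
    age: float
    sex: str
    age_at_onset: float
    years_exposure: float | None
    years_since_exposure: float | None
    signs: dict[str, int]
    components: dict[Cell, TremorComponentParams]
    realized_targets: dict[Cell, tuple[float, float]]  # (intensity, cf)


def simulate_subject(
    archetype: ArchetypeParams,
    *,
    subject_id: str = "S000",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    trait_correlation: float = TRAIT_CORRELATION,
) -> SubjectProfile:
    """Draw one subject from a group archetype.

    Intensity targets: moment-matched lognormal (mean/SD per cell exact).
    Cf targets: normal truncated to the analysis band by resampling.
    Clinical signs: independent Bernoulli draws at the archetype rates.
    Demographics: normal draws; onset is redrawn until it precedes age.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cells = [(c, s) for c in CONDITIONS for s in SIDES]
    z_int = _correlated_z(rng, len(cells), trait_correlation)
    z_cf = _correlated_z(rng, len(cells), trait_correlation)

    components: dict[Cell, TremorComponentParams] = {}
    realized: dict[Cell, tuple[float, float]] = {}
    for k, cell in enumerate(cells):
        t = archetype.cells[cell]
        intensity = float(_lognormal_from_z(t.intensity_mean, archetype.intensity_sd(cell), z_int[k]))
        cf = _truncnorm_from_z(t.cf_mean, archetype.cf_sd(cell), z_cf[k], rng)
        components[cell] = component_params_for_cell(t, intensity, cf)
        realized[cell] = (intensity, cf)

    d = archetype.demographics
    age = float(rng.normal(d.age_mean, d.age_sd))
    onset = float(rng.normal(d.onset_mean, d.onset_sd))
    for _ in range(1000):
        if onset < age:
            break
        onset = float(rng.normal(d.onset_mean, d.onset_sd))
    else:  # pragma: no cover
        onset = age - 1.0
    sex = "M" if rng.random() < d.male_fraction else "F"
    exposure = since = None
    if d.exposure_mean is not None:
        exposure = abs(float(rng.normal(d.exposure_mean, d.exposure_sd)))
        since = abs(float(rng.normal(d.since_exposure_mean, d.since_exposure_sd)))
    signs = {sign: int(rng.random() < rate) for sign, rate in archetype.sign_rates.items()}
    return SubjectProfile(
        subject_id=subject_id,
        group=archetype.group,
        age=age,
        sex=sex,
        age_at_onset=onset,
        years_exposure=exposure,
        years_since_exposure=since,
        signs=signs,
        components=components,
        realized_targets=realized,
    )


def render_subject_records(
    profile: SubjectProfile, spec: SignalSpec, rng: np.random.Generator
) -> list[AccelRecord]:
    """Render the four labelled records (2 conditions × 2 sides) of a subject."""
    records = []
    for condition in CONDITIONS:
        for side in SIDES:
            records.append(
                render_signal(
                    profile.components[(condition, side)],
                    spec,
                    rng=rng,
                    subject_id=profile.subject_id,
                    condition=condition,
                    side=side,
                )
            )
    return records


def simulate_cohort(
    n_per_group: tuple[int, int, int] | dict[str, int] = (37, 20, 20),
    spec: SignalSpec = SignalSpec(),
    seed: int | None = 0,
    *,
    archetypes: dict[str, ArchetypeParams] | None = None,
    render: bool = True,
) -> tuple[list[SubjectProfile], list[AccelRecord]]:
    """Simulate a labelled multi-group cohort.

    Returns the subject profiles and (if ``render``) the 4 records per
    subject.  Bit-identical for a fixed seed.  Default sizes mirror the
    published study (37 welders, 20 IPD, 20 ET).
    """
    if archetypes is None:
        archetypes = ARCHETYPES
    if isinstance(n_per_group, dict):
        sizes = n_per_group
    else:
        sizes = dict(zip(archetypes, n_per_group))
    for g, n in sizes.items():
        if n < 1:
            raise ValueError(f"n_per_group for {g} must be >= 1")
    root = np.random.SeedSequence(seed)
    profiles: list[SubjectProfile] = []
    records: list[AccelRecord] = []
    prefix = {"WELDER": "W", "IPD": "P", "ET": "E"}
    for group, n in sizes.items():
        archetype = archetypes[group]
        for i, child in enumerate(root.spawn(n)):
            rng = np.random.default_rng(child)
            sid = f"{prefix.get(group, group[0])}{i + 1:03d}"
            profile = simulate_subject(archetype, subject_id=sid, rng=rng)
            profiles.append(profile)
            if render:
                records.extend(render_subject_records(profile, spec, rng))
    return profiles, records


def cohort_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Tabulate profiles: demographics, signs and realized per-cell targets."""
    rows = []
    for p in profiles:
        row: dict = {
            "subject_id": p.subject_id,
            "group": p.group,
            "age": p.age,
            "sex": p.sex,
            "age_at_onset": p.age_at_onset,
            "years_exposure": p.years_exposure,
            "years_since_exposure": p.years_since_exposure,
        }
        for sign, v in p.signs.items():
            row[f"sign_{sign}"] = v
        for (condition, side), (intensity, cf) in p.realized_targets.items():
            row[f"{condition}_{side}_target_intensity"] = intensity
            row[f"{condition}_{side}_target_cf"] = cf
        rows.append(row)
    return pd.DataFrame(rows)


def draw_group_targets(
    archetype: ArchetypeParams,
    n: int,
    rng: np.random.Generator,
    trait_correlation: float = TRAIT_CORRELATION,
) -> pd.DataFrame:
    """Vectorised draw of realized targets for ``n`` subjects (no signals).

    Used for fast distribution-level studies (e.g. null regression
    simulations); one row per subject with age and per-cell target columns.
    """
    cells = [(c, s) for c in CONDITIONS for s in SIDES]
    z_int = _correlated_z(rng, len(cells), trait_correlation, size=n)
    z_cf = _correlated_z(rng, len(cells), trait_correlation, size=n)
    d = archetype.demographics
    out = {
        "group": np.repeat(archetype.group, n),
        "age": rng.normal(d.age_mean, d.age_sd, n),
    }
    for k, cell in enumerate(cells):
        t = archetype.cells[cell]
        name = f"{cell[0]}_{cell[1]}"
        out[f"{name}_target_intensity"] = _lognormal_from_z(
            t.intensity_mean, archetype.intensity_sd(cell), z_int[:, k]
        )
        out[f"{name}_target_cf"] = _truncnorm_from_z(
            t.cf_mean, archetype.cf_sd(cell), z_cf[:, k], rng
        )
    return pd.DataFrame(out)
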
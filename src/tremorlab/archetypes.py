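"""Reference group archetypes for the three tremor cohorts.

Three archetypes — occupational manganese-exposed welders (WELDER), de novo
idiopathic Parkinson's disease (IPD) and essential tremor (ET) — carry, per
condition (rest/postural) and side (R/L), the published group means and SEMs
of tremor intensity and center frequency, group-mean dispersion and harmonic
index, plus demographic distributions and clinical-sign frequencies.  They
are the population targets the cohort simulator draws from.

Between-subject SDs are recovered from the printed SEMs as SEM·sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import CONDITIONS, GROUPS, SIDES

Cell = tuple[str, str]  # (condition, side)


@dataclass(frozen=True)
class CellTargets:
    """Population targets of one condition × side cell."""

    intensity_mean: float  # m/s²
    intensity_sem: float
    cf_mean: float  # Hz
    cf_sem: float
    dispersion_mean: float  # Hz
    hi_mean: float  # unitless, (0, 1]

    def __post_init__(self) -> None:
        for name in ("intensity_mean", "cf_mean", "dispersion_mean", "hi_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hi_mean <= 1:
            raise ValueError("hi_mean must lie in (0, 1]")


@dataclass(frozen=True)
class Demographics:
    """Group-level demographic distributions (years; Bernoulli male rate)."""

    age_mean: float
    age_sd: float
    onset_mean: float
    onset_sd: float
    male_fraction: float
    exposure_mean: float | None = None  # welders only
    exposure_sd: float | None = None
    since_exposure_mean: float | None = None
    since_exposure_sd: float | None = None


@dataclass(frozen=True)
class ArchetypeParams:
    """Per-group simulation targets.

    ``n_reference`` is the published group size used to convert SEMs to
    between-subject SDs.  ``sign_rates`` are per-sign Bernoulli probabilities.
    """

    group: str
    n_reference: int
    cells: dict[Cell, CellTargets]
    demographics: Demographics
    sign_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        expected = {(c, s) for c in CONDITIONS for s in SIDES}
        if set(self.cells) != expected:
            raise ValueError(f"cells must cover {sorted(expected)}")
        for rate in self.sign_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("sign rates must lie in [0, 1]")

    def intensity_sd(self, cell: Cell) -> float:
        return self.cells[cell].intensity_sem * self.n_reference**0.5

    def cf_sd(self, cell: Cell) -> float:
        return self.cells[cell].cf_sem * self.n_reference**0.5


#: Clinical symptom/sign panel: sign -> (welders affected, welders examined,
#: IPD affected, IPD examined).  Denominators vary per sign (complete-case).
SYMPTOM_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "initial_tremor": (29, 32, 14, 17),
    "initial_bradykinesia": (5, 32, 3, 17),
    "initial_balance": (7, 31, 1, 17),
    "initial_limb_cramping": (7, 32, 0, 17),
    "resting_tremor": (19, 31, 9, 16),
    "action_tremor": (27, 31, 3, 16),
    "postural_tremor": (21, 31, 2, 16),
    "dystonic_limb_posture": (1, 31, 1, 17),
    "cogwheel_rigidity": (8, 29, 3, 17),
    "asymmetric_tremor": (4, 29, 10, 16),
    "asymmetric_rigidity": (11, 29, 11, 12),
    "asymmetric_bradykinesia": (11, 29, 11, 11),
    "dyshidrosis": (11, 29, 0, 17),
    "dizziness_on_standing": (0, 29, 1, 17),
}

SIGN_NAMES: tuple[str, ...] = tuple(SYMPTOM_COUNTS)


def _rates(column: int) -> dict[str, float]:
    out = {}
    for sign, (a, n1, b, n2) in SYMPTOM_COUNTS.items():
        num, den = (a, n1) if column == 0 else (b, n2)
        out[sign] = num / den
    return out


# ET is a mono-symptomatic postural/kinetic tremor cohort: every patient
# presented with tremor and exhibited postural tremor; the parkinsonian and
# autonomic signs are absent by the diagnostic definition.
_ET_RATES = {sign: 0.0 for sign in SIGN_NAMES}
_ET_RATES.update({"initial_tremor": 1.0, "action_tremor": 1.0, "postural_tremor": 1.0})


WELDER_ARCHETYPE = ArchetypeParams(
    group="WELDER",
    n_reference=37,
    cells={
        ("rest", "R"): CellTargets(0.774, 0.194, 7.05, 0.263, 1.19, 0.941),
        ("rest", "L"): CellTargets(0.706, 0.175, 7.59, 0.227, 1.90, 0.917),
        ("postural", "R"): CellTargets(1.61, 0.457, 7.12, 0.208, 1.36, 0.910),
        ("postural", "L"): CellTargets(1.07, 0.335, 7.28, 1.54, 2.04, 0.936),
    },
    demographics=Demographics(
        age_mean=54.8, age_sd=10.7, onset_mean=47.9, onset_sd=11.7,
        male_fraction=36 / 37,
        exposure_mean=25.6, exposure_sd=10.8,
        since_exposure_mean=7.8, since_exposure_sd=10.7,
    ),
    sign_rates=_rates(0),
)

IPD_ARCHETYPE = ArchetypeParams(
    group="IPD",
    n_reference=20,
    cells={
        ("rest", "R"): CellTargets(0.867, 0.338, 6.64, 0.367, 1.93, 0.946),
        ("rest", "L"): CellTargets(0.633, 0.424, 6.65, 0.377, 1.59, 0.944),
        ("postural", "R"): CellTargets(0.937, 0.377, 6.10, 0.315, 2.21, 0.94),
        ("postural", "L"): CellTargets(0.613, 0.235, 6.32, 0.323, 2.24, 0.936),
    },
    demographics=Demographics(
        age_mean=65.3, age_sd=9.15, onset_mean=59.5, onset_sd=9.68,
        male_fraction=13 / 20,
    ),
    sign_rates=_rates(1),
)

ET_ARCHETYPE = ArchetypeParams(
    group="ET",
    n_reference=20,
    cells={
        ("rest", "R"): CellTargets(0.241, 0.076, 5.829, 0.291, 1.755, 0.956),
        ("rest", "L"): CellTargets(0.124, 0.035, 5.995, 0.355, 2.270, 0.939),
        ("postural", "R"): CellTargets(0.588, 0.140, 6.674, 0.340, 2.580, 0.936),
        ("postural", "L"): CellTargets(0.599, 0.175, 7.055, 0.386, 2.855, 0.918),
    },
    demographics=Demographics(
        age_mean=59.5, age_sd=14.9, onset_mean=50.0, onset_sd=14.8,
        male_fraction=9 / 20,
    ),
    sign_rates=dict(_ET_RATES),
)

ARCHETYPES: dict[str, ArchetypeParams] = {
    "WELDER": WELDER_ARCHETYPE,
    "IPD": IPD_ARCHETYPE,
    "ET": ET_ARCHETYPE,
}

#: Published study group sizes (welders, IPD, ET).
STUDY_N = (37, 20, 20)
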
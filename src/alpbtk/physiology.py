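"""Age-dependent anatomy and renal function for a reference individual.

The simulator needs smooth, strictly positive physiological functions of age
from birth to 50 years: body weight, wet organ masses (bone including marrow,
brain, liver, kidney, rest-of-body), plasma volume, and glomerular filtration
rate (GFR).  Organ masses and plasma volume turn amounts into concentrations,
so body growth dilutes a fixed body burden; GFR drives the (almost exclusively
renal) elimination of aluminium.

Growth data are tabulated at a small set of age knots in a packaged CSV
(reference-female anthropometry) and interpolated monotonically in log-mass,
which keeps masses positive and derivatives smooth for the ODE right-hand
side.  GFR combines allometric size scaling (body weight to the 0.75 power,
relative to the adult) with a sigmoid maturation function of postmenstrual
age, the standard description of renal maturation after birth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

ORGANS = ("bone", "brain", "liver", "kidney", "rest")

MAX_AGE_Y = 50.0
DAYS_PER_YEAR = 365.25

#: Gestation length in years; maturation acts on postmenstrual age = age + this.
GESTATION_Y = 40.0 * 7.0 / 365.25


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0.0) or np.any(age > MAX_AGE_Y):
        raise ValueError(f"age must lie in [0, {MAX_AGE_Y}] years")
    return age


@dataclass
class GrowthTable:
    """Tabulated body weight, wet organ masses and plasma volume at age knots."""

    age_knots: np.ndarray          # years, strictly ascending, starting at 0
    body_weight: np.ndarray        # kg
    organ_mass: dict               # organ -> g, arrays aligned with age_knots
    plasma_volume: np.ndarray      # L

    def __post_init__(self):
        self.age_knots = np.asarray(self.age_knots, dtype=float)
        self.body_weight = np.asarray(self.body_weight, dtype=float)
        self.plasma_volume = np.asarray(self.plasma_volume, dtype=float)
        self.organ_mass = {k: np.asarray(v, dtype=float) for k, v in self.organ_mass.items()}
        self.validate()
        # monotone piecewise-cubic interpolation on log mass vs age
        a = self.age_knots
        self._bw = PchipInterpolator(a, np.log(self.body_weight))
        self._vpl = PchipInterpolator(a, np.log(self.plasma_volume))
        self._organs = {k: PchipInterpolator(a, np.log(v)) for k, v in self.organ_mass.items()}

    def validate(self) -> None:
        a = self.age_knots
        if a[0] != 0.0 or np.any(np.diff(a) <= 0):
            raise ValueError("age knots must be strictly ascending and start at 0")
        for name, arr in {"body_weight": self.body_weight,
                          "plasma_volume": self.plasma_volume,
                          **self.organ_mass}.items():
            if arr.shape != a.shape:
                raise ValueError(f"{name} must align with age knots")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")
        if set(self.organ_mass) != set(ORGANS):
            raise ValueError(f"organ_mass must have keys {ORGANS}")
        ped = a <= 20.0
        if np.any(np.diff(self.body_weight[ped]) < 0):
            raise ValueError("body weight must be non-decreasing on [0, 20] years")
        total = sum(self.organ_mass[o] for o in ORGANS)
        if np.any(total >= self.body_weight * 1000.0):
            raise ValueError("sum of organ masses must stay below body weight")

    @classmethod
    def from_csv(cls, path_or_buf) -> "GrowthTable":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(
            age_knots=df["age_y"].to_numpy(),
            body_weight=df["bw_kg"].to_numpy(),
            organ_mass={o: df[f"{o}_g"].to_numpy() for o in ORGANS},
            plasma_volume=df["plasma_L"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"age_y": self.age_knots, "bw_kg": self.body_weight})
        for o in ORGANS:
            df[f"{o}_g"] = self.organ_mass[o]
        df["plasma_L"] = self.plasma_volume
        df.to_csv(path, index=False)


@dataclass
class GFRModel:
    """Allometrically scaled GFR with sigmoid postnatal maturation.

    ``adult_gfr`` is the GFR (mL/min) of the adult reference individual;
    size scaling is (BW/adult BW)**size_scaling_exponent.  The maturation
    fraction is a Hill function of postmenstrual age (postnatal age plus a
    40-week gestation), with ``maturation_halftime`` on that same scale, so
    the fraction is ~0.25 at birth and approaches 1 within the first years.
    """

    adult_gfr: float = 110.0            # mL/min at adult body size
    maturation_halftime: float = 1.06   # years postmenstrual age
    maturation_hill: float = 3.4
    size_scaling_exponent: float = 0.75
    gestation_offset: float = GESTATION_Y

    def maturation(self, age_y) -> np.ndarray:
        pma = np.asarray(age_y, dtype=float) + self.gestation_offset
        x = pma ** self.maturation_hill
        return x / (x + self.maturation_halftime ** self.maturation_hill)


@dataclass
class PhysiologyProfile:
    """One sex-specific reference individual, evaluable at any age in [0, 50]."""

    sex: str
    growth: GrowthTable
    gfr_model: GFRModel = field(default_factory=GFRModel)
    interpolation: str = "pchip-log"

    @property
    def adult_body_weight(self) -> float:
        return float(self.growth.body_weight[-1])


def default_profile(sex: str = "female") -> PhysiologyProfile:
    """Packaged reference profile; only the female table ships by default."""
    if sex != "female":
        raise ValueError(
            "only the female reference table is packaged; supply a custom "
            "GrowthTable for other profiles"
        )
    text = resources.files("alpbtk.data").joinpath("growth_female.csv").read_text()
    return PhysiologyProfile(sex=sex, growth=GrowthTable.from_csv(io.StringIO(text)))


def body_weight(profile: PhysiologyProfile, age_y) -> np.ndarray:
    """Body weight (kg) at an age in years; monotone interpolation of the table."""
    age = _check_age(age_y)
    return np.exp(profile.growth._bw(age))


def organ_mass(profile: PhysiologyProfile, organ: str, age_y) -> np.ndarray:
    """Wet mass (g) of one organ at an age in years."""
    age = _check_age(age_y)
    if organ not in profile.growth._organs:
        raise KeyError(f"unknown organ {organ!r}; expected one of {ORGANS}")
    return np.exp(profile.growth._organs[organ](age))


def plasma_volume(profile: PhysiologyProfile, age_y) -> np.ndarray:
    """Plasma volume (L) at an age in years."""
    age = _check_age(age_y)
    return np.exp(profile.growth._vpl(age))


def gfr(profile: PhysiologyProfile, age_y, individual_scale: float = 1.0) -> np.ndarray:
    """GFR (mL/min) at an age in years, optionally scaled per individual.

    gfr = adult_gfr * (BW(age)/adult BW)**0.75 * maturation(age) * scale.
    """
    if individual_scale <= 0:
        raise ValueError("individual_scale must be positive")
    age = _check_age(age_y)
    m = profile.gfr_model
    size = (body_weight(profile, age) / profile.adult_body_weight) ** m.size_scaling_exponent
    return m.adult_gfr * size * m.maturation(age) * individual_scale
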
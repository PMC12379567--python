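"""Age-dependent calcium turnover driving the aluminium bone submodel.

Bone is modelled as a compartment whose aluminium uptake is proportional to
the calcium accretion flux (mg Ca/day) and to the plasma Al concentration,
while release of Al from bone follows the fractional calcium release rate
(1/day) as first-order loss on the bone Al amount.  The accretion flux has a
pronounced pubertal peak; the release fraction declines from the very high
bone turnover of infancy to a slow adult remodeling plateau, which is what
makes SCIT-induced bone increases transient.

Default curves are a packaged CSV fixture (generated from the parametric
forms below): accretion = adult baseline + Gaussian pubertal peak (female,
centre 12.5 y), release = adult plateau + exponentially decaying infant
excess.  Alternate curves can be swapped in via :meth:`CaKinetics.from_csv`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .physiology import DAYS_PER_YEAR, MAX_AGE_Y, _check_age

# Parametric defaults (female): accretion in mg Ca/day, release in 1/year.
ADULT_ACCRETION = 150.0
PEAK_ACCRETION = 250.0
PUBERTAL_PEAK_AGE = 12.5
PUBERTAL_PEAK_SD = 1.5
ADULT_RELEASE_PER_Y = 0.15
INFANT_RELEASE_EXCESS_PER_Y = 2.35
RELEASE_DECAY_Y = 9.83


def _parametric_accretion(age_y):
    age_y = np.asarray(age_y, dtype=float)
    return ADULT_ACCRETION + PEAK_ACCRETION * np.exp(
        -((age_y - PUBERTAL_PEAK_AGE) ** 2) / (2.0 * PUBERTAL_PEAK_SD**2)
    )


def _parametric_release(age_y):
    age_y = np.asarray(age_y, dtype=float)
    per_year = ADULT_RELEASE_PER_Y + INFANT_RELEASE_EXCESS_PER_Y * np.exp(
        -age_y / RELEASE_DECAY_Y
    )
    return per_year / DAYS_PER_YEAR


@dataclass
class CaKinetics:
    """Calcium accretion flux (mg/day) and fractional release rate (1/day) vs age."""

    age_grid: np.ndarray
    accretion_mg_d: np.ndarray
    release_frac_d: np.ndarray
    pubertal_peak_age: float = PUBERTAL_PEAK_AGE
    baseline_adult_accretion: float = ADULT_ACCRETION

    def __post_init__(self):
        a = np.asarray(self.age_grid, dtype=float)
        acc = np.asarray(self.accretion_mg_d, dtype=float)
        rel = np.asarray(self.release_frac_d, dtype=float)
        if np.any(np.diff(a) <= 0):
            raise ValueError("age grid must be strictly ascending")
        if np.any(acc <= 0) or np.any(rel <= 0):
            raise ValueError("accretion and release curves must be positive")
        self.age_grid, self.accretion_mg_d, self.release_frac_d = a, acc, rel
        self._acc = PchipInterpolator(a, acc)
        self._rel = PchipInterpolator(a, rel)

    def accretion(self, age_y):
        return self._acc(np.asarray(age_y, dtype=float))

    def release(self, age_y):
        return self._rel(np.asarray(age_y, dtype=float))

    @classmethod
    def parametric(cls, age_step_y: float = 0.25) -> "CaKinetics":
        a = np.arange(0.0, MAX_AGE_Y + 1e-9, age_step_y)
        return cls(a, _parametric_accretion(a), _parametric_release(a))

    @classmethod
    def from_csv(cls, path_or_buf) -> "CaKinetics":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(
            df["age_y"].to_numpy(),
            df["ca_accretion_mg_d"].to_numpy(),
            df["ca_release_frac_d"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "age_y": self.age_grid,
                "ca_accretion_mg_d": self.accretion_mg_d,
                "ca_release_frac_d": self.release_frac_d,
            }
        ).to_csv(path, index=False)


def default_ca_kinetics() -> CaKinetics:
    """Packaged female calcium-turnover fixture."""
    text = resources.files("alpbtk.data").joinpath("ca_female.csv").read_text()
    return CaKinetics.from_csv(io.StringIO(text))


@dataclass(frozen=True)
class BoneCoupling:
    """Proportionality constant for Al bone uptake.

    Units: (ug Al/day) per (mg Ca/day) per (ug Al/L plasma), i.e. the bone
    uptake clearance in L/day equals kappa_bone times the Ca accretion flux.
    """

    kappa_bone: float

    def __post_init__(self):
        if self.kappa_bone <= 0:
            raise ValueError("kappa_bone must be positive")


def ca_accretion(kin: CaKinetics, age_y) -> np.ndarray:
    """Calcium accretion flux (mg Ca/day) at an age in years."""
    return kin.accretion(_check_age(age_y))


def bone_uptake_flux(coupling: BoneCoupling, kin: CaKinetics, age_y, c_plasma) -> np.ndarray:
    """Al flux into bone (ug/day): kappa * Ca accretion * plasma concentration."""
    c = np.asarray(c_plasma, dtype=float)
    if np.any(c < 0):
        raise ValueError("plasma concentration must be non-negative")
    return coupling.kappa_bone * ca_accretion(kin, age_y) * c


def bone_release_rate(kin: CaKinetics, age_y) -> np.ndarray:
    """Fractional Al release rate from bone (1/day), identical to Ca release."""
    return kin.release(_check_age(age_y))
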
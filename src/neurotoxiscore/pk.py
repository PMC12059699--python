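"""In-vitro vs clinical exposure comparison for branaplam.

A constant in-vitro bath concentration is converted to the exposure metrics
used clinically: Cmax (here simply the bath concentration in ng/mL, assuming
the compound is stable over the treatment) and AUC (concentration x
exposure duration for a constant profile). These are compared as ratios
against clinical reference exposures (trial pharmacokinetics: Cmax
45.3 ng/mL, weekly AUC over 168 h of 3190 h*ng/mL for once-weekly 56 mg
oral dosing).

With the defaults (1,000 nM for 120 h, molar mass 393.5 g/mol) the in-vitro
condition works out to Cmax 393.5 ng/mL and AUC 47,220 h*ng/mL, i.e. 8.7x
the clinical Cmax and 14.8x the clinical weekly AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "BRANAPLAM_MOLAR_MASS",
    "CLINICAL_CMAX_NG_ML",
    "CLINICAL_AUC_H_NG_ML",
    "CLINICAL_AUC_WINDOW_H",
    "PKProfile",
    "nanomolar_to_mass_concentration",
    "mass_to_nanomolar_concentration",
    "auc_constant_exposure",
    "exposure_ratios",
    "exposure_duration_ratio",
    "in_vitro_profile",
    "clinical_reference_profile",
]

#: g/mol; the registry value (~393.48) rounds to the same results at the
#: reported precision.
BRANAPLAM_MOLAR_MASS = 393.5

#: Clinical reference exposures (once-weekly 56 mg oral dosing).
CLINICAL_CMAX_NG_ML = 45.3
CLINICAL_AUC_H_NG_ML = 3190.0
CLINICAL_AUC_WINDOW_H = 168.0


@dataclass(frozen=True)
class PKProfile:
    """Constant-exposure profile: Cmax and AUC over an exposure window."""

    cmax_ng_ml: float
    auc_h_ng_ml: float
    exposure_hours: float

    def __post_init__(self) -> None:
        for name in ("cmax_ng_ml", "auc_h_ng_ml", "exposure_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def nanomolar_to_mass_concentration(conc_nm: float,
                                    molar_mass_g_per_mol: float = BRANAPLAM_MOLAR_MASS,
                                    ) -> float:
    """Convert nM to ng/mL: ng/mL = nM * (g/mol) / 1000."""
    if conc_nm <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return conc_nm * molar_mass_g_per_mol / 1000.0


def mass_to_nanomolar_concentration(conc_ng_ml: float,
                                    molar_mass_g_per_mol: float = BRANAPLAM_MOLAR_MASS,
                                    ) -> float:
    """Inverse of `nanomolar_to_mass_concentration`."""
    if conc_ng_ml <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return conc_ng_ml * 1000.0 / molar_mass_g_per_mol


def auc_constant_exposure(conc_ng_ml: float, hours: float) -> float:
    """AUC of a constant concentration profile: conc * duration."""
    if conc_ng_ml <= 0 or hours <= 0:
        raise ValueError("concentration and duration must be positive")
    return conc_ng_ml * hours


def in_vitro_profile(dose_nm: float = 1000.0,
                     hours: float = 120.0,
                     molar_mass: float = BRANAPLAM_MOLAR_MASS) -> PKProfile:
    """Constant-bath in-vitro exposure profile (default: 1,000 nM for 5 days)."""
    cmax = nanomolar_to_mass_concentration(dose_nm, molar_mass)
    return PKProfile(cmax, auc_constant_exposure(cmax, hours), hours)


def clinical_reference_profile() -> PKProfile:
    """The clinical reference exposure (weekly dosing)."""
    return PKProfile(CLINICAL_CMAX_NG_ML, CLINICAL_AUC_H_NG_ML,
                     CLINICAL_AUC_WINDOW_H)


def _round1(x: float) -> float:
    """Round half-up to one decimal (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def exposure_ratios(in_vitro: PKProfile, clinical: PKProfile,
                    rounded: bool = True) -> tuple[float, float]:
    """(Cmax ratio, AUC ratio) of in-vitro over clinical exposure.

    Ratios are reported rounded half-up to one decimal by default; pass
    ``rounded=False`` for full precision.
    """
    cmax_ratio = in_vitro.cmax_ng_ml / clinical.cmax_ng_ml
    auc_ratio = in_vitro.auc_h_ng_ml / clinical.auc_h_ng_ml
    if rounded:
        return _round1(cmax_ratio), _round1(auc_ratio)
    return cmax_ratio, auc_ratio


def exposure_duration_ratio(weeks_in_vivo: float = 17.0,
                            days_in_vitro: float = 5.0) -> float:
    """How much longer the in-vivo dosing period is than the in-vitro one."""
    if weeks_in_vivo <= 0 or days_in_vitro <= 0:
        raise ValueError("durations must be positive")
    return weeks_in_vivo * 7.0 / days_in_vitro
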
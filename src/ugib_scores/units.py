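"""Physiological unit conversions and renal function.

All score calculators work in a single canonical unit system (urea and
creatinine in mg/dL, albumin in g/dL); thresholds published in SI units
are applied after conversion through the functions here.

Conversions are exact molar-mass ratios, so they are linear and
invertible; the estimated glomerular filtration rate uses the race-free
CKD-EPI creatinine equation (2021 revision).
"""

from __future__ import annotations

__all__ = [
    "bun_from_urea",
    "urea_mmol_from_mg",
    "creatinine_umol_from_mg",
    "egfr_ckd_epi_2021",
]

# molar masses: urea 60.06 g/mol carries two nitrogens (2 x 14.007 = 28.01)
_BUN_PER_UREA = 28.01 / 60.06
_UREA_MG_PER_MMOL = 6.006        # 60.06 g/mol -> mg/dL per mmol/L
_CREAT_UMOL_PER_MG = 88.4        # creatinine 113.12 g/mol, conventional factor


def bun_from_urea(urea: float) -> float:
    """Blood urea nitrogen (mg/dL) from urea (mg/dL).

    BUN is the nitrogen fraction of urea: BUN = urea * 28.01/60.06.
    Several bleeding scores (N-score, H3B2, Iino) threshold BUN at
    22.4 mg/dL, which corresponds to urea ~48 mg/dL.
    """
    if urea < 0:
        raise ValueError(f"urea must be non-negative, got {urea}")
    return urea * _BUN_PER_UREA


def urea_mmol_from_mg(urea: float) -> float:
    """Urea mg/dL -> mmol/L (divide by 6.006)."""
    if urea < 0:
        raise ValueError(f"urea must be non-negative, got {urea}")
    return urea / _UREA_MG_PER_MMOL


def creatinine_umol_from_mg(creatinine: float) -> float:
    """Creatinine mg/dL -> umol/L (multiply by 88.4)."""
    if creatinine < 0:
        raise ValueError(f"creatinine must be non-negative, got {creatinine}")
    return creatinine * _CREAT_UMOL_PER_MG


def egfr_ckd_epi_2021(creatinine: float, age: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m^2), CKD-EPI creatinine equation, 2021.

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200
               * 0.9938^age * (1.012 if female)

    with k = 0.7 (female) / 0.9 (male) and a = -0.241 (female) /
    -0.302 (male).  Scr is serum creatinine in mg/dL.

    Parameters
    ----------
    creatinine : serum creatinine, mg/dL (> 0)
    age : years
    sex : "male" or "female"
    """
    if creatinine <= 0:
        raise ValueError(f"creatinine must be positive, got {creatinine}")
    sex = getattr(sex, "value", sex)
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.241, 1.012
    elif sex == "male":
        kappa, alpha, sex_factor = 0.9, -0.302, 1.0
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    ratio = creatinine / kappa
    return (
        142.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.200
        * 0.9938**age
        * sex_factor
    )
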
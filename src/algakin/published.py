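"""Rate constants and activation energies reported by the source study.

The study deposited no raw time courses; its quantitative results are the
fitted rate-constant tables (per enzyme loading and per temperature) and
the Arrhenius activation energies. These serve as generating parameters
for synthetic experiments and as reference points for self-consistency
(parameter-recovery) checks.

All rate constants are in 1/min; standard errors are yield-fraction RMSE.
"""

from __future__ import annotations

from .mechanisms import (
    PretreatmentRateConstants,
    SaccharificationRateConstants,
)

__all__ = [
    "PRETREATMENT_BY_LOADING",
    "PRETREATMENT_BY_TEMPERATURE",
    "SACCHARIFICATION_BY_TEMPERATURE",
    "PRETREATMENT_SE_BY_LOADING",
    "PRETREATMENT_SE_BY_TEMPERATURE",
    "SACCHARIFICATION_SE_BY_TEMPERATURE",
    "ACTIVATION_ENERGIES_KJ_MOL",
]

# Pretreatment (cellulase + xylanase, simultaneous), by enzyme loading
# (% w/w, both enzymes) at 45 degC.
PRETREATMENT_BY_LOADING: dict[float, PretreatmentRateConstants] = {
    10: PretreatmentRateConstants(0.44, 0.01, 0.01, 0.06, 0.19, 0.01, 0.08, 0.21),
    20: PretreatmentRateConstants(0.64, 0.19, 0.11, 0.08, 0.26, 0.014, 0.16, 0.37),
    30: PretreatmentRateConstants(1.11, 0.28, 0.12, 0.32, 0.32, 0.042, 0.44, 0.38),
}
PRETREATMENT_SE_BY_LOADING = {10: 0.0291, 20: 0.0125, 30: 0.0210}

# Pretreatment, by temperature (degC) at 30% w/w loading.
PRETREATMENT_BY_TEMPERATURE: dict[float, PretreatmentRateConstants] = {
    40: PretreatmentRateConstants(0.20, 0.12, 0.004, 0.21, 0.27, 0.002, 0.37, 0.27),
    45: PretreatmentRateConstants(1.11, 0.28, 0.12, 0.32, 0.32, 0.04, 0.44, 0.38),
    50: PretreatmentRateConstants(0.03, 0.25, 0.11, 0.12, 0.32, 0.01, 0.03, 0.011),
    60: PretreatmentRateConstants(0.001, 0.02, 0.002, 0.09, 0.29, 0.001, 0.01, 0.001),
}
PRETREATMENT_SE_BY_TEMPERATURE = {40: 0.0149, 45: 0.0210, 50: 0.0223, 60: 0.0228}

# Saccharification (alpha-amylase 0.0006% + glucoamylase 0.01% w/w),
# by temperature (degC).
SACCHARIFICATION_BY_TEMPERATURE: dict[float, SaccharificationRateConstants] = {
    45: SaccharificationRateConstants(0.09, 0.02, 1.23, 0.26, 0.30, 0.03, 0.25, 0.14),
    55: SaccharificationRateConstants(0.14, 0.02, 1.45, 0.46, 0.40, 0.27, 0.50, 0.25),
    65: SaccharificationRateConstants(0.09, 0.02, 1.37, 0.34, 0.35, 0.20, 0.21, 0.18),
    75: SaccharificationRateConstants(0.06, 0.01, 1.29, 0.22, 0.10, 0.03, 0.19, 0.14),
}
SACCHARIFICATION_SE_BY_TEMPERATURE = {45: 0.0495, 55: 0.0073, 65: 0.0278, 75: 0.0259}

# Reported activation energies (kJ/mol) for glucose formation. The study
# does not state which k(T) series produced them, so they are used here as
# qualitative magnitudes only (orderings, synthetic-recovery scales).
ACTIVATION_ENERGIES_KJ_MOL = {
    ("pretreatment", "cellulose"): 31.80,
    ("pretreatment", "hemicellulose"): 30.37,
    ("pretreatment", "simultaneous"): 18.21,
    ("saccharification", "starch"): 11.29,
}
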
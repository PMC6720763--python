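"""Published reference constants for the eight studied odorants.

The study system is a set of eight odorants spanning four chemical groups
(alkanes/cycloalkanes, aromatic hydrocarbons, amines, terpenes).  This
module holds their published physical constants and panel-fitted
psychophysical coefficients, plus the published pairwise interaction
coefficient tables for the vectorial and U models (estimated from sensory
panels of binary mixtures generated at odor-intensity levels 1 and 2) and
for the level-free UPL model.

These serve as package-level reference inputs: regenerating the derived
tables (target concentrations per intensity level, UPL coefficients from
Stevens exponents, the vectorial↔U cross-check) from these constants is
the package's primary consistency exercise.
"""

from __future__ import annotations

from .perceptual import InteractionMatrix
from .psychophysics import OdorantProfile, StevensLaw, WeberFechnerLaw

__all__ = [
    "ODORANTS",
    "reference_profiles",
    "reference_profile",
    "reference_cos_matrix",
]

ODORANTS = (
    "n-hexane", "cyclohexane", "toluene", "o-xylene",
    "trimethylamine", "triethylamine", "alpha-pinene", "beta-pinene",
)

# name: (molar mass g/mol, liquid density g/cm3, vapor pressure Pa @20C,
#        literature odor threshold ppm, k_WF, C_OT ppm, Stevens n, k_S)
_CONSTANTS = {
    "n-hexane":       (86.178, 0.6606, 17600.0, 1.5,      2.14, 1.10, 0.874, 0.255),
    "cyclohexane":    (84.162, 0.7781, 10400.0, 2.5,      1.93, 1.10, 0.961, 0.191),
    "toluene":        (92.141, 0.87,    2800.0, 0.33,     1.96, 0.34, 0.382, 1.119),
    "o-xylene":       (106.168, 0.88,    933.0, 0.38,     2.23, 0.53, 0.614, 0.710),
    "trimethylamine": (59.112, 0.627, 188700.0, 0.000032, 2.14, 0.17, 0.496, 1.437),
    "triethylamine":  (101.193, 0.7255, 8506.0, 0.0054,   2.39, 0.35, 0.771, 0.821),
    "alpha-pinene":   (136.238, 0.858,   536.0, 0.018,    1.15, 0.18, 0.330, 0.927),
    "beta-pinene":    (136.238, 0.872,   391.0, 0.033,    1.45, 0.24, 0.361, 1.004),
}

#: Reported standard errors of the fitted coefficients (k_WF, Stevens n).
COEFFICIENT_STD_ERRORS = {
    "n-hexane":       {"k_wf": 0.23, "n": 0.061},
    "cyclohexane":    {"k_wf": 0.22, "n": 0.041},
    "toluene":        {"k_wf": 0.29, "n": 0.125},
    "o-xylene":       {"k_wf": 0.25, "n": 0.115},
    "trimethylamine": {"k_wf": 0.21, "n": 0.104},
    "triethylamine":  {"k_wf": 0.26, "n": 0.145},
    "alpha-pinene":   {"k_wf": 0.19, "n": 0.024},
    "beta-pinene":    {"k_wf": 0.20, "n": 0.025},
}

# Published pairwise interaction coefficients, lower-triangle row order as
# in ODORANTS (row odorant vs the earlier columns).
_VECTORIAL_COS = {
    1: [
        [-0.88],
        [-0.60, -0.56],
        [-0.55, -0.48, -0.48],
        [-0.51, -0.54, -0.54, -0.73],
        [-0.61, -0.61, -0.38, -0.44, -0.50],
        [-0.33, -0.57, -0.51, -0.63, -0.31, -0.29],
        [-0.33, -0.48, -0.39, -0.51, -0.27, -0.41, -0.63],
    ],
    2: [
        [-0.87],
        [-0.62, -0.54],
        [-0.62, -0.50, -0.48],
        [-0.50, -0.51, -0.53, -0.70],
        [-0.62, -0.61, -0.37, -0.47, -0.49],
        [-0.35, -0.58, -0.53, -0.63, -0.32, -0.30],
        [-0.34, -0.49, -0.40, -0.51, -0.28, -0.44, -0.64],
    ],
}

_U_COS = {
    1: [
        [-0.76],
        [-0.55, -0.53],
        [-0.52, -0.49, -0.49],
        [-0.51, -0.52, -0.52, -0.63],
        [-0.56, -0.56, -0.44, -0.47, -0.50],
        [-0.42, -0.54, -0.51, -0.57, -0.41, -0.40],
        [-0.42, -0.49, -0.45, -0.50, -0.40, -0.46, -0.57],
    ],
    2: [
        [-0.75],
        [-0.56, -0.52],
        [-0.54, -0.50, -0.49],
        [-0.50, -0.50, -0.51, -0.61],
        [-0.57, -0.56, -0.44, -0.48, -0.49],
        [-0.43, -0.54, -0.52, -0.57, -0.42, -0.41],
        [-0.42, -0.50, -0.45, -0.50, -0.40, -0.47, -0.58],
    ],
}

_UPL_COS = [
    [-0.06],
    [-0.21, -0.19],
    [-0.16, -0.13, -0.29],
    [-0.19, -0.16, -0.32, -0.26],
    [-0.11, -0.09, -0.25, -0.19, -0.22],
    [-0.23, -0.20, -0.36, -0.30, -0.33, -0.26],
    [-0.22, -0.19, -0.35, -0.30, -0.33, -0.25, -0.36],
]


def reference_profiles() -> list[OdorantProfile]:
    """All eight reference odorant profiles, in canonical order."""
    out = []
    for name in ODORANTS:
        m, rho, p0, ot, k_wf, c_ot, n, k_s = _CONSTANTS[name]
        out.append(OdorantProfile(
            name=name, molar_mass=m, density_liquid=rho, vapor_pressure=p0,
            odor_threshold_lit=ot,
            wf=WeberFechnerLaw(k_wf=k_wf, c_ot=c_ot),
            stevens=StevensLaw(k_s=k_s, n=n),
        ))
    return out


def reference_profile(name: str) -> OdorantProfile:
    """Look up a single reference odorant by name."""
    for p in reference_profiles():
        if p.name == name:
            return p
    raise KeyError(f"unknown odorant {name!r}; known: {', '.join(ODORANTS)}")


def _triangle_to_matrix(model: str, triangle, oi_level=None) -> InteractionMatrix:
    pairs = {}
    for i, row in enumerate(triangle, start=1):
        for j, cos in enumerate(row):
            pairs[(ODORANTS[i], ODORANTS[j])] = cos
    return InteractionMatrix.from_pairs(model, pairs, oi_level=oi_level,
                                        odorants=ODORANTS)


def reference_cos_matrix(model: str, oi_level: int | None = None) -> InteractionMatrix:
    """Published interaction-coefficient matrix for a model.

    ``oi_level`` (1 or 2) selects the sensory design level for the
    vectorial and U models; the UPL matrix is level-free.
    """
    if model == "vectorial":
        return _triangle_to_matrix("vectorial", _VECTORIAL_COS[oi_level], oi_level)
    if model == "u":
        return _triangle_to_matrix("u", _U_COS[oi_level], oi_level)
    if model == "upl":
        if oi_level is not None:
            raise ValueError("the UPL coefficient table is level-free")
        return _triangle_to_matrix("upl", _UPL_COS)
    raise ValueError(f"unknown model {model!r}")
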
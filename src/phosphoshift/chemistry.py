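"""Forward chemistry of ³¹P chemical shifts.

Maps the biochemical state of a voxel — intracellular pH, the fraction of
ATP complexed with Mg²⁺ (fast two-site exchange between free ATP and MgATP),
and a dimensionless ionic-strength surrogate ("Ion") — to the chemical
shifts of Pi and the three ATP resonances, referenced to PCr at 0 ppm with
downfield = more positive ppm.  The closed-form inversions used
conventionally (modified Henderson–Hasselbalch for pH from the Pi–PCr
shift; the β-ATP line for the Mg-bound fraction) live here too.

Model
-----
Pi follows a titration curve between its protonated and deprotonated
limits::

    δPi(pH) = δ_acid + (δ_base − δ_acid) / (1 + 10^(pKa − pH))
              [+ c_ion,Pi · (Ion − Ion_ref)]

Each ATP resonance k ∈ {γ, α, β} mixes linearly between its free-ATP and
MgATP endpoint shifts and carries linearized pH and ionic-strength
sensitivities::

    δ_k = δ_free,k + m · (δ_Mg,k − δ_free,k)
          + c_pH,k · (pH − pH_ref) + c_ion,k · (Ion − Ion_ref)

where m is the MgATP-bound fraction.  All constants are configurable; the
defaults are literature-plausible values that respect the qualitative
sensitivity orderings (pH acts strongest on Pi and γ-ATP; Mg acts strongest
on β-ATP, then γ, then α; ionic strength acts on γ and β more than on α).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "ShiftConstants",
    "BiochemState",
    "pi_shift_from_ph",
    "ph_from_pi_shift",
    "atp_shifts_from_state",
    "mg_fraction_from_beta",
    "load_constants",
    "save_constants",
]

PH_MIN = 5.5
PH_MAX = 8.5


@dataclass(frozen=True)
class ShiftConstants:
    """Calibration constants of the forward shift model.

    Shifts are in ppm relative to PCr (downfield positive); ``ph_coef_*``
    are ppm per pH unit, ``ion_coef_*`` ppm per Ion unit.
    """

    pka: float = 6.77
    delta_acid_pi: float = 3.275   # protonated-Pi titration limit
    delta_base_pi: float = 5.685   # deprotonated-Pi titration limit
    delta_free_gamma: float = -2.72
    delta_free_alpha: float = -7.57
    delta_free_beta: float = -18.95
    delta_mg_gamma: float = -2.48
    delta_mg_alpha: float = -7.52
    delta_mg_beta: float = -16.15
    ph_coef_gamma: float = 0.30
    ph_coef_alpha: float = 0.05
    ph_coef_beta: float = 0.15
    # The Ion surrogate has no absolute scale, so the coefficient
    # magnitudes fix its units; they are chosen so that one look-up grid
    # step of each state variable moves the shift signature comparably
    # (identifiability), with γ and β far more ion-sensitive than α.
    ion_coef_gamma: float = 1.00
    ion_coef_alpha: float = 0.10
    ion_coef_beta: float = 0.30
    ion_coef_pi: float = 0.10
    ph_ref: float = 7.0
    ion_ref: float = 0.15

    def __post_init__(self) -> None:
        if not self.delta_base_pi > self.delta_acid_pi:
            raise ValueError(
                "delta_base_pi must exceed delta_acid_pi "
                "(deprotonation shifts Pi downfield)"
            )
        ph_mags = [abs(self.ph_coef_gamma), abs(self.ph_coef_beta), abs(self.ph_coef_alpha)]
        if not (ph_mags[0] >= ph_mags[1] >= ph_mags[2]):
            raise ValueError("pH sensitivity must order as |γ| ≥ |β| ≥ |α|")
        mg_spans = [
            abs(self.delta_mg_beta - self.delta_free_beta),
            abs(self.delta_mg_gamma - self.delta_free_gamma),
            abs(self.delta_mg_alpha - self.delta_free_alpha),
        ]
        if not (mg_spans[0] >= mg_spans[1] >= mg_spans[2]):
            raise ValueError("Mg sensitivity must order as |β| ≥ |γ| ≥ |α|")
        if not (abs(self.ion_coef_gamma) > abs(self.ion_coef_alpha)
                and abs(self.ion_coef_beta) > abs(self.ion_coef_alpha)):
            raise ValueError("ionic-strength sensitivity of γ and β must exceed α")

    def fingerprint(self) -> str:
        """Stable hex digest identifying this constant set."""
        import hashlib

        payload = ",".join(f"{k}={v!r}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class BiochemState:
    """Per-voxel biochemical ground truth / estimate.

    ``mg_fraction`` is the MgATP-bound fraction in [0, 1]; ``ion`` the
    dimensionless ionic-strength surrogate (≥ 0).
    """

    ph: float
    mg_fraction: float
    ion: float = 0.15

    def __post_init__(self) -> None:
        if not (PH_MIN <= self.ph <= PH_MAX):
            raise ValueError(f"ph = {self.ph} outside valid range [{PH_MIN}, {PH_MAX}]")
        if not (0.0 <= self.mg_fraction <= 1.0):
            raise ValueError(f"mg_fraction = {self.mg_fraction} outside [0, 1]")
        if self.ion < 0:
            raise ValueError(f"ion = {self.ion} must be ≥ 0")


def _check_ph(ph: float) -> None:
    if ph < PH_MIN:
        raise ValueError(f"ph = {ph} below lower bound {PH_MIN}")
    if ph > PH_MAX:
        raise ValueError(f"ph = {ph} above upper bound {PH_MAX}")


def pi_shift_from_ph(
    ph: float,
    constants: ShiftConstants = ShiftConstants(),
    ion: float | None = None,
) -> float:
    """Pi chemical shift (ppm rel. PCr) from pH via the modified
    Henderson–Hasselbalch titration curve.

    When ``ion`` is supplied, the linear ionic-strength correction
    ``ion_coef_pi · (ion − ion_ref)`` is added.  Strictly increasing in pH.
    """
    _check_ph(ph)
    c = constants
    delta = c.delta_acid_pi + (c.delta_base_pi - c.delta_acid_pi) / (
        1.0 + 10.0 ** (c.pka - ph)
    )
    if ion is not None:
        delta += c.ion_coef_pi * (ion - c.ion_ref)
    return delta


def ph_from_pi_shift(
    delta_pi: float,
    constants: ShiftConstants = ShiftConstants(),
    ion: float | None = None,
) -> float:
    """Exact algebraic inverse of :func:`pi_shift_from_ph`.

    Raises ``ValueError`` when the (ion-corrected) shift lies at or outside
    the titration limits — such a shift is unphysical under the model.
    """
    c = constants
    d = delta_pi
    if ion is not None:
        d -= c.ion_coef_pi * (ion - c.ion_ref)
    if not (c.delta_acid_pi < d < c.delta_base_pi):
        raise ValueError(
            f"Pi shift {d:.4f} ppm outside open titration interval "
            f"({c.delta_acid_pi}, {c.delta_base_pi})"
        )
    return c.pka + math.log10((d - c.delta_acid_pi) / (c.delta_base_pi - d))


def atp_shifts_from_state(
    state: BiochemState,
    constants: ShiftConstants = ShiftConstants(),
) -> tuple[float, float, float]:
    """(δγ, δα, δβ) in ppm rel. PCr from a biochemical state.

    Two-site fast-exchange linear mixing between free-ATP and MgATP
    endpoints plus linearized pH and ionic-strength terms; each shift is
    affine in each state variable.
    """
    c = constants
    m = state.mg_fraction
    dph = state.ph - c.ph_ref
    dion = state.ion - c.ion_ref
    gamma = c.delta_free_gamma + m * (c.delta_mg_gamma - c.delta_free_gamma) \
        + c.ph_coef_gamma * dph + c.ion_coef_gamma * dion
    alpha = c.delta_free_alpha + m * (c.delta_mg_alpha - c.delta_free_alpha) \
        + c.ph_coef_alpha * dph + c.ion_coef_alpha * dion
    beta = c.delta_free_beta + m * (c.delta_mg_beta - c.delta_free_beta) \
        + c.ph_coef_beta * dph + c.ion_coef_beta * dion
    return gamma, alpha, beta


def mg_fraction_from_beta(
    delta_beta: float,
    ph: float,
    ion: float,
    constants: ShiftConstants = ShiftConstants(),
    slack: float = 0.05,
) -> float:
    """MgATP-bound fraction from the β-ATP shift at known pH and Ion.

    Algebraic inverse of the β line of :func:`atp_shifts_from_state`.  An
    implied fraction within ``[−slack, 1 + slack]`` (noise tolerance) is
    clipped to [0, 1]; farther outside raises ``ValueError`` since the
    shift is then inconsistent with the constants.
    """
    c = constants
    span = c.delta_mg_beta - c.delta_free_beta
    m = (delta_beta - c.delta_free_beta
         - c.ph_coef_beta * (ph - c.ph_ref)
         - c.ion_coef_beta * (ion - c.ion_ref)) / span
    if m < -slack or m > 1.0 + slack:
        raise ValueError(
            f"implied Mg-bound fraction {m:.3f} far outside [0, 1]; "
            "β-ATP shift inconsistent with the supplied constants"
        )
    return min(1.0, max(0.0, m))


# -- plain-text key=value config ------------------------------------------

def save_constants(constants: ShiftConstants, path) -> None:
    """Write constants as a key=value file with unit comments."""
    lines = [
        "# Forward shift-model constants.",
        "# Shifts in ppm relative to PCr (downfield positive);",
        "# ph_coef_* in ppm per pH unit; ion_coef_* in ppm per Ion unit.",
    ]
    for key, value in asdict(constants).items():
        lines.append(f"{key} = {value!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_constants(path) -> ShiftConstants:
    """Read a key=value constants file written by :func:`save_constants`."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
    return ShiftConstants(**values)
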
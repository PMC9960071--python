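"""Physical constants used throughout the package.

Voltages cross the public interface in millivolts and concentrations in
millimolar; conversion to SI happens inside the closed-form equations.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Constants:
    """Immutable physical constants.

    Attributes
    ----------
    F : Faraday constant, C/mol.
    R : molar gas constant, J/(mol K).
    T_default : default absolute temperature, K (room temperature as used
        for oocyte recordings).
    e : elementary charge, C.
    """

    F: float = 96485.33212
    R: float = 8.314462618
    T_default: float = 293.0
    e: float = 1.602176634e-19

    def vt(self, T: float | None = None) -> float:
        """Thermal voltage RT/F in volts at temperature ``T`` (K)."""
        return self.R * (self.T_default if T is None else T) / self.F


CONST = Constants()

F = CONST.F
R = CONST.R
T_DEFAULT = CONST.T_default
E_CHARGE = CONST.e
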
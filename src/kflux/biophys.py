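"""Closed-form biophysical models.

Goldman–Hodgkin–Katz (GHK) constant-field flux, the GHK current ratio for
two external K+ concentrations, the inhibition form of the Hill equation,
the Boltzmann activation curve with a voltage-independent offset, and the
reversal-shift permeability ratio.

Unit conventions (fixed across the package):

* membrane potential ``vm`` in mV,
* concentrations in mM (= mol/m^3),
* permeability ``p`` in cm/s,
* temperature in K (default 293 K).

``ghk_flux`` returns a current *density* in A/cm^2 (outward positive).
Most consumers use only ratios of fluxes, for which the absolute scale
cancels; the single documented scale constant is the mM -> mol/cm^3
factor 1e-6 combined with P in cm/s.
"""

from __future__ import annotations

import numpy as np

from .constants import CONST

__all__ = [
    "ghk_flux",
    "ghk_current_ratio",
    "hill_inhibition",
    "boltzmann_offset",
    "permeability_ratio",
]

# below this reduced voltage u = Vm*F/RT the flux uses a 2nd-order series
_U_SERIES = 1e-4


def _reduced_voltage(vm_mV, T: float | None = None):
    """u = Vm F / RT with Vm given in mV."""
    return np.asarray(vm_mV, dtype=float) * 1e-3 / CONST.vt(T)


def ghk_flux(p_cm_s, ki_mM, ko_mM, vm_mV, T: float | None = None):
    """GHK flux-equation current density for a monovalent cation (K+).

    I = P (Vm F^2 / RT) [Ki - Ko exp(-u)] / [1 - exp(-u)],  u = Vm F / RT.

    Parameters
    ----------
    p_cm_s : absolute permeability, cm/s (>= 0).
    ki_mM, ko_mM : internal / external concentrations, mM (Ki > 0, Ko >= 0).
    vm_mV : membrane potential, mV. Scalar or array.
    T : temperature in K; defaults to 293 K.

    Returns
    -------
    Current density in A/cm^2, outward positive.  Finite for all ``vm_mV``
    including 0, where the series limit is P F (Ki - Ko).  Crosses zero at
    the Nernst potential (RT/F) ln(Ko/Ki) when Ko > 0.
    """
    p = np.asarray(p_cm_s, dtype=float)
    ki = np.asarray(ki_mM, dtype=float)
    ko = np.asarray(ko_mM, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(ki))
            and np.all(np.isfinite(ko))):
        raise ValueError("non-finite GHK parameters")
    if np.any(ki <= 0) or np.any(ko < 0) or np.any(p < 0):
        raise ValueError("require Ki > 0, Ko >= 0, P >= 0")
    vm = np.asarray(vm_mV, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise ValueError("non-finite membrane potential")
    u = _reduced_voltage(vm, T)
    # mM -> mol/cm^3 so that P [cm/s] * c [mol/cm^3] * F [C/mol] is A/cm^2
    ki_c = ki * 1e-6
    ko_c = ko * 1e-6
    with np.errstate(over="ignore", invalid="ignore"):
        num = u * (ki_c - ko_c * np.exp(-u))
        den = -np.expm1(-u)
        full = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
    # 2nd-order expansion of u (Ki - Ko e^-u)/(1 - e^-u) around u = 0
    series = (ki_c - ko_c) + u * (ki_c + ko_c) / 2.0 + u**2 * (ki_c - ko_c) / 12.0
    bracket = np.where(np.abs(u) < _U_SERIES, series, full)
    out = p * CONST.F * bracket
    return out if out.ndim else float(out)


def ghk_current_ratio(kin1_mM, ko1_mM, kin2_mM, ko2_mM, vm_mV,
                      T: float | None = None):
    """Ratio of GHK currents in two ionic conditions at equal P and Vm.

    Ic1/Ic2 = [Kin(C1) - Ko(C1) exp(-u)] / [Kin(C2) - Ko(C2) exp(-u)].

    Used as the theoretical driving-force correction Ith for dose-response
    data: with equal internal K+ the ratio depends only on the two external
    concentrations.  Raises on a degenerate (zero) denominator bracket.
    """
    u = _reduced_voltage(vm_mV, T)
    e = np.exp(-u)
    num = np.asarray(kin1_mM, dtype=float) - np.asarray(ko1_mM, dtype=float) * e
    den = np.asarray(kin2_mM, dtype=float) - np.asarray(ko2_mM, dtype=float) * e
    if np.any(den == 0.0):
        raise ZeroDivisionError("degenerate GHK ratio: denominator bracket is zero")
    out = num / den
    return out if np.ndim(out) else float(out)


def hill_inhibition(c_mM, imax, ic50_mM, nh):
    """Hill equation, inhibition form.

    I(C) = (1 - Imax) + Imax / (1 + (C/IC50)^nH)

    ``I`` is the current remaining at blocker concentration ``C`` as a
    fraction of the unblocked current: I(0) = 1, I(inf) = 1 - Imax.
    Monotone non-increasing in C for valid parameters.
    """
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if ic50_mM <= 0 or nh <= 0:
        raise ValueError("require IC50 > 0 and nH > 0")
    if not 0.0 <= imax <= 1.0:
        raise ValueError("Imax must lie in [0, 1]")
    out = (1.0 - imax) + imax / (1.0 + (c / ic50_mM) ** nh)
    return out if out.ndim else float(out)


def boltzmann_offset(v_mV, vhalf_mV, z, gmin, T: float | None = None):
    """Boltzmann activation curve with a voltage-independent offset.

    G/Gmax = (1 - Gmin) / {1 + exp[(V1/2 - V) Z F / RT]} + Gmin

    ``z`` is the equivalent gating charge in elementary charges; ``gmin``
    the voltage-independent conductance fraction (horizontal asymptote at
    hyperpolarized voltages).
    """
    if not 0.0 <= gmin < 1.0:
        raise ValueError("Gmin must lie in [0, 1)")
    v = np.asarray(v_mV, dtype=float)
    x = (vhalf_mV - v) * 1e-3 * z / CONST.vt(T)
    with np.errstate(over="ignore"):  # exp overflow -> exact asymptote
        out = (1.0 - gmin) / (1.0 + np.exp(x)) + gmin
    return out if out.ndim else float(out)


def permeability_ratio(delta_erev_mV, z=1.0, T: float | None = None):
    """Permeability ratio P_X/P_K from a reversal-potential shift.

    P_X/P_K = exp(dErev Z F / RT), with dErev the mean reversal-potential
    shift (mV) upon exchanging the extracellular cation.  dErev = 0 gives 1;
    the function is antisymmetric in dErev under inversion of the ratio.
    """
    d = np.asarray(delta_erev_mV, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite reversal shift")
    out = np.exp(d * 1e-3 * z / CONST.vt(T))
    return out if out.ndim else float(out)


def nernst_potential(ki_mM, ko_mM, T: float | None = None) -> float:
    """Nernst equilibrium potential (mV) for a monovalent cation."""
    if ki_mM <= 0 or ko_mM <= 0:
        raise ValueError("concentrations must be positive")
    return 1e3 * CONST.vt(T) * float(np.log(ko_mM / ki_mM))
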
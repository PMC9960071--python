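"""Least-squares model fitting with a statsmodels-flavoured Model/Results API.

Each model class is built from data, ``fit()`` returns a results object
carrying parameter estimates, standard errors (from the Jacobian-based
covariance), residual diagnostics and a ``summary()`` table.  Convenience
wrappers (:func:`fit_hill`, :func:`fit_ghk_permeability`,
:func:`fit_boltzmann`) mirror the procedural interface.

Fitting engine: scipy's trust-region-reflective least squares (through
``curve_fit``) with heuristic starting values.  The reported optimum is the
first converged local optimum from the heuristic start.  Non-convergence is
flagged on the results object, never raised.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import biophys
from .constants import T_DEFAULT

__all__ = [
    "CurveFitResults",
    "HillModel",
    "GHKPermeabilityModel",
    "BoltzmannGVModel",
    "fit_hill",
    "fit_ghk_permeability",
    "fit_boltzmann",
]


class CurveFitResults:
    """Results of a nonlinear least-squares curve fit.

    Attributes
    ----------
    params : ndarray of fitted parameters (order given by ``param_names``).
    bse : per-parameter standard errors from the covariance matrix
        (non-negative; ``inf`` where the parameter is not identified).
    ssr : sum of squared residuals.
    converged : whether the optimizer reported success.
    nobs : number of data points.
    """

    def __init__(self, model, params, cov, ssr, converged):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov = cov
        with np.errstate(invalid="ignore"):
            self.bse = (np.sqrt(np.diag(cov)) if cov is not None
                        else np.full_like(self.params, np.inf))
        self.bse = np.where(np.isfinite(self.bse), self.bse, np.inf)
        self.ssr = float(ssr)
        self.converged = bool(converged)
        self.nobs = int(model.nobs)

    @property
    def param_names(self) -> list[str]:
        return list(self.model.param_names)

    @property
    def identifiable(self) -> bool:
        """False when any standard error is non-finite or dwarfs its estimate.

        A parameter counts as undetermined when its standard error exceeds
        five times its own magnitude (with a floor relative to the largest
        parameter so exact zeros are not penalized).
        """
        if not np.all(np.isfinite(self.bse)):
            return False
        floor = 1e-3 * np.max(np.abs(self.params)) + 1e-12
        scale = np.maximum(np.abs(self.params), floor)
        return bool(np.all(self.bse < 5.0 * scale))

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.bse[self.param_names.index(name)])

    def predict(self, x=None):
        return self.model.predict(self.params, x)

    @property
    def resid(self):
        return self.model.y - self.predict()

    def to_dict(self) -> dict:
        d = {n: float(v) for n, v in zip(self.param_names, self.params)}
        d.update({f"{n}_stderr": float(s)
                  for n, s in zip(self.param_names, self.bse)})
        d.update(ssr=self.ssr, converged=self.converged, n_points=self.nobs,
                 identifiable=self.identifiable)
        return d

    def plot(self, ax=None, n_grid: int = 200):
        """Plot the data and the fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = self.model.x
        ax.plot(x, self.model.y, "o", label="data")
        grid = np.linspace(x.min(), x.max(), n_grid)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} fit  "
                 f"(n={self.nobs}, converged={self.converged}, "
                 f"ssr={self.ssr:.4g})",
                 f"{'param':>12} {'estimate':>14} {'std err':>12}"]
        for n, v, s in zip(self.param_names, self.params, self.bse):
            lines.append(f"{n:>12} {v:>14.6g} {s:>12.4g}")
        if not self.identifiable:
            lines.append("warning: one or more parameters are not identified "
                         "by the data")
        return "\n".join(lines)


class _CurveModel:
    """Base for 1-D curve models fit by trust-region least squares."""

    param_names: Sequence[str] = ()

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite data")
        self.x, self.y = x, y
        self.nobs = x.size

    # subclasses implement
    def _func(self, x, *params):  # pragma: no cover - abstract
        raise NotImplementedError

    def start_params(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def bounds(self):
        k = len(self.param_names)
        return (np.full(k, -np.inf), np.full(k, np.inf))

    def predict(self, params, x=None):
        x = self.x if x is None else np.asarray(x, dtype=float)
        return self._func(x, *params)

    def fit(self, start_params=None, maxfev: int = 10000) -> CurveFitResults:
        p0 = np.asarray(self.start_params() if start_params is None
                        else start_params, dtype=float)
        lo, hi = self.bounds()
        p0 = np.clip(p0, lo, hi)
        try:
            popt, pcov = curve_fit(self._func, self.x, self.y, p0=p0,
                                   bounds=(lo, hi), maxfev=maxfev,
                                   method="trf")
            converged = True
        except RuntimeError:
            popt, pcov, converged = p0, None, False
        resid = self.y - self._func(self.x, *popt)
        return CurveFitResults(self, popt, pcov, float(resid @ resid), converged)


class HillModel(_CurveModel):
    """Hill inhibition curve fitted to (concentration, normalized current).

    Parameters are ``imax`` (maximal fractional inhibition, in [0, 1]),
    ``ic50`` (mM, > 0) and ``nh`` (Hill coefficient, > 0).  Requires at
    least 4 distinct concentrations.  Starting IC50 is the geometric middle
    of the concentration range (zero concentrations excluded).
    """

    param_names = ("imax", "ic50", "nh")

    def __init__(self, conc_mM, response):
        super().__init__(conc_mM, response)
        if np.any(self.x < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.x).size < 4:
            raise ValueError("need >= 4 distinct concentrations")

    def _func(self, c, imax, ic50, nh):
        return (1.0 - imax) + imax / (1.0 + (c / ic50) ** nh)

    def start_params(self):
        pos = self.x[self.x > 0]
        ic50 = float(np.sqrt(pos.min() * pos.max())) if pos.size else 1.0
        imax = float(np.clip(1.0 - self.y.min(), 1e-3, 1.0))
        return np.array([imax, ic50, 1.0])

    def bounds(self):
        return (np.array([0.0, 1e-12, 1e-3]), np.array([1.0, np.inf, 20.0]))


class GHKPermeabilityModel:
    """Absolute permeability from a current–voltage relation via the GHK
    flux equation.

    The GHK current is linear in P, so the least-squares estimate is the
    closed-form regression through the origin of current on the GHK shape
    function g(V) = I(P=1; V, Ki, Ko, T):

        P_hat = sum(g i) / sum(g^2),  Var(P_hat) = s^2 / sum(g^2).

    Currents must be in the same density convention as
    :func:`kflux.biophys.ghk_flux` up to a common scale; a known ``scale``
    (e.g. an effective area converting density to pA) may be supplied and
    divides out of the estimate.
    """

    param_names = ("p_cm_per_s",)

    def __init__(self, vm_mV, current, ki_mM, ko_mM, T: float = T_DEFAULT,
                 scale: float = 1.0):
        vm = np.asarray(vm_mV, dtype=float)
        i = np.asarray(current, dtype=float)
        if vm.shape != i.shape or vm.ndim != 1:
            raise ValueError("vm and current must be 1-D arrays of equal length")
        if vm.size < 3:
            raise ValueError("need >= 3 voltages")
        if np.all(i == 0.0):
            raise ValueError("all-zero currents carry no permeability information")
        self.x, self.y = vm, i
        self.ki, self.ko, self.T, self.scale = ki_mM, ko_mM, T, scale
        self.nobs = vm.size

    def _shape(self, vm):
        return self.scale * np.asarray(
            biophys.ghk_flux(1.0, self.ki, self.ko, vm, self.T))

    def predict(self, params, x=None):
        vm = self.x if x is None else np.asarray(x, dtype=float)
        return float(params[0]) * self._shape(vm)

    def fit(self) -> CurveFitResults:
        g = self._shape(self.x)
        sgg = float(g @ g)
        p_hat = float(g @ self.y) / sgg
        resid = self.y - p_hat * g
        ssr = float(resid @ resid)
        dof = max(self.nobs - 1, 1)
        cov = np.array([[ssr / dof / sgg]])
        return CurveFitResults(self, [p_hat], cov, ssr, True)


class BoltzmannGVModel(_CurveModel):
    """Boltzmann-with-offset fit to conductance–voltage data.

    Parameters: ``vhalf`` (mV), ``z`` (equivalent gating charge, e) and
    ``gmin`` (voltage-independent conductance fraction in [0, 1)).  ``z``
    is free by default and may be fixed with ``fix_z``; ``gmin`` likewise
    with ``fix_gmin`` (0 gives the plain Boltzmann).  Requires >= 5
    voltages.
    """

    def __init__(self, v_mV, g_norm, T: float = T_DEFAULT,
                 fix_z: float | None = None, fix_gmin: float | None = None):
        super().__init__(v_mV, g_norm)
        if self.nobs < 5:
            raise ValueError("need >= 5 voltages")
        self.T = T
        self.fix_z = fix_z
        self.fix_gmin = fix_gmin
        names = ["vhalf"]
        if fix_z is None:
            names.append("z")
        if fix_gmin is None:
            names.append("gmin")
        self.param_names = tuple(names)

    def _unpack(self, params):
        it = iter(params)
        vhalf = next(it)
        z = self.fix_z if self.fix_z is not None else next(it)
        gmin = self.fix_gmin if self.fix_gmin is not None else next(it)
        return vhalf, z, gmin

    def _func(self, v, *params):
        vhalf, z, gmin = self._unpack(params)
        return biophys.boltzmann_offset(v, vhalf, z, gmin, self.T)

    def start_params(self):
        gmin0 = float(np.clip(self.y.min(), 0.0, 0.9))
        half = gmin0 + (self.y.max() - gmin0) / 2.0
        idx = int(np.argmin(np.abs(self.y - half)))
        p = [float(self.x[idx])]
        if self.fix_z is None:
            p.append(2.0)
        if self.fix_gmin is None:
            p.append(gmin0)
        return np.array(p)

    def bounds(self):
        lo, hi = [-np.inf], [np.inf]
        if self.fix_z is None:
            lo.append(1e-3), hi.append(20.0)
        if self.fix_gmin is None:
            lo.append(0.0), hi.append(1.0 - 1e-9)
        return (np.array(lo), np.array(hi))


def fit_hill(conc_mM, response) -> CurveFitResults:
    """Fit the Hill inhibition equation; see :class:`HillModel`."""
    return HillModel(conc_mM, response).fit()


def fit_ghk_permeability(vm_mV, current, ki_mM, ko_mM, T: float = T_DEFAULT,
                         scale: float = 1.0) -> CurveFitResults:
    """Fit absolute permeability by GHK; see :class:`GHKPermeabilityModel`."""
    return GHKPermeabilityModel(vm_mV, current, ki_mM, ko_mM, T, scale).fit()


def fit_boltzmann(v_mV, g_norm, T: float = T_DEFAULT,
                  fix_z: float | None = None,
                  fix_gmin: float | None = None) -> CurveFitResults:
    """Fit a Boltzmann-with-offset G-V curve; see :class:`BoltzmannGVModel`."""
    return BoltzmannGVModel(v_mV, g_norm, T, fix_z, fix_gmin).fit()
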
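"""Mass-action ODE model of the AbyU catalytic cycle.

Species (all concentrations in uM):

====  =====================================================
E     free enzyme
S     free substrate (linear triene, absorbs at 325 nm)
ES    productive enzyme-substrate conformation
ES2   sub-optimal conformation, rearranges to ES
ES3   non-productive dead-end conformation
EP    enzyme-product complex (cyclised, awaiting release)
P     free product (spirotetronate)
====  =====================================================

Elementary steps::

    E + S <-> ES    (k1 / k1r)
    E + S <-> ES2   (k2 / k2r)
    E + S <-> ES3   (k3 / k3r)
    ES2   <-> ES    (k4 / k4r)
    ES     -> EP    (k5)
    EP     -> E + P (k6)
    S      -> P     (kspont, uncatalysed background cyclisation)

Two conservation laws hold exactly: total enzyme E + ES + ES2 + ES3 + EP
and total ligand S + ES + ES2 + ES3 + EP + P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import OpticalModel, RateConstants, derived_constants
from .transient import Transient

__all__ = [
    "SPECIES",
    "SimulationError",
    "Trajectory",
    "build_odes",
    "build_jacobian",
    "simulate_scheme",
    "trajectory_to_absorbance",
    "derived_constants",
]

SPECIES = ("E", "S", "ES", "ES2", "ES3", "EP", "P")
_E, _S, _ES, _ES2, _ES3, _EP, _P = range(7)


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries solver diagnostics."""


def _spont_rate(rc: RateConstants, S: float | np.ndarray):
    return rc.kspont * S * S if rc.spont_second_order else rc.kspont * S


def build_odes(rc: RateConstants):
    """Return the mass-action right-hand side f(t, y) for the scheme.

    ``y`` is ordered as :data:`SPECIES`.  The free-enzyme derivative is
    written so that the enzyme-containing derivatives sum to zero exactly
    (conservation by construction).
    """
    if not isinstance(rc, RateConstants):
        rc = RateConstants(**rc)  # validates

    def rhs(t, y):
        E, S, ES, ES2, ES3, EP, P = y
        bind = E * S
        spont = _spont_rate(rc, S)
        dES = rc.k1 * bind - rc.k1r * ES + rc.k4 * ES2 - rc.k4r * ES - rc.k5 * ES
        dES2 = rc.k2 * bind - rc.k2r * ES2 - rc.k4 * ES2 + rc.k4r * ES
        dES3 = rc.k3 * bind - rc.k3r * ES3
        dEP = rc.k5 * ES - rc.k6 * EP
        dP = rc.k6 * EP + spont
        dS = (
            -(rc.k1 + rc.k2 + rc.k3) * bind
            + rc.k1r * ES + rc.k2r * ES2 + rc.k3r * ES3
            - spont
        )
        dE = -(dES + dES2 + dES3 + dEP)
        return np.array([dE, dS, dES, dES2, dES3, dEP, dP])

    return rhs


def build_jacobian(rc: RateConstants):
    """Analytic Jacobian of :func:`build_odes`, for the implicit integrator."""

    def jac(t, y):
        E, S = y[_E], y[_S]
        ksum = rc.k1 + rc.k2 + rc.k3
        dspont_dS = 2.0 * rc.kspont * S if rc.spont_second_order else rc.kspont
        J = np.zeros((7, 7))
        # dES/dt
        J[_ES, _E] = rc.k1 * S
        J[_ES, _S] = rc.k1 * E
        J[_ES, _ES] = -(rc.k1r + rc.k4r + rc.k5)
        J[_ES, _ES2] = rc.k4
        # dES2/dt
        J[_ES2, _E] = rc.k2 * S
        J[_ES2, _S] = rc.k2 * E
        J[_ES2, _ES] = rc.k4r
        J[_ES2, _ES2] = -(rc.k2r + rc.k4)
        # dES3/dt
        J[_ES3, _E] = rc.k3 * S
        J[_ES3, _S] = rc.k3 * E
        J[_ES3, _ES3] = -rc.k3r
        # dEP/dt
        J[_EP, _ES] = rc.k5
        J[_EP, _EP] = -rc.k6
        # dP/dt
        J[_P, _EP] = rc.k6
        J[_P, _S] = dspont_dS
        # dS/dt
        J[_S, _E] = -ksum * S
        J[_S, _S] = -ksum * E - dspont_dS
        J[_S, _ES] = rc.k1r
        J[_S, _ES2] = rc.k2r
        J[_S, _ES3] = rc.k3r
        # dE/dt balances the enzyme-containing rows
        J[_E] = -(J[_ES] + J[_ES2] + J[_ES3] + J[_EP])
        return J

    return jac


@dataclass
class Trajectory:
    """Time-resolved species concentrations from one integration.

    ``states`` has shape (n_times, 7) ordered as :data:`SPECIES`.
    """

    time: np.ndarray
    states: np.ndarray
    E0: float
    S0: float
    rc: RateConstants = field(repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.time.size, 7):
            raise ValueError("states must have shape (len(time), 7)")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def __getattr__(self, name):
        if name in SPECIES:
            return self.states[:, SPECIES.index(name)]
        raise AttributeError(name)

    def conservation_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """Relative enzyme- and ligand-conservation residuals per time point."""
        enz = self.states[:, [_E, _ES, _ES2, _ES3, _EP]].sum(axis=1)
        lig = self.states[:, [_S, _ES, _ES2, _ES3, _EP, _P]].sum(axis=1)
        enz_scale = max(self.E0, 1.0e-12)
        lig_scale = max(self.S0, 1.0e-12)
        return (enz - self.E0) / enz_scale, (lig - self.S0) / lig_scale

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_s", self.time)
        return df

    def to_csv(self, path: str | Path) -> None:
        """CSV with header ``time_s,E,S,ES,ES2,ES3,EP,P`` (uM)."""
        self.to_frame().to_csv(path, index=False)


def simulate_scheme(
    rc: RateConstants,
    E0: float,
    S0: float,
    time_grid: np.ndarray,
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the scheme from mixing (t = 0) and sample on ``time_grid``.

    The reaction starts at t = 0 with only free enzyme and free substrate
    present; ``time_grid`` may begin after zero (e.g. at the instrument
    dead time), in which case the integration still starts at t = 0.

    Uses a stiff-capable implicit integrator (LSODA by default, with the
    analytic Jacobian) at rtol 1e-8 / atol 1e-10 uM.  Raises
    :class:`SimulationError` with the solver message on failure; never
    returns silent NaNs.
    """
    if E0 < 0 or S0 < 0:
        raise ValueError(f"initial concentrations must be >= 0, got E0={E0}, S0={S0}")
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time_grid must be a non-empty 1-d array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if t[0] < 0:
        raise ValueError("time_grid must be non-negative")

    y0 = np.zeros(7)
    y0[_E], y0[_S] = E0, S0
    rhs = build_odes(rc)
    jac = build_jacobian(rc)
    t_end = float(t[-1])
    sol = solve_ivp(
        rhs,
        (0.0, t_end if t_end > 0 else 1.0e-12),
        y0,
        method=method,
        t_eval=t,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed (method={method}, E0={E0} uM, S0={S0} uM): "
            f"{sol.message}"
        )
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise SimulationError("integrator returned non-finite concentrations")
    return Trajectory(time=t, states=states, E0=E0, S0=S0, rc=rc)


def trajectory_to_absorbance(traj: Trajectory, om: OpticalModel) -> Transient:
    """Project a trajectory onto 325 nm absorbance (noiseless).

    A(t) = path * [eps_substrate * (S + ES + ES2 + ES3)
                   + eps_product * (EP + P)] * 1e-6

    Bound uncyclised substrate absorbs as free substrate; the cyclised
    chromophore (in EP or free P) absorbs as product.  The 1e-6 factor
    converts uM to M.
    """
    uncyclised = traj.states[:, [_S, _ES, _ES2, _ES3]].sum(axis=1)
    cyclised = traj.states[:, [_EP, _P]].sum(axis=1)
    absorbance = (
        om.path_length
        * (om.eps_substrate * uncyclised + om.eps_product * cyclised)
        * 1.0e-6
    )
    meta = {
        "E0": traj.E0,
        "S0": traj.S0,
        "optical": om.to_dict(),
        "rate_constants": traj.rc.to_dict(),
        "noiseless": True,
    }
    return Transient(traj.time.copy(), absorbance, meta)
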
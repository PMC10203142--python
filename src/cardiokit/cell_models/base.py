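"""Common infrastructure for cardiac ionic membrane models.

Every model advances a transmembrane potential ``v`` and an ionic state
vector ``s`` (gates, concentrations, release-machinery variables) according
to  dv/dt = -(I_ion(v, s) - I_stim)/Cm  and  ds/dt = F(s, v).  Models are
vectorized: ``v`` may be a scalar or an array of shape ``(n,)`` and ``s`` an
array of shape ``(n_states, n)``, so the same right-hand side serves both
single-cell studies and tissue solves.

Units: potentials in mV, time in ms, currents per unit membrane capacitance
(mV/ms once divided by Cm).  The minimal phenomenological model is
dimensionless in ``v`` and carries its own time scale (see ``minimal.py``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellState", "IonicModel", "ionic_rhs", "step_cell",
           "register_model", "get_model", "available_models"]


@dataclass
class CellState:
    """State of one membrane patch: potential, ionic vector, active tension.

    ``v`` is the transmembrane potential (mV; dimensionless for the minimal
    model), ``s`` the model-specific ionic state vector, ``Ta`` the active
    tension (kPa) driven by the excitation.
    """

    v: float
    s: np.ndarray
    Ta: float = 0.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.isfinite(self.v):
            raise ValueError("transmembrane potential must be finite")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("ionic state vector must be finite")

    def copy(self) -> "CellState":
        return CellState(self.v, self.s.copy(), self.Ta)


class IonicModel:
    """Base class: subclasses define ``state_names``, ``gate_idx``, ``rates``.

    ``gate_idx`` lists the indices of Hodgkin–Huxley gating variables inside
    ``s`` (those confined to [0, 1] and integrable by the Rush–Larsen
    exponential rule).  ``rates`` returns the full right-hand side plus, for
    the gates, the steady-state/time-constant pair used by that rule.
    """

    name: str = "base"
    state_names: tuple = ()
    gate_idx: tuple = ()
    #: membrane capacitance per unit area, uF/mm^2 (model convention)
    Cm: float = 0.01
    #: surface-to-volume ratio of cells, 1/mm
    chi: float = 140.0
    #: resting potential and ionic vector (fixed point of the rhs)
    rest_v: float = 0.0
    rest_s: tuple = ()
    #: recommended explicit time step, ms
    dt_default: float = 0.02
    #: upstroke threshold used for activation-time detection, mV
    activation_threshold: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def rest_state(self) -> CellState:
        return CellState(self.rest_v, np.array(self.rest_s, dtype=float))

    # -- interface ---------------------------------------------------------
    def rates(self, v, s, I_stim=0.0):
        """Return ``(dv, ds, gate_inf, gate_tau)``.

        ``gate_inf``/``gate_tau`` have one row per entry of ``gate_idx``
        (empty arrays when the model has no gates); they are redundant with
        ``ds`` but let the integrator apply the exponential gating update
        without recomputing the voltage-dependent rate functions.
        """
        raise NotImplementedError

    def rhs(self, v, s, I_stim=0.0):
        """Time-derivatives ``(dv/dt, ds/dt)`` only."""
        dv, ds, _, _ = self.rates(v, s, I_stim)
        return dv, ds

    # -- helpers -----------------------------------------------------------
    def _check_state(self, v, s):
        s = np.asarray(s, dtype=float)
        if s.shape[0] != self.n_states:
            raise ValueError(
                f"{self.name}: state vector has {s.shape[0]} entries, "
                f"model defines {self.n_states}")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(s))):
            raise ValueError(f"{self.name}: non-finite state")
        return s


def ionic_rhs(model: IonicModel, state: CellState, t: float = 0.0,
              I_stim: float = 0.0):
    """Time-derivatives of (v, s) for one cell at time ``t``.

    ``I_stim`` is the stimulus current already divided by nothing: it enters
    as +I_stim/Cm in dv/dt, with Cm the model's membrane capacitance.  All
    registered models are autonomous, so ``t`` only documents the call site.
    """
    s = model._check_state(state.v, state.s)
    dv, ds = model.rhs(np.asarray(state.v, dtype=float), s, I_stim=I_stim)
    return dv, ds


def step_cell(model: IonicModel, state: CellState, dt: float,
              I_stim: float = 0.0) -> CellState:
    """Advance one cell by ``dt`` (ms).

    Gating variables use the Rush–Larsen exponential update
    ``x <- x_inf + (x - x_inf) exp(-dt/tau)``; all other states and the
    potential use forward Euler.  Gates that step outside [0, 1] (possible
    only through floating-point round-off or an oversized dt) are clamped
    with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = model._check_state(state.v, state.s).copy()
    v = float(state.v)
    dv, ds, g_inf, g_tau = model.rates(np.float64(v), s, I_stim=I_stim)
    new_s = s + dt * ds
    if len(model.gate_idx):
        idx = np.asarray(model.gate_idx)
        new_s[idx] = g_inf + (s[idx] - g_inf) * np.exp(-dt / g_tau)
        if np.any(new_s[idx] < -1e-12) or np.any(new_s[idx] > 1 + 1e-12):
            warnings.warn(f"{model.name}: gating variable left [0,1] at "
                          f"dt={dt}; clamping", RuntimeWarning)
        np.clip(new_s[idx], 0.0, 1.0, out=new_s[idx])
    return CellState(v + dt * float(dv), new_s, state.Ta)


# ---------------------------------------------------------------------------
# model registry (addressable by name from JSON run configurations)
# ---------------------------------------------------------------------------
_REGISTRY: dict = {}


def register_model(cls) -> type:
    _REGISTRY[cls.name] = cls
    for alias in getattr(cls, "aliases", ()):
        _REGISTRY[alias] = cls
    return cls


def get_model(name: str, **params) -> IonicModel:
    """Instantiate a registered ionic model by name (e.g. ``"minimal"``,
    ``"courtemanche"``, ``"tentusscher_panfilov"``, ``"stewart"``)."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown ionic model {name!r}; "
                       f"available: {sorted(set(_REGISTRY))}") from None
    return cls(**params)


def available_models() -> list:
    return sorted({cls.name for cls in _REGISTRY.values()})
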
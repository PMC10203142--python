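"""Nash–Panfilov active-tension kinetics.

The contractile stress Ta (kPa) generated along the muscle fibers follows
the excitation through a first-order relaxation toward k_Ta * v:

    dTa/dt = eps(v) * (k_Ta * v - Ta)

with v the transmembrane potential normalized to [0, 1] and eps(v) a
two-level switching rate: tension develops at rate ``eps_above`` once v
exceeds the threshold ``v_star`` and decays at ``eps_below`` during
repolarization (the development rate is the slower of the two so that
tension lags depolarization, as in the original formulation where
eps = 1 for v < 0.05 and 0.1 above).

Rates are per dimensionless excitation time unit; ``time_scale`` (ms per
unit, matching the minimal model) converts to 1/ms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NashPanfilovTension", "active_tension_rate"]


class NashPanfilovTension:
    """Parameters of the active-tension equation.

    k_Ta is the saturation tension (kPa) reached when v is held at 1.
    """

    def __init__(self, k_Ta: float = 47.9, eps_below: float = 1.0,
                 eps_above: float = 0.1, v_star: float = 0.05,
                 time_scale: float = 12.9):
        if k_Ta < 0:
            raise ValueError("tension gain k_Ta must be non-negative")
        if eps_below < 0 or eps_above < 0:
            raise ValueError("switching rates must be non-negative")
        self.k_Ta = float(k_Ta)
        self.eps_below = float(eps_below)
        self.eps_above = float(eps_above)
        self.v_star = float(v_star)
        self.time_scale = float(time_scale)

    def epsilon(self, v):
        return np.where(np.asarray(v) < self.v_star,
                        self.eps_below, self.eps_above)

    def rate(self, v, Ta):
        """dTa/dt in kPa/ms for normalized potential v."""
        return self.epsilon(v) * (self.k_Ta * v - Ta) / self.time_scale

    def step(self, v, Ta, dt):
        """Exact exponential update over dt (eps is frozen at v)."""
        eps = self.epsilon(v) / self.time_scale
        target = self.k_Ta * np.asarray(v)
        return target + (Ta - target) * np.exp(-eps * dt)


def active_tension_rate(v, Ta, params: NashPanfilovTension | None = None):
    """dTa/dt for normalized potential ``v`` and tension ``Ta`` (kPa)."""
    if params is None:
        params = NashPanfilovTension()
    return params.rate(v, Ta)
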
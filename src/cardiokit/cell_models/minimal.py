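"""Minimal two-variable phenomenological excitation model.

An Aliev–Panfilov-type polynomial model with a dimensionless potential
``v`` in [0, 1] and one recovery variable ``r``:

    dv/dt = k v (v - a)(1 - v) - v r + I
    dr/dt = (gamma + mu1 r / (mu2 + v)) (-r - k v (v - b - 1))

Both equations are stated in dimensionless time; the model carries a
``time_scale`` (ms per dimensionless unit, default 12.9) so the tissue and
coupling layers can treat it uniformly in milliseconds.  The rest point is
exactly (v, r) = (0, 0).

The model is registered alongside the biophysical ones so that every tissue
and organ fixture in the package can be exercised cheaply; its upstroke and
recovery are qualitatively cardiac (threshold ``a``, stiff upstroke ~k,
slow recovery ~gamma) but its potential is dimensionless.  The documented
affine rescaling to physical units is v_mV = 100*v - 85 (rest -85 mV,
peak ~+15 mV).
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel, register_model

__all__ = ["MinimalModel"]


@register_model
class MinimalModel(IonicModel):
    name = "minimal"
    aliases = ("aliev_panfilov",)
    state_names = ("r",)
    gate_idx = ()
    rest_v = 0.0
    rest_s = (0.0,)
    dt_default = 0.1
    activation_threshold = 0.5  # dimensionless v

    #: affine map to physical units: v_mV = v_scale*v + v_offset
    v_scale = 100.0
    v_offset = -85.0

    def __init__(self, k=8.0, a=0.15, b=0.15, gamma=0.002, mu1=0.2, mu2=0.3,
                 time_scale=12.9):
        if time_scale <= 0:
            raise ValueError("time_scale must be positive (ms per unit)")
        self.k, self.a, self.b = float(k), float(a), float(b)
        self.gamma, self.mu1, self.mu2 = float(gamma), float(mu1), float(mu2)
        self.time_scale = float(time_scale)
        self.params = dict(k=k, a=a, b=b, gamma=gamma, mu1=mu1, mu2=mu2,
                           time_scale=time_scale)

    #: dimensionless membrane "capacitance" so that I_stim enters dv/dt
    #: directly in 1/ms, matching the tissue-solver convention
    Cm = 1.0

    def rates(self, v, s, I_stim=0.0):
        r = s[0]
        k, a, b = self.k, self.a, self.b
        dv = k * v * (v - a) * (1.0 - v) - v * r
        dr = (self.gamma + self.mu1 * r / (self.mu2 + v)) \
            * (-r - k * v * (v - b - 1.0))
        ts = self.time_scale
        empty = np.empty((0,) + np.shape(v))
        return dv / ts + I_stim, np.asarray([dr]) / ts, empty, empty
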
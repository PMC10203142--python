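"""Single-cell diagnostics: action-potential duration."""

from __future__ import annotations

import numpy as np

__all__ = ["measure_apd"]


def measure_apd(t, v, level: float = 0.9) -> float:
    """Action-potential duration at repolarization fraction ``level`` (ms).

    The trace must contain one action potential.  The threshold is
    ``v_max - level * (v_max - v_min)`` (APD90 for level=0.9); the duration
    runs from the first upward to the last downward crossing, both located
    by linear interpolation between samples.

    Raises ``ValueError`` when the trace never crosses the threshold (e.g.
    it never depolarizes).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("t and v must be matching 1-D arrays")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    vmax, vmin = v.max(), v.min()
    if vmax == vmin:
        raise ValueError("flat trace: no action potential")
    thr = vmax - level * (vmax - vmin)
    above = v > thr
    if not above.any() or above.all():
        raise ValueError("trace does not cross the APD threshold")

    def _cross(i0, i1):
        # linear interpolation of the crossing between samples i0, i1
        f = (thr - v[i0]) / (v[i1] - v[i0])
        return t[i0] + f * (t[i1] - t[i0])

    up = np.where(~above[:-1] & above[1:])[0]
    down = np.where(above[:-1] & ~above[1:])[0]
    t_up = _cross(up[0], up[0] + 1) if up.size else t[0]
    t_down = _cross(down[-1], down[-1] + 1) if down.size else t[-1]
    if t_down <= t_up:
        raise ValueError("could not bracket one action potential")
    return float(t_down - t_up)
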
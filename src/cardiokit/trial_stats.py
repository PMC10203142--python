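"""Cohort-size and sampling-error calculators for in-silico clinical trials.

A virtual-patient study estimates quantities of interest (QoIs) from a cohort
of N simulated individuals.  The statistical error of the estimate depends on
the sampling strategy:

========== ============================= ========================================
method     error model                   notes
========== ============================= ========================================
MC         N**-0.5                       plain Monte Carlo moment estimation
LHS        C * N**-0.5                   variance reduction (Latin hypercube),
                                         constant C <= 1
QMC        N**-alpha                     quasi-random (low-discrepancy) sampling,
                                         alpha in [1/2, 1]
MC_RARE    (p*N)**-0.5                   plain MC estimation of a rare event of
                                         probability p
SUBSET     log10(1/p) / sqrt(N)          Subset Simulation for the same rare event
========== ============================= ========================================

These are error *models* (asymptotic convergence rates with unit prefactor
unless stated), not samplers: the module answers "how large a cohort do I
need", it does not draw the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SamplingModel", "sampling_error", "cohort_size", "error_table"]

_METHODS = ("MC", "LHS", "QMC", "SUBSET", "MC_RARE")


@dataclass(frozen=True)
class SamplingModel:
    """A sampling strategy together with the constants its error model needs.

    Parameters
    ----------
    method:
        One of ``MC``, ``LHS``, ``QMC``, ``SUBSET``, ``MC_RARE``.
    C:
        Variance-reduction prefactor for ``LHS``; must satisfy ``0 < C <= 1``.
    alpha:
        Convergence exponent for ``QMC``; must lie in ``[1/2, 1]``.
    p:
        Rare-event probability for ``SUBSET`` / ``MC_RARE``; in ``(0, 1)``.
    """

    method: str
    C: float = 1.0
    alpha: float = 0.5
    p: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown sampling method {self.method!r}; "
                             f"expected one of {_METHODS}")
        if self.method == "LHS" and not (0.0 < self.C <= 1.0):
            raise ValueError("LHS constant C must be in (0, 1]")
        if self.method == "QMC" and not (0.5 <= self.alpha <= 1.0):
            raise ValueError("QMC exponent alpha must be in [1/2, 1]")
        if self.method in ("SUBSET", "MC_RARE"):
            if self.p is None or not (0.0 < self.p < 1.0):
                raise ValueError(f"{self.method} requires a rare-event "
                                 "probability p in (0, 1)")


def sampling_error(model: SamplingModel, N: int | float) -> float:
    """Fractional statistical error of a QoI estimated from a cohort of size N.

    >>> sampling_error(SamplingModel("MC"), 400)
    0.05
    """
    if N < 1:
        raise ValueError("cohort size N must be >= 1")
    m = model.method
    if m == "MC":
        return N ** -0.5
    if m == "LHS":
        return model.C * N ** -0.5
    if m == "QMC":
        return N ** -model.alpha
    if m == "MC_RARE":
        return (model.p * N) ** -0.5
    # SUBSET: error decays as log10(1/p)/sqrt(N)
    return math.log10(1.0 / model.p) / math.sqrt(N)


def cohort_size(model: SamplingModel, target_error: float) -> int:
    """Smallest integer cohort size N with ``sampling_error(model, N) <= target``.

    All five error models are strictly decreasing in N, so the inverse is
    solved in closed form and rounded up (with an exactness guard so that
    e.g. an MC target of 5% returns exactly 400).

    >>> cohort_size(SamplingModel("MC"), 0.05)
    400
    """
    if not (0.0 < target_error < 1.0):
        raise ValueError("target_error must lie in (0, 1)")
    m = model.method
    if m == "MC":
        n_real = target_error ** -2.0
    elif m == "LHS":
        n_real = (model.C / target_error) ** 2.0
    elif m == "QMC":
        n_real = target_error ** (-1.0 / model.alpha)
    elif m == "MC_RARE":
        n_real = 1.0 / (model.p * target_error ** 2.0)
    else:  # SUBSET
        n_real = (math.log10(1.0 / model.p) / target_error) ** 2.0
    n = max(1, math.ceil(n_real - 1e-9))
    # ceil can land one short or one long at representation boundaries; repair.
    while sampling_error(model, n) > target_error:
        n += 1
    while n > 1 and sampling_error(model, n - 1) <= target_error:
        n -= 1
    return n


def error_table(model: SamplingModel, sizes) -> "list[tuple[int, float]]":
    """(N, error) rows for a sweep of cohort sizes, for CSV export."""
    return [(int(n), sampling_error(model, int(n))) for n in sizes]
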
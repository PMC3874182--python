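"""dsDNA force–extension mechanics used as the naked-DNA baseline.

The model is deliberately phenomenological: below the overstretching
transition the tether sits at its B-form contour length (plus a small
linear compliance), and near ~65 pN it lengthens cooperatively to ~1.7x
B-form. Only these features matter to downstream trace analysis, so the
transition is a logistic sigmoid anchored at the transition force, the
transition width, and the overstretched plateau factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["MechanicsParams", "contour_length", "overstretch_fraction", "force_extension"]

# A logistic rises from 10% to 90% over 2*ln(9) scale units; "transition
# width" is quoted as that 10-90% span throughout.
LOGISTIC_10_90 = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class MechanicsParams:
    """Constants of the dsDNA force–extension model.

    Parameters
    ----------
    bform_rise : float
        Contour length per base pair of B-form dsDNA, nm/bp.
    overstretch_force : float
        Midpoint of the overstretching transition, pN.
    overstretch_width : float
        10–90% width of the transition, pN.
    overstretch_factor : float
        Relative length of the overstretched state (x B-form).
    low_force_compliance : float
        Fractional extension gained per pN below the transition, 1/pN.
        Captures the shallow enthalpic stretching of B-DNA.
    """

    bform_rise: float = 0.34
    overstretch_force: float = 65.0
    overstretch_width: float = 2.0
    overstretch_factor: float = 1.7
    low_force_compliance: float = 3.0e-4

    def __post_init__(self) -> None:
        if not self.overstretch_factor > 1:
            raise ValueError("overstretch_factor must exceed 1")
        if not self.overstretch_width > 0:
            raise ValueError("overstretch_width must be positive")
        for name in ("overstretch_force",):
            f = getattr(self, name)
            if not 0.0 <= f <= 200.0:
                raise ValueError(f"{name}={f} outside [0, 200] pN")
        if self.bform_rise <= 0:
            raise ValueError("bform_rise must be positive")
        if self.low_force_compliance < 0:
            raise ValueError("low_force_compliance must be non-negative")

    @property
    def logistic_scale(self) -> float:
        """Logistic scale parameter (pN) equivalent to the 10–90% width."""
        return self.overstretch_width / LOGISTIC_10_90


def contour_length(n_bp: int, params: MechanicsParams | None = None) -> float:
    """B-form contour length (nm) of an ``n_bp`` construct."""
    params = params or MechanicsParams()
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    return n_bp * params.bform_rise


def overstretch_fraction(force, params: MechanicsParams | None = None):
    """Fraction of the molecule in the overstretched state at ``force``.

    A logistic centred at ``overstretch_force``; exactly 0.5 at the
    transition midpoint.
    """
    params = params or MechanicsParams()
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    return expit((f - params.overstretch_force) / params.logistic_scale)


def force_extension(force, n_bp: int, params: MechanicsParams | None = None):
    """Equilibrium extension (nm) of naked dsDNA at ``force`` (pN).

    extension = L0 * [1 + c*F + (k - 1) * S(F)]

    with L0 the B-form contour, c the low-force compliance, k the
    overstretch factor and S the logistic transition occupancy. Monotone
    non-decreasing in force; scalar in, scalar out.
    """
    params = params or MechanicsParams()
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    L0 = n_bp * params.bform_rise
    ext = L0 * (
        1.0
        + params.low_force_compliance * f
        + (params.overstretch_factor - 1.0) * overstretch_fraction(f, params)
    )
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(ext)
    return ext
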
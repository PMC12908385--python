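"""Normalized Legendre polynomial basis over the environmental gradient.

The gradient (EG, in units of standard deviations of contemporary-group
solutions, nominally within [-3, 3]) is mapped linearly onto [-1, 1] and
evaluated in the normalized Legendre basis

    phi_k(x) = sqrt((2k + 1) / 2) * P_k(x),

which is orthonormal on [-1, 1].  With two coefficients (the default) the
basis carries the reaction-norm intercept (phi_0, a constant sqrt(1/2)) and
slope (phi_1(x) = sqrt(3/2) x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["LegendreBasis", "legendre_design"]


def legendre_design(eg: np.ndarray, order: int, eg_max: float = 3.0) -> np.ndarray:
    """Evaluate the normalized basis at EG values; returns (len(eg), order)."""
    if order < 1:
        raise ValueError("basis order must be at least 1")
    x = np.asarray(eg, dtype=float) / eg_max
    cols = []
    for k in range(order):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(np.sqrt((2 * k + 1) / 2.0) * npleg.legval(x, coef))
    return np.column_stack(cols)


@dataclass
class LegendreBasis:
    """Basis of a given order with its EG -> [-1, 1] domain mapping.

    ``grid`` / ``grid_matrix`` give the trajectory grid T used to map
    intercept/slope solutions back onto the gradient.
    """

    order: int = 2
    eg_max: float = 3.0
    n_grid: int = 61

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("basis order must be at least 1")

    def design(self, eg: np.ndarray) -> np.ndarray:
        return legendre_design(eg, self.order, self.eg_max)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(-self.eg_max, self.eg_max, self.n_grid)

    @property
    def grid_matrix(self) -> np.ndarray:
        """T: normalized basis evaluated over the EG grid."""
        return self.design(self.grid)
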
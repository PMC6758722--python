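"""Temperature-dependent release rate of thermosensitive liposomes.

The release-rate constant k_EL(T) is tabulated from calorimetric release
experiments on a lysolipid TSL formulation between 37 and 42 degC, with
linear interpolation between knots, a constant plateau above 42 degC
(fully melted membrane), and a clamp to the 37 degC leak rate below body
temperature (defensive; the tissue never cools below 37 degC here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_KNOTS: tuple[tuple[float, float], ...] = (
    (37.0, 0.00417),
    (38.0, 0.00545),
    (39.0, 0.01492),
    (40.0, 0.02815),
    (41.0, 0.04250),
    (42.0, 0.05409),
)


@dataclass(frozen=True)
class ReleaseTable:
    """Piecewise-linear k_EL(T); override ``knots`` for other formulations."""

    knots: tuple[tuple[float, float], ...] = DEFAULT_KNOTS

    def __post_init__(self) -> None:
        temps = np.array([k[0] for k in self.knots])
        rates = np.array([k[1] for k in self.knots])
        if np.any(rates <= 0):
            raise ValueError("release rates must be strictly positive")
        if np.any(np.diff(temps) <= 0) or np.any(np.diff(rates) < 0):
            raise ValueError("knots must be sorted and non-decreasing in rate")

    def k_EL(self, T):
        """Release rate constant at temperature T [degC], s^-1."""
        T = np.asarray(T, dtype=float)
        if np.any(np.isnan(T)):
            raise ValueError("NaN temperature")
        temps = np.array([k[0] for k in self.knots])
        rates = np.array([k[1] for k in self.knots])
        out = np.interp(T, temps, rates)  # np.interp clamps at both ends
        return out if out.shape else float(out)


def k_EL(T, table: ReleaseTable | None = None):
    """Module-level convenience wrapper using the default formulation."""
    return (table or ReleaseTable()).k_EL(T)
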
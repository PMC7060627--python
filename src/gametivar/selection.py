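"""Selection-index layer: RPTA and progeny-number estimation.

RPTA (relative predicted transmitting ability) rewards both merit and
gametic diversity:

    RPTA = GEBV/2 + sigma_gamete * i_f

with i_f the assumed future selection intensity applied to an individual's
gametes (default 1.5). The progeny count needed to observe the expected
gametic variability with confidence z (default 1.96, i.e. 95%) while
tolerating at most a relative change d (default 0.1) in the progeny-based
EBV is

    n = z^2 * CRV^2 / d^2

rounded up to an integer (a progeny count is integral); the raw real value
is kept alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SelectionParams", "rpta", "progeny_number", "progeny_number_raw"]


@dataclass(frozen=True)
class SelectionParams:
    """Tunable constants of the selection-index layer.

    i_f : future gametic selection intensity (dimensionless).
    z   : normal quantile for the confidence level of the progeny-number
          estimate.
    d   : maximum tolerated relative change in the progeny-predicted EBV.
    """

    i_f: float = 1.5
    z: float = 1.96
    d: float = 0.1

    def __post_init__(self) -> None:
        if not math.isfinite(self.i_f):
            raise ValueError("i_f must be finite")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 0 < self.d < 1:
            raise ValueError("d must lie in (0, 1)")


def rpta(gebv_total: float, sigma_gamete: float,
         params: SelectionParams | None = None) -> float:
    """Selection index GEBV/2 + sigma_gamete * i_f (trait units)."""
    params = params or SelectionParams()
    if sigma_gamete < 0:
        raise ValueError("sigma_gamete must be non-negative")
    return gebv_total / 2.0 + sigma_gamete * params.i_f


def progeny_number_raw(crv: float, params: SelectionParams | None = None) -> float:
    """Real-valued progeny-number formula z^2 * CRV^2 / d^2."""
    params = params or SelectionParams()
    return (params.z**2) * (crv**2) / (params.d**2)


def progeny_number(crv: float, params: SelectionParams | None = None) -> int:
    """Smallest integer progeny count satisfying the formula (ceiling)."""
    return math.ceil(progeny_number_raw(crv, params))
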
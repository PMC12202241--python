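"""ICERs, the cost-effectiveness plane, net benefit, and CEACs.

The incremental cost-effectiveness ratio is the adjusted IG-CG cost
difference divided by the adjusted effect difference.  Uncertainty is
summarized on the cost-effectiveness plane — the cloud of bootstrapped
(delta-effect, delta-cost) pairs over four quadrants — and with
cost-effectiveness acceptability curves (CEACs).

Two CEAC definitions are provided because they differ outside the
north-east quadrant:

* ``net_benefit`` (default): the fraction of draws with strictly
  positive net monetary benefit, wtp * dE - dC > 0.  Quadrant-safe and
  the standard net-benefit-approach curve.
* ``icer_below_wtp``: the verbal "proportion of bootstrapped ICERs below
  the threshold" reading.  Quadrant rule: SE draws (dominant) count as
  acceptable at every threshold, NW draws (dominated) never, NE draws
  when ICER < wtp, and SW draws when ICER > wtp (south-west ratios are
  willingness-to-accept, where a *higher* ratio is better).  With every
  draw in the NE quadrant the two definitions agree exactly.

Boundary tie rule: a zero difference counts toward the non-negative
side, so a draw with dE = 0 sits in a northern/southern quadrant by the
sign of dC and (0, 0) is NE; dominance labels require strict signs.
Ties in net benefit (probability zero for continuous draws) count as not
cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .resampling import DrawSet

__all__ = [
    "QUADRANTS",
    "CEAC_DEFINITIONS",
    "ICERResult",
    "CEACCurve",
    "icer",
    "nmb",
    "ceac",
    "plane_summary",
    "default_wtp_grid",
]

QUADRANTS = ("NE", "NW", "SE", "SW")
CEAC_DEFINITIONS = ("net_benefit", "icer_below_wtp")


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_effect: float
    icer: float | None  # None when delta_effect == 0 (undefined ratio)
    quadrant: str
    dominance: str  # none | intervention_dominant | intervention_dominated


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    probability: np.ndarray
    definition: str

    def __post_init__(self) -> None:
        if self.definition not in CEAC_DEFINITIONS:
            raise ValueError(f"definition must be one of {CEAC_DEFINITIONS}")
        if len(self.wtp_grid) != len(self.probability):
            raise ValueError("grid and probability lengths differ")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def _quadrant(delta_cost: float, delta_effect: float) -> str:
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_effect >= 0 else "W"
    return ns + ew


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Ratio, quadrant, and dominance classification of a (dC, dE) pair."""
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("delta_cost and delta_effect must be finite")
    quadrant = _quadrant(delta_cost, delta_effect)
    ratio = delta_cost / delta_effect if delta_effect != 0.0 else None
    if delta_cost < 0 and delta_effect > 0:
        dominance = "intervention_dominant"
    elif delta_cost > 0 and delta_effect < 0:
        dominance = "intervention_dominated"
    else:
        dominance = "none"
    return ICERResult(delta_cost, delta_effect, ratio, quadrant, dominance)


def nmb(wtp: float, delta_effect: float, delta_cost: float) -> float:
    """Incremental net monetary benefit at a willingness-to-pay."""
    return wtp * delta_effect - delta_cost


def ceac(draws: DrawSet, wtp_grid, definition: str = "net_benefit") -> CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    dc, de = draws.delta_cost, draws.delta_effect
    if definition == "net_benefit":
        # fraction of draws with strictly positive NMB at each threshold
        prob = np.array([np.mean(w * de - dc > 0.0) for w in grid])
    elif definition == "icer_below_wtp":
        ne = (dc >= 0) & (de > 0)
        se = (dc < 0) & (de > 0)
        sw = (dc < 0) & (de < 0)
        prob = np.empty(grid.size)
        for j, w in enumerate(grid):
            acc = se.copy()
            acc |= ne & (np.divide(dc, de, out=np.full_like(dc, np.inf), where=de != 0) < w)
            acc |= sw & (np.divide(dc, de, out=np.full_like(dc, np.inf), where=de != 0) > w)
            prob[j] = np.mean(acc)
    else:
        raise ValueError(f"definition must be one of {CEAC_DEFINITIONS}")
    curve = CEACCurve(grid, prob, definition)
    if definition == "net_benefit" and np.all(de > 0) and np.all(np.diff(grid) >= 0):
        assert np.all(np.diff(curve.probability) >= 0), "CEAC must be non-decreasing"
    return curve


def plane_summary(draws: DrawSet) -> dict[str, float]:
    """Fractions of bootstrap draws per cost-effectiveness-plane quadrant."""
    dc, de = draws.delta_cost, draws.delta_effect
    north = dc >= 0
    east = de >= 0
    fractions = {
        "NE": float(np.mean(north & east)),
        "NW": float(np.mean(north & ~east)),
        "SE": float(np.mean(~north & east)),
        "SW": float(np.mean(~north & ~east)),
    }
    assert abs(sum(fractions.values()) - 1.0) < 1e-12
    return fractions


def default_wtp_grid(effect_name: str) -> np.ndarray:
    """Default threshold grids: euros per QALY or per reliable improvement."""
    if effect_name in ("QALY_EQ5D", "QALY_VAS"):
        return np.arange(0.0, 300_000.0 + 1.0, 1000.0)
    if effect_name == "RELIABLE_IMPROVEMENT":
        return np.arange(0.0, 30_000.0 + 1.0, 100.0)
    raise ValueError(f"unknown effect measure {effect_name!r}")
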
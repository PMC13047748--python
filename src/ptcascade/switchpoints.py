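"""Switch-point detection on scaled, smoothed expression trajectories.

A switch point is a position along pseudotime where a gene's
standardized fitted trajectory changes state.  Three criteria are
supported: zero-crossing (default), crossing of a user threshold gamma,
and the position of maximum absolute first derivative (forward
differences).  Positions are reported 1-based, ``i`` in ``1..N-1``
meaning the switch lies between grid points ``i`` and ``i+1``; the
accompanying pseudotime is the linear interpolation of the crossing
between ``t_i`` and ``t_{i+1}`` (the left grid point's pseudotime for
the derivative method).

Exactly-zero grid values are handled by a limit convention: a run of
grid points sitting exactly on the threshold, flanked by opposite
signs, counts as one crossing at the first index of the run (the limit
of perturbing the run by any small epsilon); a run flanked by equal
signs is a touch, not a crossing.  The strict product rule
``x_i * x_{i+1} < 0``, which silently drops crossings landing on a grid
point, is available via ``ties='strict'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import ScaledTrajectory

__all__ = [
    "SwitchPointSet",
    "detect_zero_crossings",
    "detect_threshold_crossings",
    "detect_max_derivative",
    "detect_switch_points",
]


@dataclass
class SwitchPointSet:
    """Ordered switch positions of one gene with direction labels.

    ``positions`` are 1-based indices in ``1..N-1``; ``directions`` has
    one label per position, ``"I"`` for increasing and ``"D"`` for
    decreasing.
    """

    gene_id: str
    method: str
    positions: list[int]
    pseudotimes: list[float]
    directions: list[str]
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.pseudotimes) == len(self.directions)):
            raise ValueError("positions, pseudotimes and directions must align")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if any(d not in ("I", "D") for d in self.directions):
            raise ValueError("directions must be 'I' or 'D'")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def pattern(self) -> str:
        return "".join(self.directions)


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Pseudotime where the segment (i, i+1) of v crosses 0 (0-based i)."""
    v0, v1 = v[i], v[i + 1]
    if v1 == v0:
        return float(t[i])
    frac = -v0 / (v1 - v0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _crossings(
    x: np.ndarray, t: np.ndarray, gamma: float, ties: str
) -> tuple[list[int], list[float], list[str]]:
    v = np.asarray(x, dtype=float) - gamma
    n = len(v)
    positions: list[int] = []
    pseudotimes: list[float] = []
    directions: list[str] = []
    if ties == "strict":
        for i in range(n - 1):
            if v[i] * v[i + 1] < 0:
                positions.append(i + 1)
                pseudotimes.append(_interp_crossing(t, v, i))
                directions.append("I" if v[i] < v[i + 1] else "D")
        return positions, pseudotimes, directions
    if ties != "limit":
        raise ValueError(f"unknown tie rule {ties!r}")
    # limit convention: collapse runs of exact zeros onto one crossing
    sign = np.sign(v)
    nz = np.flatnonzero(sign)
    for k in range(len(nz) - 1):
        a, b = nz[k], nz[k + 1]
        if sign[a] * sign[b] < 0:
            positions.append(a + 1)  # first index of the (possibly empty) zero run
            pseudotimes.append(_interp_crossing(t, v, a) if b == a + 1 else float(t[a + 1]))
            directions.append("I" if sign[a] < sign[b] else "D")
    return positions, pseudotimes, directions


def detect_zero_crossings(
    x: ScaledTrajectory, ties: str = "limit"
) -> SwitchPointSet:
    """Switch points where the standardized trajectory crosses zero."""
    return detect_threshold_crossings(x, 0.0, ties=ties, _method="zero")


def detect_threshold_crossings(
    x: ScaledTrajectory, gamma: float, ties: str = "limit", _method: str = "threshold"
) -> SwitchPointSet:
    """Switch points where the trajectory crosses the level ``gamma``."""
    if len(x.x) < 2:
        raise ValueError("trajectory needs at least 2 grid points")
    pos, pt, dirs = _crossings(x.x, x.grid, gamma, ties)
    return SwitchPointSet(
        x.gene_id, _method, pos, pt, dirs, gamma=None if _method == "zero" else gamma
    )


def detect_max_derivative(x: ScaledTrajectory) -> SwitchPointSet:
    """The single switch point of maximal absolute forward-difference
    derivative; ties broken toward the smallest index."""
    t = np.asarray(x.grid, dtype=float)
    v = np.asarray(x.x, dtype=float)
    if len(v) < 2:
        raise ValueError("trajectory needs at least 2 grid points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("pseudotimes must be strictly increasing")
    deriv = np.diff(v) / dt
    i = int(np.argmax(np.abs(deriv)))  # argmax takes the first maximum
    direction = "I" if deriv[i] > 0 else "D"
    return SwitchPointSet(x.gene_id, "max-derivative", [i + 1], [float(t[i])], [direction])


def detect_switch_points(
    x: ScaledTrajectory,
    method: str = "zero",
    gamma: float = 0.0,
    ties: str = "limit",
) -> SwitchPointSet:
    """Dispatch to the requested switch-point criterion."""
    if method == "zero":
        return detect_zero_crossings(x, ties=ties)
    if method == "threshold":
        return detect_threshold_crossings(x, gamma, ties=ties)
    if method == "max-derivative":
        return detect_max_derivative(x)
    raise ValueError(f"unknown switch-point method {method!r}")
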
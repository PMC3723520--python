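"""Named reproductions of the printed simulation setups.

Built-in scenarios:

* ``fig1C`` — fully symmetric parameter set, 3 AD + 3 AB cells: the boundary
  stays fixed.
* ``fig1D`` — r2 = 1.8 (weakened repression of AB production): the AD domain
  expands, the boundary shifts toward the abaxial end.
* ``fig1E`` — r1 = 1.8: the mirror case, shifting toward the adaxial end.
* ``figS12A`` — assumed wild type: r2 = 1.8, adaxial-most cell pinned in the
  AD-expressing state, five AB cells.
* ``figS12B`` — assumed phb-1d/+ heterozygote: additionally c1 = 1.9
  (weakened AD degradation), which speeds up the abaxial shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .boundary import BoundaryTrajectory, make_initial_tissue, simulate_boundary
from .model import ModelParameters
from .phase_plane import find_steady_states

__all__ = ["ScenarioSpec", "SpeedResult", "SCENARIOS", "get_scenario", "run_scenario", "shift_speed"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation setup: parameters, initial composition, options."""

    name: str
    params: ModelParameters
    n_AD: int = 3
    n_AB: int = 3
    pinned_adaxial: bool = False
    t_end: float = 2000.0
    dt: float = 0.2

    def replace(self, **changes) -> "ScenarioSpec":
        return replace(self, **changes)


def _builtin() -> dict[str, ScenarioSpec]:
    sym = ModelParameters()
    s12_base = ModelParameters(r2=1.8)
    return {
        "fig1C": ScenarioSpec("fig1C", sym),
        "fig1D": ScenarioSpec("fig1D", ModelParameters(r2=1.8)),
        "fig1E": ScenarioSpec("fig1E", ModelParameters(r1=1.8)),
        "figS12A": ScenarioSpec(
            "figS12A", s12_base, n_AD=1, n_AB=5, pinned_adaxial=True, t_end=4000.0
        ),
        "figS12B": ScenarioSpec(
            "figS12B",
            s12_base.replace(c1=1.9),
            n_AD=1,
            n_AB=5,
            pinned_adaxial=True,
            t_end=4000.0,
        ),
    }


SCENARIOS: dict[str, ScenarioSpec] = _builtin()


def get_scenario(name: str, **overrides) -> ScenarioSpec:
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    return spec.replace(**overrides) if overrides else spec


def run_scenario(spec: ScenarioSpec, record_stride: int = 5) -> BoundaryTrajectory:
    """Simulate a scenario; with ``pinned_adaxial`` the adaxial-most cell is
    clamped to the AD-expressing fixed point after every integration step
    while still feeding diffusive flux to its neighbour."""
    ss = find_steady_states(spec.params)
    init = make_initial_tissue(spec.n_AD, spec.n_AB, spec.params, steady_states=ss)
    pinned = None
    if spec.pinned_adaxial:
        if spec.n_AD < 1:
            raise ValueError("pinned scenario requires at least one adaxial cell")
        hi = ss.ad_expressing
        pinned = {0: (hi.AD, hi.AB)}
    return simulate_boundary(
        spec.params, init, spec.t_end, dt=spec.dt, record_stride=record_stride, pinned=pinned
    )


@dataclass(frozen=True)
class SpeedResult:
    """Boundary shift speed between two positions plus per-interface
    first-passage times (None where the boundary never arrives)."""

    speed: float | None
    first_passage: dict[float, float | None]
    from_pos: float
    to_pos: float


def _first_passage_time(times: np.ndarray, positions: np.ndarray, target: float, direction: float) -> float | None:
    """First time the boundary reaches ``target`` travelling in ``direction``
    (+1 abaxial, -1 adaxial), linearly interpolated between recorded times."""
    prev_t = prev_p = None
    for t, p in zip(times, positions):
        if not np.isfinite(p):
            prev_t = prev_p = None
            continue
        if direction * (p - target) >= 0.0:
            if prev_p is None:
                return float(t)
            return float(prev_t + (t - prev_t) * (target - prev_p) / (p - prev_p))
        prev_t, prev_p = t, p
    return None


def shift_speed(
    traj: BoundaryTrajectory, from_pos: float = 1.5, to_pos: float = 3.5
) -> SpeedResult:
    """Average boundary speed between two positions (cells per unit time).

    First-passage times are reported for every inter-cell interface (the
    half-integer positions) between ``from_pos`` and ``to_pos`` inclusive;
    an interface the boundary never crosses gets None, and the speed is None
    unless both endpoints are reached.
    """
    direction = 1.0 if to_pos >= from_pos else -1.0
    lo, hi = sorted((from_pos, to_pos))
    interfaces = [x for x in np.arange(np.ceil(lo - 0.5) + 0.5, hi + 0.5) if lo <= x <= hi]
    for endpoint in (from_pos, to_pos):
        if endpoint not in interfaces:
            interfaces.append(endpoint)
    interfaces = sorted(set(interfaces), key=lambda x: direction * x)

    passage = {
        float(x): _first_passage_time(traj.times, traj.positions, x, direction)
        for x in interfaces
    }
    t_from = passage[float(from_pos)]
    t_to = passage[float(to_pos)]
    speed = None
    if t_from is not None and t_to is not None and t_to != t_from:
        speed = (to_pos - from_pos) / (t_to - t_from)
    return SpeedResult(speed, passage, from_pos, to_pos)
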
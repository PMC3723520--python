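"""Tissue-level boundary dynamics: dominance labelling, sub-cell boundary
localization, trajectory simulation, dynamics-type classification and
two-parameter sweeps.

The central observable is the position of the interface between the
AD-dominant (adaxial) and AB-dominant (abaxial) domains along the cell file,
measured as the linearly interpolated zero crossing of s_i = AD_i - AB_i.
Depending on parameter (a)symmetry the interface either stays put or travels
toward one tissue end, converting one expression domain into the other.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ModelParameters, TissueState, Trajectory, integrate
from .phase_plane import SteadyStateSet, find_steady_states

__all__ = [
    "ConfigurationError",
    "BoundaryTrajectory",
    "DynamicsClass",
    "FIXED",
    "SHIFT_TO_AD_END",
    "SHIFT_TO_AB_END",
    "NOT_BISTABLE",
    "UNRESOLVED",
    "make_initial_tissue",
    "dominance_labels",
    "boundary_position",
    "domain_fraction",
    "simulate_boundary",
    "classify_dynamics",
    "parameter_sweep",
]

FIXED = "FIXED"
SHIFT_TO_AD_END = "SHIFT_TO_AD_END"
SHIFT_TO_AB_END = "SHIFT_TO_AB_END"
NOT_BISTABLE = "NOT_BISTABLE"
UNRESOLVED = "UNRESOLVED"

DEFAULT_T_END = 2000.0
DEFAULT_FIXED_THRESHOLD = 0.5


class ConfigurationError(ValueError):
    """Requested setup is inconsistent with the parameter regime."""


@dataclass
class BoundaryTrajectory:
    """Boundary position and dominance labels over a recorded trajectory.

    ``positions[t]`` is NaN when no boundary exists at that time (all cells
    share one dominance label).  ``labels`` is a (T, N) array of "AD"/"AB".
    """

    times: np.ndarray
    positions: np.ndarray
    labels: np.ndarray
    params: ModelParameters
    init: TissueState
    trajectory: Trajectory

    @property
    def n_cells(self) -> int:
        return self.labels.shape[1]

    @property
    def n_ad_dominant(self) -> np.ndarray:
        return (self.labels == "AD").sum(axis=1)

    @property
    def n_ab_dominant(self) -> np.ndarray:
        return (self.labels == "AB").sum(axis=1)

    @property
    def net_displacement(self) -> float:
        """Final minus initial boundary position (NaN if either undefined)."""
        finite = np.flatnonzero(np.isfinite(self.positions))
        if finite.size == 0 or not np.isfinite(self.positions[0]):
            return float("nan")
        return float(self.positions[finite[-1]] - self.positions[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "position": self.positions,
                "n_AD_dominant": self.n_ad_dominant,
                "n_AB_dominant": self.n_ab_dominant,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DynamicsClass:
    """Qualitative boundary behaviour of one parameter set."""

    label: str
    displacement: float
    t_end_used: float


def make_initial_tissue(
    n_AD: int,
    n_AB: int,
    params: ModelParameters,
    steady_states: SteadyStateSet | None = None,
) -> TissueState:
    """Tissue of ``n_AD`` cells at the AD-expressing fixed point followed by
    ``n_AB`` cells at the AB-expressing fixed point (adaxial end first).

    Requires a bistable parameter set; raises :class:`ConfigurationError`
    otherwise.
    """
    if n_AD < 0 or n_AB < 0 or n_AD + n_AB < 1:
        raise ValueError("need n_AD, n_AB >= 0 with at least one cell")
    ss = steady_states if steady_states is not None else find_steady_states(params)
    if len(ss.stable) < 2:
        raise ConfigurationError(
            "parameter set is not bistable; no two expression states to juxtapose"
        )
    hi = ss.ad_expressing
    lo = ss.ab_expressing
    AD = np.concatenate([np.full(n_AD, hi.AD), np.full(n_AB, lo.AD)])
    AB = np.concatenate([np.full(n_AD, hi.AB), np.full(n_AB, lo.AB)])
    return TissueState(AD, AB, 0.0)


def dominance_labels(state: TissueState) -> np.ndarray:
    """Per-cell label: "AD" iff AD_i > AB_i, else "AB" (ties labelled AB)."""
    return np.where(state.AD > state.AB, "AD", "AB")


def _positions_from_arrays(AD: np.ndarray, AB: np.ndarray) -> float:
    s = AD - AB
    for i in range(s.size - 1):
        if s[i] == 0.0:
            return float(i)
        if s[i] * s[i + 1] < 0:
            return float(i + s[i] / (s[i] - s[i + 1]))
    if s[-1] == 0.0:
        return float(s.size - 1)
    return float("nan")


def boundary_position(state: TissueState) -> float | None:
    """Interpolated zero crossing of AD - AB, or None when no boundary exists.

    With several crossings the one nearest the adaxial end (index 0) is
    returned; a cell sitting exactly on the tie is itself the boundary.
    """
    pos = _positions_from_arrays(state.AD, state.AB)
    return None if np.isnan(pos) else pos


def domain_fraction(state: TissueState) -> float:
    """Percentage of AB-dominant cells — in-silico analog of the measured
    abaxial-marker expression area fraction."""
    labels = dominance_labels(state)
    return 100.0 * float((labels == "AB").sum()) / state.n_cells


def simulate_boundary(
    params: ModelParameters,
    init: TissueState,
    t_end: float,
    dt: float = 0.2,
    record_stride: int = 5,
    pinned: Mapping[int, tuple[float, float]] | None = None,
) -> BoundaryTrajectory:
    """Integrate and map every recorded state to labels + boundary position."""
    traj = integrate(init, params, t_end, dt=dt, record_stride=record_stride, pinned=pinned)
    labels = np.where(traj.AD > traj.AB, "AD", "AB")
    positions = np.array(
        [_positions_from_arrays(traj.AD[i], traj.AB[i]) for i in range(len(traj.times))]
    )
    return BoundaryTrajectory(
        times=traj.times,
        positions=positions,
        labels=labels,
        params=params,
        init=init,
        trajectory=traj,
    )


def classify_dynamics(
    params: ModelParameters,
    n_AD: int = 3,
    n_AB: int = 3,
    t_end: float = DEFAULT_T_END,
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    dt: float = 0.2,
    record_stride: int = 5,
    steady_states: SteadyStateSet | None = None,
) -> DynamicsClass:
    """Classify the boundary dynamics of one parameter set.

    NOT_BISTABLE when the single-cell system lacks two stable states;
    otherwise FIXED / SHIFT_TO_AB_END / SHIFT_TO_AD_END by the net boundary
    displacement at ``t_end`` against ``fixed_threshold`` (cells).  A boundary
    that reaches a tissue end (one domain extinct) is classified by the
    surviving domain; UNRESOLVED covers the remaining degenerate outcomes.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    ss = steady_states if steady_states is not None else find_steady_states(params)
    if len(ss.stable) < 2:
        return DynamicsClass(NOT_BISTABLE, float("nan"), t_end)
    init = make_initial_tissue(n_AD, n_AB, params, steady_states=ss)
    bt = simulate_boundary(params, init, t_end, dt=dt, record_stride=record_stride)

    if not np.isfinite(bt.positions[0]):
        return DynamicsClass(UNRESOLVED, float("nan"), t_end)
    finite = np.flatnonzero(np.isfinite(bt.positions))
    last = finite[-1]
    if last < len(bt.positions) - 1:
        # boundary vanished: one domain took over the whole tissue
        final_labels = bt.labels[-1]
        disp = float(bt.positions[last] - bt.positions[0])
        if (final_labels == "AD").all():
            return DynamicsClass(SHIFT_TO_AB_END, disp, t_end)
        if (final_labels == "AB").all():
            return DynamicsClass(SHIFT_TO_AD_END, disp, t_end)
        return DynamicsClass(UNRESOLVED, disp, t_end)
    disp = float(bt.positions[-1] - bt.positions[0])
    if abs(disp) < fixed_threshold:
        return DynamicsClass(FIXED, disp, t_end)
    return DynamicsClass(SHIFT_TO_AB_END if disp > 0 else SHIFT_TO_AD_END, disp, t_end)


class _ParamArrays:
    """Parameter container whose fields are (B, 1) arrays, for integrating a
    batch of parameter sets in lockstep.  Duck-types ModelParameters for the
    right-hand-side evaluation (elementwise float ops are identical to the
    per-point path, so batching does not change any result bitwise)."""

    __slots__ = tuple(f.name for f in dataclasses.fields(ModelParameters))

    def __init__(self, param_list: list[ModelParameters]):
        for name in self.__slots__:
            values = np.array([[getattr(p, name)] for p in param_list], dtype=float)
            if name in ("n_f", "n_g"):
                exps = {getattr(p, name) for p in param_list}
                if len(exps) != 1:
                    raise ValueError("batched integration requires a common Hill exponent")
                setattr(self, name, exps.pop())
            else:
                setattr(self, name, values)


def _classify_batch(
    param_list: list[ModelParameters],
    n_AD: int,
    n_AB: int,
    t_end: float,
    fixed_threshold: float,
    dt: float,
    record_stride: int,
) -> list[DynamicsClass]:
    """Classify many parameter sets by integrating them as one (B, N) batch."""
    import math

    results: list[DynamicsClass | None] = [None] * len(param_list)
    active: list[int] = []
    inits: list[TissueState] = []
    for k, params in enumerate(param_list):
        try:
            ss = find_steady_states(params)
            if len(ss.stable) < 2:
                results[k] = DynamicsClass(NOT_BISTABLE, float("nan"), t_end)
                continue
            inits.append(make_initial_tissue(n_AD, n_AB, params, steady_states=ss))
            active.append(k)
        except Exception:
            results[k] = DynamicsClass(UNRESOLVED, float("nan"), t_end)
    if not active:
        return results  # type: ignore[return-value]

    from .model import _derivatives

    pa = _ParamArrays([param_list[k] for k in active])
    ad = np.vstack([s.AD for s in inits])
    ab = np.vstack([s.AB for s in inits])
    B = ad.shape[0]

    p0 = np.array([_positions_from_arrays(ad[b], ab[b]) for b in range(B)])
    last_pos = p0.copy()
    failed = np.zeros(B, dtype=bool)

    n_steps = int(math.ceil(t_end / dt - 1e-9))
    half, sixth = dt / 2.0, dt / 6.0
    for step in range(1, n_steps + 1):
        k1a, k1b = _derivatives(ad, ab, pa)
        k2a, k2b = _derivatives(ad + half * k1a, ab + half * k1b, pa)
        k3a, k3b = _derivatives(ad + half * k2a, ab + half * k2b, pa)
        k4a, k4b = _derivatives(ad + dt * k3a, ab + dt * k3b, pa)
        ad = ad + sixth * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        ab = ab + sixth * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        if step % record_stride == 0 or step == n_steps:
            bad = ~(np.isfinite(ad).all(axis=1) & np.isfinite(ab).all(axis=1))
            bad |= (ad < 0).any(axis=1) | (ab < 0).any(axis=1)
            newly = bad & ~failed
            if newly.any():
                failed |= newly
                ad[failed] = 1.0  # inert value; rows already marked failed
                ab[failed] = 1.0
            for b in range(B):
                if failed[b]:
                    continue
                pos = _positions_from_arrays(ad[b], ab[b])
                if np.isfinite(pos):
                    last_pos[b] = pos

    for row, k in enumerate(active):
        if failed[row]:
            results[k] = DynamicsClass(UNRESOLVED, float("nan"), t_end)
            continue
        if not np.isfinite(p0[row]):
            results[k] = DynamicsClass(UNRESOLVED, float("nan"), t_end)
            continue
        disp = float(last_pos[row] - p0[row])
        final_pos = _positions_from_arrays(ad[row], ab[row])
        if np.isnan(final_pos):
            all_ad = bool((ad[row] > ab[row]).all())
            all_ab = bool((ad[row] <= ab[row]).all())
            if all_ad:
                results[k] = DynamicsClass(SHIFT_TO_AB_END, disp, t_end)
            elif all_ab:
                results[k] = DynamicsClass(SHIFT_TO_AD_END, disp, t_end)
            else:
                results[k] = DynamicsClass(UNRESOLVED, disp, t_end)
            continue
        if abs(disp) < fixed_threshold:
            results[k] = DynamicsClass(FIXED, disp, t_end)
        else:
            results[k] = DynamicsClass(
                SHIFT_TO_AB_END if disp > 0 else SHIFT_TO_AD_END, disp, t_end
            )
    return results  # type: ignore[return-value]


def parameter_sweep(
    base: ModelParameters,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    n_AD: int = 3,
    n_AB: int = 3,
    t_end: float = DEFAULT_T_END,
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    dt: float = 0.2,
    record_stride: int = 25,
) -> pd.DataFrame:
    """Classify boundary dynamics over a 2D parameter grid.

    All grid points are integrated in one lockstep RK4 batch (identical
    elementwise arithmetic to per-point runs).  Returns a tidy long-format
    table with one row per grid point; a failure at one point is recorded as
    UNRESOLVED with a note and never aborts the sweep.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    for name in (name1, name2):
        if name not in valid:
            raise ValueError(f"unknown parameter field {name!r}")

    points = []
    param_list = []
    notes = []
    for v1 in np.asarray(grid1, dtype=float):
        for v2 in np.asarray(grid2, dtype=float):
            points.append((float(v1), float(v2)))
            try:
                param_list.append(base.replace(**{name1: float(v1), name2: float(v2)}))
                notes.append("")
            except Exception as exc:
                param_list.append(None)
                notes.append(str(exc))

    ok_idx = [i for i, p in enumerate(param_list) if p is not None]
    classes = _classify_batch(
        [param_list[i] for i in ok_idx], n_AD, n_AB, t_end, fixed_threshold, dt, record_stride
    )
    by_index: dict[int, DynamicsClass] = dict(zip(ok_idx, classes))

    rows = []
    for i, (v1, v2) in enumerate(points):
        dc = by_index.get(i)
        rows.append(
            {
                "axis1_name": name1,
                "axis1_value": v1,
                "axis2_name": name2,
                "axis2_value": v2,
                "class": dc.label if dc else UNRESOLVED,
                "displacement": dc.displacement if dc else float("nan"),
                "t_end": t_end,
                "note": notes[i],
            }
        )
    return pd.DataFrame(rows)


def default_sweep_grid(base_value: float, n_points: int = 21) -> np.ndarray:
    """Grid spanning +/-50% of a base parameter value."""
    return np.linspace(0.5 * base_value, 1.5 * base_value, n_points)
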
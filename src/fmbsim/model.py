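"""Core dynamical model: two mutually repressing, diffusible gene products on a
1D cell file.

The state of each cell ``i`` is a concentration pair ``(AD_i, AB_i)`` for the
adaxial-side and abaxial-side products.  Within a cell the dynamics are

    dAD_i/dt = f1(AB_i) - AD_i * g1(AB_i) + D_AD * L(AD)_i
    dAB_i/dt = f2(AD_i) - AB_i * g2(AD_i) + D_AB * L(AB)_i

where ``f_j`` is a decreasing Hill production function (basal rate ``p_j`` plus
a repressible increment ``r_j``), ``g_j`` an increasing Hill degradation-rate
function (basal ``d_j`` plus an inducible increment ``c_j``), and ``L`` the
zero-flux (reflective) discrete Laplacian coupling nearest-neighbour cells.

Integration is classical fixed-step fourth-order Runge-Kutta.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParameters",
    "CellState",
    "TissueState",
    "Trajectory",
    "IntegrationError",
    "production_rate",
    "degradation_rate",
    "laplacian",
    "rhs",
    "integrate",
]

_DIFFUSION_FIELDS = ("D_AD", "D_AB")


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite or negative state."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of one AD/AB system.

    Units: ``p_j``, ``r_j`` are production rates (concentration/time);
    ``d_j``, ``c_j`` degradation rate constants (1/time); ``D_AD``, ``D_AB``
    intercellular exchange coefficients (1/time); ``n_f``, ``n_g`` Hill
    exponents (dimensionless); ``K_f``, ``K_g`` half-saturation
    concentrations.  Concentrations are nondimensionalized so K defaults to 1.
    """

    p1: float = 0.1
    p2: float = 0.1
    r1: float = 2.0
    r2: float = 2.0
    d1: float = 0.1
    d2: float = 0.1
    c1: float = 2.0
    c2: float = 2.0
    D_AD: float = 0.1
    D_AB: float = 0.1
    n_f: int = 2
    n_g: int = 1
    K_f: float = 1.0
    K_g: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "d1", "d2", "K_f", "K_g"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        # r and c may be zero: degenerate (repression-free) reductions are legal
        for name in ("r1", "r2", "c1", "c2") + _DIFFUSION_FIELDS:
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        for name in ("n_f", "n_g"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ValueError(f"{name} must be a positive integer, got {value!r}")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def swapped(self) -> "ModelParameters":
        """Parameters with the 1<->2 gene roles (and diffusivities) exchanged."""
        return self.replace(
            p1=self.p2, p2=self.p1, r1=self.r2, r2=self.r1,
            d1=self.d2, d2=self.d1, c1=self.c2, c2=self.c1,
            D_AD=self.D_AB, D_AB=self.D_AD,
        )

    @property
    def is_symmetric(self) -> bool:
        return self == self.swapped()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        coerced = {
            k: int(v) if k in ("n_f", "n_g") else float(v) for k, v in mapping.items()
        }
        return cls(**coerced)


@dataclass(frozen=True)
class CellState:
    """One cell's (AD, AB) concentration pair."""

    AD: float
    AB: float

    def __post_init__(self) -> None:
        if self.AD < 0 or self.AB < 0:
            raise ValueError("concentrations must be nonnegative")


class TissueState:
    """Ordered adaxial->abaxial cell file: index 0 is the adaxial-most cell.

    Stores concentrations as two 1D arrays for efficiency; ``cells`` exposes
    the per-cell view.
    """

    __slots__ = ("AD", "AB", "time")

    def __init__(self, AD, AB, time: float = 0.0):
        AD = np.asarray(AD, dtype=float)
        AB = np.asarray(AB, dtype=float)
        if AD.ndim != 1 or AD.shape != AB.shape or AD.size < 1:
            raise ValueError("AD and AB must be equal-length 1D arrays, N >= 1")
        if (AD < 0).any() or (AB < 0).any():
            raise ValueError("concentrations must be nonnegative")
        self.AD = AD
        self.AB = AB
        self.time = float(time)

    @classmethod
    def from_cells(cls, cells: Sequence[CellState], time: float = 0.0) -> "TissueState":
        return cls([c.AD for c in cells], [c.AB for c in cells], time)

    @property
    def n_cells(self) -> int:
        return self.AD.size

    @property
    def cells(self) -> list[CellState]:
        return [CellState(a, b) for a, b in zip(self.AD, self.AB)]

    def copy(self) -> "TissueState":
        return TissueState(self.AD.copy(), self.AB.copy(), self.time)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TissueState(N={self.n_cells}, time={self.time})"


@dataclass
class Trajectory:
    """Recorded time evolution of a tissue: ``AD``/``AB`` have shape (T, N)."""

    times: np.ndarray
    AD: np.ndarray
    AB: np.ndarray
    params: ModelParameters
    dt: float
    record_stride: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("recorded times must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return self.AD.shape[1]

    @property
    def states(self) -> list[TissueState]:
        return [self.state_at(i) for i in range(len(self.times))]

    def state_at(self, index: int) -> TissueState:
        return TissueState(self.AD[index], self.AB[index], self.times[index])

    @property
    def final_state(self) -> TissueState:
        return self.state_at(len(self.times) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per cell per recorded time."""
        T, N = self.AD.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, N),
                "cell_index": np.tile(np.arange(N), T),
                "AD": self.AD.ravel(),
                "AB": self.AB.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_j(j: int) -> None:
    if j not in (1, 2):
        raise ValueError(f"gene index must be 1 or 2, got {j!r}")


def _check_z(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if (z < 0).any():
        raise ValueError("repressor/inducer concentration must be nonnegative")
    return z


def production_rate(j: int, z, params: ModelParameters):
    """Repressible Hill production rate f_j(z) = p_j + r_j K^n / (K^n + z^n).

    Strictly decreasing in the repressor concentration ``z``, ranging from
    ``p_j + r_j`` at z=0 down toward the basal rate ``p_j``.
    """
    _check_j(j)
    z = _check_z(z)
    p = params.p1 if j == 1 else params.p2
    r = params.r1 if j == 1 else params.r2
    Kn = params.K_f ** params.n_f
    out = p + r * Kn / (Kn + z ** params.n_f)
    return float(out) if out.ndim == 0 else out


def degradation_rate(j: int, z, params: ModelParameters):
    """Inducible Hill degradation rate g_j(z) = d_j + c_j z^n / (K^n + z^n).

    Strictly increasing in the inducer concentration ``z``, ranging from the
    basal constant ``d_j`` up toward ``d_j + c_j``.
    """
    _check_j(j)
    z = _check_z(z)
    d = params.d1 if j == 1 else params.d2
    c = params.c1 if j == 1 else params.c2
    Kn = params.K_g ** params.n_g
    zn = z ** params.n_g
    out = d + c * zn / (Kn + zn)
    return float(out) if out.ndim == 0 else out


def laplacian(u: np.ndarray) -> np.ndarray:
    """Zero-flux (reflective) discrete Laplacian on a 1D cell file.

    Interior: u[i-1] + u[i+1] - 2 u[i]; end cells have a single neighbour so
    no material crosses the tissue ends and the sum over cells is exactly 0.
    """
    out = np.empty_like(u)
    if u.shape[-1] == 1:
        out[...] = 0.0
        return out
    out[..., 1:-1] = u[..., :-2] + u[..., 2:] - 2.0 * u[..., 1:-1]
    out[..., 0] = u[..., 1] - u[..., 0]
    out[..., -1] = u[..., -2] - u[..., -1]
    return out


def _derivatives(AD, AB, p: ModelParameters):
    Knf = p.K_f ** p.n_f
    Kng = p.K_g ** p.n_g
    ABnf = AB ** p.n_f
    ADnf = AD ** p.n_f
    ABng = AB ** p.n_g
    ADng = AD ** p.n_g
    dAD = (p.p1 + p.r1 * Knf / (Knf + ABnf)) - AD * (p.d1 + p.c1 * ABng / (Kng + ABng))
    dAB = (p.p2 + p.r2 * Knf / (Knf + ADnf)) - AB * (p.d2 + p.c2 * ADng / (Kng + ADng))
    if AD.shape[-1] > 1:
        if np.any(p.D_AD != 0.0):
            dAD += p.D_AD * laplacian(AD)
        if np.any(p.D_AB != 0.0):
            dAB += p.D_AB * laplacian(AB)
    return dAD, dAB


def rhs(state: TissueState, params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dAD/dt, dAB/dt) for every cell of ``state``."""
    return _derivatives(state.AD, state.AB, params)


def integrate(
    state: TissueState,
    params: ModelParameters,
    t_end: float,
    dt: float = 0.2,
    record_stride: int = 5,
    pinned: Mapping[int, tuple[float, float]] | None = None,
) -> Trajectory:
    """Integrate the lattice ODE system with classical fixed-step RK4.

    Parameters
    ----------
    state
        Initial tissue state; ``state.time`` is the start time.
    t_end
        Stop after the first step whose time reaches ``t_end`` (the final
        recorded time is within ``dt`` of it).
    dt
        Fixed integration step (default 0.2).
    record_stride
        Record every this many steps (the initial and final states are always
        recorded).
    pinned
        Optional map cell_index -> (AD, AB): those cells are reset to the
        given values after every RK4 step (Dirichlet-type clamp); they still
        exchange material diffusively with their neighbours.

    Raises
    ------
    IntegrationError
        If a non-finite or negative concentration arises (the model is not
        clamped; negativity indicates an out-of-regime parameter set).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if record_stride < 1:
        raise ValueError("record_stride must be a positive integer")
    if t_end <= state.time:
        raise ValueError("t_end must exceed the initial time")

    n_steps = int(math.ceil((t_end - state.time) / dt - 1e-9))
    ad = state.AD.copy()
    ab = state.AB.copy()
    if pinned:
        for idx, (a, b) in pinned.items():
            ad[idx] = a
            ab[idx] = b

    rec_times = [state.time]
    rec_ad = [ad.copy()]
    rec_ab = [ab.copy()]
    half = dt / 2.0
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1a, k1b = _derivatives(ad, ab, params)
        k2a, k2b = _derivatives(ad + half * k1a, ab + half * k1b, params)
        k3a, k3b = _derivatives(ad + half * k2a, ab + half * k2b, params)
        k4a, k4b = _derivatives(ad + dt * k3a, ab + dt * k3b, params)
        ad = ad + sixth * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        ab = ab + sixth * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        if pinned:
            for idx, (a, b) in pinned.items():
                ad[idx] = a
                ab[idx] = b
        if not (np.isfinite(ad).all() and np.isfinite(ab).all()):
            raise IntegrationError(f"non-finite state at step {step}")
        if (ad < 0).any() or (ab < 0).any():
            raise IntegrationError(f"negative concentration at step {step}")
        if step % record_stride == 0 or step == n_steps:
            rec_times.append(state.time + step * dt)
            rec_ad.append(ad.copy())
            rec_ab.append(ab.copy())

    return Trajectory(
        times=np.asarray(rec_times),
        AD=np.vstack(rec_ad),
        AB=np.vstack(rec_ab),
        params=params,
        dt=dt,
        record_stride=record_stride,
    )
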
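"""Single-cell (diffusion-free) analysis: nullclines, fixed points, stability.

With mutual repression strong enough, the single-cell system is bistable: an
AD-expressing and an AB-expressing stable fixed point coexist, separated by a
saddle.  Fixed points are located as intersections of the two nullclines

    AD-nullcline:  AD = f1(AB) / g1(AB)
    AB-nullcline:  AB = f2(AD) / g2(AD)

by a sign-change scan along the AD-nullcline followed by Newton refinement of
the full 2D system, and classified through the Jacobian eigenvalues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import ModelParameters, TissueState, degradation_rate, production_rate

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "SolverError",
    "MarginalStabilityError",
    "nullclines",
    "jacobian",
    "find_steady_states",
    "is_bistable",
]

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-6
STABILITY_EPS = 1e-9
SCAN_POINTS = 2000


class SolverError(RuntimeError):
    """A bracketed nullcline intersection failed to converge."""


class MarginalStabilityError(RuntimeError):
    """An eigenvalue real part is numerically zero; classification is unsafe."""


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the diffusion-free system with its stability label."""

    AD: float
    AB: float
    stability: str  # "stable" | "unstable" | "saddle"
    eigenvalues: tuple[complex, complex]

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class SteadyStateSet:
    """Deduplicated fixed points of one parameter set."""

    states: tuple[SteadyState, ...]
    params: ModelParameters

    @property
    def stable(self) -> tuple[SteadyState, ...]:
        return tuple(s for s in self.states if s.is_stable)

    @property
    def ad_expressing(self) -> SteadyState:
        """The stable state with AD dominant (highest AD among stable states)."""
        stable = self.stable
        if not stable:
            raise ValueError("no stable steady state")
        best = max(stable, key=lambda s: s.AD - s.AB)
        if best.AD <= best.AB:
            raise ValueError("no stable state with AD > AB")
        return best

    @property
    def ab_expressing(self) -> SteadyState:
        stable = self.stable
        if not stable:
            raise ValueError("no stable steady state")
        best = max(stable, key=lambda s: s.AB - s.AD)
        if best.AB <= best.AD:
            raise ValueError("no stable state with AB > AD")
        return best

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "AD": s.AD,
                    "AB": s.AB,
                    "stability": s.stability,
                    "eigenvalue_real_parts": [e.real for e in s.eigenvalues],
                }
                for s in self.states
            ],
            indent=2,
        )


def _f(j, z, p):
    return production_rate(j, z, p)


def _g(j, z, p):
    return degradation_rate(j, z, p)


def nullclines(params: ModelParameters, z_grid) -> tuple[np.ndarray, np.ndarray]:
    """Sample both nullclines over a concentration grid.

    Returns ``(ad_curve, ab_curve)``: arrays of shape (M, 2) with columns
    (AD, AB).  The AD-nullcline is parameterized by AB = z, the AB-nullcline
    by AD = z.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.size == 0:
        raise ValueError("grid must be nonempty")
    if (z < 0).any():
        raise ValueError("grid must be nonnegative")
    ad_curve = np.column_stack([_f(1, z, params) / _g(1, z, params), z])
    ab_curve = np.column_stack([z, _f(2, z, params) / _g(2, z, params)])
    return ad_curve, ab_curve


def _hill_derivs(z, n, K, scale):
    """d/dz of scale * z^n / (K^n + z^n) and of scale * K^n / (K^n + z^n)."""
    Kn = K ** n
    zn = z ** n
    denom = (Kn + zn) ** 2
    rising = scale * n * Kn * z ** (n - 1) / denom
    return rising  # the falling form's derivative is just -rising


def jacobian(AD: float, AB: float, p: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the diffusion-free system at (AD, AB)."""
    f1p = -_hill_derivs(AB, p.n_f, p.K_f, p.r1)
    f2p = -_hill_derivs(AD, p.n_f, p.K_f, p.r2)
    g1p = _hill_derivs(AB, p.n_g, p.K_g, p.c1)
    g2p = _hill_derivs(AD, p.n_g, p.K_g, p.c2)
    return np.array(
        [
            [-_g(1, AB, p), f1p - AD * g1p],
            [f2p - AB * g2p, -_g(2, AD, p)],
        ]
    )


def _classify(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) <= STABILITY_EPS):
        raise MarginalStabilityError(
            f"marginal eigenvalue real part {re}; cannot classify"
        )
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def _single_cell_rhs(xy: np.ndarray, p: ModelParameters) -> np.ndarray:
    AD, AB = xy
    dAD = _f(1, AB, p) - AD * _g(1, AB, p)
    dAB = _f(2, AD, p) - AB * _g(2, AD, p)
    return np.array([dAD, dAB])


def find_steady_states(params: ModelParameters) -> SteadyStateSet:
    """Locate and classify all fixed points of the single-cell system.

    The AD-nullcline AD = f1(AB)/g1(AB) is scanned over
    AB in [0, (p2+r2)/d2] (the analytic supremum of the AB-nullcline);
    sign changes of the AB-nullcline residual bracket each intersection,
    which is refined by Brent's method and then Newton-polished on the full
    2D system to residual below ``RESIDUAL_TOL``.
    """
    ab_max = (params.p2 + params.r2) / params.d2

    def residual(ab: float) -> float:
        ad = _f(1, ab, params) / _g(1, ab, params)
        return ab - _f(2, ad, params) / _g(2, ad, params)

    grid = np.linspace(0.0, ab_max, SCAN_POINTS)
    ad_on = _f(1, grid, params) / _g(1, grid, params)
    res = grid - _f(2, ad_on, params) / _g(2, ad_on, params)

    roots_ab: list[float] = []
    for i in range(len(grid) - 1):
        if res[i] == 0.0:
            roots_ab.append(grid[i])
        elif res[i] * res[i + 1] < 0:
            try:
                ab_root = optimize.brentq(
                    residual, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise SolverError(
                    f"no convergence in bracket [{grid[i]}, {grid[i + 1]}]"
                ) from exc
            roots_ab.append(ab_root)
    if res[-1] == 0.0:
        roots_ab.append(grid[-1])

    states: list[SteadyState] = []
    for ab_root in roots_ab:
        ad_root = _f(1, ab_root, params) / _g(1, ab_root, params)
        sol = optimize.root(
            _single_cell_rhs,
            np.array([ad_root, ab_root]),
            args=(params,),
            jac=lambda xy, p: jacobian(xy[0], xy[1], p),
            method="hybr",
            tol=1e-13,
        )
        point = sol.x if sol.success else np.array([ad_root, ab_root])
        resid = np.max(np.abs(_single_cell_rhs(point, params)))
        if resid >= RESIDUAL_TOL:
            raise SolverError(
                f"fixed point near (AD={ad_root:.6g}, AB={ab_root:.6g}) "
                f"refined only to residual {resid:.3g}"
            )
        AD, AB = float(point[0]), float(point[1])
        if any(abs(AD - s.AD) < DEDUP_TOL and abs(AB - s.AB) < DEDUP_TOL for s in states):
            continue
        eigs = np.linalg.eigvals(jacobian(AD, AB, params))
        states.append(
            SteadyState(AD, AB, _classify(eigs), (complex(eigs[0]), complex(eigs[1])))
        )

    states.sort(key=lambda s: s.AB)
    return SteadyStateSet(tuple(states), params)


def is_bistable(params: ModelParameters) -> bool:
    """True iff the single-cell system has at least two stable fixed points."""
    return len(find_steady_states(params).stable) >= 2


def steady_state_tissue(ss: SteadyState, n_cells: int, time: float = 0.0) -> TissueState:
    """Uniform tissue with every cell at the given fixed point."""
    return TissueState(
        np.full(n_cells, ss.AD), np.full(n_cells, ss.AB), time
    )
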
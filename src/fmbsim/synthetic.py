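"""Synthetic two-channel marker-intensity profiles with a known boundary.

Stands in for per-cell fluorescence readouts of an abaxial marker (e.g. a
FIL-promoter GFP reporter) and an adaxial miRNA-sensor channel along a 1D
adaxial->abaxial cell column.  Noiseless channel means are opposing logistic
profiles centred on the ground-truth boundary; observed intensities carry
independent multiplicative lognormal noise per cell and channel (fluorescence
noise is strictly positive and roughly multiplicative, so additive Gaussian —
which can go negative — is deliberately avoided).

The estimator mirrors the simulation-side boundary localizer: normalize each
channel to unit maximum and take the interpolated zero crossing of
(abaxial - adaxial) nearest the adaxial end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerProfile",
    "EstimationError",
    "generate_profile",
    "estimate_boundary",
    "generate_stage_series",
]

DEFAULT_STEEPNESS = 4.0
DEFAULT_BASELINE_FRAC = 0.05


class EstimationError(RuntimeError):
    """The boundary cannot be estimated from the profile."""


@dataclass(frozen=True)
class MarkerProfile:
    """Per-cell intensities of the adaxial and abaxial channels plus the
    generating ground truth."""

    adaxial_channel: np.ndarray
    abaxial_channel: np.ndarray
    true_boundary: float
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        n = self.adaxial_channel.size
        if n < 2 or self.abaxial_channel.size != n:
            raise ValueError("channels must be equal-length with N >= 2")
        if (self.adaxial_channel < 0).any() or (self.abaxial_channel < 0).any():
            raise ValueError("intensities must be nonnegative")
        if not 0.0 <= self.true_boundary <= n - 1:
            raise ValueError("true_boundary must lie within [0, N-1]")

    @property
    def n_cells(self) -> int:
        return self.adaxial_channel.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": np.arange(self.n_cells),
                "adaxial_intensity": self.adaxial_channel,
                "abaxial_intensity": self.abaxial_channel,
            }
        )

    def write_csv(self, path, sidecar_path=None) -> None:
        """Write intensities as CSV; optionally a JSON sidecar with the
        ground truth and generation settings."""
        self.to_frame().to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "true_boundary": self.true_boundary,
                        "noise_sigma": self.noise_sigma,
                        "seed": self.seed,
                    },
                    fh,
                    indent=2,
                )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_profile(
    N: int,
    true_boundary: float,
    steepness: float = DEFAULT_STEEPNESS,
    noise_sigma: float = 0.1,
    baseline_frac: float = DEFAULT_BASELINE_FRAC,
    seed: int = 0,
) -> MarkerProfile:
    """Generate one noisy two-channel profile over ``N`` cells.

    The abaxial channel rises and the adaxial channel falls logistically
    across ``true_boundary`` with the given per-cell ``steepness``, scaled to
    [baseline_frac, 1]; the default steepness keeps the both-channels-high
    overlap within about one cell width.  ``noise_sigma`` is the lognormal
    shape parameter of the multiplicative noise (0 = noiseless).
    """
    if N < 2:
        raise ValueError("need N >= 2 cells")
    if not 0.0 <= true_boundary <= N - 1:
        raise ValueError("true_boundary must lie within [0, N-1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not 0.0 <= baseline_frac < 1.0:
        raise ValueError("baseline_frac must lie in [0, 1)")
    x = np.arange(N, dtype=float) - true_boundary
    span = 1.0 - baseline_frac
    abaxial = baseline_frac + span * _logistic(steepness * x)
    adaxial = baseline_frac + span * _logistic(-steepness * x)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        adaxial = adaxial * rng.lognormal(0.0, noise_sigma, N)
        abaxial = abaxial * rng.lognormal(0.0, noise_sigma, N)
    return MarkerProfile(adaxial, abaxial, float(true_boundary), float(noise_sigma), int(seed))


def estimate_boundary(profile: MarkerProfile) -> float:
    """Estimate the boundary as the interpolated crossing of the normalized
    channels, nearest the adaxial end."""
    ad_max = profile.adaxial_channel.max()
    ab_max = profile.abaxial_channel.max()
    if ad_max == 0 or ab_max == 0:
        raise EstimationError("a channel is entirely zero; no boundary signal")
    s = profile.abaxial_channel / ab_max - profile.adaxial_channel / ad_max
    for i in range(s.size - 1):
        if s[i] == 0.0:
            return float(i)
        if s[i] * s[i + 1] < 0:
            return float(i + s[i] / (s[i] - s[i + 1]))
    if s[-1] == 0.0:
        return float(s.size - 1)
    raise EstimationError("channels never cross; no boundary within the profile")


def _replicate_seed(master_seed: int, counter: int) -> int:
    """Derive a well-mixed per-replicate seed from (master seed, counter)."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % (2**31))


def generate_stage_series(
    stages: list[float],
    N: int,
    steepness: float = DEFAULT_STEEPNESS,
    noise_sigma: float = 0.1,
    baseline_frac: float = DEFAULT_BASELINE_FRAC,
    replicates: int = 1,
    seed: int = 0,
) -> dict[int, list[MarkerProfile]]:
    """Replicated profiles across a developmental series of true boundaries.

    Emulates sections of progressively older primordia in which the boundary
    sits progressively more abaxially.  Returns ``{stage_index: [profiles]}``;
    replicate seeds are derived from the master seed via a stage-major
    counter, so the whole collection is reproducible from ``seed`` alone.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out: dict[int, list[MarkerProfile]] = {}
    counter = 0
    for stage_idx, b in enumerate(stages):
        profiles = []
        for _ in range(replicates):
            profiles.append(
                generate_profile(
                    N,
                    b,
                    steepness=steepness,
                    noise_sigma=noise_sigma,
                    baseline_frac=baseline_frac,
                    seed=_replicate_seed(seed, counter),
                )
            )
            counter += 1
        out[stage_idx] = profiles
    return out
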
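"""Multiscale entropy: coarse-graining, sample entropy, per-channel profiles.

Entropy values are reported in nats. The matching tolerance is derived once
from the scale-1 series (population standard deviation) and held fixed
across scales, so that coarse-grained variance loss is part of the measured
complexity rather than normalized away.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._sampen import count_matches

__all__ = [
    "MseParams",
    "MseProfile",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
    "grand_average_profiles",
    "CoarseScaleWarning",
]


class CoarseScaleWarning(UserWarning):
    """Raised when coarse scales leave few samples and estimates are noisy."""


@dataclass(frozen=True)
class MseParams:
    """Parameters of the multiscale sample-entropy computation."""

    m: int = 2
    r_coeff: float = 0.15
    scales: tuple[int, ...] = tuple(range(1, 21))
    tolerance_reference: str = "scale1_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"pattern length m must be >= 1, got {self.m}")
        if not (self.r_coeff > 0):
            raise ValueError(f"r_coeff must be > 0, got {self.r_coeff}")
        scales = tuple(int(s) for s in self.scales)
        if len(scales) == 0:
            raise ValueError("scales must be non-empty")
        if any(s < 1 for s in scales):
            raise ValueError("scales must be positive integers")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", scales)
        if self.tolerance_reference not in ("scale1_sd", "per_scale_sd"):
            raise ValueError(
                f"unknown tolerance_reference {self.tolerance_reference!r}"
            )


@dataclass
class MseProfile:
    """Entropy value per scale factor plus the scale-averaged scalar."""

    channel: str | None
    values: dict[int, float]
    averaged_mse: float
    undefined_scales: list[int] = field(default_factory=list)

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(self.values.keys())


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping windows of ``tau`` samples; remainder dropped."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    tau = int(tau)
    if tau < 1:
        raise ValueError(f"scale factor must be >= 1, got {tau}")
    if tau > x.shape[0]:
        raise ValueError(
            f"scale factor {tau} exceeds series length {x.shape[0]}"
        )
    if tau == 1:
        return x.copy()
    n_out = x.shape[0] // tau
    return x[: n_out * tau].reshape(n_out, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = 2, r_tol: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with absolute tolerance ``r_tol``.

    Returns NaN when no template pair matches at length ``m`` or ``m+1``
    (the conditional probability is undefined).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if m < 1:
        raise ValueError(f"pattern length m must be >= 1, got {m}")
    if x.shape[0] <= m + 1:
        raise ValueError(
            f"series length {x.shape[0]} too short for m={m}; need > {m + 1}"
        )
    if r_tol is None or not np.isfinite(r_tol) or r_tol <= 0:
        raise ValueError(f"r_tol must be a positive finite number, got {r_tol}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    a, b = count_matches(x, int(m), float(r_tol))
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def multiscale_entropy(
    series: np.ndarray,
    params: MseParams = MseParams(),
    channel: str | None = None,
) -> MseProfile:
    """Sample entropy of the coarse-grained series at each scale factor.

    The tolerance ``r = r_coeff * sd`` is fixed from the scale-1 series by
    default. A degenerate (constant) series yields an all-undefined profile
    rather than an error.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    max_scale = max(params.scales)
    n_coarse_min = x.shape[0] // max_scale
    if n_coarse_min <= params.m + 1:
        raise ValueError(
            f"series of length {x.shape[0]} leaves {n_coarse_min} samples at "
            f"scale {max_scale}; need more than m+1={params.m + 1}"
        )
    if n_coarse_min < 100:
        warnings.warn(
            f"only {n_coarse_min} samples at scale {max_scale}; coarse-scale "
            "entropy estimates are high-variance",
            CoarseScaleWarning,
            stacklevel=2,
        )
    sd = float(np.std(x))  # population SD (ddof=0), pinned for reproducibility
    values: dict[int, float] = {}
    undefined: list[int] = []
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):  # degenerate series
        for tau in params.scales:
            values[tau] = math.nan
            undefined.append(tau)
        return MseProfile(channel, values, math.nan, undefined)
    r_tol = params.r_coeff * sd
    for tau in params.scales:
        cg = coarse_grain(x, tau)
        if params.tolerance_reference == "per_scale_sd":
            sd_tau = float(np.std(cg))
            r_use = params.r_coeff * sd_tau if sd_tau > 0 else math.nan
        else:
            r_use = r_tol
        if not (r_use > 0):
            values[tau] = math.nan
            undefined.append(tau)
            continue
        val = sample_entropy(cg, params.m, r_use)
        values[tau] = val
        if math.isnan(val):
            undefined.append(tau)
    defined = [v for v in values.values() if not math.isnan(v)]
    averaged = float(np.mean(defined)) if defined else math.nan
    return MseProfile(channel, values, averaged, undefined)


def grand_average_profiles(profiles: Sequence[MseProfile]) -> MseProfile:
    """Per-scale arithmetic mean over profiles, ignoring undefined values."""
    if len(profiles) == 0:
        raise ValueError("cannot average an empty list of profiles")
    scales = profiles[0].scales
    for p in profiles[1:]:
        if p.scales != scales:
            raise ValueError("profiles have mismatched scale sets")
    values: dict[int, float] = {}
    undefined: list[int] = []
    for tau in scales:
        vals = [p.values[tau] for p in profiles if not math.isnan(p.values[tau])]
        if vals:
            values[tau] = float(np.mean(vals))
        else:
            values[tau] = math.nan
            undefined.append(tau)
    defined = [v for v in values.values() if not math.isnan(v)]
    averaged = float(np.mean(defined)) if defined else math.nan
    return MseProfile(None, values, averaged, undefined)
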
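"""Preprocessing chain: bandpass filter, linear detrend, skin-blood-flow
removal via rest-period eigen-decomposition.

Stage order is fixed: filter -> detrend -> SBF removal. The SBF model is a
set of spatial (channel-space) principal components fitted on the filtered,
detrended rest segment of the same session; the task segment is centered
with the rest-period channel means before projection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .synthetic import NirsSession

__all__ = [
    "FilterSpec",
    "SbfModel",
    "bandpass_filter",
    "detrend_linear",
    "fit_sbf",
    "remove_sbf",
    "preprocess_session",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass: first order, 0.01-0.6 Hz, zero-phase by default."""

    order: int = 1
    low_hz: float = 0.01
    high_hz: float = 0.6
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"need 0 < low_hz < high_hz < fs/2; got "
                f"low={self.low_hz}, high={self.high_hz}, fs={fs}"
            )
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")


def bandpass_filter(series: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the Butterworth bandpass along the last axis.

    Accepts a 1-D series or a channels x samples matrix.
    """
    x = np.asarray(series, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    spec.validate(fs)
    b, a = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs
    )
    warmup = 3 * max(len(a), len(b))
    min_len = 3 * warmup + 1
    if x.shape[-1] < min_len:
        raise ValueError(
            f"series length {x.shape[-1]} too short for stable filtering; "
            f"minimum is {min_len} samples"
        )
    if spec.zero_phase:
        return signal.filtfilt(b, a, x, axis=-1)
    return signal.lfilter(b, a, x, axis=-1)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares line along the last axis."""
    x = np.asarray(series, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError(f"need at least 2 samples to detrend, got {x.shape[-1]}")
    return signal.detrend(x, axis=-1, type="linear")


@dataclass
class SbfModel:
    """Spatial principal components of the rest period, fitted per session."""

    n_components: int
    component_vectors: np.ndarray  # channels x n_components, orthonormal
    channel_means: np.ndarray  # per-channel mean of the rest data

    @property
    def n_channels(self) -> int:
        return self.channel_means.shape[0]


def fit_sbf(rest: np.ndarray, n_components: int = 3) -> SbfModel:
    """Fit the top channel-space eigenvectors of the rest-period covariance."""
    rest = np.asarray(rest, dtype=np.float64)
    if rest.ndim != 2:
        raise ValueError("rest must be a channels x samples matrix")
    n_ch, n_samp = rest.shape
    if n_samp < 2:
        raise ValueError("rest period needs at least 2 samples")
    if not (0 <= n_components <= n_ch):
        raise ValueError(
            f"n_components={n_components} must lie in [0, {n_ch}] "
            f"for {n_ch} channels"
        )
    means = rest.mean(axis=1)
    centered = rest - means[:, None]
    cov = centered @ centered.T / n_samp
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    vectors = eigvecs[:, order[:n_components]]
    return SbfModel(n_components=n_components, component_vectors=vectors, channel_means=means)


def remove_sbf(task: np.ndarray, model: SbfModel) -> np.ndarray:
    """Project the model's components out of the (centered) task data."""
    task = np.asarray(task, dtype=np.float64)
    if task.ndim != 2:
        raise ValueError("task must be a channels x samples matrix")
    if task.shape[0] != model.n_channels:
        raise ValueError(
            f"task has {task.shape[0]} channels but model was fitted on "
            f"{model.n_channels}"
        )
    if model.n_components == 0:
        return task.copy()
    centered = task - model.channel_means[:, None]
    v = model.component_vectors
    return task - v @ (v.T @ centered)


def preprocess_session(
    session: NirsSession,
    filter_spec: FilterSpec = FilterSpec(),
    n_components: int = 3,
) -> NirsSession:
    """Full chain on one session: filter, detrend, then SBF removal.

    The SBF model is fitted on the identically filtered and detrended rest
    segment; the returned session carries the preprocessed rest for audit.
    """
    if session.task.size == 0 or session.rest.size == 0:
        raise ValueError("session has an empty rest or task matrix")
    fs = session.sampling_rate_hz
    rest = detrend_linear(bandpass_filter(session.rest, fs, filter_spec))
    task = detrend_linear(bandpass_filter(session.task, fs, filter_spec))
    model = fit_sbf(rest, n_components)
    task = remove_sbf(task, model)
    return replace(session, rest=rest, task=task)
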
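"""Sensor-to-source projection onto two auditory-cortex sources.

A transparent algebraic stand-in for dipole fitting: the sensor-space TRF
restricted to the P1 window is decomposed per hemisphere by SVD, the two
leading hemisphere-lateralized singular vectors become forward
topographies, and their pseudo-inverse is the spatial (unmixing) filter.
The filter is fitted once per subject on single-stream (prime) data and
then applied unchanged to the kernels and continuous data of every
condition, mirroring how a P1-anchored dipole model is reused as a fixed
spatial filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trf import Recording, TRFEstimate

__all__ = ["SpatialFilter", "fit_spatial_filter", "to_source"]


@dataclass
class SpatialFilter:
    """Linear sensor->source weights for two lateralized sources."""

    unmixing: np.ndarray  # 2 x channels
    forward: np.ndarray  # channels x 2
    p1_window: tuple[float, float]
    hemispheres: tuple[str, str] = ("L", "R")

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.unmixing)):
            raise ValueError("spatial filter weights must be finite")


def _hemisphere_of(name: str) -> str:
    """Channel names carry their hemisphere as the first 'L'/'R' letter."""
    for ch in name:
        if ch in "LR":
            return ch
    raise ValueError(f"cannot infer hemisphere from channel name {name!r}")


def fit_spatial_filter(
    sensor_trf: TRFEstimate,
    p1_window: tuple[float, float] = (0.050, 0.100),
    regressor: str = "target_onsets",
    hemispheres: Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
) -> SpatialFilter:
    """Fit the two-source spatial filter to the P1 of a sensor-space TRF.

    The envelope-onset kernel (channels x lags) restricted to the P1 window
    is SVD-decomposed separately over left- and right-hemisphere channels;
    the leading singular vectors (zero outside their hemisphere) form the
    forward topographies and the unmixing is their pseudo-inverse. The sign
    convention makes the P1 positive in each source waveform.
    """
    kernel = sensor_trf.kernel(regressor)  # channels x lags
    lags = sensor_trf.lags
    sel = (lags >= p1_window[0] - 1e-12) & (lags <= p1_window[1] + 1e-12)
    if not np.any(sel):
        raise ValueError("P1 window contains no lag samples")
    win = kernel[:, sel]
    n_ch = kernel.shape[0]
    if hemispheres is None:
        if channel_names is None:
            raise ValueError("provide hemispheres or channel_names")
        hemispheres = [_hemisphere_of(n) for n in channel_names]
    hemispheres = list(hemispheres)
    forward = np.zeros((n_ch, 2))
    for col, side in enumerate(["L", "R"]):
        idx = np.array([h == side for h in hemispheres])
        if idx.sum() == 0:
            raise ValueError(f"no channels labeled {side!r}")
        block = win[idx]
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        if s[0] <= 1e-12 * max(1.0, np.abs(win).max()):
            raise ValueError(
                f"sensor kernel has no energy on {side!r} channels in the P1 window"
            )
        topo = u[:, 0]
        # sign: source waveform (topo . block) must peak positive in window
        if np.max(topo @ block) < np.max(-(topo @ block)):
            topo = -topo
        forward[idx, col] = topo
    if np.linalg.matrix_rank(forward) < 2:
        raise ValueError("forward topographies are rank deficient")
    unmixing = np.linalg.pinv(forward)
    return SpatialFilter(unmixing=unmixing, forward=forward, p1_window=tuple(p1_window))


def to_source(data, filt: SpatialFilter):
    """Project sensor-space data or kernels onto the two source waveforms.

    Accepts a Recording (returns a 2 x samples array), a TRFEstimate
    (returns a TRFEstimate whose 'channels' are the two sources), or a raw
    channels x samples array. The same filter is reused for all of a
    subject's conditions.
    """
    n_ch = filt.unmixing.shape[1]
    if isinstance(data, Recording):
        if data.data.shape[0] != n_ch:
            raise ValueError("channel count does not match the spatial filter")
        return filt.unmixing @ data.data
    if isinstance(data, TRFEstimate):
        if data.kernels.shape[1] != n_ch:
            raise ValueError("channel count does not match the spatial filter")
        src_kernels = np.einsum("sc,rcl->rsl", filt.unmixing, data.kernels)
        return TRFEstimate(
            kernels=src_kernels,
            regressor_names=list(data.regressor_names),
            lags=data.lags,
            lambda_=data.lambda_,
            residual_var=data.residual_var,
            n_samples=data.n_samples,
            intercept=None,
        )
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] != n_ch:
        raise ValueError("channel count does not match the spatial filter")
    return filt.unmixing @ arr
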
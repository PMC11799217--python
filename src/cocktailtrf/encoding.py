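"""Neural-encoding (forward prediction) accuracy.

How well does the estimated TRF, convolved with the stimulus envelope
onsets, predict the continuous source signal? Accuracy is the Pearson
correlation between predicted and recorded signal on held-out data,
evaluated in a 5-fold leave-one-out scheme: the TRF is fitted on 80% of a
condition's trials and tested on the remaining 20%, and the per-subject
mean over the five folds is retained. Target and masker envelopes are
modeled jointly in the fit but scored separately (each stream's kernel
convolved with its own envelope); event regressors are excluded here.
Windowed variants zero the kernel outside a latency window (e.g. the P1
or Nd range) before predicting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .trf import (
    DEFAULT_LAG_RANGE,
    Recording,
    RegressorSet,
    TRFEstimate,
    Trial,
    build_design,
    lag_axis,
    ridge_solve,
)

__all__ = [
    "EncodingResult",
    "predict_signal",
    "encoding_accuracy",
    "crossval_encoding",
    "windowed_encoding",
]

STREAM_REGRESSORS = {"target": "target_onsets", "masker": "masker_onsets"}


@dataclass
class EncodingResult:
    """Per-fold and mean encoding accuracies for one condition."""

    table: pd.DataFrame  # columns: fold, stream, channel, r
    mean_r: dict[str, float]  # stream -> mean r over folds and channels
    fold_trials: list[list[int]]
    lambda_: float
    window: tuple[float, float] | None = None


def predict_signal(
    trf: TRFEstimate,
    regs: RegressorSet,
    trials: list[Trial],
    n_samples: int,
    regressors: list[str] | None = None,
) -> np.ndarray:
    """Convolve kernels with regressors, trial-bounded (channels x samples).

    The prediction at sample n is sum over regressors and lags of
    T(m) s(n - m), where s is zeroed outside each trial (no cross-trial
    leakage, matching the design-matrix convention).
    """
    rate = regs.rate
    n_lags = len(trf.lags)
    l0 = int(round(trf.lags[0] * rate))
    if n_lags != trf.kernels.shape[2]:
        raise ValueError("lag axis does not match kernel shape")
    names = regressors if regressors is not None else trf.regressor_names
    n_ch = trf.kernels.shape[1]
    pred = np.zeros((n_ch, n_samples))
    for trial in trials:
        sl = trial.sample_slice(rate)
        n = sl.stop - sl.start
        acc = np.zeros((n_ch, n))
        for name in names:
            if name not in regs.series:
                raise ValueError(f"regressor {name!r} missing from the set")
            k = trf.kernel(name)  # (C, L)
            s = regs.series[name][sl]
            full = _signal.fftconvolve(k, s[None, :], axes=1)  # (C, n + L - 1)
            lo = max(0, l0)
            src_lo = lo - l0
            take = min(n - lo, full.shape[1] - src_lo)
            if take > 0:
                acc[:, lo : lo + take] += full[:, src_lo : src_lo + take]
        pred[:, sl] += acc
    if trf.intercept is not None:
        for trial in trials:
            sl = trial.sample_slice(rate)
            pred[:, sl] += trf.intercept[:, None]
    return pred


def encoding_accuracy(pred: np.ndarray, observed: np.ndarray) -> float | np.ndarray:
    """Pearson correlation between predicted and observed series.

    One-dimensional inputs give a scalar r; channels x samples inputs give
    one r per channel. Zero variance in either series is an error.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed series must have equal shapes")
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    o = np.atleast_2d(o)
    p = p - p.mean(axis=1, keepdims=True)
    o = o - o.mean(axis=1, keepdims=True)
    sp = np.sqrt((p**2).sum(axis=1))
    so = np.sqrt((o**2).sum(axis=1))
    if np.any(sp == 0) or np.any(so == 0):
        raise ValueError("zero variance in predicted or observed series")
    r = (p * o).sum(axis=1) / (sp * so)
    return float(r[0]) if squeeze else r


def _fold_blocks(n_trials: int, n_folds: int, shuffle: bool, rng) -> list[list[int]]:
    order = np.arange(n_trials)
    if shuffle:
        np.random.default_rng(rng).shuffle(order)
    return [list(block) for block in np.array_split(order, n_folds)]


def crossval_encoding(
    recording: Recording,
    regs: RegressorSet,
    lam: float,
    condition: str | None = None,
    n_folds: int = 5,
    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE,
    stream_regressors: dict[str, str] | None = None,
    shuffle: bool = False,
    rng=None,
) -> EncodingResult:
    """5-fold cross-validated encoding accuracy for one condition.

    Folds are contiguous trial blocks by default (seedable random blocks
    via ``shuffle``). Per fold the TRF is fitted on the other folds' trials
    with the pre-selected lambda and the held-out trials are predicted; r
    is computed per stream role over the fold's unmasked samples.
    """
    return _crossval(
        recording, regs, lam, condition, n_folds, lag_range,
        stream_regressors, shuffle, rng, window=None,
    )


def windowed_encoding(
    recording: Recording,
    regs: RegressorSet,
    lam: float,
    window: tuple[float, float],
    condition: str | None = None,
    n_folds: int = 5,
    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE,
    stream_regressors: dict[str, str] | None = None,
    shuffle: bool = False,
    rng=None,
) -> EncodingResult:
    """Encoding accuracy with kernels zeroed outside a latency window."""
    return _crossval(
        recording, regs, lam, condition, n_folds, lag_range,
        stream_regressors, shuffle, rng, window=window,
    )


def _crossval(
    recording, regs, lam, condition, n_folds, lag_range,
    stream_regressors, shuffle, rng, window,
) -> EncodingResult:
    stream_regressors = stream_regressors or {
        k: v for k, v in STREAM_REGRESSORS.items() if v in regs.series
    }
    trials = [
        t for t in recording.trials if condition is None or t.condition == condition
    ]
    if len(trials) < n_folds:
        raise ValueError(f"need at least {n_folds} trials, got {len(trials)}")
    env_names = list(stream_regressors.values())
    env_regs = regs.subset(env_names)
    lags = lag_axis(lag_range, recording.rate)
    mask = recording.exclusion_mask()
    folds = _fold_blocks(len(trials), n_folds, shuffle, rng)
    rows = []
    for fi, test_idx in enumerate(folds):
        train = [t for i, t in enumerate(trials) if i not in test_idx]
        test = [trials[i] for i in test_idx]
        X, rows_idx = build_design(env_regs, lag_range, train, recording.rate, mask)
        y = recording.data[:, rows_idx].T
        est = ridge_solve(
            X, y, lam, regressor_names=env_names, lags=lags, has_intercept=True
        )
        if window is not None:
            zeroed = est.kernels.copy()
            keep = (lags >= window[0] - 1e-12) & (lags <= window[1] + 1e-12)
            zeroed[:, :, ~keep] = 0.0
            est = TRFEstimate(
                kernels=zeroed,
                regressor_names=est.regressor_names,
                lags=est.lags,
                lambda_=est.lambda_,
                residual_var=est.residual_var,
                n_samples=est.n_samples,
                intercept=est.intercept,
            )
        test_samples = np.concatenate(
            [np.arange(t.sample_slice(recording.rate).start,
                       t.sample_slice(recording.rate).stop) for t in test]
        )
        test_samples = test_samples[~mask[test_samples]]
        for stream, reg_name in stream_regressors.items():
            pred = predict_signal(est, env_regs, test, recording.n_samples,
                                  regressors=[reg_name])
            r = encoding_accuracy(pred[:, test_samples],
                                  recording.data[:, test_samples])
            for ch, rv in enumerate(np.atleast_1d(r)):
                rows.append((fi, stream, ch, float(rv)))
    table = pd.DataFrame(rows, columns=["fold", "stream", "channel", "r"])
    mean_r = table.groupby("stream")["r"].mean().to_dict()
    return EncodingResult(
        table=table, mean_r=mean_r, fold_trials=folds, lambda_=lam, window=window
    )
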
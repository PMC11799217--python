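"""Temporal response function (TRF) estimation by ridge deconvolution.

The forward model is r(n) = sum_m T(m) s(n - m) + e(n): the continuous
neural response is the stimulus feature convolved with an unknown kernel T
over lags spanning -500 to +1000 ms, plus residual noise. T is estimated
per channel from a lagged design matrix with an L2 (ridge) penalty; the
penalty weight lambda is selected by leave-one-trial-out cross-validation
on single-stream data and then reused for all conditions so that kernel
amplitudes remain comparable across conditions.

Regressors are the envelope-onset series of each stream plus unit-impulse
event series (target-word onsets per stream, button presses) fitted
jointly. Lags referencing samples outside a trial are zero-padded within
the trial; excluded spans (the cue second at the start of each mixture
trial) are dropped row-wise after lagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import linalg, signal

__all__ = [
    "Trial",
    "Recording",
    "RegressorSet",
    "TRFEstimate",
    "LatencyEstimate",
    "preprocess_recording",
    "lag_axis",
    "build_design",
    "ridge_solve",
    "select_lambda",
    "estimate_trf",
    "bootstrap_peak_latency",
    "DEFAULT_LAG_RANGE",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAG_RANGE = (-0.5, 1.0)
#: decade-spaced grid spanning 1e-6 ... 1e10 (17 values)
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-6, 11))


@dataclass
class Trial:
    """One contiguous stimulus presentation within a Recording."""

    start: float
    stop: float
    condition: str

    def sample_slice(self, rate: float) -> slice:
        return slice(int(round(self.start * rate)), int(round(self.stop * rate)))


@dataclass
class Recording:
    """Multichannel continuous neural time series at the analysis rate.

    ``data`` is channels x samples; ``trials`` mark non-overlapping stimulus
    presentations; ``exclude`` lists (start, stop) spans in seconds (e.g. the
    cue second of each mixture trial) that are dropped from all fits.
    """

    data: np.ndarray
    rate: float
    channel_names: Sequence[str]
    trials: list[Trial] = field(default_factory=list)
    exclude: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        spans = sorted((t.start, t.stop) for t in self.trials)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("trials overlap")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def exclusion_mask(self) -> np.ndarray:
        """Boolean per-sample mask, True where the sample is excluded."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for start, stop in self.exclude:
            mask[int(round(start * self.rate)) : int(round(stop * self.rate))] = True
        return mask


@dataclass
class RegressorSet:
    """Named regressor series sharing the Recording's time base."""

    series: dict[str, np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        lengths = {name: len(np.asarray(x)) for name, x in self.series.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"regressors have unequal lengths: {lengths}")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}

    @property
    def names(self) -> list[str]:
        return list(self.series)

    def n_samples(self) -> int:
        return len(next(iter(self.series.values())))

    def subset(self, names: Sequence[str]) -> "RegressorSet":
        return RegressorSet({n: self.series[n] for n in names}, self.rate)


@dataclass
class TRFEstimate:
    """Estimated kernels per regressor and channel over the lag axis."""

    kernels: np.ndarray  # (n_regressors, n_channels, n_lags)
    regressor_names: list[str]
    lags: np.ndarray  # seconds
    lambda_: float
    residual_var: np.ndarray  # per channel
    n_samples: int
    intercept: np.ndarray | None = None  # per channel

    def kernel(self, name: str) -> np.ndarray:
        return self.kernels[self.regressor_names.index(name)]


@dataclass
class LatencyEstimate:
    """Bootstrap peak-latency summary for a component."""

    mean: float
    sd: float
    n_resamples: int
    window: tuple[float, float]
    polarity: int


def preprocess_recording(raw: Recording, out_rate: float = 128.0) -> Recording:
    """Band-limit and resample a native-rate recording for TRF analysis.

    Zero-phase 4th-order Butterworth bandpass 1-20 Hz (applied forward and
    backward), then anti-aliased polyphase resampling to ``out_rate``
    (128 samples/s by default). Trial boundaries and exclusions carry over
    unchanged (they are stored in seconds).
    """
    if raw.rate < 2 * out_rate:
        raise ValueError("native rate must be at least twice the analysis rate")
    sos = signal.butter(4, [1.0, 20.0], btype="bandpass", fs=raw.rate, output="sos")
    try:
        filtered = signal.sosfiltfilt(sos, raw.data, axis=1)
    except ValueError as err:
        raise ValueError("recording too short for filter edge padding") from err
    frac = Fraction(out_rate / raw.rate).limit_denominator(10**6)
    data = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return Recording(
        data=data,
        rate=out_rate,
        channel_names=list(raw.channel_names),
        trials=list(raw.trials),
        exclude=list(raw.exclude),
    )


def lag_axis(lag_range: tuple[float, float], rate: float) -> np.ndarray:
    """Sample-aligned lag axis in seconds for a lag range at a given rate."""
    l0 = int(round(lag_range[0] * rate))
    l1 = int(round(lag_range[1] * rate))
    return np.arange(l0, l1 + 1) / rate


def _lagged_block(x: np.ndarray, l0: int, l1: int) -> np.ndarray:
    """Columns X[n, j] = x[n - (l0 + j)], zero-padded at the edges."""
    n = len(x)
    m = l1 - l0 + 1
    out = np.zeros((n, m))
    for j, k in enumerate(range(l0, l1 + 1)):
        if k >= 0:
            out[k:, j] = x[: n - k] if k > 0 else x
        else:
            out[: n + k, j] = x[-k:]
    return out


def build_design(
    regs: RegressorSet,
    lag_range: tuple[float, float],
    trials: Sequence[Trial],
    rate: float,
    mask: np.ndarray | None = None,
    add_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the lagged design matrix over the given trials.

    Returns ``(X, rows)`` where ``rows`` are the retained sample indices into
    the recording. Each regressor contributes one column per lag; lags that
    would reach outside a trial are zero-padded within that trial (no
    cross-trial leakage), and masked rows (e.g. the cue second) are dropped
    after lagging. An intercept column is appended last.
    """
    l0 = int(round(lag_range[0] * rate))
    l1 = int(round(lag_range[1] * rate))
    blocks: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    for trial in trials:
        sl = trial.sample_slice(rate)
        idx = np.arange(sl.start, sl.stop)
        if mask is not None:
            keepers = ~mask[idx]
        else:
            keepers = np.ones(len(idx), dtype=bool)
        cols = [
            _lagged_block(regs.series[name][sl], l0, l1)[keepers]
            for name in regs.names
        ]
        if len(idx[keepers]):
            blocks.append(np.concatenate(cols, axis=1))
            rows.append(idx[keepers])
    if not blocks:
        raise ValueError("no samples left after masking")
    X = np.concatenate(blocks, axis=0)
    if add_intercept:
        X = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)
    return X, np.concatenate(rows)


def _penalty_diag(n_cols: int, intercept: bool) -> np.ndarray:
    d = np.ones(n_cols)
    if intercept:
        d[-1] = 0.0  # intercept unpenalized
    return d


def _ridge_from_gram(
    xtx: np.ndarray,
    xty: np.ndarray,
    lam: float,
    intercept: bool,
) -> np.ndarray:
    n_cols = xtx.shape[0]
    pen = _penalty_diag(n_cols, intercept)
    n_pen = int(pen.sum())
    mean_diag = float(np.trace(xtx) - (xtx[-1, -1] if intercept else 0.0)) / max(n_pen, 1)
    A = xtx + lam * mean_diag * np.diag(pen)
    if lam == 0:
        try:
            return linalg.solve(A, xty, assume_a="pos")
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "design matrix is singular at lambda=0; use lambda > 0"
            ) from err
    return linalg.solve(A, xty, assume_a="pos")


def ridge_solve(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    regressor_names: Sequence[str] | None = None,
    lags: np.ndarray | None = None,
    has_intercept: bool = True,
) -> TRFEstimate:
    """Solve the penalized normal equations (X'X + lambda*rbar*I) b = X'y.

    The penalty is scaled by the mean diagonal of X'X (``rbar``) so the
    printed lambda range (1e-6 ... 1e10) is portable across data sizes; the
    intercept column (last, if present) is unpenalized. ``y`` may be a
    vector or samples x channels matrix.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, C)
    xtx = X.T @ X
    xty = X.T @ y2
    if lam == 0 and np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise linalg.LinAlgError(
            "design matrix is singular at lambda=0; use lambda > 0"
        )
    beta = _ridge_from_gram(xtx, xty, lam, has_intercept)  # (p, C)
    resid = y2 - X @ beta
    residual_var = resid.var(axis=0)

    n_cols = X.shape[1] - (1 if has_intercept else 0)
    if regressor_names is None:
        regressor_names = ["regressor"]
    if lags is None:
        n_lags = n_cols // len(regressor_names)
        lags = np.arange(n_lags, dtype=float)
    n_lags = len(lags)
    coef = beta[:n_cols].T.reshape(y2.shape[1], len(regressor_names), n_lags)
    kernels = np.transpose(coef, (1, 0, 2))
    intercept = beta[-1] if has_intercept else None
    return TRFEstimate(
        kernels=kernels,
        regressor_names=list(regressor_names),
        lags=np.asarray(lags, dtype=float),
        lambda_=lam,
        residual_var=residual_var,
        n_samples=X.shape[0],
        intercept=intercept,
    )


def _trial_grams(
    recording: Recording,
    regs: RegressorSet,
    lag_range: tuple[float, float],
    trials: Sequence[Trial],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, int]]:
    """Per-trial (X'X, X'y, y'y, n) with masking applied."""
    mask = recording.exclusion_mask()
    out = []
    for trial in trials:
        X, rows = build_design(regs, lag_range, [trial], recording.rate, mask)
        y = recording.data[:, rows].T  # (n, C)
        out.append((X.T @ X, X.T @ y, np.einsum("nc,nc->c", y, y), X.shape[0]))
    return out


def select_lambda(
    recording: Recording,
    regs: RegressorSet,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE,
    conditions: Sequence[str] | None = None,
) -> float:
    """Choose lambda by leave-one-trial-out cross-validated prediction MSE.

    For each lambda in the grid, every trial is held out in turn, the TRF is
    fitted on the remaining trials, and the mean-square prediction error on
    the held-out trial is recorded; the lambda with the smallest mean
    held-out MSE wins. Selection is meant to run on single-stream (prime)
    data and the chosen value reused for all conditions.
    """
    if len(grid) == 0:
        raise ValueError("lambda grid is empty")
    trials = [
        t for t in recording.trials if conditions is None or t.condition in conditions
    ]
    if len(trials) < 2:
        raise ValueError("need at least 2 trials for leave-one-out selection")
    grams = _trial_grams(recording, regs, lag_range, trials)
    xtx_tot = sum(g[0] for g in grams)
    xty_tot = sum(g[1] for g in grams)
    fold_mse = np.zeros((len(grams), len(grid)))
    for i, (xtx_i, xty_i, yty_i, n_i) in enumerate(grams):
        xtx_fit = xtx_tot - xtx_i
        xty_fit = xty_tot - xty_i
        for j, lam in enumerate(grid):
            beta = _ridge_from_gram(xtx_fit, xty_fit, lam, intercept=True)
            # held-out SSE = b'X'Xb - 2 b'X'y + y'y, summed over channels
            sse = (
                np.einsum("pc,pq,qc->", beta, xtx_i, beta)
                - 2.0 * np.einsum("pc,pc->", beta, xty_i)
                + yty_i.sum()
            )
            fold_mse[i, j] = sse / n_i
    mse = fold_mse.mean(axis=0)
    # one-standard-error rule: prefer the strongest regularization whose CV
    # error is within one SE of the minimum (breaks the tie on the flat
    # fully-shrunk plateau that pure-noise responses produce)
    best = int(np.argmin(mse))
    se = fold_mse[:, best].std(ddof=1) / np.sqrt(len(grams))
    order = np.argsort(grid)
    admissible = [j for j in order if mse[j] <= mse[best] + se]
    return float(grid[admissible[-1]])


def estimate_trf(
    recording: Recording,
    regs: RegressorSet,
    lam: float,
    conditions: Sequence[str] | None = None,
    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE,
    regressors_by_condition: dict[str, Sequence[str]] | None = None,
) -> dict[str, TRFEstimate]:
    """Fit one TRF per condition from that condition's concatenated trials.

    All of a condition's trials (minus excluded spans) enter a single joint
    fit of all its regressors at the pre-selected lambda.
    ``regressors_by_condition`` optionally restricts which regressors apply
    to a condition (e.g. single-stream conditions have no masker regressors).
    """
    lags = lag_axis(lag_range, recording.rate)
    if conditions is None:
        seen: list[str] = []
        for t in recording.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        conditions = seen
    results: dict[str, TRFEstimate] = {}
    mask = recording.exclusion_mask()
    for cond in conditions:
        trials = [t for t in recording.trials if t.condition == cond]
        if not trials:
            raise ValueError(f"condition {cond!r} has zero trials")
        use = regs
        if regressors_by_condition and cond in regressors_by_condition:
            use = regs.subset(regressors_by_condition[cond])
        X, rows = build_design(use, lag_range, trials, recording.rate, mask)
        y = recording.data[:, rows].T
        est = ridge_solve(
            X, y, lam, regressor_names=use.names, lags=lags, has_intercept=True
        )
        results[cond] = est
    return results


def bootstrap_peak_latency(
    kernels: np.ndarray,
    lags: np.ndarray,
    window: tuple[float, float],
    polarity: int = 1,
    n_resamples: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> LatencyEstimate:
    """Bootstrap the grand-average peak latency over subjects.

    ``kernels`` is subjects x lags. Subjects are resampled with replacement
    ``n_resamples`` times; per resample the latency is the polarity-signed
    argmax of the resampled grand average inside ``window``. Returns the
    mean and SD of those latencies.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    if kernels.shape[0] < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    rng = np.random.default_rng(rng)
    sel = (lags >= window[0] - 1e-12) & (lags <= window[1] + 1e-12)
    if not np.any(sel):
        raise ValueError("window contains no lag samples")
    sub = polarity * kernels[:, sel]
    if np.ptp(sub.mean(axis=0)) == 0:
        raise ValueError("kernel is flat within the search window")
    win_lags = lags[sel]
    n_subj = kernels.shape[0]
    idx = rng.integers(0, n_subj, size=(n_resamples, n_subj))
    lat = win_lags[np.argmax(sub[idx].mean(axis=1), axis=1)]
    return LatencyEstimate(
        mean=float(lat.mean()),
        sd=float(lat.std()),
        n_resamples=n_resamples,
        window=window,
        polarity=polarity,
    )
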
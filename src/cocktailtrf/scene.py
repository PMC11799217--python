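"""Synthetic two-speaker listening scenes with known ground truth.

Emulates the measurement situation of a cocktail-party MEG experiment:
two simultaneous speech-like envelope-onset streams (language-specific
peak rates, ~7.9/s for German-like and ~6.6/s for Chinese-like speech), a
7-s target stream starting 1 s before a 6-s masker, envelope-locked
cortical kernels with P1 (~90 ms), N1 (~150 ms), P2 (~219 ms) and an
attention- and nativeness-dependent sustained negativity (Nd, 150-250 ms),
two bilateral cortical sources mixed into the sensor array, additive
1/f-like noise, target-word events (0/1/2 per stream at 10/80/10%), and
button responses with condition-dependent hit/false-alarm probabilities.

Everything is deterministic under a fixed seed, so downstream estimation
stages can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .audio import EnvelopeSeries
from .trf import Recording, Trial, lag_axis

__all__ = [
    "TRFComponentParams",
    "GroundTruthTRF",
    "SceneSpec",
    "SceneTruth",
    "CohortSpec",
    "SubjectData",
    "CohortData",
    "condition_grid",
    "gen_onset_stream",
    "gen_true_trf",
    "gen_target_events",
    "gen_responses",
    "gen_scene",
    "gen_cohort",
    "ONSET_RATES",
]

#: default envelope-peak rates per language (events/s)
ONSET_RATES = {"german": 7.9, "chinese": 6.6}


@dataclass
class TRFComponentParams:
    """Latencies (s), amplitudes, and widths (s) of the ground-truth kernel.

    The kernel is a sum of Gaussian bumps (P1, N1, P2) plus a smoothed
    boxcar negativity (Nd) over 150-250 ms whose amplitude is multiplied by
    ``attention_gain`` when the stream is attended and by ``native_gain``
    when it is in the listener's native language.
    """

    p1_latency: float = 0.090
    p1_amp: float = 1.0
    p1_width: float = 0.012
    n1_latency: float = 0.150
    n1_amp: float = -0.7
    n1_width: float = 0.015
    p2_latency: float = 0.219
    p2_amp: float = 0.5
    p2_width: float = 0.020
    nd_window: tuple[float, float] = (0.150, 0.250)
    nd_amp: float = -0.5
    nd_edge: float = 0.010
    attention_gain: float = 2.0
    native_gain: float = 1.5


@dataclass
class GroundTruthTRF:
    """A known envelope-onset kernel over the lag axis."""

    lags: np.ndarray
    kernel: np.ndarray
    params: TRFComponentParams
    attention: bool
    native: bool

    def nd_contribution(self) -> np.ndarray:
        """The Nd part of the kernel alone (same lag axis)."""
        base = replace(self.params, p1_amp=0.0, n1_amp=0.0, p2_amp=0.0)
        return _compose_kernel(self.lags, base, self.attention, self.native)


def _gauss(lags: np.ndarray, latency: float, amp: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((lags - latency) / width) ** 2)


def _compose_kernel(
    lags: np.ndarray, p: TRFComponentParams, attention: bool, native: bool
) -> np.ndarray:
    k = (
        _gauss(lags, p.p1_latency, p.p1_amp, p.p1_width)
        + _gauss(lags, p.n1_latency, p.n1_amp, p.n1_width)
        + _gauss(lags, p.p2_latency, p.p2_amp, p.p2_width)
    )
    nd_amp = p.nd_amp
    if attention:
        nd_amp *= p.attention_gain
    if native:
        nd_amp *= p.native_gain
    if nd_amp != 0.0:
        # smoothed boxcar: difference of sigmoid-like error-function edges
        lo, hi = p.nd_window
        edge = max(p.nd_edge, 1e-6)
        box = 0.5 * (
            stats.norm.cdf(lags, loc=lo, scale=edge)
            - stats.norm.cdf(lags, loc=hi, scale=edge)
        ) * 2.0
        k = k + nd_amp * box
    return k


def gen_true_trf(
    params: TRFComponentParams | None = None,
    attention: bool = False,
    native: bool = False,
    rate: float = 128.0,
    lag_range: tuple[float, float] = (-0.5, 1.0),
) -> GroundTruthTRF:
    """Build the ground-truth envelope-onset kernel for one stream role."""
    params = params or TRFComponentParams()
    lags = lag_axis(lag_range, rate)
    kernel = _compose_kernel(lags, params, attention, native)
    return GroundTruthTRF(
        lags=lags, kernel=kernel, params=params, attention=attention, native=native
    )


def gen_onset_stream(
    rate_per_s: float,
    duration: float,
    rng: np.random.Generator | int | None = None,
    analysis_rate: float = 128.0,
    gamma_shape: float = 2.0,
    pulse_width: float = 0.030,
) -> EnvelopeSeries:
    """Generate a speech-like envelope-onset stream.

    Events follow a renewal process with gamma inter-event intervals
    (shape 2 by default, mimicking syllabic regularity) at mean rate
    ``rate_per_s``; the resulting impulse train is convolved with a
    one-sided (half-)Gaussian pulse of ~``pulse_width`` total support.
    """
    if rate_per_s <= 0:
        raise ValueError("event rate must be positive")
    if duration * rate_per_s < 1:
        raise ValueError("expected fewer than one event; increase duration or rate")
    rng = np.random.default_rng(rng)
    n_expect = int(np.ceil(duration * rate_per_s * 2 + 10))
    intervals = rng.gamma(gamma_shape, 1.0 / (gamma_shape * rate_per_s), size=n_expect)
    times = np.cumsum(intervals)
    while times[-1] < duration:  # pragma: no cover - extremely unlikely
        more = rng.gamma(gamma_shape, 1.0 / (gamma_shape * rate_per_s), size=n_expect)
        times = np.concatenate([times, times[-1] + np.cumsum(more)])
    times = times[times < duration]
    n = int(round(duration * analysis_rate))
    train = np.zeros(n)
    idx = np.floor(times * analysis_rate).astype(int)
    np.add.at(train, idx, 1.0)
    sigma = pulse_width / 3.0
    half = np.arange(0, int(round(3 * sigma * analysis_rate)) + 1)
    pulse = np.exp(-0.5 * (half / (sigma * analysis_rate)) ** 2)
    values = np.convolve(train, pulse)[:n]
    return EnvelopeSeries(values=values, rate=analysis_rate)


def gen_target_events(
    n_streams: int = 2,
    duration: float = 7.0,
    rng: np.random.Generator | int | None = None,
    word_duration: float = 0.4,
    min_start: float = 1.0,
    min_separation: float = 2.0,
    count_probs: tuple[float, float, float] = (0.1, 0.8, 0.1),
    max_retries: int = 1000,
) -> pd.DataFrame:
    """Draw target-word events for the streams of one trial.

    Per stream the word count is 0, 1 or 2 with probabilities 10/80/10%;
    onsets are uniform subject to: none before ``min_start`` seconds, and
    pairwise separation of at least ``min_separation`` seconds across all
    streams. Stream 0 is the target, stream 1 the masker.
    """
    if duration < 6.0:
        raise ValueError("duration must be at least 6 s")
    rng = np.random.default_rng(rng)
    names = ["target", "masker"] + [f"stream{i}" for i in range(2, n_streams)]
    names = names[:n_streams]
    lo, hi = min_start, duration - word_duration
    if hi <= lo:
        raise ValueError("trial too short to place target words")
    # rejection-sample placements; if a count combination cannot be placed
    # (e.g. 2+2 words in a short trial), the counts are redrawn too
    for attempt in range(max_retries):
        if attempt % 25 == 0:
            counts = rng.choice([0, 1, 2], size=n_streams, p=list(count_probs))
        onsets = rng.uniform(lo, hi, size=int(counts.sum()))
        if len(onsets) < 2 or np.diff(np.sort(onsets)).min() >= min_separation:
            break
    else:
        raise RuntimeError("could not satisfy target-word separation constraints")
    rows = []
    k = 0
    for name, c in zip(names, counts):
        for _ in range(int(c)):
            rows.append((name, float(onsets[k]), float(onsets[k] + word_duration), "target_word"))
            k += 1
    return pd.DataFrame(rows, columns=["stream", "onset_s", "offset_s", "kind"]).sort_values(
        "onset_s", ignore_index=True
    )


def gen_responses(
    events: pd.DataFrame,
    p_hit: float,
    p_fa: float,
    rt_mean: float = 0.7,
    rt_sd: float = 0.3,
    rng: np.random.Generator | int | None = None,
    rt_bounds: tuple[float, float] = (0.2, 2.0),
) -> pd.DataFrame:
    """Simulate button presses for the target words of an event table.

    Each target-stream word elicits a press with probability ``p_hit`` and
    each masker-stream word with probability ``p_fa``; the press occurs at
    word offset plus a truncated-normal response time within ``rt_bounds``.
    """
    if not (0 <= p_hit <= 1 and 0 <= p_fa <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    lo, hi = rt_bounds
    a, b = (lo - rt_mean) / rt_sd, (hi - rt_mean) / rt_sd
    words = events[events["kind"] == "target_word"]
    rows = []
    for _, w in words.iterrows():
        p = p_hit if w["stream"] == "target" else p_fa
        if rng.uniform() < p:
            rt = float(stats.truncnorm.rvs(a, b, loc=rt_mean, scale=rt_sd, random_state=rng))
            t = float(w["offset_s"]) + rt
            rows.append(("response", t, t, "button_press"))
    return pd.DataFrame(rows, columns=["stream", "onset_s", "offset_s", "kind"])


@dataclass
class SceneSpec:
    """Parameters of one synthetic recording block (one condition).

    The block holds ``n_trials`` presentations of a 7-s target (optionally
    masked by a 6-s stream starting 1 s later), separated by an inter-trial
    gap. Noise level is given as sensor-space SNR in the 1-20 Hz band
    (``None`` = noiseless).
    """

    n_sensors: int = 24
    n_trials: int = 30
    trial_duration: float = 7.0
    masker_duration: float = 6.0
    masker_offset: float = 1.0
    inter_trial_gap: float = 2.0
    rate: float = 128.0
    lag_range: tuple[float, float] = (-0.5, 1.0)
    target_language: str = "german"
    masker_language: str = "german"
    onset_rates: dict = field(default_factory=lambda: dict(ONSET_RATES))
    single_stream: bool = False
    identity_mixing: bool = False
    noise_snr_db: float | None = 10.0
    noise_alpha: float = 1.0
    white_frac: float = 0.1
    condition: str = "mix"
    word_kernel_amp: float = 0.8
    press_kernel_amp: float = 0.5
    p_hit: float = 0.8
    p_fa: float = 0.1
    exclude_cue: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 2:
            raise ValueError("need at least 2 sensors for two sources")
        if self.identity_mixing and self.n_sensors != 2:
            raise ValueError("identity mixing requires exactly 2 sensors")


@dataclass
class SceneTruth:
    """Ground-truth bundle accompanying a generated scene."""

    mixing: np.ndarray  # channels x 2
    source_kernels: dict[str, np.ndarray]  # regressor -> (2 sources, n_lags)
    lags: np.ndarray
    sources: np.ndarray  # 2 x samples
    noiseless: np.ndarray  # channels x samples
    regressors: dict[str, np.ndarray]
    hemispheres: list[str]


def _mixing_matrix(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    n = spec.n_sensors
    hemis = ["L"] * (n // 2) + ["R"] * (n - n // 2)
    if spec.identity_mixing:
        return np.eye(2), hemis
    mix = np.zeros((n, 2))
    left = np.array([h == "L" for h in hemis])
    for col, side in enumerate([left, ~left]):
        v = rng.normal(size=int(side.sum()))
        v /= np.linalg.norm(v)
        # fixed sign convention so the topography is seed-stable
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        mix[side, col] = v
    return mix, hemis


def _event_kernels(spec: SceneSpec, lags: np.ndarray) -> dict[str, np.ndarray]:
    out = {
        "word_target": _gauss(lags, 0.300, spec.word_kernel_amp, 0.040),
        "word_masker": _gauss(lags, 0.250, 0.75 * spec.word_kernel_amp, 0.040),
        "press": _gauss(lags, 0.0, spec.press_kernel_amp, 0.050),
    }
    return out


def _colored_noise(
    shape: tuple[int, int], alpha: float, white_frac: float, rng: np.random.Generator
) -> np.ndarray:
    n_ch, n = shape
    white = rng.normal(size=(n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-alpha / 2.0)
    pink = np.fft.irfft(spec, n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    floor = rng.normal(size=(n_ch, n))
    mix = (1.0 - white_frac) * pink + white_frac * floor
    return mix / mix.std(axis=1, keepdims=True)


def _band_power(x: np.ndarray, rate: float) -> float:
    sos = signal.butter(4, [1.0, 20.0], btype="bandpass", fs=rate, output="sos")
    return float(np.mean(signal.sosfiltfilt(sos, x, axis=1) ** 2))


def _convolve_lagged(series: np.ndarray, kernel: np.ndarray, l0: int) -> np.ndarray:
    """y(n) = sum_j kernel[j] * series[n - (l0 + j)]."""
    full = np.convolve(series, kernel)
    n = len(series)
    out = np.zeros(n)
    # out[n] = full[n - l0]
    lo = max(0, l0)
    src_lo = lo - l0
    take = min(n - lo, len(full) - src_lo)
    if take > 0:
        out[lo : lo + take] = full[src_lo : src_lo + take]
    return out


def gen_scene(
    spec: SceneSpec,
    trf_target: GroundTruthTRF,
    trf_masker: GroundTruthTRF | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Recording, pd.DataFrame, SceneTruth]:
    """Generate one condition block: recording, event table, ground truth.

    Both cortical sources receive both streams (with mild per-source gains
    standing in for lateralization); sensor data are the two sources mixed
    through seeded unit-norm topography columns plus 1/f-like noise at the
    requested band SNR. The target stream starts 1 s before the masker and
    the cue second of each trial is marked excluded for mixture scenes.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    rate = spec.rate
    lags = lag_axis(spec.lag_range, rate)
    l0 = int(round(spec.lag_range[0] * rate))
    trial_len = spec.trial_duration
    step = trial_len + spec.inter_trial_gap
    n_total = int(round((spec.n_trials * step) * rate))

    # topographies drawn from a seed-derived stream so the mixing is stable
    # across scenes generated from the same spec
    mix_rng = np.random.default_rng(spec.seed + 777)
    mixing, hemis = _mixing_matrix(spec, mix_rng)

    reg_names = ["target_onsets"] + ([] if spec.single_stream else ["masker_onsets"])
    reg_names += ["word_target"] + ([] if spec.single_stream else ["word_masker"])
    reg_names += ["press"]
    regressors = {name: np.zeros(n_total) for name in reg_names}

    trials: list[Trial] = []
    exclude: list[tuple[float, float]] = []
    all_events = []
    target_rate = spec.onset_rates[spec.target_language]
    masker_rate = spec.onset_rates[spec.masker_language]
    for i in range(spec.n_trials):
        t0 = i * step
        sl0 = int(round(t0 * rate))
        tgt = gen_onset_stream(target_rate, trial_len, rng, analysis_rate=rate)
        regressors["target_onsets"][sl0 : sl0 + len(tgt.values)] += tgt.values
        if not spec.single_stream:
            msk = gen_onset_stream(masker_rate, spec.masker_duration, rng, analysis_rate=rate)
            m0 = sl0 + int(round(spec.masker_offset * rate))
            regressors["masker_onsets"][m0 : m0 + len(msk.values)] += msk.values
        ev = gen_target_events(
            n_streams=1 if spec.single_stream else 2, duration=trial_len, rng=rng
        )
        presses = gen_responses(ev, spec.p_hit, spec.p_fa, rng=rng)
        for _, w in ev.iterrows():
            name = "word_target" if w["stream"] == "target" else "word_masker"
            j = int(round((t0 + w["onset_s"]) * rate))
            if j < n_total:
                regressors[name][j] += 1.0
        for _, p in presses.iterrows():
            j = int(round((t0 + p["onset_s"]) * rate))
            if j < n_total:
                regressors["press"][j] += 1.0
        ev = ev.assign(trial=i, onset_s=ev["onset_s"] + t0, offset_s=ev["offset_s"] + t0)
        presses = presses.assign(
            trial=i, onset_s=presses["onset_s"] + t0, offset_s=presses["offset_s"] + t0
        )
        all_events.extend([ev, presses])
        trials.append(Trial(start=t0, stop=t0 + trial_len, condition=spec.condition))
        if spec.exclude_cue and not spec.single_stream:
            exclude.append((t0, t0 + spec.masker_offset))

    nonempty = [df for df in all_events if len(df)]
    if nonempty:
        events = pd.concat(nonempty, ignore_index=True)[
            ["trial", "stream", "onset_s", "offset_s", "kind"]
        ]
    else:
        events = pd.DataFrame(
            columns=["trial", "stream", "onset_s", "offset_s", "kind"]
        )

    # per-source gains: both sources receive both streams, mildly lateralized
    gains = {name: np.array([1.0, 0.9]) for name in reg_names}
    if "masker_onsets" in gains:
        gains["masker_onsets"] = np.array([0.9, 1.0])
    ev_kernels = _event_kernels(spec, lags)
    kernels = {"target_onsets": trf_target.kernel}
    if not spec.single_stream:
        if trf_masker is None:
            raise ValueError("two-stream scene requires a masker kernel")
        kernels["masker_onsets"] = trf_masker.kernel
    kernels.update({k: ev_kernels[k] for k in reg_names if k in ev_kernels})

    source_kernels = {
        name: np.outer(gains[name], kernels[name]) for name in reg_names
    }
    sources = np.zeros((2, n_total))
    for name in reg_names:
        resp = _convolve_lagged(regressors[name], kernels[name], l0)
        sources += gains[name][:, None] * resp[None, :]
    noiseless = mixing @ sources
    data = noiseless.copy()
    if spec.noise_snr_db is not None:
        noise = _colored_noise(noiseless.shape, spec.noise_alpha, spec.white_frac, rng)
        sig_p = _band_power(noiseless, rate)
        noise_p = _band_power(noise, rate)
        scale = np.sqrt(sig_p / (noise_p * 10 ** (spec.noise_snr_db / 10.0)))
        data = noiseless + scale * noise

    rec = Recording(
        data=data,
        rate=rate,
        channel_names=[f"MEG{h}{i:02d}" for i, h in enumerate(hemis)],
        trials=trials,
        exclude=exclude,
    )
    truth = SceneTruth(
        mixing=mixing,
        source_kernels=source_kernels,
        lags=lags,
        sources=sources,
        noiseless=noiseless,
        regressors=regressors,
        hemispheres=hemis,
    )
    return rec, events, truth


def condition_grid() -> pd.DataFrame:
    """The full 2x2x2x2 analysis design: 16 condition cells.

    attention (target|masker stream role) x stimulus language x
    target-masker consistency x priming.
    """
    rows = [
        (att, lang, cons, prime)
        for att in ("target", "masker")
        for lang in ("german", "chinese")
        for cons in ("consistent", "inconsistent")
        for prime in ("unprimed", "primed")
    ]
    return pd.DataFrame(rows, columns=["attention", "language", "consistency", "priming"])


@dataclass
class CohortSpec:
    """Two listener groups (native German / native Chinese) with the full grid."""

    n_per_group: int = 17
    groups: tuple[str, str] = ("german", "chinese")
    subject_jitter_sd: float = 0.2
    kernel_noise_sd: float = 0.5
    trf_params: TRFComponentParams = field(default_factory=TRFComponentParams)
    mode: str = "kernels"  # "kernels" | "full"
    rate: float = 128.0
    lag_range: tuple[float, float] = (-0.5, 1.0)
    # full-mode scene parameters
    n_trials: int = 30
    n_sensors: int = 24
    noise_snr_db: float | None = 10.0
    seed: int = 0


@dataclass
class SubjectData:
    subject: str
    group: str  # native language
    jitter: float
    kernels: np.ndarray | None = None  # (16 cells, 2 hemispheres, n_lags)
    scenes: dict | None = None  # condition label -> (Recording, events, truth)
    true_kernels: np.ndarray | None = None  # (16, n_lags), noise-free source kernel


@dataclass
class CohortData:
    grid: pd.DataFrame
    subjects: list[SubjectData]
    lags: np.ndarray
    spec: CohortSpec


def _cell_truth(
    cell, group: str, params: TRFComponentParams, rate: float, lag_range
) -> GroundTruthTRF:
    return gen_true_trf(
        params,
        attention=(cell.attention == "target"),
        native=(cell.language == group),
        rate=rate,
        lag_range=lag_range,
    )


def gen_cohort(spec: CohortSpec | None = None, rng: np.random.Generator | int | None = None) -> CohortData:
    """Simulate a cohort of listeners over the full 16-cell design.

    Subjects carry lognormal kernel-amplitude jitter; the Nd of each cell's
    ground-truth kernel is scaled by the attention gain (attended streams)
    and the native-language gain (streams in the subject's native language).

    ``mode="kernels"`` returns per-subject, per-cell source-kernel
    *estimates* directly (ground truth x subject jitter + white kernel
    noise on each of two hemispheres) — fast enough for power studies.
    ``mode="full"`` returns per-subject sensor-space scenes (one block per
    stimulus condition plus single-stream prime blocks) for end-to-end
    estimation.
    """
    spec = spec or CohortSpec()
    if spec.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    grid = condition_grid()
    lags = lag_axis(spec.lag_range, spec.rate)
    subjects: list[SubjectData] = []
    for group in spec.groups:
        for i in range(spec.n_per_group):
            sid = f"{group[:2]}{i:02d}"
            jitter = float(np.exp(rng.normal(0.0, spec.subject_jitter_sd)))
            true_k = np.stack(
                [
                    jitter
                    * _cell_truth(c, group, spec.trf_params, spec.rate, spec.lag_range).kernel
                    for c in grid.itertuples()
                ]
            )
            subj = SubjectData(subject=sid, group=group, jitter=jitter, true_kernels=true_k)
            if spec.mode == "kernels":
                noise = rng.normal(0.0, spec.kernel_noise_sd, size=(len(grid), 2, len(lags)))
                subj.kernels = true_k[:, None, :] + noise
            elif spec.mode == "full":
                subj.scenes = _subject_scenes(spec, group, jitter, rng)
            else:
                raise ValueError(f"unknown cohort mode {spec.mode!r}")
            subjects.append(subj)
    return CohortData(grid=grid, subjects=subjects, lags=lags, spec=spec)


def mixture_conditions() -> pd.DataFrame:
    """The 8 stimulus conditions (target language x consistency x priming)."""
    rows = [
        (tl, cons, prime)
        for tl in ("german", "chinese")
        for cons in ("consistent", "inconsistent")
        for prime in ("unprimed", "primed")
    ]
    return pd.DataFrame(rows, columns=["target_language", "consistency", "priming"])


def mixture_label(target_language: str, consistency: str, priming: str) -> str:
    return f"mix|tl={target_language}|{consistency}|{priming}"


def prime_label(language: str) -> str:
    return f"prime|{language}"


def _other(lang: str) -> str:
    return "chinese" if lang == "german" else "german"


def _subject_scenes(
    spec: CohortSpec, group: str, jitter: float, rng: np.random.Generator
) -> dict:
    scenes = {}
    params = spec.trf_params
    base = SceneSpec(
        n_sensors=spec.n_sensors,
        n_trials=spec.n_trials,
        rate=spec.rate,
        lag_range=spec.lag_range,
        noise_snr_db=spec.noise_snr_db,
        seed=spec.seed,
    )
    scaled = replace(
        params,
        p1_amp=jitter * params.p1_amp,
        n1_amp=jitter * params.n1_amp,
        p2_amp=jitter * params.p2_amp,
        nd_amp=jitter * params.nd_amp,
    )
    for lang in ("german", "chinese"):
        label = prime_label(lang)
        sp = replace(
            base,
            single_stream=True,
            target_language=lang,
            condition=label,
            noise_snr_db=spec.noise_snr_db,
        )
        trf_t = gen_true_trf(scaled, attention=True, native=(lang == group),
                             rate=spec.rate, lag_range=spec.lag_range)
        scenes[label] = gen_scene(sp, trf_t, rng=rng)
    for row in mixture_conditions().itertuples():
        ml = row.target_language if row.consistency == "consistent" else _other(row.target_language)
        label = mixture_label(row.target_language, row.consistency, row.priming)
        sp = replace(base, target_language=row.target_language, masker_language=ml, condition=label)
        trf_t = gen_true_trf(scaled, attention=True, native=(row.target_language == group),
                             rate=spec.rate, lag_range=spec.lag_range)
        trf_m = gen_true_trf(scaled, attention=False, native=(ml == group),
                             rate=spec.rate, lag_range=spec.lag_range)
        scenes[label] = gen_scene(sp, trf_t, trf_m, rng=rng)
    return scenes
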
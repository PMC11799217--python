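"""Signal-detection scoring of button presses against target-word events.

A press within the 2-s window after a target-stream word's offset is a
hit (the first press claims the word; words are processed earliest-first);
unclaimed target words are misses; presses in the window of a masker-
stream word are false alarms (only those false alarms are scored). Hit
and false-alarm rates are corrected at the extremes — a perfect rate n/n
becomes (n-0.5)/n and an empty rate 0/n becomes 0.5/n — and sensitivity
is d' = z(H) - z(F) with z the standard-normal quantile. Response times
are measured from word offset, matching the hit-window anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreCounts",
    "score_responses",
    "corrected_rates",
    "dprime",
    "summarize_behavior",
]


@dataclass
class ScoreCounts:
    """Raw per-condition detection counts and hit response times."""

    n_target_words: int
    n_masker_words: int
    hits: int
    false_alarms: int
    rts: list[float]

    @property
    def misses(self) -> int:
        return self.n_target_words - self.hits


def score_responses(
    events: pd.DataFrame, presses: pd.DataFrame, window: float = 2.0
) -> ScoreCounts:
    """Assign presses to target words within the response window.

    ``events`` holds target_word rows (columns stream, onset_s, offset_s);
    ``presses`` holds button_press rows (column onset_s). A press at time p
    claims a word with offset o when o < p <= o + window; words claim
    presses earliest-word-first and each press is used at most once.
    Scoring is invariant to the row order of the press table.
    """
    words = (
        events[events["kind"] == "target_word"]
        .sort_values("onset_s")
        .reset_index(drop=True)
        if "kind" in events.columns
        else events.sort_values("onset_s").reset_index(drop=True)
    )
    press_times = np.sort(presses["onset_s"].to_numpy(dtype=float))
    claimed = np.zeros(len(press_times), dtype=bool)
    hits = 0
    fas = 0
    rts: list[float] = []
    n_t = int((words["stream"] == "target").sum())
    n_m = int((words["stream"] == "masker").sum())
    for _, w in words.iterrows():
        off = float(w["offset_s"])
        ok = (press_times > off) & (press_times <= off + window) & ~claimed
        idx = np.flatnonzero(ok)
        if len(idx) == 0:
            continue
        claimed[idx[0]] = True
        if w["stream"] == "target":
            hits += 1
            rts.append(float(press_times[idx[0]] - off))
        elif w["stream"] == "masker":
            fas += 1
    return ScoreCounts(
        n_target_words=n_t, n_masker_words=n_m, hits=hits, false_alarms=fas, rts=rts
    )


def corrected_rates(
    hits: int, n_targets: int, fas: int, n_fa_opportunities: int
) -> tuple[float, float]:
    """Extreme-rate-corrected hit and false-alarm rates.

    A perfect hit rate n/n is replaced by (n-0.5)/n and a zero false-alarm
    rate by 0.5/n (and symmetrically at the opposite extremes), keeping
    both rates strictly inside (0, 1) so d' stays finite.
    """
    if n_targets < 1 or n_fa_opportunities < 1:
        raise ValueError("need at least one target word and one false-alarm opportunity")

    def correct(k: int, n: int) -> float:
        if k >= n:
            return (n - 0.5) / n
        if k <= 0:
            return 0.5 / n
        return k / n

    return correct(hits, n_targets), correct(fas, n_fa_opportunities)


def dprime(H: float, F: float) -> float:
    """Sensitivity index d' = z(H) - z(F) (standard-normal quantiles)."""
    if not (0 < H < 1) or not (0 < F < 1):
        raise ValueError(
            "rates must lie strictly in (0, 1); apply corrected_rates first"
        )
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


def summarize_behavior(
    trials: pd.DataFrame, window: float = 2.0
) -> pd.DataFrame:
    """Per-(subject, condition) behavioral summary from a tidy trial table.

    ``trials`` has one row per event with columns subject, condition,
    stream, onset_s, offset_s, kind (target_word | button_press). Counts
    are aggregated per condition before the extreme-rate correction, then
    d' and the mean response time over hits are computed.
    """
    required = {"subject", "condition", "stream", "onset_s", "offset_s", "kind"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    out = []
    for (subj, cond), chunk in trials.groupby(["subject", "condition"], sort=True):
        events = chunk[chunk["kind"] == "target_word"]
        presses = chunk[chunk["kind"] == "button_press"]
        sc = score_responses(events, presses, window=window)
        H, F = corrected_rates(
            sc.hits, max(sc.n_target_words, 1), sc.false_alarms, max(sc.n_masker_words, 1)
        )
        out.append(
            {
                "subject": subj,
                "condition": cond,
                "n_target_words": sc.n_target_words,
                "n_masker_words": sc.n_masker_words,
                "hits": sc.hits,
                "false_alarms": sc.false_alarms,
                "hit_rate": H,
                "fa_rate": F,
                "dprime": dprime(H, F),
                "mean_rt": float(np.mean(sc.rts)) if sc.rts else np.nan,
            }
        )
    return pd.DataFrame(out)
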
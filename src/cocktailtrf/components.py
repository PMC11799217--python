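"""Windowed component amplitudes on source TRFs, and reliability.

Component amplitudes are mean kernel values in fixed latency windows
defined on the grand-average source waveforms: P1/N1/P2 for unmasked
(single-stream) responses and P1/Nd for masked (two-stream) responses.
The attention effect is the Nd window (150-250 ms) difference between
attended (target) and ignored (masker) streams. Reliability across the 16
design cells is summarized with Cronbach's alpha, treating conditions as
items and participants as cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import CohortData

__all__ = [
    "ComponentWindows",
    "window_mean",
    "component_table",
    "cronbach_alpha",
]


@dataclass
class ComponentWindows:
    """Named component latency intervals in seconds (closed intervals)."""

    unmasked: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P1": (0.050, 0.100),
            "N1": (0.125, 0.175),
            "P2": (0.195, 0.245),
        }
    )
    masked: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P1": (0.060, 0.110),
            "Nd": (0.150, 0.250),
        }
    )

    def __post_init__(self) -> None:
        for name, windows in [("unmasked", self.unmasked), ("masked", self.masked)]:
            spans = sorted(windows.values())
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(f"{name} component windows overlap")


def window_mean(kernel: np.ndarray, lags: np.ndarray, window: tuple[float, float]) -> float:
    """Mean kernel amplitude over a closed latency window.

    Window edges are snapped to the nearest lag sample; samples with lag in
    [start, end] (inclusive) are averaged. Linear in the kernel.
    """
    kernel = np.asarray(kernel, dtype=float)
    rate = 1.0 / float(np.median(np.diff(lags)))
    lo = np.rint(window[0] * rate)
    hi = np.rint(window[1] * rate)
    idx = np.rint(lags * rate)
    sel = (idx >= lo) & (idx <= hi)
    if not np.any(sel):
        raise ValueError("window contains no lag samples after gridding")
    return float(kernel[sel].mean())


def component_table(
    cohort: CohortData,
    windows: ComponentWindows | None = None,
    hemisphere_average: bool = False,
) -> pd.DataFrame:
    """Tidy per-cell component amplitudes for a cohort of source kernels.

    One row per (subject, condition cell, hemisphere, window) with the mean
    source-kernel amplitude in that window. Requires every subject to carry
    kernels for the complete 16-cell grid. With ``hemisphere_average`` the
    two hemisphere waveforms are averaged before windowing (the design's
    hemisphere factor collapses, as done when no hemisphere effects exist).
    """
    windows = windows or ComponentWindows()
    grid = cohort.grid
    rows = []
    for subj in cohort.subjects:
        if subj.kernels is None:
            raise ValueError(
                f"subject {subj.subject} has no source kernels; run estimation first"
            )
        if subj.kernels.shape[0] != len(grid):
            raise ValueError(
                f"subject {subj.subject}: expected {len(grid)} condition cells, "
                f"got {subj.kernels.shape[0]}"
            )
        for ci, cell in enumerate(grid.itertuples()):
            k = subj.kernels[ci]  # (hemis, lags)
            if hemisphere_average:
                hemi_kernels = {"both": k.mean(axis=0)}
            else:
                hemi_kernels = {"L": k[0], "R": k[1]}
            for hemi, kern in hemi_kernels.items():
                for wname, span in windows.masked.items():
                    rows.append(
                        (
                            subj.subject,
                            subj.group,
                            cell.attention,
                            cell.language,
                            cell.consistency,
                            cell.priming,
                            hemi,
                            wname,
                            window_mean(kern, cohort.lags, span),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "group",
            "attention",
            "language",
            "consistency",
            "priming",
            "hemisphere",
            "window",
            "amplitude",
        ],
    )


def cronbach_alpha(matrix: np.ndarray) -> float:
    """Cronbach's alpha of a participants x conditions matrix.

    Conditions act as items and participants as cases:
    alpha = k/(k-1) * (1 - sum of per-condition variances / variance of
    participant sums), with k the number of conditions. Perfectly parallel
    rows (identical up to an additive participant constant) give alpha = 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of participant sums; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
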
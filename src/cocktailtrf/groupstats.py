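"""Mixed repeated-measures ANOVA for all-two-level factorial designs.

The analysis design has several two-level within-subject factors
(attention, stimulus language, target-masker consistency, ...) and one
two-level between-subject factor (listener group). For such designs the
univariate sums-of-squares decomposition reduces exactly to contrast
scores: for each within-effect the per-subject contrast (the signed mean
over cells) is submitted to a one-way groups analysis, giving the effect
F (test of the contrast's grand mean), the effect x group F (test of the
group difference), and the matching subject-level error term. Every
effect then has df = (1, N - 2), and partial eta squared is
SS_effect / (SS_effect + SS_error). With two-level factors sphericity is
moot and the univariate and multivariate statistics coincide.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rm_anova_mixed", "partial_eta_sq"]


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero; effect size undefined")
    return ss_effect / (ss_effect + ss_error)


def _check_two_levels(table: pd.DataFrame, factors: list[str]) -> dict[str, list]:
    levels = {}
    for f in factors:
        lv = sorted(table[f].unique())
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, has {lv}")
        levels[f] = lv
    return levels


def rm_anova_mixed(
    table: pd.DataFrame,
    within: list[str],
    between: str = "group",
    subject: str = "subject",
    value: str = "amplitude",
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA with partial eta squared.

    ``table`` is tidy: one row per subject x within-cell, with columns for
    the subject id, the between-group label, each within factor, and the
    dependent value. All factors must be two-level and the design balanced
    and complete (equal group sizes; every subject contributes every
    cell). Returns one row per effect (between main effect, every within
    effect, and every within x between interaction) with F, dfs, p, SS,
    and partial eta squared.
    """
    for col in [subject, between, value, *within]:
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    levels = _check_two_levels(table, within)
    glevels = sorted(table[between].unique())
    if len(glevels) != 2:
        raise ValueError("the between factor must have exactly 2 levels")

    wide = table.pivot_table(
        index=[subject, between], columns=within, values=value, aggfunc="mean",
        sort=True,
    )
    expected_cells = 2 ** len(within)
    if wide.shape[1] != expected_cells or wide.isna().any().any():
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(
            f"design incomplete: expected {expected_cells} cells per subject; "
            f"problem subjects: {incomplete or 'missing cells entirely'}"
        )
    groups = wide.index.get_level_values(between).to_numpy()
    n0, n1 = (groups == glevels[0]).sum(), (groups == glevels[1]).sum()
    if n0 != n1:
        raise ValueError("groups must be of equal size for the balanced decomposition")
    n_subj = wide.shape[0]
    df_err = n_subj - 2

    # signed weights per cell for each within factor (first level = +1)
    if len(within) == 1:
        cell_levels = [(lv,) for lv in wide.columns]
    else:
        cell_levels = list(wide.columns)
    signs = {
        f: np.array([1.0 if cl[i] == levels[f][0] else -1.0 for cl in cell_levels])
        for i, f in enumerate(within)
    }
    Y = wide.to_numpy()
    g_ind = (groups == glevels[1]).astype(int)

    def one_way(z: np.ndarray):
        """SS and F of grand-mean and group effects on subject scores z."""
        gm = z.mean()
        means = np.array([z[g_ind == g].mean() for g in (0, 1)])
        counts = np.array([n0, n1])
        ss_int = n_subj * gm**2
        ss_grp = float(np.sum(counts * (means - gm) ** 2))
        ss_err = float(np.sum((z - means[g_ind]) ** 2))
        ms_err = ss_err / df_err
        return ss_int, ss_grp, ss_err, ms_err

    rows = []

    def emit(name: str, ss_eff: float, ss_err: float, ms_err: float) -> None:
        F = ss_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        rows.append(
            {
                "effect": name,
                "F": float(F),
                "df1": 1,
                "df2": df_err,
                "p": p,
                "ss_effect": float(ss_eff),
                "ss_error": float(ss_err),
                "partial_eta_sq": partial_eta_sq(ss_eff, ss_err),
            }
        )

    # between-subject main effect on subject means
    ss_int, ss_grp, ss_err, ms_err = one_way(Y.mean(axis=1))
    emit(between, ss_grp, ss_err, ms_err)

    # within effects and their interactions with the between factor
    for order in range(1, len(within) + 1):
        for combo in combinations(within, order):
            w = np.ones(Y.shape[1])
            for f in combo:
                w = w * signs[f]
            z = Y @ (w / Y.shape[1])
            ss_int, ss_grp, ss_err, ms_err = one_way(z)
            name = " * ".join(combo)
            emit(name, ss_int, ss_err, ms_err)
            emit(f"{name} * {between}", ss_grp, ss_err, ms_err)

    return pd.DataFrame(rows)
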
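"""ROI averaging and mixed-design ANOVA.

Peak HbO2 responses are averaged over each region of interest (inferior
frontal, posterior temporal; four channels per hemisphere each) for every
participant, hemisphere and language modality, then analysed with a
2 (modality) x 2 (hemisphere) x 3 (group) mixed ANOVA: modality and
hemisphere are within-subject, group is between-subject.

With two-level within-subject factors the repeated-measures decomposition
reduces exactly to ordinary regressions on per-subject contrast scores:
the subject mean carries the between-group effect, and each within-factor
difference score carries that factor's main effect (regression intercept)
and its interaction with group.  Sum-coded type-III tests are used so that
unequal group sizes are handled as in standard mixed-ANOVA software;
sphericity corrections are vacuous for two-level factors.  Effect size is
partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Montage, ROISet

ROI_NAMES = ("inferior_frontal", "posterior_temporal")


def build_roi_table(
    peaks: pd.DataFrame,
    rois: ROISet,
    montage: Montage,
    groups: dict[str, str],
    kind: str = "modality",
    chromophore: str = "hbo2",
) -> pd.DataFrame:
    """Average channel peaks into ROI x hemisphere cells per participant.

    ``peaks`` is the long table from :func:`babelnirs.univariate.extract_peaks`;
    ``groups`` maps participant_id -> group.  Cell means use whatever
    channels are present for that participant (QC-rejected channels are
    absent from the peak table); cells with no available channel are
    omitted (flagged by their absence, handled downstream by listwise
    deletion).
    """
    sub = peaks[(peaks.kind == kind) & (peaks.chromophore == chromophore)]
    rows = []
    for (pid, key), grp in sub.groupby(["participant_id", "key"]):
        by_channel = grp.set_index("channel").peak_amplitude
        for roi in ROI_NAMES:
            for hemi in ("left", "right"):
                cell_channels = rois.channels(roi, hemi, montage)
                vals = [by_channel[c] for c in cell_channels if c in by_channel]
                if not vals:
                    continue
                rows.append({
                    "participant_id": pid,
                    "group": groups[pid],
                    "roi": roi,
                    "hemisphere": hemi,
                    "key": key,
                    "mean_peak": float(np.mean(vals)),
                    "n_channels": len(vals),
                })
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "roi", "hemisphere",
                       "key", "mean_peak", "n_channels"],
    )


def _contrast_scores(table: pd.DataFrame, within: list[str],
                     dv: str) -> pd.DataFrame:
    """Per-subject mean and difference scores over the within-factor cells.

    Subjects missing any within cell are dropped (listwise deletion).
    Factor levels are taken in sorted order; each difference score is
    (level2 - level1), averaged over the other factor where applicable.
    """
    cells = table.pivot_table(
        index=["participant_id", "group"], columns=within, values=dv,
        aggfunc="mean",
    )
    cells = cells.dropna(axis=0, how="any")
    out = pd.DataFrame(index=cells.index)
    out["mean"] = cells.mean(axis=1)
    levels = {f: sorted(table[f].unique()) for f in within}
    for f in within:
        if len(levels[f]) != 2:
            raise ValueError(f"within factor {f!r} must have exactly 2 levels")
    if len(within) == 1:
        f = within[0]
        out[f] = cells[levels[f][1]] - cells[levels[f][0]]
    else:
        a, b = within
        (a1, a2), (b1, b2) = levels[a], levels[b]
        out[a] = (cells[(a2, b1)] + cells[(a2, b2)]
                  - cells[(a1, b1)] - cells[(a1, b2)]) / 2.0
        out[b] = (cells[(a1, b2)] + cells[(a2, b2)]
                  - cells[(a1, b1)] - cells[(a2, b1)]) / 2.0
        out[f"{a}*{b}"] = (cells[(a2, b2)] - cells[(a2, b1)]
                           - cells[(a1, b2)] + cells[(a1, b1)])
    return out.reset_index()


def _effect_rows(scores: pd.DataFrame, column: str, label: str,
                 between: bool) -> list[dict]:
    """F tests for one contrast score: intercept (within effect) and, when a
    group factor is present, the group term (interaction / between effect).

    Type-III sums of squares with sum-to-zero group coding reduce, for a
    single between factor, to closed forms: the intercept tests the
    unweighted mean of group means (M* with SS = M*^2 k^2 / sum(1/n_g)),
    the group term is the classical between-group SS, and the error is the
    pooled within-group SS.
    """
    y = scores[column].to_numpy(float)
    if "_tol" in scores.columns:
        # snap float dust in exactly-cancelling contrasts to zero so that
        # degenerate effects report F = 0 rather than a 0/0 artifact
        tol = float(scores["_tol"].iloc[0])
        y = np.where(np.abs(y) < tol, 0.0, y)
    groups = scores.group.to_numpy()
    levels = np.unique(groups)
    k = len(levels)
    n = len(y)
    group_means = np.array([y[groups == g].mean() for g in levels])
    group_ns = np.array([(groups == g).sum() for g in levels])
    ss_err = float(sum(
        ((y[groups == g] - m) ** 2).sum()
        for g, m in zip(levels, group_means)
    ))
    df_err = n - k
    rows = []
    if between:
        if k < 2:
            return []  # no between factor with a single group
        m_w = y.mean()
        ss_group = float((group_ns * (group_means - m_w) ** 2).sum())
        rows.append(_row(label, ss_group, k - 1, df_err, ss_err))
    else:
        m_star = group_means.mean()  # unweighted grand mean
        ss_icept = m_star ** 2 * k ** 2 / (1.0 / group_ns).sum()
        rows.append(_row(label, float(ss_icept), 1, df_err, ss_err))
        if k > 1:
            m_w = y.mean()
            ss_group = float((group_ns * (group_means - m_w) ** 2).sum())
            rows.append(_row(f"{label} * group", ss_group, k - 1,
                             df_err, ss_err))
    return rows


def _row(effect: str, ss_eff: float, df1: int, df2: int,
         ss_err: float) -> dict:
    from scipy import stats
    if ss_err <= 0 or df2 <= 0:
        f = 0.0 if ss_eff <= 1e-300 else np.inf
        p = 1.0 if f == 0.0 else 0.0
        eta = 0.0 if f == 0.0 else 1.0
    else:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, df1, df2))
        eta = ss_eff / (ss_eff + ss_err)
    return {"effect": effect, "F": float(f), "df_num": df1, "df_den": df2,
            "p": p, "partial_eta_sq": float(eta)}


def mixed_anova(
    table: pd.DataFrame,
    within: list[str] | tuple[str, ...] = ("key", "hemisphere"),
    dv: str = "mean_peak",
) -> pd.DataFrame:
    """Mixed-design ANOVA with 1-2 two-level within factors and group between.

    ``table`` is in long format with columns ``participant_id``, ``group``,
    the within factors, and ``dv``.  Returns one row per effect: the within
    mains, the between main, all interactions, with F, degrees of freedom,
    p and partial eta squared.  Participants missing any within cell are
    dropped listwise.
    """
    within = list(within)
    scores = _contrast_scores(table, within, dv)
    scores["_tol"] = 1e-10 * max(1.0, float(np.abs(table[dv]).max()))
    n_groups = scores.group.nunique()
    if scores.groupby("group").size().min() < 2:
        raise ValueError("need at least 2 participants per group")
    rows = []
    for col in within + ([f"{within[0]}*{within[1]}"] if len(within) == 2 else []):
        rows.extend(_effect_rows(scores, col, col, between=False))
    if n_groups > 1:
        rows.extend(_effect_rows(scores, "mean", "group", between=True))
    return pd.DataFrame(rows)


def per_group_hemisphere_anova(
    table: pd.DataFrame,
    group: str,
    within: list[str] | tuple[str, ...] = ("key", "hemisphere"),
    dv: str = "mean_peak",
) -> pd.DataFrame:
    """Within-subject (hemisphere x modality) ANOVA for a single group."""
    sub = table[table.group == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    return mixed_anova(sub, within=within, dv=dv)
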
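"""Peak-window univariate statistics: channel t tests, FDR, activation calls.

Peak amplitude variation from baseline is extracted per channel within the
8-16 s post-onset analysis window (the infant response maximum sits around
12 s): the signed maximum for HbO2 and the signed minimum for HHb.  Channel
maps are tested with two-tailed t tests and corrected with the
Benjamini-Hochberg false discovery rate over the 46 montage channels.
A channel where HbO2 and HHb move significantly in the same direction is
inconsistent with a hemodynamic response and is never reported as active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ConditionAverage

PEAK_WINDOW_S = (8.0, 16.0)


def extract_peaks(
    averages: list[ConditionAverage],
    window_s: tuple[float, float] = PEAK_WINDOW_S,
    include_excluded: bool = False,
) -> pd.DataFrame:
    """Build the peak table: one row per (participant, key, channel, chromophore).

    ``key`` is a condition or modality name (``kind`` distinguishes them).
    HbO2 peaks are window maxima, HHb peaks window minima, both signed.
    Channels with no valid data (QC-rejected or zero valid trials) are
    absent from the table; non-included averages are skipped unless
    ``include_excluded``.
    """
    rows = []
    for avg in averages:
        if not (avg.included or include_excluded):
            continue
        sel = (avg.times >= window_s[0]) & (avg.times <= window_s[1])
        if not sel.any():
            raise ValueError("average does not cover the peak window")
        windowed = avg.data[:, :, sel]
        for ci, cid in enumerate(avg.channel_ids):
            if np.isnan(windowed[ci]).all():
                continue
            rows.append({
                "participant_id": avg.participant_id,
                "key": avg.key,
                "kind": avg.kind,
                "channel": cid,
                "chromophore": "hbo2",
                "peak_amplitude": float(np.nanmax(windowed[ci, 0])),
            })
            rows.append({
                "participant_id": avg.participant_id,
                "key": avg.key,
                "kind": avg.kind,
                "channel": cid,
                "chromophore": "hhb",
                "peak_amplitude": float(np.nanmin(windowed[ci, 1])),
            })
    return pd.DataFrame(
        rows, columns=["participant_id", "key", "kind", "channel",
                       "chromophore", "peak_amplitude"],
    )


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False  # zero-variance input; p undefined


def one_sample_channel_test(values: np.ndarray) -> TestResult:
    """Two-tailed one-sample t test of channel peaks against zero."""
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least two participants")
    if np.allclose(values.std(ddof=1), 0.0):
        if np.allclose(values.mean(), 0.0):
            return TestResult(t=0.0, p=1.0, n=values.size, degenerate=True)
        return TestResult(t=np.nan, p=np.nan, n=values.size, degenerate=True)
    t, p = stats.ttest_1samp(values, 0.0)
    return TestResult(t=float(t), p=float(p), n=values.size)


def paired_familiarity_test(
    familiar: np.ndarray, unfamiliar: np.ndarray
) -> TestResult:
    """Paired two-tailed t test (familiar - unfamiliar), pairs by position.

    Pairs with either member missing (NaN) are dropped.
    """
    familiar = np.asarray(familiar, float)
    unfamiliar = np.asarray(unfamiliar, float)
    if familiar.shape != unfamiliar.shape:
        raise ValueError("paired inputs must have equal length")
    ok = ~(np.isnan(familiar) | np.isnan(unfamiliar))
    return one_sample_channel_test(familiar[ok] - unfamiliar[ok])


def fdr_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    ``m`` is the number of comparisons; it defaults to ``len(pvalues)`` but
    can be fixed (here, 46 channels) when some channels are absent from the
    input.  Adjusted values are ``min_{j >= i} m * p_(j) / j`` clipped to 1,
    mapped back to the input order.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def channel_map_tests(
    peaks: pd.DataFrame,
    chromophore: str,
    key: str,
    alpha: float = 0.05,
    n_channels_fdr: int = 46,
) -> pd.DataFrame:
    """Channel-by-channel one-sample tests with FDR over the montage.

    Returns one row per channel: t, p, p_fdr, direction, significance
    flags before and after correction (both are reported, mirroring the
    exploratory first step of the analysis).
    """
    sub = peaks[(peaks.chromophore == chromophore) & (peaks.key == key)]
    rows = []
    for channel, grp in sub.groupby("channel"):
        vals = grp.peak_amplitude.to_numpy()
        if len(vals) < 2:
            continue
        res = one_sample_channel_test(vals)
        rows.append({
            "channel": int(channel),
            "chromophore": chromophore,
            "key": key,
            "n": res.n,
            "t": res.t,
            "p": res.p,
            "direction": "up" if np.nanmean(vals) >= 0 else "down",
            "degenerate": res.degenerate,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    valid = ~df.p.isna()
    p_fdr = np.full(len(df), np.nan)
    if valid.any():
        p_fdr[valid.to_numpy()] = fdr_adjust(
            df.p[valid].to_numpy(), m=max(n_channels_fdr, int(valid.sum()))
        )
    df["p_fdr"] = p_fdr
    df["significant_uncorrected"] = df.p < alpha
    df["significant_fdr"] = df.p_fdr < alpha
    return df


def classify_activation(
    hbo2_map: pd.DataFrame, hhb_map: pd.DataFrame,
    alpha: float = 0.05, corrected: bool = False,
) -> pd.DataFrame:
    """Per-channel activation labels from the two chromophore maps.

    Labels: ``active_hbo2`` (significant HbO2 increase), ``active_hhb``
    (significant HHb decrease without an HbO2 call), ``inconsistent``
    (both chromophores significant in the same direction -- not a
    hemodynamic response), or ``null``.
    """
    col = "significant_fdr" if corrected else "significant_uncorrected"
    a = hbo2_map.set_index("channel")
    b = hhb_map.set_index("channel")
    rows = []
    for channel in sorted(set(a.index) & set(b.index)):
        sig_o, dir_o = bool(a.loc[channel, col]), a.loc[channel, "direction"]
        sig_h, dir_h = bool(b.loc[channel, col]), b.loc[channel, "direction"]
        if sig_o and sig_h and dir_o == dir_h:
            label = "inconsistent"
        elif sig_o and dir_o == "up":
            label = "active_hbo2"
        elif sig_h and dir_h == "down":
            label = "active_hhb"
        else:
            label = "null"
        rows.append({"channel": channel, "label": label})
    return pd.DataFrame(rows)
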
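"""Spike-in-anchored normalization and percent-m6A / expression quantification.

Normalization subtracts, per sample x channel ("array"), the mean of the
log2-scaled spike-in intensities, then adds back the grand mean of those
anchors so values stay on the original fluorescence scale.  Subtraction on
the log2 scale is division on the linear scale, so any multiplicative factor
shared by all probes of an array cancels exactly.

Quantification works on linear normalized signals per transcript x sample:

    percent-m6A = 100 * IP / (IP + Sup)        (modified percentage)
    expression  = IP + Sup                     (total transcript signal)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CHANNELS
from .exceptions import ValidationError


def normalize_spikein(intensities: pd.DataFrame, epsilon: float = 1.0) -> pd.DataFrame:
    """Anchor each array's log2 intensities to its spike-in mean.

    Parameters
    ----------
    intensities : DataFrame
        Validated probe-level table (columns ``probe_id, transcript_id,
        sample_id, channel, intensity, is_spike_in`` at least).
    epsilon : float
        Additive floor before the log2 transform; guards raw zeros.

    Returns
    -------
    DataFrame
        The input with a ``log2_norm`` column:
        ``log2(raw + eps) - anchor[sample, channel] + grand_mean(anchors)``.
        Spike-in rows are retained (still flagged).
    """
    df = intensities.copy()
    li = np.log2(df["intensity"].to_numpy(dtype=float) + epsilon)
    df["_log2_raw"] = li

    spikes = df[df["is_spike_in"]]
    cells = set(zip(df["sample_id"], df["channel"]))
    have = set(zip(spikes["sample_id"], spikes["channel"]))
    missing = sorted(cells - have)
    if missing:
        raise ValidationError(
            f"no spike-in probes for sample x channel {missing}"
        )

    anchors = spikes.groupby(["sample_id", "channel"])["_log2_raw"].mean()
    grand = float(anchors.mean())
    keyed = df.set_index(["sample_id", "channel"]).index
    df["log2_norm"] = li - anchors.reindex(keyed).to_numpy() + grand
    return df.drop(columns="_log2_raw")


def summarize_probes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level normalized signals to transcript level.

    Multiple probes of one transcript are averaged on the log2 scale within
    each channel (the standard two-channel convention).  Spike-in rows are
    excluded.
    """
    df = normalized[~normalized["is_spike_in"]]
    out = (
        df.groupby(["transcript_id", "sample_id", "channel"], sort=True)[
            "log2_norm"
        ]
        .mean()
        .reset_index()
    )
    return out


def compute_quant(norm: pd.DataFrame) -> pd.DataFrame:
    """Percent-m6A and expression per transcript x sample.

    Expects transcript-level normalized signals (``transcript_id, sample_id,
    channel, log2_norm``) with both channels present for every
    transcript x sample.
    """
    wide = norm.pivot_table(
        index=["transcript_id", "sample_id"],
        columns="channel",
        values="log2_norm",
        aggfunc="first",
    )
    for channel in CHANNELS:
        if channel not in wide.columns or wide[channel].isna().any():
            bad = (
                wide.index[wide[channel].isna()].tolist()[:5]
                if channel in wide.columns
                else "all rows"
            )
            raise ValidationError(
                f"missing channel '{channel}' for transcript x sample: {bad}"
            )
    ip = 2.0 ** wide["IP"].to_numpy(dtype=float)
    sup = 2.0 ** wide["Sup"].to_numpy(dtype=float)
    out = wide.reset_index()[["transcript_id", "sample_id"]]
    out["m6a_percent"] = 100.0 * ip / (ip + sup)
    out["expression"] = ip + sup
    return out


def quantify(intensities: pd.DataFrame, epsilon: float = 1.0) -> pd.DataFrame:
    """Full quantification: normalize, summarize probes, compute statistics."""
    return compute_quant(summarize_probes(normalize_spikein(intensities, epsilon)))
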
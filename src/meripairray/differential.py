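"""Two-group differential analysis of methylation level and expression.

Both layers use the pooled-variance (Student's) two-sample t-test:

* methylation — tested on percent-m6A values; fold change is the ratio of
  group mean percentages (sci / sham);
* expression — tested on log2(expression); fold change is
  2 ** (mean log2 difference), i.e. the ratio of geometric means.

Screening: fold change >= cutoff (or <= 1/cutoff) AND raw p < p_cutoff, the
boundary being inclusive.  Benjamini-Hochberg adjusted p-values are computed
within each layer x biotype stratum and reported alongside, but screening
uses raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import GROUP_SCI, GROUP_SHAM, GroupDesign, RunConfig
from .exceptions import ValidationError

LAYER_METH = "methylation"
LAYER_EXPR = "expression"

STATUS_HYPER = "hyper"
STATUS_HYPO = "hypo"
STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


def _pooled_t(sham: np.ndarray, sci: np.ndarray):
    """Vectorised pooled-variance two-sided t-test along axis 1.

    Returns (mean_sham, mean_sci, p).  Rows where the pooled variance is zero
    get p = 1.0 when the means are equal (no evidence) and p = 0.0 otherwise
    (a difference with zero noise).
    """
    sham = np.atleast_2d(np.asarray(sham, dtype=float))
    sci = np.atleast_2d(np.asarray(sci, dtype=float))
    n1, n2 = sham.shape[1], sci.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("group_test needs at least 2 values per group")
    m1 = sham.mean(axis=1)
    m2 = sci.mean(axis=1)
    v1 = sham.var(axis=1, ddof=1)
    v2 = sci.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0.0
    if degenerate.any():
        p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return m1, m2, p


def group_test(values_sham, values_sci, scale: str = "linear"):
    """Fold change, log2 fold change and Student's t p-value for one feature.

    Parameters
    ----------
    values_sham, values_sci : sequences of float
        Per-replicate values (percent-m6A for the methylation layer,
        log2 expression for the expression layer).
    scale : {"linear", "log2"}
        "linear": fc = mean(sci) / mean(sham) of the values as given.
        "log2":   the values are log2-scale; fc = 2 ** (mean difference).

    Returns
    -------
    (fc, log2fc, p_value)
    """
    m1, m2, p = _pooled_t(values_sham, values_sci)
    m1, m2, p = float(m1[0]), float(m2[0]), float(p[0])
    if scale == "linear":
        if m1 <= 0 or m2 <= 0:
            raise ValidationError("linear-scale group means must be positive")
        fc = m2 / m1
        log2fc = float(np.log2(fc))
    elif scale == "log2":
        log2fc = m2 - m1
        fc = float(2.0**log2fc)
    else:
        raise ValidationError(f"unknown scale '{scale}'")
    return fc, log2fc, p


def screen(fc: float, p_value: float, layer: str, fc_cutoff: float, p_cutoff: float) -> str:
    """Classify one record as hyper/hypo (methylation), up/down (expression) or ns.

    The fold-change boundary is inclusive (fc == cutoff qualifies); the
    p-value gate is strict (p < p_cutoff).
    """
    if fc_cutoff <= 1:
        raise ValidationError("fc_cutoff must be > 1")
    if layer == LAYER_METH:
        pos, neg = STATUS_HYPER, STATUS_HYPO
    elif layer == LAYER_EXPR:
        pos, neg = STATUS_UP, STATUS_DOWN
    else:
        raise ValidationError(f"unknown layer '{layer}'")
    if p_value < p_cutoff:
        if fc >= fc_cutoff:
            return pos
        if fc <= 1.0 / fc_cutoff:
            return neg
    return STATUS_NS


def _screen_vec(fc: np.ndarray, p: np.ndarray, layer: str, fc_cutoff: float, p_cutoff: float):
    pos, neg = (
        (STATUS_HYPER, STATUS_HYPO) if layer == LAYER_METH else (STATUS_UP, STATUS_DOWN)
    )
    sig = p < p_cutoff
    return np.select(
        [sig & (fc >= fc_cutoff), sig & (fc <= 1.0 / fc_cutoff)],
        [pos, neg],
        default=STATUS_NS,
    )


def _layer_table(
    quant: pd.DataFrame,
    design: GroupDesign,
    layer: str,
    config: RunConfig,
) -> pd.DataFrame:
    if layer == LAYER_METH:
        values = quant.pivot(
            index="transcript_id", columns="sample_id", values="m6a_percent"
        )
    else:
        values = np.log2(
            quant.pivot(
                index="transcript_id", columns="sample_id", values="expression"
            )
        )
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"incomplete quantification for transcripts {bad}")

    sham = values[design.samples(GROUP_SHAM)].to_numpy()
    sci = values[design.samples(GROUP_SCI)].to_numpy()

    if layer == LAYER_METH and config.meth_on_logit:
        # test on log2-odds; fold change stays on the percent scale
        def logit2(x):
            return np.log2(x / (100.0 - x))

        _, _, p = _pooled_t(logit2(sham), logit2(sci))
        m1, m2 = sham.mean(axis=1), sci.mean(axis=1)
    else:
        m1, m2, p = _pooled_t(sham, sci)

    if layer == LAYER_METH:
        fc = m2 / m1
        mean_sham, mean_sci = m1, m2
    else:
        log2fc = m2 - m1
        fc = 2.0**log2fc
        mean_sham, mean_sci = 2.0**m1, 2.0**m2

    return pd.DataFrame(
        {
            "transcript_id": values.index,
            "layer": layer,
            "mean_sham": mean_sham,
            "mean_sci": mean_sci,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p_value": p,
            "status": _screen_vec(fc, p, layer, config.fc_cutoff_screen, config.p_cutoff),
        }
    )


def differential_table(
    quant: pd.DataFrame,
    design: GroupDesign,
    annotation: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """One differential record per transcript per layer (long format).

    BH-adjusted p-values are computed within each layer x biotype stratum;
    the ``status`` column reflects the raw-p screen.
    """
    design.require_replicates(2)
    biotype = annotation.set_index("transcript_id")["biotype"]
    missing = set(quant["transcript_id"]) - set(biotype.index)
    if missing:
        raise ValidationError(
            f"transcripts absent from annotation: {sorted(missing)[:5]}"
        )
    frames = []
    for layer in (LAYER_METH, LAYER_EXPR):
        tab = _layer_table(quant, design, layer, config)
        tab.insert(1, "biotype", biotype.reindex(tab["transcript_id"]).to_numpy())
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)

    out["adj_p"] = np.nan
    for (_, _), idx in out.groupby(["layer", "biotype"]).groups.items():
        out.loc[idx, "adj_p"] = multipletests(
            out.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    cols = [
        "transcript_id",
        "biotype",
        "layer",
        "mean_sham",
        "mean_sci",
        "fc",
        "log2fc",
        "p_value",
        "adj_p",
        "status",
    ]
    return out[cols].sort_values(["layer", "transcript_id"], ignore_index=True)


def status_counts(differential: pd.DataFrame) -> pd.DataFrame:
    """Counts of each screening status per layer x biotype (summary table)."""
    return (
        differential.groupby(["layer", "biotype", "status"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["layer", "biotype", "status"], ignore_index=True)
    )
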
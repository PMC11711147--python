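"""Nine-quadrant conjoint analysis, lncRNA classification and cis-target mapping.

The nine-quadrant grid crosses the methylation axis {hyper, ns, hypo} with
the expression axis {up, ns, down} at the conjoint gate |log2FC| >= 1
(fold change >= 2) together with p < p_cutoff on each axis.  The concordant
cells hyper-up and hypo-down are the modes the study highlights; discordant
modes are reported too.

Genomic coordinates are 0-based half-open throughout.  An mRNA is a cis
target of a lncRNA when both lie on the same chromosome and the gap between
their spans is at most the window (100 kb by default, boundary inclusive,
strand-agnostic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import ValidationError

MODE_NONE = "none"

LNC_CLASSES = (
    "exon-sense-overlapping",
    "intronic",
    "natural-antisense",
    "intronic-antisense",
    "bidirectional",
    "intergenic",
)


def nine_quadrant(
    meth: pd.DataFrame, expr: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Assign every transcript to one cell of the 3x3 methylation x expression grid.

    Parameters
    ----------
    meth, expr : DataFrame
        Differential records of the two layers (must cover the same
        transcripts; columns ``transcript_id, biotype, log2fc, p_value``).
    config : RunConfig
        Supplies ``fc_cutoff_conjoint`` (|log2fc| gate = log2 of it) and
        ``p_cutoff``.
    """
    m_ids, e_ids = set(meth["transcript_id"]), set(expr["transcript_id"])
    if m_ids != e_ids:
        only = sorted(m_ids ^ e_ids)[:10]
        raise ValidationError(
            f"layers cover different transcripts (e.g. {only})"
        )
    m = meth.set_index("transcript_id")
    e = expr.set_index("transcript_id").reindex(m.index)

    thresh = np.log2(config.fc_cutoff_conjoint)
    m_lfc, m_p = m["log2fc"].to_numpy(), m["p_value"].to_numpy()
    e_lfc, e_p = e["log2fc"].to_numpy(), e["p_value"].to_numpy()

    meth_class = np.select(
        [
            (m_lfc >= thresh) & (m_p < config.p_cutoff),
            (m_lfc <= -thresh) & (m_p < config.p_cutoff),
        ],
        ["hyper", "hypo"],
        default="ns",
    )
    expr_class = np.select(
        [
            (e_lfc >= thresh) & (e_p < config.p_cutoff),
            (e_lfc <= -thresh) & (e_p < config.p_cutoff),
        ],
        ["up", "down"],
        default="ns",
    )
    both = (meth_class != "ns") & (expr_class != "ns")
    mode = np.where(
        both, np.char.add(np.char.add(meth_class.astype(str), "-"), expr_class.astype(str)), MODE_NONE
    )
    return pd.DataFrame(
        {
            "transcript_id": m.index,
            "biotype": m["biotype"].to_numpy(),
            "meth_log2fc": m_lfc,
            "meth_p": m_p,
            "expr_log2fc": e_lfc,
            "expr_p": e_p,
            "meth_class": meth_class,
            "expr_class": expr_class,
            "quadrant": np.char.add(
                np.char.add(meth_class.astype(str), "/"), expr_class.astype(str)
            ),
            "mode": mode,
        }
    ).sort_values("transcript_id", ignore_index=True)


def venn_counts(quadrants: pd.DataFrame) -> dict:
    """Venn-style counts per biotype of the conjoint analysis.

    For each biotype: how many transcripts pass the conjoint gate on the
    methylation axis, on the expression axis, on both, plus per-mode counts.
    """
    out = {}
    for biotype, sub in quadrants.groupby("biotype"):
        meth_sig = sub["meth_class"] != "ns"
        expr_sig = sub["expr_class"] != "ns"
        entry = {
            "n_transcripts": int(len(sub)),
            "n_meth": int(meth_sig.sum()),
            "n_expr": int(expr_sig.sum()),
            "n_both": int((meth_sig & expr_sig).sum()),
        }
        for mode in ("hyper-up", "hypo-down", "hyper-down", "hypo-up"):
            entry[mode.replace("-", "_")] = int((sub["mode"] == mode).sum())
        out[biotype] = entry
    return out


def _overlaps(l_start, l_end, m_start, m_end):
    return (l_start < m_end) & (m_start < l_end)


def _contained(l_start, l_end, m_start, m_end):
    return (m_start <= l_start) & (l_end <= m_end)


def classify_lncrna(
    lnc: pd.Series, mrnas: pd.DataFrame, bidirectional_window: int = 1_000
) -> str:
    """Positional class of one lncRNA against the coding annotation.

    Precedence (first match wins):

    1. exon-sense-overlapping — overlaps a coding gene, same strand;
    2. intronic — contained in a coding gene's span, same strand (with
       span-only annotation rule 1 already captures these; kept for
       completeness);
    3. natural-antisense — overlaps, opposite strand;
    4. intronic-antisense — contained, opposite strand;
    5. bidirectional — TSS within ``bidirectional_window`` of a coding TSS,
       opposite strand, no overlap;
    6. intergenic — none of the above.
    """
    sub = mrnas[mrnas["chrom"] == lnc["chrom"]]
    if sub.empty:
        return "intergenic"
    m_start = sub["start"].to_numpy()
    m_end = sub["end"].to_numpy()
    same = sub["strand"].to_numpy() == lnc["strand"]

    ov = _overlaps(lnc["start"], lnc["end"], m_start, m_end)
    cont = _contained(lnc["start"], lnc["end"], m_start, m_end)
    if (ov & same).any():
        return "exon-sense-overlapping"
    if (cont & same).any():
        return "intronic"
    if (ov & ~same).any():
        return "natural-antisense"
    if (cont & ~same).any():
        return "intronic-antisense"
    # no overlap with any coding gene from here on
    m_tss = np.where(sub["strand"].to_numpy() == "+", m_start, m_end)
    l_tss = lnc["start"] if lnc["strand"] == "+" else lnc["end"]
    if ((~same) & (np.abs(m_tss - l_tss) <= bidirectional_window)).any():
        return "bidirectional"
    return "intergenic"


def classify_all_lncrnas(
    annotation: pd.DataFrame, bidirectional_window: int = 1_000
) -> pd.DataFrame:
    """Positional class for every lncRNA in the annotation."""
    mrnas = annotation[annotation["biotype"] == "mRNA"]
    lncs = annotation[annotation["biotype"] == "lncRNA"]
    classes = [
        classify_lncrna(row, mrnas, bidirectional_window)
        for _, row in lncs.iterrows()
    ]
    return pd.DataFrame(
        {"transcript_id": lncs["transcript_id"].to_numpy(), "lncrna_class": classes}
    )


def find_cis_targets(annotation: pd.DataFrame, window: int = 100_000) -> pd.DataFrame:
    """All (lncRNA, mRNA) pairs within ``window`` bp on the same chromosome.

    The distance is measured between gene-span boundaries (0 when the spans
    overlap); the window boundary is inclusive.
    """
    if window < 0:
        raise ValidationError("cis window must be >= 0")
    mrnas = annotation[annotation["biotype"] == "mRNA"]
    lncs = annotation[annotation["biotype"] == "lncRNA"]
    rows = []
    for chrom, m_sub in mrnas.groupby("chrom"):
        l_sub = lncs[lncs["chrom"] == chrom]
        if l_sub.empty:
            continue
        m_ids = m_sub["transcript_id"].to_numpy()
        m_start = m_sub["start"].to_numpy()
        m_end = m_sub["end"].to_numpy()
        for _, lnc in l_sub.iterrows():
            gap = np.maximum(m_start - lnc["end"], lnc["start"] - m_end)
            dist = np.maximum(gap, 0)
            keep = dist <= window
            for mid, d in zip(m_ids[keep], dist[keep]):
                rows.append((lnc["transcript_id"], mid, int(d)))
    out = pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "distance_bp"])
    return out.sort_values(["lncrna_id", "mrna_id"], ignore_index=True)
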
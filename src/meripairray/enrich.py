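"""Hypergeometric over-representation analysis against user-supplied gene sets.

For a study list of n genes drawn from a universe of N genes, and a gene set
with K members in the universe of which k appear in the study list, the
enrichment p-value is the one-sided tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

Benjamini-Hochberg adjustment is applied across all sets; significance is
called on the raw p-value (p < 0.05 by convention here).  lncRNA function is
inferred by mapping a lncRNA list to the union of its cis-target mRNA gene
symbols and enriching that list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

logger = logging.getLogger("meripairray")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT line)."""

    set_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set '{self.set_id}' is empty")


def hypergeom_enrich(
    study, universe, sets, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """One-sided over-representation test of ``study`` against each gene set.

    Genes outside the universe are dropped from both the study list and the
    sets (with a logged count).  Results are sorted by p-value, ties broken
    by set_id.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    study = set(study)
    dropped = study - universe
    if dropped:
        logger.warning(
            "enrich: dropping %d study genes outside the universe", len(dropped)
        )
    study &= universe
    if not study:
        raise ValidationError("empty study list after intersecting with universe")

    N, n = len(universe), len(study)
    rows = []
    for gs in sets:
        members = gs.members & universe
        K = len(members)
        k = len(members & study)
        # P(X >= k); sf(k-1) is exact, k = 0 gives 1.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.set_id, gs.name, k, n, K, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "n", "K", "N", "p_value"]
    )
    if len(out):
        out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        out["adj_p"] = np.nan
    out["significant"] = out["p_value"] < p_cutoff
    return out.sort_values(["p_value", "set_id"], ignore_index=True)


def lncrna_enrich_via_cis(
    lnc_study,
    cis_targets: pd.DataFrame,
    universe,
    sets,
    symbol_map=None,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Enrich a lncRNA list through the union of its cis-target mRNA symbols.

    Parameters
    ----------
    lnc_study : iterable of lncRNA ids
    cis_targets : DataFrame with columns ``lncrna_id, mrna_id``
    symbol_map : optional mapping mrna_id -> gene symbol (identity if None)
    """
    lnc_study = set(lnc_study)
    pairs = cis_targets[cis_targets["lncrna_id"].isin(lnc_study)]
    with_targets = set(pairs["lncrna_id"])
    orphans = len(lnc_study - with_targets)
    if orphans:
        logger.info(
            "enrich: %d of %d lncRNAs have no cis target and contribute nothing",
            orphans,
            len(lnc_study),
        )
    targets = set(pairs["mrna_id"])
    if symbol_map is not None:
        targets = {symbol_map.get(t, t) for t in targets}
    return hypergeom_enrich(targets, universe, sets, p_cutoff=p_cutoff)
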
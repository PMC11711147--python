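"""Synthetic two-channel MeRIP-array experiments with planted ground truth.

The generator emulates a 3-vs-3 (sham vs SCI) epitranscriptomic microarray:
for every transcript a baseline methylated fraction pi and a baseline
expression level E are drawn; the injured-group values apply planted effects
on the log-odds of pi (so the modified fraction stays inside (0, 1) for any
effect size) and on log2 E.  Each array channel carries a multiplicative
scale factor that spike-in normalization must remove; spike-in probes see
only that factor, never biological noise, which makes the normalization
exactly identifiable.

Raw signals follow the quantification model downstream:

    IP  = A[s, IP]  * E * pi       * 2^N(0, noise_sd)
    Sup = A[s, Sup] * E * (1 - pi) * 2^N(0, noise_sd)
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .config import CHANNELS, GROUP_SCI, GROUP_SHAM, GROUPS, GroupDesign
from .exceptions import ValidationError

logger = logging.getLogger("meripairray")

MODE_HYPER_UP = "hyper-up"
MODE_HYPO_DOWN = "hypo-down"
MODE_HYPER_ONLY = "hyper-only"
MODE_UP_ONLY = "up-only"
MODE_NULL = "null"
PLANTED_MODES = (MODE_HYPER_UP, MODE_HYPO_DOWN, MODE_HYPER_ONLY, MODE_UP_ONLY)

# signs of (methylation effect, expression effect) per planted mode
_MODE_SIGNS = {
    MODE_HYPER_UP: (1, 1),
    MODE_HYPO_DOWN: (-1, -1),
    MODE_HYPER_ONLY: (1, 0),
    MODE_UP_ONLY: (0, 1),
    MODE_NULL: (0, 0),
}


def _default_planted() -> dict:
    return {
        MODE_HYPER_UP: 150,
        MODE_HYPO_DOWN: 150,
        MODE_HYPER_ONLY: 100,
        MODE_UP_ONLY: 100,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The defaults describe a desk-scale version of the study design: 2,000
    mRNAs and 500 lncRNAs on the array, three biological replicates per
    group, a baseline modified fraction around 10% (Beta(2, 18), typical m6A
    stoichiometry), replicate noise of 0.25 log2 units, and per-array-channel
    scale wobble of 0.25 log2 units.  Methylation effects are planted on the
    odds scale (logit-additive); ``meth_effect_log2 = 1`` doubles the odds of
    a transcript being modified.
    """

    n_mrna: int = 2_000
    n_lncrna: int = 500
    n_per_group: int = 3
    planted: dict = field(default_factory=_default_planted)
    meth_effect_log2: float = 1.0
    expr_effect_log2: float = 1.5
    noise_sd_log2: float = 0.25
    array_scale_sd_log2: float = 0.25
    n_spikein: int = 10
    baseline_meth_alpha: float = 2.0
    baseline_meth_beta: float = 18.0
    expr_mu_log2: float = 10.0
    expr_sd_log2: float = 1.5
    cis_fraction: float = 0.5
    fixed_meth_fraction: Optional[float] = None
    fixed_expr_log2: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_mrna < 1 or self.n_lncrna < 0:
            raise ValidationError("need n_mrna >= 1 and n_lncrna >= 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_spikein < 1:
            raise ValidationError("n_spikein must be >= 1")
        if min(self.noise_sd_log2, self.array_scale_sd_log2) < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        unknown = set(self.planted) - set(PLANTED_MODES)
        if unknown:
            raise ValidationError(f"unknown planted modes: {sorted(unknown)}")
        if any(v < 0 for v in self.planted.values()):
            raise ValidationError("planted counts must be >= 0")
        if sum(self.planted.values()) > self.n_mrna + self.n_lncrna:
            raise ValidationError(
                "planted counts exceed the number of transcripts"
            )
        if not 0 <= self.cis_fraction <= 1:
            raise ValidationError("cis_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)


class SimulatedExperiment(NamedTuple):
    intensities: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    design: GroupDesign


def _assign_modes(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign planted modes across both biotypes, proportionally.

    Planted transcripts for each mode are split between mRNAs and lncRNAs in
    proportion to the pool sizes (lncRNA share floored), then drawn without
    replacement so planted effects are not confounded with genomic position.
    """
    n_total = cfg.n_mrna + cfg.n_lncrna
    modes = np.array([MODE_NULL] * n_total, dtype=object)
    mrna_pool = list(rng.permutation(cfg.n_mrna))
    lnc_pool = list(cfg.n_mrna + rng.permutation(cfg.n_lncrna))
    for mode in PLANTED_MODES:
        count = int(cfg.planted.get(mode, 0))
        n_lnc = int(np.floor(count * cfg.n_lncrna / n_total))
        n_lnc = min(n_lnc, len(lnc_pool))
        n_mrna = count - n_lnc
        if n_mrna > len(mrna_pool):
            raise ValidationError(
                f"planted mode '{mode}' does not fit in the mRNA pool"
            )
        for _ in range(n_mrna):
            modes[mrna_pool.pop()] = mode
        for _ in range(n_lnc):
            modes[lnc_pool.pop()] = mode
    return modes


def _place_transcripts(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out genomic coordinates on five chromosomes.

    mRNAs occupy 300-kb slots so neighbouring genes are always farther apart
    than the default cis window.  Each lncRNA is anchored to a random mRNA:
    with probability ``cis_fraction`` at a gap drawn in [0, 100 kb]
    (a genuine cis pair), otherwise at a gap of 135-150 kb, beyond the window
    from every mRNA.
    """
    n_chrom = 5
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    m_chrom = np.array([chroms[i % n_chrom] for i in range(cfg.n_mrna)])
    slot = np.arange(cfg.n_mrna) // n_chrom
    m_start = 10_000 + slot * 300_000
    m_len = rng.integers(1_000, 10_001, size=cfg.n_mrna)
    m_end = m_start + m_len
    m_strand = rng.choice(["+", "-"], size=cfg.n_mrna)

    anchor = rng.integers(0, cfg.n_mrna, size=cfg.n_lncrna)
    is_cis = rng.random(cfg.n_lncrna) < cfg.cis_fraction
    # cis lncRNAs sit within the window of their anchor; a slightly negative
    # gap makes some of them overlap it, exercising the positional classes
    gap = np.where(
        is_cis,
        rng.integers(-3_000, 100_001, size=cfg.n_lncrna),
        rng.integers(135_000, 150_001, size=cfg.n_lncrna),
    )
    l_start = m_end[anchor] + gap
    l_len = rng.integers(500, 3_001, size=cfg.n_lncrna)
    l_end = l_start + l_len
    l_chrom = m_chrom[anchor]
    l_strand = rng.choice(["+", "-"], size=cfg.n_lncrna)

    return (
        np.concatenate([m_chrom, l_chrom]),
        np.concatenate([m_start, l_start]).astype(int),
        np.concatenate([m_end, l_end]).astype(int),
        np.concatenate([m_strand, l_strand]),
    )


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Generate (intensity table, annotation, truth table, design).

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_mrna + cfg.n_lncrna

    width = max(4, len(str(n_total)))
    ids = np.array(
        [f"MRNA_{i + 1:0{width}d}" for i in range(cfg.n_mrna)]
        + [f"LNC_{i + 1:0{width}d}" for i in range(cfg.n_lncrna)]
    )
    symbols = np.array(
        [f"Gene{i + 1:0{width}d}" for i in range(cfg.n_mrna)]
        + [f"Linc{i + 1:0{width}d}" for i in range(cfg.n_lncrna)]
    )
    biotype = np.array(["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna)

    modes = _assign_modes(cfg, rng)
    chrom, start, end, strand = _place_transcripts(cfg, rng)

    # baseline biology
    if cfg.fixed_meth_fraction is not None:
        pi_sham = np.full(n_total, float(cfg.fixed_meth_fraction))
    else:
        pi_sham = rng.beta(cfg.baseline_meth_alpha, cfg.baseline_meth_beta, n_total)
        pi_sham = np.clip(pi_sham, 1e-4, 1 - 1e-4)
    if cfg.fixed_expr_log2 is not None:
        expr_sham = np.full(n_total, 2.0 ** float(cfg.fixed_expr_log2))
    else:
        expr_sham = 2.0 ** rng.normal(cfg.expr_mu_log2, cfg.expr_sd_log2, n_total)

    meth_sign = np.array([_MODE_SIGNS[m][0] for m in modes])
    expr_sign = np.array([_MODE_SIGNS[m][1] for m in modes])

    odds = pi_sham / (1.0 - pi_sham)
    odds_sci = odds * 2.0 ** (meth_sign * cfg.meth_effect_log2)
    # keep unplanted fractions bit-identical (no odds round-trip residue)
    pi_sci = np.where(meth_sign == 0, pi_sham, odds_sci / (1.0 + odds_sci))
    expr_sci = expr_sham * 2.0 ** (expr_sign * cfg.expr_effect_log2)

    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "biotype": biotype,
            "true_mode": modes,
            "true_meth_log2fc": np.log2(pi_sci / pi_sham),
            "true_expr_log2fc": (expr_sign * cfg.expr_effect_log2).astype(float),
        }
    )

    annotation = pd.DataFrame(
        {
            "transcript_id": ids,
            "gene_symbol": symbols,
            "biotype": biotype,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
        }
    )

    samples = [f"{GROUP_SHAM}_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"{GROUP_SCI}_{i + 1}" for i in range(cfg.n_per_group)
    ]
    design = GroupDesign(
        {
            s: (GROUP_SHAM if s.startswith(GROUP_SHAM) else GROUP_SCI)
            for s in samples
        }
    )

    # per-array x channel multiplicative scale (what normalization removes)
    array_factor = {
        (s, c): 2.0 ** rng.normal(0.0, cfg.array_scale_sd_log2)
        for s in samples
        for c in CHANNELS
    }

    spike_ids = np.array(
        [f"SPIKE_{i + 1:02d}" for i in range(cfg.n_spikein)]
    )
    # one shared nominal level: within a sample x channel every spike-in
    # probe reads identically (only the array factor acts on them)
    spike_nominal = np.full(cfg.n_spikein, 2.0**10)

    frames = []
    for s in samples:
        group = design.groups[s]
        pi = pi_sham if group == GROUP_SHAM else pi_sci
        expr = expr_sham if group == GROUP_SHAM else expr_sci
        for channel, frac in (("IP", pi), ("Sup", 1.0 - pi)):
            noise = 2.0 ** rng.normal(0.0, cfg.noise_sd_log2, n_total)
            raw = array_factor[(s, channel)] * expr * frac * noise
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": np.char.add("p_", ids.astype(str)),
                        "transcript_id": ids,
                        "sample_id": s,
                        "channel": channel,
                        "intensity": raw,
                        "is_spike_in": False,
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": spike_ids,
                        "transcript_id": spike_ids,
                        "sample_id": s,
                        "channel": channel,
                        "intensity": array_factor[(s, channel)] * spike_nominal,
                        "is_spike_in": True,
                    }
                )
            )
    intensities = pd.concat(frames, ignore_index=True)
    intensities["group"] = intensities["sample_id"].map(design.groups)
    return SimulatedExperiment(intensities, annotation, truth, design)


@dataclass
class ConfusionSummary:
    """Planted-mode recovery metrics from truth vs called modes."""

    confusion: pd.DataFrame  # rows: true mode, cols: called mode
    sensitivity: dict  # planted concordant mode -> TP / planted
    fdr: dict  # called mode -> FP / called (NaN when nothing called)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"ConfusionSummary(sensitivity={self.sensitivity}, fdr={self.fdr})\n"
            f"{self.confusion}"
        )


def truth_confusion(truth: pd.DataFrame, quadrants: pd.DataFrame) -> ConfusionSummary:
    """Cross-tabulate planted truth modes against called nine-quadrant modes.

    Sensitivity is reported for the planted modes that have a representable
    call (hyper-up, hypo-down); FDR per called mode counts calls whose truth
    differs.
    """
    t_ids = set(truth["transcript_id"])
    q_ids = set(quadrants["transcript_id"])
    if t_ids != q_ids:
        diff = sorted((t_ids ^ q_ids))[:5]
        raise ValidationError(
            f"truth and calls cover different transcripts (e.g. {diff})"
        )
    merged = truth.merge(
        quadrants[["transcript_id", "mode"]], on="transcript_id", how="inner"
    )
    confusion = pd.crosstab(merged["true_mode"], merged["mode"])
    sensitivity = {}
    for mode in (MODE_HYPER_UP, MODE_HYPO_DOWN):
        planted = merged["true_mode"] == mode
        if planted.any():
            sensitivity[mode] = float(
                (planted & (merged["mode"] == mode)).sum() / planted.sum()
            )
    fdr = {}
    for mode in sorted(set(merged["mode"]) - {"none"}):
        called = merged["mode"] == mode
        fdr[mode] = float(
            (called & (merged["true_mode"] != mode)).sum() / called.sum()
        )
    return ConfusionSummary(confusion=confusion, sensitivity=sensitivity, fdr=fdr)
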
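"""Run configuration and sample-design containers.

All thresholds of the analysis live in :class:`RunConfig` so that a run is
fully described by one object (serialised into the run manifest).  Fold-change
cutoffs are expressed on the linear scale; the conjoint (nine-quadrant) cutoff
of 2.0 corresponds to the |log2FC| >= 1 gate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .exceptions import ValidationError

GROUP_SHAM = "sham"
GROUP_SCI = "sci"
GROUPS = (GROUP_SHAM, GROUP_SCI)

CHANNEL_IP = "IP"
CHANNEL_SUP = "Sup"
CHANNELS = (CHANNEL_IP, CHANNEL_SUP)


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters.

    Parameters
    ----------
    fc_cutoff_screen : float
        Minimum linear fold change (inclusive) for the differential screen.
    p_cutoff : float
        Raw p-value gate used by both the screen and the conjoint analysis.
    fc_cutoff_conjoint : float
        Linear fold-change gate of the nine-quadrant analysis
        (2.0 means |log2FC| >= 1).
    cis_window : int
        Genomic window (bp) on each side of a lncRNA within which an mRNA
        counts as a cis target; boundary inclusive.
    ppi_score_cutoff : float
        Edges with combined score strictly greater than this are kept.
    mcode_vwp : float
        MCODE vertex weight percentage: a neighbour joins a cluster when its
        weight >= seed_weight * (1 - vwp).
    mcode_degree_cutoff : int
        Nodes with degree below this receive vertex weight 0.
    mcode_haircut : bool
        Remove singly-connected members from clusters larger than two nodes.
    epsilon : float
        Additive intensity floor applied before log2 to guard raw zeros.
    meth_on_logit : bool
        Run the methylation-layer t-test on log2-odds of the modified
        fraction instead of raw percent values.
    bidirectional_window : int
        Maximum TSS-to-TSS distance (bp) for the "bidirectional" lncRNA class.
    seed : int
        Seed recorded in the manifest; the analysis itself is deterministic.
    """

    fc_cutoff_screen: float = 1.5
    p_cutoff: float = 0.05
    fc_cutoff_conjoint: float = 2.0
    cis_window: int = 100_000
    ppi_score_cutoff: float = 0.4
    mcode_vwp: float = 0.2
    mcode_degree_cutoff: int = 2
    mcode_haircut: bool = True
    epsilon: float = 1.0
    meth_on_logit: bool = False
    bidirectional_window: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.fc_cutoff_screen <= 1 or self.fc_cutoff_conjoint <= 1:
            raise ValidationError("fold-change cutoffs must be > 1")
        if not 0 < self.p_cutoff <= 1:
            raise ValidationError("p_cutoff must lie in (0, 1]")
        if self.cis_window < 0:
            raise ValidationError("cis_window must be >= 0")
        if not 0 <= self.ppi_score_cutoff <= 1:
            raise ValidationError("ppi_score_cutoff must lie in [0, 1]")
        if not 0 <= self.mcode_vwp < 1:
            raise ValidationError("mcode_vwp must lie in [0, 1)")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class GroupDesign:
    """Mapping of sample identifiers to the two experimental groups."""

    groups: dict = field(default_factory=dict)  # sample_id -> group

    def __post_init__(self):
        seen = set(self.groups.values())
        if not seen <= set(GROUPS):
            raise ValidationError(
                f"groups must be within {GROUPS}, got {sorted(seen)}"
            )
        if seen != set(GROUPS):
            raise ValidationError("design must contain both sham and sci samples")

    @property
    def sample_ids(self) -> list:
        return list(self.groups)

    def samples(self, group: str) -> list:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def n_per_group(self) -> dict:
        return {g: len(self.samples(g)) for g in GROUPS}

    def require_replicates(self, minimum: int = 2) -> None:
        for g, n in self.n_per_group.items():
            if n < minimum:
                raise ValidationError(
                    f"group '{g}' has {n} samples; at least {minimum} required"
                )
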
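"""Model/Results interface over the full analysis.

:class:`MeripArrayModel` holds the raw data (probe intensities, annotation,
design) plus a :class:`~meripairray.config.RunConfig`; :meth:`fit` executes
normalization, quantification, both differential layers, the nine-quadrant
integration, lncRNA classification and cis-target mapping, and returns a
:class:`MeripArrayResults` carrying every table.  Enrichment and network
clustering — which need extra inputs (gene sets, a PPI edge list) — hang off
the results object, as do plotting and disk export.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import differential as diff_mod
from . import enrich as enrich_mod
from . import integrate as integrate_mod
from . import network as network_mod
from . import quantify as quantify_mod
from .config import GroupDesign, RunConfig
from .exceptions import ValidationError
from .io import (
    COORD_COMMENT,
    read_annotation,
    read_design,
    read_intensity_table,
    validate_intensities,
    write_table,
)

logger = logging.getLogger("meripairray")


class MeripArrayModel:
    """Two-channel MeRIP-array experiment ready to be analysed.

    Parameters
    ----------
    intensities : DataFrame
        Probe-level raw intensities (validated against the design).
    annotation : DataFrame
        Transcript annotation (0-based half-open coordinates).
    design : GroupDesign
        Sample-to-group assignment (sham vs sci).
    config : RunConfig, optional
        Analysis thresholds; defaults apply when omitted.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        annotation: pd.DataFrame,
        design: GroupDesign,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.design = design
        self.intensities = validate_intensities(intensities, design)
        self.annotation = annotation
        known = set(annotation["transcript_id"])
        measured = set(
            self.intensities.loc[~self.intensities["is_spike_in"], "transcript_id"]
        )
        missing = measured - known
        if missing:
            raise ValidationError(
                f"transcripts without annotation: {sorted(missing)[:5]}"
            )

    @classmethod
    def from_files(
        cls,
        intensity_path,
        annotation_path,
        design_path,
        config: RunConfig | None = None,
    ) -> "MeripArrayModel":
        design = read_design(design_path)
        return cls(
            read_intensity_table(intensity_path, design),
            read_annotation(annotation_path),
            design,
            config,
        )

    def fit(self) -> "MeripArrayResults":
        """Run the core pipeline and return the fitted results."""
        cfg = self.config
        logger.info("[quantify] spike-in normalization (epsilon=%g)", cfg.epsilon)
        normalized = quantify_mod.normalize_spikein(self.intensities, cfg.epsilon)
        quant = quantify_mod.compute_quant(
            quantify_mod.summarize_probes(normalized)
        )
        logger.info("[differential] %d transcripts x 2 layers", quant["transcript_id"].nunique())
        differential = diff_mod.differential_table(
            quant, self.design, self.annotation, cfg
        )
        meth = differential[differential["layer"] == diff_mod.LAYER_METH]
        expr = differential[differential["layer"] == diff_mod.LAYER_EXPR]
        logger.info("[integrate] nine-quadrant conjoint analysis")
        quadrants = integrate_mod.nine_quadrant(meth, expr, cfg)
        venn = integrate_mod.venn_counts(quadrants)
        logger.info("[integrate] lncRNA classification and cis targets (window=%d)", cfg.cis_window)
        lnc_classes = integrate_mod.classify_all_lncrnas(
            self.annotation, cfg.bidirectional_window
        )
        cis = integrate_mod.find_cis_targets(self.annotation, cfg.cis_window)
        return MeripArrayResults(
            model=self,
            normalized=normalized,
            quant=quant,
            differential=differential,
            quadrants=quadrants,
            venn=venn,
            lncrna_classes=lnc_classes,
            cis_targets=cis,
        )


class MeripArrayResults:
    """Fitted tables of one analysis run, with export / follow-up methods."""

    def __init__(
        self,
        model: MeripArrayModel,
        normalized: pd.DataFrame,
        quant: pd.DataFrame,
        differential: pd.DataFrame,
        quadrants: pd.DataFrame,
        venn: dict,
        lncrna_classes: pd.DataFrame,
        cis_targets: pd.DataFrame,
    ):
        self.model = model
        self.config = model.config
        self.design = model.design
        self.normalized = normalized
        self.quant = quant
        self.differential = differential
        self.quadrants = quadrants
        self.venn_counts = venn
        self.lncrna_classes = lncrna_classes
        self.cis_targets = cis_targets

    # ------------------------------------------------------------------ views
    @property
    def diff_methylation(self) -> pd.DataFrame:
        return self.differential[
            self.differential["layer"] == diff_mod.LAYER_METH
        ].reset_index(drop=True)

    @property
    def diff_expression(self) -> pd.DataFrame:
        return self.differential[
            self.differential["layer"] == diff_mod.LAYER_EXPR
        ].reset_index(drop=True)

    def status_counts(self) -> pd.DataFrame:
        return diff_mod.status_counts(self.differential)

    def mode_counts(self) -> pd.DataFrame:
        return (
            self.quadrants.groupby(["biotype", "mode"])
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["biotype", "mode"], ignore_index=True)
        )

    def summary(self) -> str:
        """Human-readable run summary (screen counts and conjoint modes)."""
        lines = ["MeRIP-array analysis summary", "=" * 28]
        n = self.design.n_per_group
        lines.append(
            f"design: {n['sham']} sham vs {n['sci']} sci; "
            f"{self.quant['transcript_id'].nunique()} transcripts"
        )
        lines.append(
            f"screen: fold change >= {self.config.fc_cutoff_screen}, "
            f"p < {self.config.p_cutoff}"
        )
        lines.append("")
        lines.append("differential screen counts (layer / biotype):")
        for (layer, biotype), sub in self.status_counts().groupby(
            ["layer", "biotype"]
        ):
            parts = ", ".join(
                f"{s}={c}" for s, c in zip(sub["status"], sub["count"]) if s != "ns"
            )
            lines.append(f"  {layer:<12} {biotype:<7} {parts or 'none'}")
        lines.append("")
        lines.append(
            f"nine-quadrant modes (|log2FC| >= "
            f"{_log2_str(self.config.fc_cutoff_conjoint)}, p < {self.config.p_cutoff}):"
        )
        for biotype, entry in self.venn_counts.items():
            lines.append(
                f"  {biotype:<7} hyper-up={entry['hyper_up']} "
                f"hypo-down={entry['hypo_down']} "
                f"(meth={entry['n_meth']}, expr={entry['n_expr']}, "
                f"both={entry['n_both']})"
            )
        lines.append("")
        lines.append("lncRNA positional classes:")
        counts = self.lncrna_classes["lncrna_class"].value_counts()
        total = int(counts.sum()) or 1
        for cls in integrate_mod.LNC_CLASSES:
            if cls in counts:
                lines.append(
                    f"  {cls:<24} {counts[cls]:>5} ({100 * counts[cls] / total:.2f}%)"
                )
        lines.append(f"cis-target pairs (window {self.config.cis_window} bp): "
                     f"{len(self.cis_targets)}")
        return "\n".join(lines)

    # ------------------------------------------------------------- follow-ups
    def enrich(self, sets, study=None, universe=None, p_cutoff=None) -> pd.DataFrame:
        """Over-representation of a study list (default: DME mRNA symbols).

        The default universe is every annotated mRNA gene symbol on the
        array; the default study list is the concordant-mode (hyper-up /
        hypo-down) mRNAs.
        """
        ann = self.model.annotation
        symbols = ann.set_index("transcript_id")["gene_symbol"]
        if universe is None:
            universe = set(ann.loc[ann["biotype"] == "mRNA", "gene_symbol"])
        if study is None:
            dme = self.quadrants[
                (self.quadrants["biotype"] == "mRNA")
                & (self.quadrants["mode"].isin(["hyper-up", "hypo-down"]))
            ]["transcript_id"]
            study = set(symbols.reindex(dme))
        return enrich_mod.hypergeom_enrich(
            study, universe, sets, p_cutoff=p_cutoff or self.config.p_cutoff
        )

    def enrich_lncrna_via_cis(
        self, sets, lnc_study=None, universe=None, p_cutoff=None
    ) -> pd.DataFrame:
        """Enrich a lncRNA list through its cis-target mRNA symbols."""
        ann = self.model.annotation
        if universe is None:
            universe = set(ann.loc[ann["biotype"] == "mRNA", "gene_symbol"])
        if lnc_study is None:
            lnc_study = set(
                self.quadrants[
                    (self.quadrants["biotype"] == "lncRNA")
                    & (self.quadrants["mode"].isin(["hyper-up", "hypo-down"]))
                ]["transcript_id"]
            )
        symbol_map = dict(zip(ann["transcript_id"], ann["gene_symbol"]))
        return enrich_mod.lncrna_enrich_via_cis(
            lnc_study,
            self.cis_targets,
            universe,
            sets,
            symbol_map=symbol_map,
            p_cutoff=p_cutoff or self.config.p_cutoff,
        )

    def network(self, edges: pd.DataFrame):
        """Filter a PPI edge list and detect MCODE modules.

        Returns (graph, ranked clusters).
        """
        cfg = self.config
        graph = network_mod.build_graph(edges, cfg.ppi_score_cutoff)
        clusters = network_mod.mcode_find_clusters(
            graph,
            vwp=cfg.mcode_vwp,
            haircut=cfg.mcode_haircut,
            degree_cutoff=cfg.mcode_degree_cutoff,
        )
        return graph, clusters

    def plot_nine_quadrant(self, biotype: str = "mRNA", ax=None):
        """Scatter of methylation vs expression log2 fold changes."""
        from .plotting import plot_nine_quadrant

        return plot_nine_quadrant(
            self.quadrants, self.config.fc_cutoff_conjoint, biotype=biotype, ax=ax
        )

    # ----------------------------------------------------------------- export
    def save(self, out_dir) -> Path:
        """Write all result tables plus a JSON run manifest; returns its path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.quant, out / "quant.tsv")
        write_table(self.diff_methylation, out / "diff_methylation.tsv")
        write_table(self.diff_expression, out / "diff_expression.tsv")
        write_table(self.quadrants, out / "quadrants.tsv")
        write_table(self.cis_targets, out / "cis_targets.tsv", coord_comment=True)
        write_table(self.lncrna_classes, out / "lncrna_classes.tsv")
        with open(out / "venn_counts.json", "w") as fh:
            json.dump(self.venn_counts, fh, indent=2, sort_keys=True)
        manifest = {
            "package": "meripairray",
            "config": self.config.to_dict(),
            "design": dict(self.design.groups),
            "n_transcripts": int(self.quant["transcript_id"].nunique()),
            "status_counts": {
                f"{r.layer}/{r.biotype}/{r.status}": int(r.count)
                for r in self.status_counts().itertuples()
            },
            "venn_counts": self.venn_counts,
            "coordinate_convention": COORD_COMMENT.lstrip("# "),
        }
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return path


def _log2_str(fc: float) -> str:
    import math

    v = math.log2(fc)
    return f"{v:g}"
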
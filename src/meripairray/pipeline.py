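"""File-to-file orchestration of the full analysis.

``run_pipeline`` reads the external inputs, fits the model, runs the
optional enrichment and network stages, writes every result table into the
output directory and records the exact configuration plus input paths in
``manifest.json`` — re-running from that manifest reproduces the outputs
byte-identically.  Any stage failure aborts with the stage name in the
message.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx

from .config import RunConfig
from .exceptions import MeripArrayError, StageError
from .io import read_gmt, read_ppi, write_table
from .model import MeripArrayModel
from .network import clusters_to_frame

logger = logging.getLogger("meripairray")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except MeripArrayError as exc:
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(
    config: RunConfig,
    intensity_path,
    annotation_path,
    design_path,
    gmt_path=None,
    ppi_path=None,
    out_dir="results",
) -> Path:
    """Execute every stage and write the result bundle; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = _stage("load")(MeripArrayModel.from_files)(
        intensity_path, annotation_path, design_path, config
    )
    results = _stage("fit")(model.fit)()
    manifest_path = _stage("export")(results.save)(out)

    enrichment_written = False
    if gmt_path is not None:
        logger.info("[enrich] gene-set over-representation from %s", gmt_path)
        sets = _stage("enrich")(read_gmt)(gmt_path)
        enrichment = _stage("enrich")(results.enrich)(sets)
        write_table(enrichment, out / "enrichment.tsv")
        enrichment_written = True
    else:
        logger.info("[enrich] no GMT supplied; enrichment stage skipped")

    clusters_written = False
    if ppi_path is not None:
        logger.info("[network] PPI filtering and MCODE clustering from %s", ppi_path)
        edges = _stage("network")(read_ppi)(ppi_path)
        graph, clusters = _stage("network")(results.network)(edges)
        write_table(clusters_to_frame(clusters), out / "clusters.tsv")
        nx.write_graphml(graph, out / "network.graphml")
        clusters_written = True
    else:
        logger.info("[network] no PPI edge list supplied; network stage skipped")

    # extend the manifest with provenance so the run can be replayed
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    manifest["inputs"] = {
        "intensities": str(intensity_path),
        "annotation": str(annotation_path),
        "design": str(design_path),
        "gmt": str(gmt_path) if gmt_path else None,
        "ppi": str(ppi_path) if ppi_path else None,
    }
    manifest["outputs_written"] = sorted(
        p.name for p in out.iterdir() if p.name != "manifest.json"
    )
    manifest["stages_skipped"] = [
        s
        for s, done in (("enrich", enrichment_written), ("network", clusters_written))
        if not done
    ]
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path


def run_from_manifest(manifest_path, out_dir) -> Path:
    """Replay a recorded run: same config, same inputs, fresh output directory."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    inputs = manifest["inputs"]
    return run_pipeline(
        config,
        inputs["intensities"],
        inputs["annotation"],
        inputs["design"],
        gmt_path=inputs.get("gmt"),
        ppi_path=inputs.get("ppi"),
        out_dir=out_dir,
    )
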
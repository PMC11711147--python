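"""Readers and writers for the pipeline's external tab-separated formats.

Conventions
-----------
* All genomic coordinates are 0-based, half-open (BED convention); files that
  carry coordinates state this in a ``#`` header comment.
* Real numbers are written with 12 significant digits so that a written table
  read back reproduces identical values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CHANNELS, GroupDesign
from .exceptions import ValidationError

logger = logging.getLogger("meripairray")

FLOAT_FORMAT = "%.12g"
COORD_COMMENT = "# coordinates: 0-based, half-open (BED convention)"

INTENSITY_COLUMNS = [
    "probe_id",
    "transcript_id",
    "sample_id",
    "channel",
    "intensity",
    "is_spike_in",
]
ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_symbol",
    "biotype",
    "chrom",
    "start",
    "end",
    "strand",
]
PPI_COLUMNS = ["node_a", "node_b", "combined_score"]

BIOTYPES = ("mRNA", "lncRNA")

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def _parse_bool(series: pd.Series, what: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = ~s.isin(_TRUTHY | _FALSY)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"{what}: unparseable boolean at row {row}")
    return s.isin(_TRUTHY)


def read_design(path) -> GroupDesign:
    """Read a two-column design table (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, ["sample_id", "group"], "design table")
    if df["sample_id"].duplicated().any():
        raise ValidationError("design table: duplicate sample_id")
    return GroupDesign(dict(zip(df["sample_id"], df["group"])))


def write_design(design: GroupDesign, path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(design.groups), "group": list(design.groups.values())}
    )
    write_table(df, path)


def read_intensity_table(path, design: GroupDesign) -> pd.DataFrame:
    """Read and validate a raw probe-level two-channel intensity table.

    Returns one row per probe x sample x channel with the sample's group
    merged in.  Row numbers in error messages are 1-based data rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")
    df = df[INTENSITY_COLUMNS].copy()
    for col in ("probe_id", "transcript_id", "sample_id", "channel"):
        df[col] = df[col].astype(str)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    df["is_spike_in"] = _parse_bool(df["is_spike_in"], "intensity table")
    return validate_intensities(df, design)


def validate_intensities(df: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Enforce the intensity-table contract; returns the table with group."""
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")

    unknown_channels = set(df["channel"]) - set(CHANNELS)
    if unknown_channels:
        raise ValidationError(
            f"intensity table: unknown channels {sorted(unknown_channels)}"
        )

    unknown_samples = set(df["sample_id"]) - set(design.sample_ids)
    if unknown_samples:
        raise ValidationError(
            f"intensity table: unknown sample_id {sorted(unknown_samples)}"
        )
    absent = set(design.sample_ids) - set(df["sample_id"])
    if absent:
        raise ValidationError(
            f"intensity table: design samples absent from table: {sorted(absent)}"
        )

    neg = df["intensity"].to_numpy() < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 1
        raise ValidationError(
            f"intensity table: negative intensity at row {row}"
        )

    for sample in design.sample_ids:
        have = set(df.loc[df["sample_id"] == sample, "channel"])
        for channel in CHANNELS:
            if channel not in have:
                raise ValidationError(
                    f"intensity table: sample '{sample}' is missing "
                    f"channel '{channel}'"
                )

    if df.duplicated(["probe_id", "sample_id", "channel"]).any():
        dup = df[df.duplicated(["probe_id", "sample_id", "channel"])].iloc[0]
        raise ValidationError(
            "intensity table: duplicate (probe_id, sample_id, channel): "
            f"({dup['probe_id']}, {dup['sample_id']}, {dup['channel']})"
        )

    spike = df[df["is_spike_in"]]
    present = set(zip(spike["sample_id"], spike["channel"]))
    for sample in design.sample_ids:
        for channel in CHANNELS:
            if (sample, channel) not in present:
                raise ValidationError(
                    f"intensity table: no spike-in probe for sample "
                    f"'{sample}' channel '{channel}'"
                )

    out = df.copy()
    out["group"] = out["sample_id"].map(design.groups)
    return out


def read_annotation(path) -> pd.DataFrame:
    """Read the BED-like transcript annotation table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    df = df[ANNOTATION_COLUMNS].copy()
    df["start"] = pd.to_numeric(df["start"]).astype(int)
    df["end"] = pd.to_numeric(df["end"]).astype(int)
    bad_bt = set(df["biotype"]) - set(BIOTYPES)
    if bad_bt:
        raise ValidationError(f"annotation: unknown biotype {sorted(bad_bt)}")
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValidationError(f"annotation: unknown strand {sorted(bad_strand)}")
    bad = df["start"] >= df["end"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"annotation: start >= end at row {row}")
    if df["transcript_id"].duplicated().any():
        raise ValidationError("annotation: duplicate transcript_id")
    return df


def read_gmt(path):
    """Parse a GMT gene-set file into a list of GeneSet objects.

    Duplicate members within a set are collapsed; sets left empty are dropped
    with a logged warning.  A line with fewer than three fields is an error.
    """
    from .enrich import GeneSet  # local import to avoid a cycle

    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT {path}: line {lineno} has fewer than 3 fields"
                )
            set_id, name = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                logger.warning("GMT %s: dropping empty set '%s'", path, set_id)
                continue
            sets.append(GeneSet(set_id=set_id, name=name, members=members))
    return sets


def read_ppi(path) -> pd.DataFrame:
    """Read a PPI edge list (node_a, node_b, combined_score in [0, 1])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, PPI_COLUMNS, "PPI table")
    df = df[PPI_COLUMNS].copy()
    df["combined_score"] = pd.to_numeric(df["combined_score"])
    bad = (df["combined_score"] < 0) | (df["combined_score"] > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"PPI table: combined_score outside [0,1] at row {row}")
    return df


def write_table(df: pd.DataFrame, path, coord_comment: bool = False) -> None:
    """Write a TSV with 12-significant-digit reals (round-trip safe)."""
    with open(path, "w") as fh:
        if coord_comment:
            fh.write(COORD_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    """Read back any table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
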